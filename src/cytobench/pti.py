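"""Pseudotime inference and criteria for trajectory-inference (PTI) studies.

The trajectory is inferred by a deterministic, dependency-light pipeline:
PCA to 5 components, k-means with k = 3 x (number of time points), a
minimum spanning tree over the cluster centroids, the root chosen as the
centroid richest in earliest-time-point events, and per-event pseudotime =
geodesic MST distance of the event's centroid plus the event's projection
onto the edge toward the root, min-max normalized to [0, 1].

Criteria (all in [0, 1], rounded to 3 decimals, larger = better):

* Conformance (Ca): Kendall's tau-b between pseudotime and the ordinal
  collection time, mapped to [0, 1].
* Smoothness (Cb): 1 - p from a paired one-sided t-test across markers that
  expression profiles binned along pseudotime are smoother (lower roughness)
  than under a seeded random ordering of the same events.
* Robustness (Cc): mean |Spearman rho| between pseudotimes inferred on
  paired 80% subsamples, compared on shared events.
* Correspondence (Cd): 1 - fraction of proteins whose peak-activation
  pseudotime precedes their pathway's key protein.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse.csgraph import minimum_spanning_tree, shortest_path
from scipy.spatial.distance import squareform, pdist
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .errors import ArgumentError, EvaluationError, MetadataError
from .fcs import SampleAnnotation, StudyKind
from .csi import CriterionResult
from .pipeline import ProcessedData

__all__ = [
    "Pseudotime",
    "PathwayHierarchy",
    "read_pathway_hierarchy",
    "infer_trajectory",
    "criterion_conformance",
    "criterion_smoothness",
    "criterion_robustness_pti",
    "criterion_correspondence_pti",
    "evaluate_pti",
]

N_BINS = 50  # equal-count pseudotime bins for smoothness and peak detection


@dataclass
class Pseudotime:
    t: np.ndarray              # per-event scalar in [0, 1]
    root: int                  # root centroid index
    method_seed: int

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=np.float64)
        if self.t.size and (self.t.min() != 0.0 or self.t.max() != 1.0):
            raise EvaluationError("pseudotime must be min-max normalized to [0, 1]")


@dataclass
class PathwayHierarchy:
    """Ordered protein lists per signaling cascade; first entry = key protein
    (the first to reach maximal expression)."""

    pathways: list[list[str]]

    def __post_init__(self) -> None:
        for pw in self.pathways:
            if len(pw) < 2:
                raise ArgumentError("each pathway needs at least two proteins")
            if pw.count(pw[0]) != 1:
                raise ArgumentError("key protein must be unique within its pathway")

    @property
    def proteins(self) -> list[str]:
        return [p for pw in self.pathways for p in pw]


def read_pathway_hierarchy(path: str | os.PathLike) -> PathwayHierarchy:
    """Semicolon-separated table: one pathway per column, key protein first."""
    df = pd.read_csv(path, sep=";", dtype=str)
    pathways = []
    for col in df.columns:
        prots = [str(v).strip() for v in [col] + df[col].tolist()
                 if str(v).strip() not in ("", "nan")]
        pathways.append(prots)
    return PathwayHierarchy(pathways=pathways)


def _ordinal_time_per_event(data: ProcessedData, annotation: SampleAnnotation) -> np.ndarray:
    if annotation.study_kind != StudyKind.PTI or not annotation.label_order:
        raise MetadataError("PTI annotation with ordered time points is required")
    md = data.data
    ords = np.array([annotation.ordinal_of(annotation.label_of(s)) for s in md.sample_ids])
    return ords[md.origin]


def _pseudotime_from_matrix(X: np.ndarray, ordinal: np.ndarray, k: int, seed: int) -> tuple[np.ndarray, int]:
    n = X.shape[0]
    n_comp = min(5, X.shape[1], n)
    Z = PCA(n_components=n_comp, random_state=seed).fit_transform(X)
    k = max(2, min(k, n // 10))
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed)
    labels = km.fit_predict(Z)
    cents = km.cluster_centers_

    D = squareform(pdist(cents))
    mst = minimum_spanning_tree(D)
    geo = shortest_path(mst, directed=False)

    earliest = ordinal.min()
    frac_early = np.array([
        np.mean(ordinal[labels == c] == earliest) if np.any(labels == c) else 0.0
        for c in range(k)
    ])
    root = int(np.argmax(frac_early))
    d_root = geo[root]

    # parent of each centroid on its MST path to the root
    mst_sym = mst.toarray()
    mst_sym = mst_sym + mst_sym.T
    parent = np.full(k, -1)
    order = np.argsort(d_root)
    for c in order[1:]:
        nbrs = np.nonzero(mst_sym[c])[0]
        parent[c] = nbrs[np.argmin(d_root[nbrs])]

    t = np.empty(n)
    for c in range(k):
        rows = labels == c
        if not np.any(rows):
            continue
        if parent[c] < 0:  # root cluster: project onto its outgoing edge
            nbrs = np.nonzero(mst_sym[c])[0]
            ref = nbrs[np.argmax(d_root[nbrs])] if nbrs.size else c
            direction = cents[ref] - cents[c]
        else:
            direction = cents[c] - cents[parent[c]]
        norm = np.linalg.norm(direction)
        if norm == 0:
            proj = np.zeros(rows.sum())
        else:
            u = direction / norm
            proj = (Z[rows] - cents[c]) @ u
            proj = np.clip(proj, -norm / 2, norm / 2)
        t[rows] = d_root[c] + proj
    t = t - t.min()
    tmax = t.max()
    if tmax == 0:
        raise EvaluationError("degenerate trajectory: constant pseudotime")
    return t / tmax, root


def infer_trajectory(
    data: ProcessedData,
    annotation: SampleAnnotation,
    seed: int = 0,
) -> Pseudotime:
    """Infer a per-event pseudotime in [0, 1]; deterministic for a fixed seed."""
    ordinal = _ordinal_time_per_event(data, annotation)
    if len(np.unique(ordinal)) < 2:
        raise MetadataError("trajectory inference requires at least two time points")
    k = 3 * len(annotation.label_order)
    t, root = _pseudotime_from_matrix(data.data.values, ordinal, k, seed)
    return Pseudotime(t=t, root=root, method_seed=seed)


def criterion_conformance(
    pt: Pseudotime,
    data: ProcessedData,
    annotation: SampleAnnotation,
) -> CriterionResult:
    """Ca = (Kendall tau-b(pseudotime, ordinal collection time) + 1) / 2."""
    ordinal = _ordinal_time_per_event(data, annotation)
    tau = stats.kendalltau(pt.t, ordinal, variant="b").statistic
    if not np.isfinite(tau):
        raise EvaluationError("Kendall tau undefined (constant input)")
    return CriterionResult("Ca", (tau + 1.0) / 2.0)


def _roughness(values: np.ndarray, order: np.ndarray, n_bins: int = N_BINS) -> np.ndarray:
    """Per-marker roughness of bin-mean profiles along an event ordering.

    R_m = sum of squared successive bin-mean differences / Var(marker).
    """
    bins = np.array_split(order, n_bins)
    means = np.stack([values[b].mean(axis=0) for b in bins if b.size])
    var = values.var(axis=0)
    var[var == 0] = np.inf
    return np.sum(np.diff(means, axis=0) ** 2, axis=0) / var


def smoothness_pvalue(roughness: np.ndarray, naive: np.ndarray) -> float:
    """Paired one-sided t-test of H1: roughness < naive, across markers.

    Returns p; all-zero differences give 0.5 by convention (no evidence).
    """
    d = np.asarray(roughness, dtype=np.float64) - np.asarray(naive, dtype=np.float64)
    if np.all(d == 0):
        return 0.5
    res = stats.ttest_rel(roughness, naive, alternative="less")
    return float(res.pvalue)


def criterion_smoothness(
    pt: Pseudotime,
    data: ProcessedData,
    seed: int = 0,
) -> CriterionResult:
    """Cb = 1 - p, p from the paired test of pseudotime-ordered vs random-ordered roughness."""
    values = data.data.values
    if values.shape[1] < 3:
        raise ArgumentError("smoothness requires at least 3 markers")
    order = np.argsort(pt.t, kind="stable")
    rng = np.random.default_rng(seed)
    naive_order = rng.permutation(values.shape[0])
    r = _roughness(values, order)
    r_naive = _roughness(values, naive_order)
    p = smoothness_pvalue(r, r_naive)
    return CriterionResult("Cb", 1.0 - p)


def criterion_robustness_pti(
    data: ProcessedData,
    annotation: SampleAnnotation,
    seed: int = 0,
    reps: int = 5,
    subsample_fraction: float = 0.8,
) -> CriterionResult:
    """Cc: mean |Spearman| between pseudotimes of paired 80% subsamples.

    |rho| absorbs the arbitrary direction of an inferred trajectory.
    """
    if reps < 2:
        raise ArgumentError(f"robustness needs reps >= 2, got {reps}")
    ordinal = _ordinal_time_per_event(data, annotation)
    X = data.data.values
    n = X.shape[0]
    k = 3 * max(2, len(annotation.label_order))
    rng = np.random.default_rng(seed)
    rhos = []
    for r in range(reps):
        ia = np.sort(rng.choice(n, size=int(subsample_fraction * n), replace=False))
        ib = np.sort(rng.choice(n, size=int(subsample_fraction * n), replace=False))
        ta, _ = _pseudotime_from_matrix(X[ia], ordinal[ia], k, seed + 2 * r)
        tb, _ = _pseudotime_from_matrix(X[ib], ordinal[ib], k, seed + 2 * r + 1)
        shared, pa, pb = np.intersect1d(ia, ib, return_indices=True)
        if shared.size < 10:
            continue
        rho = stats.spearmanr(ta[pa], tb[pb]).statistic
        if np.isfinite(rho):
            rhos.append(abs(rho))
    if not rhos:
        raise EvaluationError("no valid subsample pairs for robustness")
    return CriterionResult("Cc", float(np.clip(np.mean(rhos), 0.0, 1.0)))


def peak_activation_bins(pt: Pseudotime, data: ProcessedData, n_bins: int = N_BINS) -> dict[str, int]:
    """Peak-activation bin (argmax of the 50-bin profile; ties -> earliest)."""
    md = data.data
    order = np.argsort(pt.t, kind="stable")
    bins = [b for b in np.array_split(order, n_bins) if b.size]
    profile = np.stack([md.values[b].mean(axis=0) for b in bins])  # bins x markers
    return {m: int(np.argmax(profile[:, j])) for j, m in enumerate(md.markers)}


def criterion_correspondence_pti(
    pt: Pseudotime,
    data: ProcessedData,
    hierarchy: PathwayHierarchy,
) -> CriterionResult:
    """Cd = 1 - (proteins peaking strictly before their pathway's key protein) / total."""
    md = data.data
    for prot in hierarchy.proteins:
        if prot not in md.markers:
            raise EvaluationError(f"hierarchy protein {prot!r} absent from the panel")
    peaks = peak_activation_bins(pt, data)
    total = 0
    violations = 0
    for pw in hierarchy.pathways:
        key_peak = peaks[pw[0]]
        total += len(pw)
        for prot in pw[1:]:
            if peaks[prot] < key_peak:
                violations += 1
    return CriterionResult("Cd", 1.0 - violations / total)


def evaluate_pti(
    data: ProcessedData,
    annotation: SampleAnnotation,
    seed: int = 0,
    reps: int = 5,
    hierarchy: PathwayHierarchy | None = None,
) -> list[CriterionResult]:
    """All applicable PTI criteria for one processed dataset."""
    pt = infer_trajectory(data, annotation, seed=seed)
    results = [
        criterion_conformance(pt, data, annotation),
        criterion_smoothness(pt, data, seed=seed),
        criterion_robustness_pti(data, annotation, seed=seed, reps=reps),
    ]
    if hierarchy is not None:
        results.append(criterion_correspondence_pti(pt, data, hierarchy))
    return results
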