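"""Criteria for cell-subpopulation-identification (CSI) studies.

A processed dataset is scored under four independent criteria, each a value
in [0, 1] rounded to three decimals (larger = better):

* Accuracy (Ca): how well per-sample cluster-abundance profiles predict the
  condition under leave-one-sample-out cross-validation.
* Tightness (Cb): mean silhouette coefficient of the clustering, rescaled
  from [-1, 1] to [0, 1].
* Robustness (Cc): mean adjusted Rand index between the full clustering and
  re-clusterings of bootstrap subsamples.
* Correspondence (Cd): fraction of known directional markers recovered with
  the right sign and a top-ranking effect size (optional; needs a
  ground-truth marker list).
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import adjusted_rand_score, balanced_accuracy_score, silhouette_score
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .errors import ArgumentError, EvaluationError, MetadataError
from .fcs import SampleAnnotation
from .pipeline import ProcessedData

__all__ = [
    "ClusterModel",
    "KnownMarkerSet",
    "CriterionResult",
    "read_known_markers",
    "cluster_cells",
    "criterion_accuracy",
    "criterion_tightness",
    "criterion_robustness_csi",
    "criterion_correspondence_csi",
    "evaluate_csi",
]


@dataclass
class CriterionResult:
    criterion: str          # "Ca" | "Cb" | "Cc" | "Cd"
    value: float            # in [0, 1], rounded to 3 decimals
    category: str | None = None  # filled in by the ranking stage

    def __post_init__(self) -> None:
        v = round(float(self.value), 3)
        if not (0.0 <= v <= 1.0):
            raise EvaluationError(f"criterion {self.criterion} value {v} outside [0, 1]")
        self.value = v


@dataclass
class ClusterModel:
    k: int
    labels: np.ndarray
    centroids: np.ndarray
    seed: int


@dataclass
class KnownMarkerSet:
    """Known differential markers between two named conditions.

    ``direction`` is relative to the stated condition pair: "up" means the
    marker is higher in ``conditions[0]`` than in ``conditions[1]``.
    """

    conditions: tuple[str, str]
    entries: list[tuple[str, str]]  # (marker, "up"|"down")

    def __post_init__(self) -> None:
        names = [m for m, _ in self.entries]
        if len(set(names)) != len(names):
            raise ArgumentError("duplicate markers in known-marker set")
        for _, d in self.entries:
            if d not in ("up", "down"):
                raise ArgumentError(f"direction must be up or down, got {d!r}")


def read_known_markers(path: str | os.PathLike) -> KnownMarkerSet:
    """CSV whose header row names the two conditions, then marker,direction rows."""
    df = pd.read_csv(path, dtype=str)
    if df.shape[1] != 2:
        raise MetadataError("known-marker CSV must have exactly two columns")
    conditions = (str(df.columns[0]).strip(), str(df.columns[1]).strip())
    entries = [(str(r.iloc[0]).strip(), str(r.iloc[1]).strip().lower()) for _, r in df.iterrows()]
    return KnownMarkerSet(conditions=conditions, entries=entries)


def cluster_cells(data: ProcessedData, k: int, seed: int) -> ClusterModel:
    """k-means (k-means++ init, 10 restarts) on the processed marker matrix."""
    if k < 2:
        raise ArgumentError(f"cluster count k must be >= 2, got {k}")
    X = data.data.values
    if X.shape[0] < 10 * k:
        raise ArgumentError(
            f"clustering needs >= 10*k events ({10 * k}), got {X.shape[0]}"
        )
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed)
    labels = km.fit_predict(X)
    return ClusterModel(k=k, labels=labels, centroids=km.cluster_centers_, seed=seed)


def _abundance_features(labels: np.ndarray, origin: np.ndarray, n_samples: int, k: int) -> np.ndarray:
    feats = np.zeros((n_samples, k))
    for si in range(n_samples):
        rows = origin == si
        if rows.sum() == 0:
            continue
        feats[si] = np.bincount(labels[rows], minlength=k) / rows.sum()
    return feats


def criterion_accuracy(
    data: ProcessedData,
    clusters: ClusterModel,
    annotation: SampleAnnotation,
    seed: int = 0,
) -> CriterionResult:
    """Ca: leave-one-sample-out balanced accuracy of condition prediction.

    Each sample is summarized by its vector of cluster-abundance fractions;
    an L2-regularized logistic classifier (features standardized within the
    training fold, balanced class weights so the held-out sample's class is
    not penalized for being the fold minority) predicts the held-out
    sample's condition.
    """
    md = data.data
    conditions = np.array([annotation.label_of(s) for s in md.sample_ids])
    counts = pd.Series(conditions).value_counts()
    if (counts < 2).any():
        raise MetadataError(
            "accuracy criterion requires at least two samples per condition "
            f"(violated by {sorted(counts[counts < 2].index)})"
        )
    X = _abundance_features(clusters.labels, md.origin, len(md.sample_ids), clusters.k)
    y_true, y_pred = [], []
    for held in range(len(md.sample_ids)):
        train = np.arange(len(md.sample_ids)) != held
        if len(set(conditions[train])) < 2:
            continue
        clf = make_pipeline(
            StandardScaler(),
            LogisticRegression(max_iter=2000, class_weight="balanced", random_state=seed),
        )
        clf.fit(X[train], conditions[train])
        y_true.append(conditions[held])
        y_pred.append(clf.predict(X[held][None, :])[0])
    if not y_true:
        raise EvaluationError("no cross-validation folds with both conditions")
    return CriterionResult("Ca", balanced_accuracy_score(y_true, y_pred))


def criterion_tightness(
    data: ProcessedData,
    clusters: ClusterModel,
    max_events: int = 5000,
    seed: int = 0,
) -> CriterionResult:
    """Cb = (mean silhouette + 1) / 2, on a subsample of at most ``max_events``."""
    X = data.data.values
    labels = clusters.labels
    if len(np.unique(labels)) < 2:
        raise EvaluationError("silhouette undefined: all events in one cluster")
    if X.shape[0] > max_events:
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(X.shape[0], size=max_events, replace=False))
        X, labels = X[idx], labels[idx]
        if len(np.unique(labels)) < 2:
            raise EvaluationError("silhouette undefined on subsample")
    s = silhouette_score(X, labels, metric="euclidean")
    return CriterionResult("Cb", (s + 1.0) / 2.0)


def criterion_robustness_csi(
    data: ProcessedData,
    k: int,
    seed: int = 0,
    reps: int = 5,
    subsample_fraction: float = 0.8,
) -> CriterionResult:
    """Cc: mean adjusted Rand index between full and subsample clusterings."""
    if reps < 2:
        raise ArgumentError(f"robustness needs reps >= 2, got {reps}")
    full = cluster_cells(data, k=k, seed=seed)
    n = data.data.n_events
    rng = np.random.default_rng(seed)
    aris = []
    for r in range(reps):
        idx = np.sort(rng.choice(n, size=int(subsample_fraction * n), replace=False))
        sub = ProcessedData(data=data.data.take(idx), removed_mask=data.removed_mask, log=data.log)
        labels = cluster_cells(sub, k=k, seed=seed + 1 + r).labels
        aris.append(adjusted_rand_score(full.labels[idx], labels))
    return CriterionResult("Cc", float(np.clip(np.mean(aris), 0.0, 1.0)))


def criterion_correspondence_csi(
    data: ProcessedData,
    annotation: SampleAnnotation,
    known: KnownMarkerSet,
) -> CriterionResult | None:
    """Cd: fraction of known markers recovered with the right sign and rank.

    Per marker, the effect is the standardized difference of condition
    medians; a known marker counts as recovered when its sign matches the
    stated direction and its |effect| ranks in the top
    max(|known|, 25% of markers).  Returns None when the set is empty
    (datasets without a complete biomarker list skip this criterion).
    """
    if not known.entries:
        return None
    md = data.data
    for marker, _ in known.entries:
        if marker not in md.markers:
            raise EvaluationError(f"known marker {marker!r} absent from the selected panel")
    labels = md.labels_per_event()
    c1, c2 = known.conditions
    rows1, rows2 = labels == c1, labels == c2
    if rows1.sum() == 0 or rows2.sum() == 0:
        raise EvaluationError(f"conditions {known.conditions} not found in the annotation")
    effects = np.zeros(md.n_channels)
    for j in range(md.n_channels):
        a, b = md.values[rows1, j], md.values[rows2, j]
        scale = np.sqrt(0.5 * (a.std() ** 2 + b.std() ** 2))
        effects[j] = (np.median(a) - np.median(b)) / (scale if scale > 0 else 1.0)
    top_n = max(len(known.entries), int(np.ceil(0.25 * md.n_channels)))
    rank_cut = np.sort(np.abs(effects))[::-1][min(top_n, md.n_channels) - 1]
    recovered = 0
    for marker, direction in known.entries:
        j = md.marker_index(marker)
        sign_ok = effects[j] > 0 if direction == "up" else effects[j] < 0
        if sign_ok and np.abs(effects[j]) >= rank_cut:
            recovered += 1
    return CriterionResult("Cd", recovered / len(known.entries))


def evaluate_csi(
    data: ProcessedData,
    annotation: SampleAnnotation,
    k: int | None = None,
    seed: int = 0,
    reps: int = 5,
    known: KnownMarkerSet | None = None,
) -> list[CriterionResult]:
    """All applicable CSI criteria for one processed dataset.

    Default k = 4 x number of conditions: enough granularity for abundance
    features without starving clusters.
    """
    if k is None:
        k = 4 * len(set(annotation.labels))
    clusters = cluster_cells(data, k=k, seed=seed)
    results = [
        criterion_accuracy(data, clusters, annotation, seed=seed),
        criterion_tightness(data, clusters, seed=seed),
        criterion_robustness_csi(data, k=k, seed=seed, reps=reps),
    ]
    if known is not None and known.entries:
        cd = criterion_correspondence_csi(data, annotation, known)
        if cd is not None:
            results.append(cd)
    return results
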