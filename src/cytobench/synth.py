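"""Seeded synthetic cytometry data with known ground truth.

Every stage of the pipeline is testable offline against fixtures produced
here.  The generators emulate the features preprocessing exists to fix:

* log-normal marker mixtures over several cell populations per sample,
* condition-specific marker shifts with a known direction (CSI),
* linear spillover mixing across detection channels,
* slow multiplicative acquisition-time drift plus optional abrupt anomaly
  segments (event-rate spike and level shift),
* time-course data driven by a latent pseudotime with ordered
  sigmoid-pulse activation cascades (PTI).

FC-mode data adds Gaussian detector noise (negative values occur); MC-mode
zero-inflates low signals.  All generators are bit-reproducible for a fixed
seed and emit exactly the formats the pipeline consumes (FCS files,
metadata CSV, known-marker CSV, semicolon-separated hierarchy table).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

from .compensate import SpilloverMatrix
from .csi import KnownMarkerSet
from .errors import ArgumentError
from .fcs import ExpressionFrame, SampleAnnotation, StudyKind, Technique, write_fcs
from .pti import PathwayHierarchy

__all__ = [
    "SyntheticSpec",
    "SyntheticDataset",
    "generate_spillover",
    "generate_csi_dataset",
    "generate_pti_dataset",
    "corrupt_structure",
]


@dataclass
class SyntheticSpec:
    """Study conditions for the generators.

    CSI defaults: two conditions x three samples of 1500 events over 10
    channels and 3 populations, three planted directional markers shifted by
    2 sigma on the log scale (two up, one down), population 0 twice as
    abundant in the second condition, 5% spillover, 10% drift.  PTI
    defaults: 39 proteins in 7 cascades, 4 time points x 500 events,
    log-scale noise sigma = 0.3.
    """

    study_kind: StudyKind = StudyKind.CSI
    technique: Technique = Technique.FC
    n_channels: int = 10
    n_populations: int = 3
    samples_per_group: int = 3
    events_per_sample: int = 1500
    effect: dict[str, float] = field(default_factory=dict)  # marker -> log-scale shift (+/-)
    effect_sigma: float = 2.0
    n_effect_markers: int = 3
    abundance_factor: float = 2.0
    spillover_intensity: float = 0.05
    drift_amplitude: float = 0.1
    anomaly: tuple[float, float, float] | None = None  # (start_frac, length_frac, rate_magnitude)
    noise_sigma: float = 0.3
    n_pathways: int = 7
    n_proteins: int = 39
    n_timepoints: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_channels", "n_populations", "samples_per_group", "events_per_sample"):
            if getattr(self, name) < 1:
                raise ArgumentError(f"{name} must be >= 1")
        if not (0.0 <= self.spillover_intensity < 0.3):
            raise ArgumentError("spillover_intensity must lie in [0, 0.3)")
        if self.anomaly is not None:
            start, length, mag = self.anomaly
            if not (0.0 < start < 1.0 and 0.0 < length < 1.0 and start + length <= 1.0):
                raise ArgumentError("anomaly start/length fractions must lie in (0, 1)")
            if mag <= 1.0:
                raise ArgumentError("anomaly magnitude must exceed 1")


@dataclass
class SyntheticDataset:
    """Paths plus the ground truth needed by the recovery tests."""

    fcs_paths: list[str]
    metadata_path: str
    annotation: SampleAnnotation
    spillover: SpilloverMatrix
    truth: dict
    known_markers: KnownMarkerSet | None = None
    known_markers_path: str | None = None
    hierarchy: PathwayHierarchy | None = None
    hierarchy_path: str | None = None


def generate_spillover(n_channels: int, intensity: float, seed: int = 0) -> SpilloverMatrix:
    """Unit-diagonal spillover with Uniform(0, intensity) off-diagonals that
    decay with channel distance; always invertible at intensity < 0.3."""
    if not (0.0 <= intensity < 0.3):
        raise ArgumentError("spillover intensity must lie in [0, 0.3)")
    rng = np.random.default_rng(seed)
    S = np.eye(n_channels)
    for i in range(n_channels):
        for j in range(n_channels):
            if i == j:
                continue
            decay = np.exp(-(abs(i - j) - 1) / 2.0)
            S[i, j] = rng.uniform(0.0, intensity) * decay
    channels = [f"Ch{i + 1:02d}" for i in range(n_channels)]
    return SpilloverMatrix(channels=channels, S=S)


def _marker_names(n: int) -> list[str]:
    return [f"M{i + 1:02d}" for i in range(n)]


def _acquisition(
    rng: np.random.Generator,
    true_values: np.ndarray,
    S: np.ndarray,
    technique: Technique,
    drift_amplitude: float,
    anomaly: tuple[float, float, float] | None,
):
    """Mix through spillover, apply drift over Time, inject the anomaly.

    Returns (observed values, time vector, anomaly mask) with events in
    acquisition (time) order.
    """
    n = true_values.shape[0]
    observed = true_values @ S
    t = np.sort(rng.uniform(0.0, 1000.0, size=n))
    drift = 1.0 - drift_amplitude * (t / t[-1])
    observed = observed * drift[:, None]

    anomaly_mask = np.zeros(n, dtype=bool)
    if anomaly is not None:
        start, length, mag = anomaly
        t0, t1 = 1000.0 * start, 1000.0 * (start + length)
        # rate spike: extra events crammed into the window, with a level
        # shift on the first half of the channels
        n_extra = int(n * length * (mag - 1.0))
        base = true_values[rng.integers(0, n, size=n_extra)]
        shift_cols = np.arange(observed.shape[1] // 2)
        base = base.copy()
        base[:, shift_cols] *= 3.0
        extra = (base @ S)
        t_extra = np.sort(rng.uniform(t0, t1, size=n_extra))
        extra *= (1.0 - drift_amplitude * (t_extra / 1000.0))[:, None]

        t = np.concatenate([t, t_extra])
        observed = np.vstack([observed, extra])
        anomaly_mask = np.concatenate([anomaly_mask, np.ones(n_extra, dtype=bool)])
        order = np.argsort(t, kind="stable")
        t, observed, anomaly_mask = t[order], observed[order], anomaly_mask[order]

    if technique == Technique.FC:
        observed = observed + rng.normal(0.0, 3.0, size=observed.shape)
    else:
        low = observed < np.quantile(observed, 0.3, axis=0)
        zero = rng.uniform(size=observed.shape) < 0.3
        observed = np.where(low & zero, 0.0, observed)
    return observed, t, anomaly_mask


def _write_frame(out_dir, sample_id, technique, channels, markers, values, t) -> str:
    frame = ExpressionFrame(
        sample_id=sample_id,
        technique=technique,
        channels=channels + ["Time"],
        markers=markers + ["Time"],
        values=np.column_stack([values, t]),
    )
    return write_fcs(frame, os.path.join(out_dir, f"{sample_id}.fcs"))


def generate_csi_dataset(spec: SyntheticSpec, out_dir: str | os.PathLike) -> SyntheticDataset:
    """Two-condition dataset with planted directional markers and a planted
    abundance shift; writes FCS files, metadata CSV and the known-marker CSV."""
    if spec.study_kind != StudyKind.CSI:
        raise ArgumentError("generate_csi_dataset requires a CSI spec")
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    nch, npop = spec.n_channels, spec.n_populations
    markers = _marker_names(nch)
    channels = [f"Ch{i + 1:02d}" for i in range(nch)]

    # population templates on the log scale
    loc = rng.uniform(1.0, 3.0, size=(npop, nch))
    log_sigma = 0.4

    # planted directional effects (marker -> log shift), condition B vs A.
    # The shift is effect_sigma times the marker's TOTAL log-scale spread
    # (within-population noise + between-population dispersion): a
    # well-established differential marker separates conditions relative to
    # the marker's overall variability, not just its measurement noise
    sd_total = np.sqrt(log_sigma**2 + loc.var(axis=0))
    effect = dict(spec.effect)
    if not effect:
        picks = rng.choice(nch, size=min(spec.n_effect_markers, nch), replace=False)
        for rank, j in enumerate(picks):
            sign = -1.0 if rank == len(picks) - 1 else 1.0  # two up, one down
            effect[markers[j]] = float(sign * spec.effect_sigma * sd_total[j])

    # population weights; condition B doubles population 0
    base_w = rng.dirichlet(np.full(npop, 5.0))
    w_b = base_w.copy()
    w_b[0] *= spec.abundance_factor
    w_b /= w_b.sum()
    weights = {"A": base_w, "B": w_b}

    spill = generate_spillover(nch, spec.spillover_intensity, seed=spec.seed + 1)
    effect_cols = {markers.index(m): delta for m, delta in effect.items()}

    fcs_paths, entries = [], []
    truth: dict = {
        "population_labels": {},
        "anomaly_mask": {},
        "effect": effect,
        "weights": {k: v.tolist() for k, v in weights.items()},
    }
    for cond in ("A", "B"):
        for rep in range(spec.samples_per_group):
            sid = f"sample_{cond}{rep + 1}"
            srng = np.random.default_rng(rng.integers(0, 2**31 - 1))
            pop = srng.choice(npop, size=spec.events_per_sample, p=weights[cond])
            z = loc[pop] + srng.normal(0.0, log_sigma, size=(spec.events_per_sample, nch))
            if cond == "B":
                for j, delta in effect_cols.items():
                    z[:, j] += delta
            true_vals = np.exp(z) * 10.0
            obs, t, amask = _acquisition(
                srng, true_vals, spill.S, spec.technique,
                spec.drift_amplitude, spec.anomaly,
            )
            # acquisition may interleave anomaly events; keep labels aligned
            labels = np.full(obs.shape[0], -1, dtype=int)
            labels[~amask] = pop
            fcs_paths.append(_write_frame(out_dir, sid, spec.technique, channels, markers, obs, t))
            entries.append((sid, cond))
            truth["population_labels"][sid] = labels.tolist()
            truth["anomaly_mask"][sid] = amask.tolist()

    annotation = SampleAnnotation(study_kind=StudyKind.CSI, entries=entries)
    metadata_path = os.path.join(out_dir, "metadata.csv")
    with open(metadata_path, "w") as fh:
        fh.write("filename,condition\n")
        fh.writelines(f"{f},{c}\n" for f, c in entries)

    km_entries = [(m, "up" if d > 0 else "down") for m, d in sorted(effect.items())]
    known = KnownMarkerSet(conditions=("B", "A"), entries=km_entries)
    known_path = os.path.join(out_dir, "known_markers.csv")
    with open(known_path, "w") as fh:
        fh.write("B,A\n")
        fh.writelines(f"{m},{d}\n" for m, d in km_entries)

    with open(os.path.join(out_dir, "truth.json"), "w") as fh:
        json.dump({"effect": effect, "weights": truth["weights"]}, fh, indent=1)

    return SyntheticDataset(
        fcs_paths=fcs_paths,
        metadata_path=metadata_path,
        annotation=annotation,
        spillover=spill,
        truth=truth,
        known_markers=known,
        known_markers_path=known_path,
    )


def _sigmoid_pulse(u: np.ndarray, mid: float, width: float = 0.15, tau: float = 0.05) -> np.ndarray:
    """Rise-then-fall activation: the product of two opposing sigmoids, peaked at ``mid``."""
    rise = 1.0 / (1.0 + np.exp(-(u - (mid - width)) / tau))
    fall = 1.0 / (1.0 + np.exp((u - (mid + width)) / tau))
    return rise * fall


def generate_pti_dataset(spec: SyntheticSpec, out_dir: str | os.PathLike) -> SyntheticDataset:
    """Time-course dataset driven by a latent pseudotime with an ordered
    activation cascade per pathway; writes FCS files, metadata CSV and the
    semicolon-separated pathway-hierarchy table."""
    if spec.study_kind != StudyKind.PTI:
        raise ArgumentError("generate_pti_dataset requires a PTI spec")
    if spec.n_proteins < 2 * spec.n_pathways:
        raise ArgumentError("need at least two proteins per pathway")
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    prots = [f"P{i + 1:02d}" for i in range(spec.n_proteins)]
    channels = [f"Ch{i + 1:02d}" for i in range(spec.n_proteins)]
    # deal proteins round-robin into pathways, in cascade order
    pathways: list[list[str]] = [[] for _ in range(spec.n_pathways)]
    for i, p in enumerate(prots):
        pathways[i % spec.n_pathways].append(p)
    mids: dict[str, float] = {}
    for pw_idx, pw in enumerate(pathways):
        offs = 0.05 * (pw_idx / max(1, spec.n_pathways - 1))
        for pos, p in enumerate(pw):
            mids[p] = 0.12 + offs + 0.72 * pos / max(1, len(pw) - 1)

    spill = generate_spillover(spec.n_proteins, spec.spillover_intensity, seed=spec.seed + 1)
    fcs_paths, entries = [], []
    latent: dict[str, list[float]] = {}
    n_tp = spec.n_timepoints
    for ti in range(n_tp):
        for rep in range(spec.samples_per_group):
            sid = f"tp{ti + 1}_s{rep + 1}" if spec.samples_per_group > 1 else f"tp{ti + 1}"
            srng = np.random.default_rng(rng.integers(0, 2**31 - 1))
            lo = max(0.0, ti / n_tp - 0.08)
            hi = min(1.0, (ti + 1) / n_tp + 0.08)
            u = srng.uniform(lo, hi, size=spec.events_per_sample)
            base = 1.0
            amp = 8.0
            mean = np.stack([base + amp * _sigmoid_pulse(u, mids[p]) for p in prots], axis=1)
            z = np.log(mean) + srng.normal(0.0, spec.noise_sigma, size=mean.shape)
            true_vals = np.exp(z) * 10.0
            # without an anomaly, acquisition preserves event order (event i
            # is simply assigned the i-th sorted timestamp), so the latent u
            # stays row-aligned with the written file
            obs, t, _ = _acquisition(
                srng, true_vals, spill.S, spec.technique, spec.drift_amplitude, None
            )
            fcs_paths.append(_write_frame(out_dir, sid, spec.technique, channels, prots, obs, t))
            entries.append((sid, str(ti)))
            latent[sid] = u.tolist()

    annotation = SampleAnnotation(
        study_kind=StudyKind.PTI,
        entries=entries,
        label_order={str(i): i + 1 for i in range(n_tp)},
    )
    metadata_path = os.path.join(out_dir, "metadata.csv")
    with open(metadata_path, "w") as fh:
        fh.write("filename,timepoint\n")
        fh.writelines(f"{f},{tp}\n" for f, tp in entries)

    hierarchy = PathwayHierarchy(pathways=pathways)
    hierarchy_path = os.path.join(out_dir, "Pathway_Hierarchy.csv")
    depth = max(len(pw) for pw in pathways)
    with open(hierarchy_path, "w") as fh:
        fh.write(";".join(pw[0] for pw in pathways) + "\n")
        for row in range(1, depth):
            fh.write(";".join(pw[row] if row < len(pw) else "" for pw in pathways) + "\n")

    truth = {"latent": latent, "midpoints": mids, "pathways": pathways}
    return SyntheticDataset(
        fcs_paths=fcs_paths,
        metadata_path=metadata_path,
        annotation=annotation,
        spillover=spill,
        truth=truth,
        hierarchy=hierarchy,
        hierarchy_path=hierarchy_path,
    )


def corrupt_structure(values: np.ndarray, origin: np.ndarray, seed: int = 0) -> np.ndarray:
    """Structure-destroying comparator for ranking-sanity checks.

    Z-scores each channel within each sample (washing out condition shifts)
    and then applies an independent random channel permutation per sample
    (breaking marker identity across samples).  A pipeline that preserves
    planted structure should beat this on accuracy and correspondence.
    """
    rng = np.random.default_rng(seed)
    out = values.copy()
    for si in np.unique(origin):
        rows = origin == si
        block = out[rows]
        mu, sd = block.mean(axis=0), block.std(axis=0)
        sd[sd == 0] = 1.0
        block = (block - mu) / sd
        out[rows] = block[:, rng.permutation(values.shape[1])]
    return out
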