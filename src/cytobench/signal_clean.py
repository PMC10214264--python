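"""Acquisition-time signal cleaning.

Flow-rate spikes, clogs and unstable acquisition leave contiguous stretches
of anomalous events along the Time channel.  Each method bins a file's
events into B equal-count Time bins (B = max(10, n/500) by default) and
removes whole bins:

* FAI flags bins whose event rate deviates from the across-bin median by
  more than k robust SDs, or whose per-channel median sits more than k
  event-level robust SDs from the file median (two passes).
* FCL scores each bin by the centred-log-ratio composition of events over
  per-channel intensity classes and flags runs of >= 2 consecutive bins
  whose summed CLR deviation exceeds a robust changepoint threshold.
* FCU iteratively removes the single worst bin judged by the mean absolute
  robust z-score over eight per-bin summary statistics (mean, median,
  5th/20th/80th/95th percentiles, variance, skewness) until the worst bin
  falls below the threshold.

Cleaning operates per file (anomalies are acquisition-specific), is a pure
event-subset operation, and returns a removal mask aligned to the original
merged event order.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .errors import ArgumentError, SignalCleanError
from .fcs import MergedData

__all__ = ["apply_signal_clean"]

_MADN = 1.4826  # normal-consistency factor for the median absolute deviation


def _madn(x: np.ndarray) -> float:
    return float(np.median(np.abs(x - np.median(x)))) * _MADN


def _default_bins(n: int) -> int:
    return max(10, n // 500)


def _time_bins(t: np.ndarray, n_bins: int) -> list[np.ndarray]:
    """Indices (into the file's event order) of equal-count Time bins."""
    order = np.argsort(t, kind="stable")
    return [chunk for chunk in np.array_split(order, n_bins) if chunk.size]


def _fai_mask(values: np.ndarray, t: np.ndarray, k: float, n_bins: int) -> np.ndarray:
    bins = _time_bins(t, n_bins)
    file_median = np.median(values, axis=0)
    file_scale = np.array([_madn(values[:, j]) for j in range(values.shape[1])])
    file_scale[file_scale == 0] = np.inf  # constant channels cannot deviate

    def rates(active: list[int]) -> np.ndarray:
        r = np.empty(len(active))
        for a, bi in enumerate(active):
            span = t[bins[bi]].max() - t[bins[bi]].min()
            r[a] = bins[bi].size / max(span, 1e-12)
        return r

    flagged = np.zeros(len(bins), dtype=bool)
    for _ in range(2):  # two-pass: re-estimate rate stats without flagged bins
        active = [i for i in range(len(bins)) if not flagged[i]]
        if len(active) < 3:
            break
        r = rates(active)
        r_med = np.median(r)
        # floor the scale at 10% of the median rate: with few bins the MAD
        # of the rates is itself noisy, and sub-10% rate wobble is normal
        # acquisition jitter, not a flow anomaly
        r_scale = max(_madn(r), 0.1 * abs(r_med))
        if r_scale == 0:
            r_scale = np.inf
        changed = False
        for a, bi in enumerate(active):
            med = np.median(values[bins[bi]], axis=0)
            med_dev = np.abs(med - file_median) / file_scale
            rate_dev = abs(r[a] - r_med) / r_scale
            if rate_dev > k or np.any(med_dev > k):
                flagged[bi] = True
                changed = True
        if not changed:
            break
    mask = np.zeros(values.shape[0], dtype=bool)
    for bi in np.nonzero(flagged)[0]:
        mask[bins[bi]] = True
    return mask


def _clr_scores(values: np.ndarray, bins: list[np.ndarray], n_classes: int = 5) -> np.ndarray:
    """Per-bin summed squared CLR deviation of the intensity-class profile."""
    n, p = values.shape
    eps = 0.5 / max(1, n // len(bins))
    scores = np.zeros(len(bins))
    for j in range(p):
        col = values[:, j]
        qs = np.quantile(col, np.linspace(0, 1, n_classes + 1)[1:-1])
        classes = np.searchsorted(qs, col)
        profiles = np.zeros((len(bins), n_classes))
        for bi, rows in enumerate(bins):
            frac = np.bincount(classes[rows], minlength=n_classes) / rows.size
            logf = np.log(frac + eps)
            profiles[bi] = logf - logf.mean()  # centred log-ratio
        scores += np.sum((profiles - np.median(profiles, axis=0)) ** 2, axis=1)
    return scores


def _fcl_mask(values: np.ndarray, t: np.ndarray, threshold: float,
              min_run: int, n_bins: int) -> np.ndarray:
    bins = _time_bins(t, n_bins)
    scores = _clr_scores(values, bins)
    scale = _madn(scores)
    cut = np.median(scores) + threshold * (scale if scale > 0 else np.inf)
    over = scores > cut
    flagged = np.zeros(len(bins), dtype=bool)
    i = 0
    while i < len(bins):  # keep only runs of >= min_run consecutive bins
        if over[i]:
            j = i
            while j < len(bins) and over[j]:
                j += 1
            if j - i >= min_run:
                flagged[i:j] = True
            i = j
        else:
            i += 1
    mask = np.zeros(values.shape[0], dtype=bool)
    for bi in np.nonzero(flagged)[0]:
        mask[bins[bi]] = True
    return mask


_FCU_STATS = (
    lambda x: np.mean(x, axis=0),
    lambda x: np.median(x, axis=0),
    lambda x: np.percentile(x, 5, axis=0),
    lambda x: np.percentile(x, 20, axis=0),
    lambda x: np.percentile(x, 80, axis=0),
    lambda x: np.percentile(x, 95, axis=0),
    lambda x: np.var(x, axis=0),
    lambda x: stats.skew(x, axis=0),
)


def _fcu_mask(values: np.ndarray, t: np.ndarray, threshold: float,
              max_removed_fraction: float, n_bins: int) -> np.ndarray:
    bins = _time_bins(t, n_bins)
    n = values.shape[0]
    summary = np.stack([
        np.column_stack([fn(values[rows]) for fn in _FCU_STATS]).ravel()
        for rows in bins
    ])  # bins x (channels * 8)
    active = list(range(len(bins)))
    removed: list[int] = []
    while len(active) > 2:
        sub = summary[active]
        med = np.median(sub, axis=0)
        scale = np.median(np.abs(sub - med), axis=0) * _MADN
        scale[scale == 0] = np.inf
        dev = np.mean(np.abs(sub - med) / scale, axis=1)
        worst = int(np.argmax(dev))
        if dev[worst] < threshold:
            break
        would_remove = sum(bins[b].size for b in removed) + bins[active[worst]].size
        if would_remove > max_removed_fraction * n:
            raise SignalCleanError(
                "signal cleaning would remove more than "
                f"{max_removed_fraction:.0%} of events; review threshold/"
                "max_removed_fraction parameters"
            )
        removed.append(active.pop(worst))
    mask = np.zeros(n, dtype=bool)
    for bi in removed:
        mask[bins[bi]] = True
    return mask


def apply_signal_clean(
    data: MergedData,
    method: str,
    params: dict | None = None,
) -> tuple[MergedData, np.ndarray]:
    """Clean each file and return (retained data, per-original-event mask).

    The mask is True for removed events and aligns with the event order of
    the input.  Retained events are bit-identical to the input.
    """
    if method == "NON":
        return data.copy(), np.zeros(data.n_events, dtype=bool)
    if method not in ("FAI", "FCL", "FCU"):
        raise ArgumentError(f"unknown signal cleaning method {method!r}")
    if data.time is None:
        raise SignalCleanError(f"{method}: Time channel required for signal cleaning")
    params = params or {}
    mask = np.zeros(data.n_events, dtype=bool)
    for si in range(len(data.sample_ids)):
        rows = np.nonzero(data.origin == si)[0]
        vals, t = data.values[rows], data.time[rows]
        n_bins = params.get("bins") or _default_bins(rows.size)
        if method == "FAI":
            sub = _fai_mask(vals, t, float(params.get("k", 3.0)), n_bins)
        elif method == "FCL":
            sub = _fcl_mask(vals, t, float(params.get("threshold", 3.0)),
                            int(params.get("min_run", 2)), n_bins)
        else:
            sub = _fcu_mask(vals, t, float(params.get("threshold", 2.0)),
                            float(params.get("max_removed_fraction", 0.5)), n_bins)
        mask[rows] = sub
    removed_frac = mask.mean()
    if removed_frac > float(params.get("max_removed_fraction", 0.5)):
        raise SignalCleanError(
            f"signal cleaning flagged {removed_frac:.0%} of events (> limit); "
            "review the method parameters"
        )
    keep = np.nonzero(~mask)[0]
    return data.take(keep), mask
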