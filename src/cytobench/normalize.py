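"""Cross-sample normalization.

Long acquisitions and multi-batch studies show signal decay and technical
shifts between files.  The three methods here align each sample's
per-channel distribution to the cohort: GSN shifts density peaks onto the
cross-sample mean peak positions, WPS warps decile anchors onto their
cross-sample means, and FDN performs full percentile-grid quantile
normalization.  Every per-sample map is monotone piecewise-linear, and
event counts are never changed.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import stats

from .errors import ArgumentError, NormalizationError
from .fcs import MergedData

__all__ = ["apply_normalization"]

log = logging.getLogger(__name__)

_MIN_EVENTS = 50  # below this, density/quantile estimates are unreliable


def _density_peaks(x: np.ndarray, grid: np.ndarray, max_peaks: int) -> np.ndarray:
    """Locations of the up-to-``max_peaks`` highest KDE peaks, by descending
    density (so truncating keeps the dominant modes, not the leftmost)."""
    sub = x
    if sub.size > 2000:
        sub = np.sort(sub)[np.linspace(0, sub.size - 1, 2000).astype(int)]
    if np.ptp(sub) == 0:
        return np.array([sub[0]])
    try:
        kde = stats.gaussian_kde(sub)
    except np.linalg.LinAlgError:
        return np.array([np.median(sub)])
    dens = kde(grid)
    interior = np.nonzero((dens[1:-1] >= dens[:-2]) & (dens[1:-1] > dens[2:]))[0] + 1
    if interior.size == 0:
        interior = np.array([int(np.argmax(dens))])
    # ignore minor wiggles: a real second mode carries substantial density
    interior = interior[dens[interior] >= 0.25 * dens[interior].max()]
    top = interior[np.argsort(dens[interior])[::-1][:max_peaks]]
    return grid[top]


def _piecewise_map(x: np.ndarray, src: np.ndarray, dst: np.ndarray,
                   lo: float, hi: float) -> np.ndarray:
    """Monotone piecewise-linear map sending src anchors to dst anchors."""
    xs = np.concatenate(([lo], src, [hi]))
    ys = np.concatenate(([lo + (dst[0] - src[0])], dst, [hi + (dst[-1] - src[-1])]))
    # enforce strict monotonicity of the knots
    keep = np.concatenate(([True], np.diff(xs) > 0))
    xs, ys = xs[keep], ys[keep]
    ys = np.maximum.accumulate(ys)
    return np.interp(x, xs, ys)


def _gsn_channel(cols: list[np.ndarray], max_peaks: int) -> list[np.ndarray]:
    lo = min(c.min() for c in cols)
    hi = max(c.max() for c in cols)
    if hi == lo:
        return cols
    grid = np.linspace(lo, hi, 512)
    peaks = [
        _density_peaks(c, grid, max_peaks) if c.size >= _MIN_EVENTS else None
        for c in cols
    ]
    usable = [p for p in peaks if p is not None]
    if not usable:
        return cols
    # when samples disagree on peak count, keep each sample's n_peaks
    # densest modes, then sort by location so peaks correspond across samples
    n_peaks = min(p.size for p in usable)
    aligned = np.vstack([np.sort(p[:n_peaks]) for p in usable])
    target = aligned.mean(axis=0)
    out = []
    ui = 0
    span = hi - lo
    for c, p in zip(cols, peaks):
        if p is None:
            log.warning("GSN: sample with < %d events left unnormalized", _MIN_EVENTS)
            out.append(c)
            continue
        src = aligned[ui]
        ui += 1
        out.append(_piecewise_map(c, src, target, lo - span, hi + span))
    return out


def _anchor_channel(cols: list[np.ndarray], qs: np.ndarray) -> list[np.ndarray]:
    anchors = []
    for c in cols:
        if c.size < _MIN_EVENTS:
            anchors.append(None)
        else:
            anchors.append(np.quantile(c, qs))
    usable = [a for a in anchors if a is not None]
    if not usable:
        return cols
    target = np.mean(np.vstack(usable), axis=0)
    lo = min(c.min() for c in cols)
    hi = max(c.max() for c in cols)
    span = max(hi - lo, 1e-12)
    out = []
    for c, a in zip(cols, anchors):
        if a is None:
            log.warning("normalize: sample with < %d events left unnormalized", _MIN_EVENTS)
            out.append(c)
            continue
        out.append(_piecewise_map(c, a, target, lo - span, hi + span))
    return out


def apply_normalization(
    data: MergedData,
    method: str,
    params: dict | None = None,
) -> MergedData:
    """Normalize every analysis channel across the merged samples."""
    if method == "NON":
        return data.copy()
    if method not in ("GSN", "WPS", "FDN"):
        raise ArgumentError(f"unknown normalization method {method!r}")
    if len(data.sample_ids) < 2:
        raise NormalizationError("normalization requires at least 2 samples")
    params = params or {}
    values = data.values.copy()
    sample_rows = [np.nonzero(data.origin == si)[0] for si in range(len(data.sample_ids))]
    for j in range(data.n_channels):
        cols = [values[rows, j] for rows in sample_rows]
        if method == "GSN":
            new_cols = _gsn_channel(cols, int(params.get("max_peaks", 2)))
        elif method == "WPS":
            n_anchors = int(params.get("n_anchors", 9))
            qs = np.linspace(0, 1, n_anchors + 2)[1:-1]  # deciles by default
            new_cols = _anchor_channel(cols, qs)
        else:  # FDN: dense percentile grid = quantile normalization
            n_anchors = int(params.get("n_anchors", 101))
            qs = np.linspace(0, 1, n_anchors)
            new_cols = _anchor_channel(cols, qs)
        for rows, col in zip(sample_rows, new_cols):
            values[rows, j] = col
    return data.copy(values=values)
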