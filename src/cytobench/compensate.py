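"""Spillover compensation.

A spillover matrix S has S[i, j] = the fraction of channel i's true signal
observed in channel j (unit diagonal), so an observed event row x relates
to the true abundances y by x = y @ S.  Compensation solves for y, either
by direct inversion (FLC, CMP, MTC) or under a non-negativity constraint
(CTS, suited to mass cytometry where true abundances cannot be negative).
ATS first refines the spillover estimate from single-stain control files by
iterative robust regression before inverting.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .errors import ArgumentError, CompensationError
from .fcs import ExpressionFrame, MergedData

__all__ = ["SpilloverMatrix", "read_spillover_csv", "spillover_from_keywords", "apply_compensation"]

log = logging.getLogger(__name__)


@dataclass
class SpilloverMatrix:
    channels: list[str]
    S: np.ndarray

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=np.float64)
        n = len(self.channels)
        if self.S.shape != (n, n):
            raise ArgumentError("spillover matrix must be square over its channel list")
        if not np.allclose(np.diag(self.S), 1.0, atol=1e-9):
            raise ArgumentError("spillover diagonal must be 1")
        off = self.S[~np.eye(n, dtype=bool)]
        if off.size and (off.min() < 0 or off.max() >= 1):
            raise ArgumentError("off-diagonal spillover must lie in [0, 1)")
        if not np.isfinite(np.linalg.cond(self.S)) or np.linalg.cond(self.S) > 1e12:
            raise CompensationError("spillover matrix is singular or near-singular")

    def reordered(self, channels: list[str]) -> "SpilloverMatrix":
        """Restrict/permute to ``channels`` (identity rows for missing ones)."""
        n = len(channels)
        S = np.eye(n)
        idx = {ch: i for i, ch in enumerate(self.channels)}
        for a, ca in enumerate(channels):
            for b, cb in enumerate(channels):
                if ca in idx and cb in idx:
                    S[a, b] = self.S[idx[ca], idx[cb]]
        return SpilloverMatrix(channels=list(channels), S=S)


def read_spillover_csv(path: str) -> SpilloverMatrix:
    """Spillover CSV: header row = channel names, square numeric body."""
    df = pd.read_csv(path)
    return SpilloverMatrix(channels=[str(c) for c in df.columns], S=df.to_numpy(dtype=np.float64))


def spillover_from_keywords(keywords: dict[str, str]) -> SpilloverMatrix | None:
    """Parse the $SPILLOVER (or SPILL) keyword: ``n,ch1,..,chn,v11,v12,...``."""
    raw = keywords.get("$SPILLOVER") or keywords.get("SPILL") or keywords.get("$SPILL")
    if not raw:
        return None
    parts = [p.strip() for p in raw.split(",")]
    try:
        n = int(parts[0])
        channels = parts[1 : 1 + n]
        vals = np.array([float(v) for v in parts[1 + n : 1 + n + n * n]]).reshape(n, n)
    except (ValueError, IndexError) as exc:
        raise CompensationError(f"malformed $SPILLOVER keyword: {exc}") from exc
    return SpilloverMatrix(channels=channels, S=vals)


def _invert(values: np.ndarray, S: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.solve(S.T, values.T).T
    except np.linalg.LinAlgError as exc:
        raise CompensationError("singular spillover matrix") from exc


def _nnls_unmix(values: np.ndarray, S: np.ndarray) -> np.ndarray:
    """Per-event y = argmin_{y>=0} ||x - y S||_2.

    The unconstrained solution is used wherever it is already non-negative;
    only events with negative components go through scipy's NNLS.
    """
    y = _invert(values, S)
    neg = np.any(y < 0, axis=1)
    if neg.any():
        A = S.T  # x^T = S^T y^T
        for i in np.nonzero(neg)[0]:
            y[i], _ = optimize.nnls(A, values[i])
    return y


def estimate_spillover_from_controls(
    controls: dict[str, ExpressionFrame],
    channels: list[str],
    n_iter: int = 3,
) -> SpilloverMatrix:
    """Refine spillover from single-stain controls by robust linear fits.

    Each control file is stained for a single channel; the spillover of
    channel i into channel j is the slope of a robust (Huber) regression of
    channel j on channel i within that file, re-fit on inliers over
    ``n_iter`` rounds.
    """
    import statsmodels.api as sm

    n = len(channels)
    S = np.eye(n)
    for i, ch in enumerate(channels):
        frame = controls.get(ch)
        if frame is None:
            continue
        xi = frame.values[:, frame.channel_index(ch)]
        for j, other in enumerate(channels):
            if j == i or other not in frame.channels:
                continue
            xj = frame.values[:, frame.channel_index(other)]
            keep = np.ones(xi.size, dtype=bool)
            slope = 0.0
            for _ in range(n_iter):
                X = sm.add_constant(xi[keep])
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fit = sm.RLM(xj[keep], X, M=sm.robust.norms.HuberT()).fit()
                slope = float(fit.params[1])
                resid = xj - (fit.params[0] + slope * xi)
                mad = np.median(np.abs(resid - np.median(resid))) * 1.4826
                if mad == 0:
                    break
                keep = np.abs(resid - np.median(resid)) < 4 * mad
                if keep.sum() < 10:
                    break
            S[i, j] = float(np.clip(slope, 0.0, 0.999))
    return SpilloverMatrix(channels=list(channels), S=S)


def apply_compensation(
    data: MergedData,
    method: str,
    spill: SpilloverMatrix | None = None,
    controls: dict[str, ExpressionFrame] | None = None,
    autofluor_percentile: float = 1.0,
) -> MergedData:
    """Run compensation ``method`` over the merged matrix.

    ``spill`` may be omitted when the frames carried a $SPILLOVER keyword
    (not reconstructed here; pass it explicitly).  Event counts are never
    changed.
    """
    if method == "NON":
        return data.copy()
    if method not in ("FLC", "ATS", "MTC", "CTS", "CMP"):
        raise ArgumentError(f"unknown compensation method {method!r}")

    if method == "ATS" and controls:
        spill = estimate_spillover_from_controls(controls, data.channels)
    elif method == "ATS":
        log.warning("ATS: no single-stain controls supplied; falling back to direct inversion")
    if spill is None:
        raise CompensationError(
            f"{method}: no spillover source (pass a SpilloverMatrix or, for ATS, controls)"
        )
    S = spill.reordered(data.channels).S

    values = data.values
    if method == "MTC":
        # subtract per-file autofluorescence background before unmixing
        values = values.copy()
        for si in range(len(data.sample_ids)):
            rows = data.origin == si
            bg = np.percentile(values[rows], autofluor_percentile, axis=0)
            values[rows] = values[rows] - bg
    if method == "CTS":
        comp = _nnls_unmix(values, S)
    else:
        comp = _invert(values, S)
    return data.copy(values=comp)
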