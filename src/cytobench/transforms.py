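"""Per-channel intensity transformations.

Cytometry intensities are heavily right-skewed and span several decades, so
every registered transformation is a monotone non-decreasing map applied
independently per analysis channel (the Time channel is never transformed).
Fourteen methods are provided, from simple closed forms (asinh, log,
truncation, z-score) through parametric display scales (logicle,
biexponential, hyperlog-style signed log) to data-driven maps (Box-Cox by
maximum likelihood, variance-stabilizing cofactor search, rank-based
quantile mapping).
"""

from __future__ import annotations

import numpy as np
from scipy import optimize, stats

from .errors import TransformError
from .fcs import Technique

__all__ = ["apply_transform", "TRANSFORM_IDS", "logicle", "biexp_inverse"]


def _asinh_cofactor(technique: Technique, override) -> float:
    # community defaults: 5 for mass, 150 for fluorescence data
    if override is not None:
        return float(override)
    return 5.0 if technique == Technique.MC else 150.0


def _shift_positive(x: np.ndarray) -> np.ndarray:
    return x - x.min() + 1.0


# --- closed forms -----------------------------------------------------------

def _acs(x, technique, params):
    return np.arcsinh(x / _asinh_cofactor(technique, params.get("cofactor")))


def _ann(x, technique, params):
    """asinh with an automatic per-channel cofactor.

    The cofactor is the 5th percentile of the positive values (floored at
    1) so dim channels are expanded less aggressively than bright ones.
    """
    pos = x[x > 0]
    c = max(1.0, float(np.percentile(pos, 5))) if pos.size else 1.0
    return np.arcsinh(x / c)


def _arn(x, technique, params):
    y = _acs(x, technique, params)
    lo, hi = y.min(), y.max()
    if hi == lo:
        return np.zeros_like(y)
    return (y - lo) / (hi - lo)


def _lnt(x, technique, params):
    return np.log(_shift_positive(x))


def _log(x, technique, params):
    return np.log10(_shift_positive(x))


def _tru(x, technique, params):
    return np.maximum(x, float(params.get("t", 1.0)))


def _lin(x, technique, params):
    lo, hi = float(params.get("lo", 0.0)), float(params.get("hi", 4.5))
    xmin, xmax = x.min(), x.max()
    if xmax == xmin:
        return np.full_like(x, lo)
    return lo + (x - xmin) * (hi - lo) / (xmax - xmin)


def _sca(x, technique, params):
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def _qua(x, technique, params):
    """Rank-based quantile map onto the standard normal (midrank ties)."""
    n = x.size
    r = stats.rankdata(x, method="average")
    return stats.norm.ppf(r / (n + 1.0))


def _hpl(x, technique, params):
    """Hyperlog-style signed log: linear near zero, log10 in the tails."""
    T = params.get("T")
    if T is None:
        T = 100.0 if technique == Technique.FC else 1.0
    return np.sign(x) * np.log10(1.0 + np.abs(x) / float(T))


# --- Box-Cox ----------------------------------------------------------------

def _box(x, technique, params):
    """Box-Cox with lambda estimated by maximum likelihood.

    The channel is shifted to be strictly positive (min -> 1); lambda is fit
    on an evenly spaced subsample of at most ``subsample`` order statistics,
    which keeps the estimate deterministic and cheap.
    """
    xt = _shift_positive(x)
    if np.ptp(xt) == 0:
        raise TransformError("Box-Cox: channel is constant after shift")
    cap = int(params.get("subsample", 1000))
    srt = np.sort(xt)
    if srt.size > cap:
        srt = srt[np.linspace(0, srt.size - 1, cap).astype(int)]
    try:
        lam = float(stats.boxcox(srt)[1])
    except Exception as exc:  # pragma: no cover - scipy failure surface
        raise TransformError(f"Box-Cox lambda estimation failed: {exc}") from exc
    if abs(lam) < 1e-12:
        return np.log(xt)
    return (np.power(xt, lam) - 1.0) / lam


# --- biexponential ----------------------------------------------------------

def biexp_inverse(
    x: np.ndarray,
    a: float = 0.5,
    b: float = 1.0,
    c: float = 0.5,
    d: float = 1.0,
    f: float = 0.0,
    tol: float = 1e-8,
) -> np.ndarray:
    """Numerically invert g(y) = a*e^(b*y) - c*e^(-d*y) + f by bisection.

    g is strictly increasing for positive a, b, c, d, so a sign-bracketing
    bisection converges unconditionally; iteration stops when
    |g(y) - x| < tol everywhere.
    """
    x = np.asarray(x, dtype=np.float64)

    def g(y):
        return a * np.exp(b * y) - c * np.exp(-d * y) + f

    lo = np.full_like(x, -1.0)
    hi = np.full_like(x, 1.0)
    for _ in range(200):  # expand brackets geometrically
        need_lo = g(lo) > x
        need_hi = g(hi) < x
        if not (need_lo.any() or need_hi.any()):
            break
        lo[need_lo] *= 2.0
        hi[need_hi] *= 2.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        gm = g(mid)
        err = gm - x
        if np.all(np.abs(err) < tol):
            return mid
        high = err > 0
        hi = np.where(high, mid, hi)
        lo = np.where(high, lo, mid)
    return 0.5 * (lo + hi)


def _bep(x, technique, params):
    return biexp_inverse(
        x,
        a=float(params.get("a", 0.5)),
        b=float(params.get("b", 1.0)),
        c=float(params.get("c", 0.5)),
        d=float(params.get("d", 1.0)),
        f=float(params.get("f", 0.0)),
    )


# --- logicle ----------------------------------------------------------------

def _logicle_coefficients(T: float, W: float, M: float, A: float):
    w = W / (M + A)
    x2 = A / (M + A)
    x1 = x2 + w
    x0 = x2 + 2.0 * w
    b = (M + A) * np.log(10.0)
    if w == 0:
        d = b
    else:
        # d solves 2 (ln d - ln b) + w (b + d) = 0 on (0, b)
        def fd(d):
            return 2.0 * (np.log(d) - np.log(b)) + w * (b + d)

        d = optimize.brentq(fd, 1e-12, b, xtol=1e-14)
    c_a = np.exp(x0 * (b + d))
    mf_a = np.exp(b * x1) - c_a / np.exp(d * x1)
    a = T / ((np.exp(b) - mf_a) - c_a / np.exp(d))
    c = c_a * a
    f = -mf_a * a
    return a, b, c, d, f, x1


def logicle(
    x: np.ndarray,
    T: float = 262144.0,
    W: float = 0.5,
    M: float = 4.5,
    A: float = 0.0,
    tol: float = 1e-8,
) -> np.ndarray:
    """Four-parameter logicle scale, returned on the [0, M]-decade axis.

    T is the top of scale (logicle(T) = M), W the linearization width in
    decades around zero (logicle(0) = (A/(M+A) + W/(M+A)) * M), M the number
    of decades and A the extra negative range.  The forward biexponential
    S(y) is inverted by safeguarded Newton iteration to |S(y) - x| <= tol
    relative to max(1, |x|).
    """
    x = np.asarray(x, dtype=np.float64)
    a, b, c, d, f, x1 = _logicle_coefficients(T, W, M, A)

    def S(y):
        return a * np.exp(b * y) - c * np.exp(-d * y) + f

    def Sp(y):
        return a * b * np.exp(b * y) + c * d * np.exp(-d * y)

    lo = np.full_like(x, -1.0)
    hi = np.full_like(x, 2.0)
    for _ in range(200):
        need_lo = S(lo) > x
        need_hi = S(hi) < x
        if not (need_lo.any() or need_hi.any()):
            break
        lo[need_lo] -= 1.0
        hi[need_hi] += 1.0
    y = np.full_like(x, x1)
    scale = np.maximum(1.0, np.abs(x))
    for _ in range(100):
        err = S(y) - x
        if np.all(np.abs(err) <= tol * scale):
            break
        step = err / Sp(y)
        y_new = y - step
        # fall back to bisection where Newton leaves the bracket
        bad = (y_new <= lo) | (y_new >= hi)
        y_new[bad] = 0.5 * (lo[bad] + hi[bad])
        high = S(y_new) > x
        hi = np.where(high, y_new, hi)
        lo = np.where(high, lo, y_new)
        y = y_new
    return y * M


def _lgt(x, technique, params):
    return logicle(
        x,
        T=float(params.get("T", 262144.0)),
        W=float(params.get("W", 0.5)),
        M=float(params.get("M", 4.5)),
        A=float(params.get("A", 0.0)),
    )


# --- variance-stabilizing cofactor search -----------------------------------

def _kmeans_1d(x: np.ndarray, k: int, iters: int = 25) -> np.ndarray:
    """Deterministic 1-D Lloyd iteration seeded at evenly spaced quantiles."""
    centers = np.quantile(x, np.linspace(0.1, 0.9, k))
    for _ in range(iters):
        edges = 0.5 * (centers[1:] + centers[:-1])
        lab = np.searchsorted(edges, x)
        new = np.array([x[lab == j].mean() if np.any(lab == j) else centers[j] for j in range(k)])
        if np.allclose(new, centers):
            break
        centers = new
    edges = 0.5 * (centers[1:] + centers[:-1])
    return np.searchsorted(edges, x)


def _fvs(x, technique, params):
    """asinh with a per-channel cofactor chosen to stabilize variance.

    Candidate cofactors are scanned on a log grid; for each, the channel is
    asinh-transformed, partitioned by a deterministic 1-D k-means (k = 5 by
    default), and Bartlett's statistic for equal within-group variances is
    computed.  The cofactor minimizing the statistic wins.
    """
    k = int(params.get("k", 5))
    srt = np.sort(x)
    if srt.size > 2000:
        srt = srt[np.linspace(0, srt.size - 1, 2000).astype(int)]
    if np.ptp(srt) == 0:
        return np.zeros_like(x)
    best_c, best_stat = 5.0, np.inf
    for c in np.logspace(-1, 4, 16):
        y = np.arcsinh(srt / c)
        lab = _kmeans_1d(y, k)
        groups = [y[lab == j] for j in range(k)]
        groups = [g for g in groups if g.size >= 2 and g.std() > 0]
        if len(groups) < 2:
            continue
        try:
            stat, _ = stats.bartlett(*groups)
        except Exception:
            continue
        if np.isfinite(stat) and stat < best_stat:
            best_stat, best_c = stat, c
    return np.arcsinh(x / best_c)


TRANSFORMS = {
    "ACS": _acs,
    "ANN": _ann,
    "ARN": _arn,
    "BEP": _bep,
    "BOX": _box,
    "FVS": _fvs,
    "HPL": _hpl,
    "LGT": _lgt,
    "LIN": _lin,
    "LNT": _lnt,
    "LOG": _log,
    "QUA": _qua,
    "SCA": _sca,
    "TRU": _tru,
}

TRANSFORM_IDS = sorted(TRANSFORMS)


def apply_transform(
    values: np.ndarray,
    method: str,
    technique: Technique,
    params: dict | None = None,
) -> np.ndarray:
    """Apply transformation ``method`` to every column of ``values``."""
    if method == "NON":
        return values.copy()
    try:
        fn = TRANSFORMS[method]
    except KeyError:
        raise TransformError(f"unknown transformation {method!r}") from None
    params = params or {}
    out = np.empty_like(values, dtype=np.float64)
    for j in range(values.shape[1]):
        out[:, j] = fn(values[:, j], technique, params)
    return out
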