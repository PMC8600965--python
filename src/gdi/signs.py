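"""Excitatory/inhibitory sign inference via time-lagged (partial) correlation.

Information-theoretic edge weights are sign-blind, so each detected edge
is labelled excitatory (+1) or inhibitory (-1) from the sign of the
time-lagged partial correlation (TLPC) at the negative lag of peak
absolute value.  The TLPC between channels j and k at lag tau, given a
conditioning set W, correlates x_j at time i with x_k at time i - tau
after both are residualized on the conditioning channels taken at time i
(lag 0).  With an empty conditioning set this reduces to the plain
time-lagged correlation (TLC).  The residual-regression form is the
canonical implementation; the classical one-variable-at-a-time recursion
is kept as a cross-check and agrees to ~1e-8.

A causal effect of j on k with delay s shows up at tau = -s, because the
convention pairs x_i with y_{i-tau}.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .timeseries import TimeSeriesSet

__all__ = ["LagCorrelation", "tlc", "tlpc", "tlpc_recursive", "infer_sign"]


@dataclass
class LagCorrelation:
    """Correlation-vs-lag profile of one ordered channel pair."""

    lags: np.ndarray
    values: np.ndarray
    kind: str  # "TLC" | "TLPC"
    conditioning: tuple[int, ...] = field(default_factory=tuple)


def _aligned(series: TimeSeriesSet, j: int, k: int, tau: int,
             conditioning: tuple[int, ...]) -> np.ndarray:
    """Design matrix [x_j(i), x_k(i - tau), W(i)...] over the valid overlap."""
    x = series.values[:, j]
    y = series.values[:, k]
    T = len(x)
    if tau <= 0:
        i0, i1 = 0, T + tau if tau < 0 else T
    else:
        i0, i1 = tau, T
    idx = np.arange(i0, i1)
    cols = [x[idx], y[idx - tau]]
    cols += [series.values[idx, c] for c in conditioning]
    return np.column_stack(cols)


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a ** 2).sum() * (b ** 2).sum())
    if denom == 0:
        raise ValueError("undefined correlation: constant segment")
    return float((a * b).sum() / denom)


def tlc(x: np.ndarray, y: np.ndarray, tau: int) -> float:
    """Time-lagged Pearson correlation between x_i and y_{i-tau}.

    Means are computed on the overlap, which must contain >= 3 samples of
    non-constant data.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    series = TimeSeriesSet(np.column_stack([x, y]))
    D = _aligned(series, 0, 1, tau, ())
    if D.shape[0] < 3:
        raise ValueError("overlap after shifting must contain >= 3 samples")
    return _corr(D[:, 0], D[:, 1])


def tlpc(series: TimeSeriesSet, j, k, tau: int,
         conditioning_set=()) -> float:
    """Time-lagged partial correlation of (x_j(i), x_k(i-tau)) given the
    conditioning channels at lag 0, via residual regression."""
    j = series.channel_index(j)
    k = series.channel_index(k)
    cond = tuple(series.channel_index(c) for c in conditioning_set)
    if j in cond or k in cond:
        raise ValueError("conditioning set may not contain j or k")
    if not cond:
        return tlc(series.values[:, j], series.values[:, k], tau)

    D = _aligned(series, j, k, tau, cond)
    if D.shape[0] < 3 + len(cond):
        raise ValueError("overlap too short for the conditioning set size")
    Dc = D - D.mean(axis=0)
    W = Dc[:, 2:]
    rank = np.linalg.matrix_rank(W)
    if rank < W.shape[1]:
        raise np.linalg.LinAlgError("collinear conditioning channels")
    coef, *_ = np.linalg.lstsq(W, Dc[:, :2], rcond=None)
    resid = Dc[:, :2] - W @ coef
    return _corr(resid[:, 0], resid[:, 1])


def tlpc_recursive(series: TimeSeriesSet, j, k, tau: int,
                   conditioning_set=()) -> float:
    """One-variable-at-a-time recursion for the TLPC (cross-check route).

    All base correlations are taken from the same aligned design matrix as
    the regression route, so the two agree to numerical precision.
    """
    j = series.channel_index(j)
    k = series.channel_index(k)
    cond = tuple(series.channel_index(c) for c in conditioning_set)
    D = _aligned(series, j, k, tau, cond)
    if D.shape[0] < 3 + len(cond):
        raise ValueError("overlap too short for the conditioning set size")
    C = np.corrcoef(D.T) if D.shape[1] > 1 else np.ones((1, 1))

    def partial(a: int, b: int, given: frozenset) -> float:
        if not given:
            return float(C[a, b])
        w = max(given)
        rest = given - {w}
        r_ab = partial(a, b, rest)
        r_aw = partial(a, w, rest)
        r_wb = partial(w, b, rest)
        denom = np.sqrt((1 - r_aw ** 2) * (1 - r_wb ** 2))
        if denom == 0:
            raise ValueError("degenerate correlation in recursion")
        return (r_ab - r_aw * r_wb) / denom

    return partial(0, 1, frozenset(range(2, D.shape[1])))


def lag_profile(series: TimeSeriesSet, j, k, lags,
                conditioning_set=()) -> LagCorrelation:
    """TLPC (or TLC when unconditioned) evaluated over a set of lags."""
    cond = tuple(conditioning_set)
    vals = np.array([tlpc(series, j, k, int(t), cond) for t in lags], dtype=float)
    return LagCorrelation(lags=np.asarray(list(lags)), values=vals,
                          kind="TLPC" if cond else "TLC", conditioning=cond)


def infer_sign(series: TimeSeriesSet, j, k, conditioning_set=(),
               lag_range=None) -> tuple[int, int]:
    """Edge sign and peak lag from the TLPC profile over negative lags.

    Returns ``(S, tau_star)`` where ``tau_star`` maximizes the absolute
    partial correlation over ``lag_range`` (negative integers; default
    ``-5M .. -1`` is supplied by the graph layer, here ``-10 .. -1``) and
    ``S`` is the sign of the coefficient there.  Ties break toward the lag
    closest to zero.  ``S = 0`` with ``tau_star = 0`` signals an
    undetermined sign (all coefficients undefined).
    """
    if lag_range is None:
        lag_range = range(-10, 0)
    lags = sorted((int(t) for t in lag_range), key=abs)  # tie-break order
    if not lags or any(t >= 0 for t in lags):
        raise ValueError("lag_range must contain only negative integers")

    best_val = None
    best_lag = None
    for t in lags:
        try:
            v = tlpc(series, j, k, t, tuple(conditioning_set))
        except (ValueError, np.linalg.LinAlgError):
            continue
        if best_val is None or abs(v) > abs(best_val):
            best_val, best_lag = v, t
    if best_val is None or best_val == 0:
        return 0, 0
    return (1 if best_val > 0 else -1), best_lag
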