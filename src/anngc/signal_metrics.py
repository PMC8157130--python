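"""Application-layer signal measures: envelope/phase, lagged
cross-correlation, Spearman rank correlation, and graph in-strength.

These are the measures used downstream of GC estimation on real
recordings — amplitude synchronization between oscillators, agreement
between estimated coupling patterns, and the total inward causal weight
of a network node.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert
from scipy.stats import rankdata, t as t_dist

from .state_space import GCResult

__all__ = [
    "AnalyticSignal",
    "CrossCorrResult",
    "SpearmanResult",
    "analytic_signal",
    "max_crosscorr",
    "spearman_rank",
    "in_strength",
]


@dataclass
class AnalyticSignal:
    """Envelope and instantaneous phase of a single channel."""

    amplitude: np.ndarray
    phase: np.ndarray
    edge_fraction: float = 0.05

    def interior(self) -> slice:
        """Index range excluding transform edge effects (5% per side)."""
        n = self.amplitude.size
        k = int(round(self.edge_fraction * n))
        return slice(k, n - k if k else n)


@dataclass
class CrossCorrResult:
    lags: np.ndarray
    coeffs: np.ndarray
    max_value: float
    argmax_lag: int


@dataclass
class SpearmanResult:
    rs: float
    t: float
    p_value: float
    n: int


def analytic_signal(series: np.ndarray) -> AnalyticSignal:
    """Hilbert-transform envelope and phase of a (mean-removed) series."""
    x = np.asarray(series, dtype=float).ravel()
    if x.size < 4:
        raise ValueError("series too short")
    if np.ptp(x) == 0:
        raise ValueError("constant series has no analytic representation")
    x = x - x.mean()
    z = hilbert(x)
    return AnalyticSignal(amplitude=np.abs(z), phase=np.angle(z))


def max_crosscorr(x: np.ndarray, y: np.ndarray, max_lag: int
                  ) -> CrossCorrResult:
    """Normalized cross-correlation over non-negative lags.

    ``C_xy(tau)`` correlates the driver's present against the target
    ``tau`` steps later, ``k(tau) = E[x_n * y_{n+tau}]``: a positive lag
    is a propagation time from ``x`` to ``y`` along the coupling
    direction.  The biased estimator (sum divided by the full length)
    keeps every coefficient in [-1, 1].
    """
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    if x.size != y.size:
        raise ValueError("series must have equal length")
    n = x.size
    if max_lag >= n // 2:
        raise ValueError("max_lag must be below half the series length")
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        raise ValueError("zero-variance input")
    xc = x - x.mean()
    yc = y - y.mean()
    lags = np.arange(max_lag + 1)
    coeffs = np.empty(lags.size)
    for tau in lags:
        seg = xc[:n - tau] * yc[tau:] if tau else xc * yc
        coeffs[tau] = seg.sum() / (n * sx * sy)
    k = int(np.argmax(coeffs))
    return CrossCorrResult(lags=lags, coeffs=coeffs,
                           max_value=float(coeffs[k]), argmax_lag=k)


def spearman_rank(a: np.ndarray, b: np.ndarray) -> SpearmanResult:
    """Spearman rank correlation with its Student-t significance.

    ``r_s`` is the Pearson correlation of mean-tie ranks; the statistic
    ``t = r_s sqrt((n-2)/(1-r_s^2))`` is referred to a t distribution with
    n-2 degrees of freedom.
    """
    a = np.asarray(a, float).ravel()
    b = np.asarray(b, float).ravel()
    if a.size != b.size or a.size < 3:
        raise ValueError("need two equal-length vectors with n >= 3")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant vector has undefined rank correlation")
    ra, rb = rankdata(a), rankdata(b)
    ra = ra - ra.mean()
    rb = rb - rb.mean()
    rs = float(ra @ rb / np.sqrt((ra @ ra) * (rb @ rb)))
    n = a.size
    if abs(rs) >= 1.0:
        tt, p = float("inf") * np.sign(rs), 0.0
    else:
        tt = rs * np.sqrt((n - 2) / (1.0 - rs * rs))
        p = 2.0 * t_dist.sf(abs(tt), df=n - 2)
    return SpearmanResult(rs=rs, t=float(tt), p_value=float(p), n=n)


def in_strength(gc: GCResult, node: int, significant_only: bool = True
                ) -> float:
    """Sum of inward GC weights at ``node``.

    By default only links flagged significant contribute; with
    ``significant_only=False`` the raw magnitudes are summed.
    """
    M = gc.gc.shape[0]
    if not 0 <= node < M:
        raise ValueError("node out of range")
    col = gc.gc[:, node].copy()
    col[node] = 0.0
    if significant_only:
        if gc.significance is None:
            return 0.0
        col = np.where(gc.significance[:, node], col, 0.0)
        col[node] = 0.0
    return float(col.sum())
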