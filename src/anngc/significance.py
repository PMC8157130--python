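"""Statistical significance of estimated Granger-causality links.

Two mechanisms, one per identification route:

* OLS — IAAFT surrogates destroy cross-channel coupling while preserving
  each channel's amplitude distribution exactly and its power spectrum
  approximately; a link is significant when its GC exceeds the 95th
  percentile of its surrogate null distribution.
* ANN — the cumulative L1 penalty produces exact zeros, so a link is
  significant iff any of the p weights from the driver's lag block to the
  target output is nonzero.  No thresholding epsilon is involved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .identify import build_regression, ols_fit
from .models import TimeSeriesPanel
from .state_space import DareNonConvergenceError, conditional_gc

__all__ = [
    "SurrogateEnsemble",
    "iaaft_surrogate",
    "significance_ols",
    "significance_ann",
]


@dataclass
class SurrogateEnsemble:
    """Null GC distribution from IAAFT surrogates and the decisions it yields."""

    gc: np.ndarray             # observed conditional GC (M, M)
    null: np.ndarray           # (n_surrogates, M, M), NaN where a set failed
    thresholds: np.ndarray     # per-pair 95th percentile of the null
    mask: np.ndarray           # significant links (M, M) bool
    n_failed: int              # surrogate sets lost to DARE failures
    unresolved: bool           # True when > 10% of the sets failed


def iaaft_surrogate(series: np.ndarray, rng: np.random.Generator,
                    max_iter: int = 100, tol: float = 1e-8) -> np.ndarray:
    """Iterative amplitude-adjusted Fourier-transform surrogate of a series.

    Alternates spectrum substitution (impose the original periodogram,
    keep current phases) with rank-ordered amplitude substitution (impose
    the original sorted values) until the relative spectral change drops
    below ``tol`` or ``max_iter`` is reached.  The output is ended on the
    amplitude step, so its sorted values equal the input's exactly.
    """
    x = np.asarray(series, dtype=float).ravel()
    if x.size < 8:
        raise ValueError("series too short for a meaningful surrogate")
    if np.ptp(x) == 0:
        raise ValueError("constant series has no surrogate")
    sorted_amp = np.sort(x)
    target_mag = np.abs(np.fft.rfft(x))
    y = rng.permutation(x)
    prev_err = np.inf
    for _ in range(max_iter):
        spec = np.fft.rfft(y)
        mag = np.abs(spec)
        phase = np.where(mag > 0, spec / np.where(mag > 0, mag, 1.0), 1.0)
        y = np.fft.irfft(target_mag * phase, n=x.size)
        ranks = np.argsort(np.argsort(y))
        y = sorted_amp[ranks]
        err = float(np.linalg.norm(np.abs(np.fft.rfft(y)) - target_mag))
        scale = float(np.linalg.norm(target_mag))
        if scale > 0 and abs(prev_err - err) / scale < tol:
            break
        prev_err = err
    return y


def significance_ols(panel: TimeSeriesPanel, p: int, n_surr: int = 100,
                     rng: np.random.Generator | None = None,
                     percentile: float = 95.0,
                     allow_singular: bool = True) -> SurrogateEnsemble:
    """Surrogate-based significance of OLS-estimated conditional GC.

    Each surrogate set randomizes every channel independently, is refitted
    with the same model order, and contributes one null GC matrix.  DARE
    failures on surrogates are counted; if more than 10% of the sets fail
    the ensemble is flagged unresolved.  A DARE failure on the *original*
    panel propagates (there is nothing to threshold).
    """
    if n_surr < 20:
        raise ValueError("need at least 20 surrogate sets")
    rng = np.random.default_rng() if rng is None else rng
    reg = build_regression(panel, p)
    model = ols_fit(reg, allow_singular=allow_singular)
    gc_obs = conditional_gc(model).gc

    M = panel.M
    null = np.full((n_surr, M, M), np.nan)
    n_failed = 0
    for s in range(n_surr):
        surr = np.column_stack([
            iaaft_surrogate(panel.values[:, j], rng) for j in range(M)])
        try:
            m_s = ols_fit(build_regression(TimeSeriesPanel(surr), p),
                          allow_singular=allow_singular)
            null[s] = conditional_gc(m_s).gc
        except DareNonConvergenceError:
            n_failed += 1
    unresolved = n_failed > 0.1 * n_surr
    if unresolved:
        warnings.warn(f"{n_failed}/{n_surr} surrogate sets failed: "
                      "significance decisions are unresolved", stacklevel=2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
        thresholds = np.nanpercentile(null, percentile, axis=0)
    mask = gc_obs > thresholds
    np.fill_diagonal(mask, False)
    return SurrogateEnsemble(gc=gc_obs, null=null, thresholds=thresholds,
                             mask=mask, n_failed=n_failed,
                             unresolved=unresolved)


def significance_ann(weights: np.ndarray, p: int, M: int) -> np.ndarray:
    """Link mask from the exact-zero structure of trained weights.

    ``weights`` is the ``Mp x M`` trained matrix with design column
    ``k*M + i`` holding driver ``i`` at lag ``k+1``; link (i, j) is
    significant iff any of its p weights is nonzero.  The diagonal is
    ignored.
    """
    W = np.asarray(weights, dtype=float)
    if W.shape != (M * p, M):
        raise ValueError(f"expected ({M * p}, {M}) weights, got {W.shape}")
    blocks = W.reshape(p, M, M)
    mask = (blocks != 0.0).any(axis=0)
    np.fill_diagonal(mask, False)
    return mask
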