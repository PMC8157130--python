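"""Ground-truth network generators and VAR realizations for the benchmarks.

Three benchmark families are supported:

* study I/II — sparse VAR(16) networks of M=10 channels with 14 of the 90
  ordered channel pairs carrying a single nonzero coefficient at a random
  lag (study II adds measurement noise at a target SNR on top of study-I
  realizations);
* study III — denser reduced VAR(6) networks with lag-1 self-dynamics and
  paired off-diagonal coefficients at random delays.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .models import TimeSeriesPanel, VARModel, is_stable

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

__all__ = [
    "SimulationSpec",
    "k_ratio_to_length",
    "generate_network_sim1",
    "generate_network_sim3",
    "simulate_var",
    "add_noise_snr",
]

MAX_STABILITY_ATTEMPTS = 1000


@dataclass
class SimulationSpec:
    """Parameters of one benchmark network family.

    ``K_ratio`` is the ratio between the number of data samples (N*M) and
    the number of AR coefficients to estimate (M^2*p); the realization
    length follows as N = K*M*p.
    """

    study: str = "I"
    M: int = 10
    p: int = 16
    n_links: int = 14
    coeff_range: tuple[float, float] = (-0.8, 0.8)
    K_ratio: float = 20.0
    snr: float | None = None
    innov_var: float = 0.1
    candidate_fraction: float = 0.8  # study III: fraction of pairs eligible
    activation_prob: float = 0.5     # study III: prob. an eligible pair is a link
    magnitude_grid: tuple[float, float, float] = (0.15, 0.5, 0.01)

    def __post_init__(self) -> None:
        if self.study not in {"I", "III"}:
            raise ValueError("study must be 'I' or 'III'")
        if self.K_ratio <= 0:
            raise ValueError("K_ratio must be positive")

    @property
    def N(self) -> int:
        return k_ratio_to_length(self.K_ratio, self.M, self.p)


def k_ratio_to_length(K: float, M: int, p: int) -> int:
    """Realization length N such that (N*M)/(M^2*p) = K, i.e. N = K*M*p."""
    if K <= 0 or M < 1 or p < 1:
        raise ValueError("K, M and p must be positive")
    return int(round(K * M * p))


def generate_network_sim1(spec: SimulationSpec, rng: np.random.Generator) -> VARModel:
    """Sparse study-I ground truth: VAR(16), 14 of 90 off-diagonal links.

    Each link is one nonzero coefficient, uniform on ``coeff_range``, at a
    lag drawn uniformly in 1..p.  Every channel additionally receives one
    diagonal self-coefficient by the same scheme (not counted as a link).
    The draw is repeated until the companion matrix is stable.
    """
    M, p = spec.M, spec.p
    pairs = [(i, j) for i in range(M) for j in range(M) if i != j]
    lo, hi = spec.coeff_range
    for _ in range(MAX_STABILITY_ATTEMPTS):
        coeffs = np.zeros((p, M, M))
        links = np.zeros((M, M), dtype=bool)
        if spec.n_links:
            chosen = rng.choice(len(pairs), size=spec.n_links, replace=False)
            for idx in chosen:
                i, j = pairs[idx]
                coeffs[rng.integers(p), i, j] = rng.uniform(lo, hi)
                links[i, j] = True
        for j in range(M):  # self-dynamics
            coeffs[rng.integers(p), j, j] = rng.uniform(lo, hi)
        model = VARModel(coeffs, spec.innov_var * np.eye(M), links=links,
                         meta={"study": "I"})
        stable, rho = is_stable(model)
        if stable:
            model.meta["spectral_radius"] = rho
            return model
    raise RuntimeError(
        f"no stable study-I network found in {MAX_STABILITY_ATTEMPTS} attempts")


def generate_network_sim3(spec: SimulationSpec, rng: np.random.Generator) -> VARModel:
    """Denser study-III ground truth: reduced VAR(6) with paired couplings.

    Self-dynamics are a single lag-1 coefficient per channel.  Off-diagonal
    interactions live on a random ``candidate_fraction`` of the ordered
    pairs, each activated with ``activation_prob`` (~38 of 90 links); an
    active interaction is a pair of consecutive-lag coefficients starting at
    a random delay, magnitudes drawn from ``magnitude_grid`` with random
    sign.  Regeneration is repeated until asymptotic stability.
    """
    M, p = spec.M, spec.p
    lo, hi, step = spec.magnitude_grid
    grid = np.round(np.arange(lo, hi + step / 2, step), 10)
    pairs = [(i, j) for i in range(M) for j in range(M) if i != j]

    def draw_coeff() -> float:
        return rng.choice(grid) * rng.choice([-1.0, 1.0])

    n_candidates = int(round(spec.candidate_fraction * len(pairs)))
    for _ in range(MAX_STABILITY_ATTEMPTS):
        coeffs = np.zeros((p, M, M))
        links = np.zeros((M, M), dtype=bool)
        for j in range(M):
            coeffs[0, j, j] = draw_coeff()
        cand_idx = rng.choice(len(pairs), size=n_candidates, replace=False)
        for idx in cand_idx:
            if rng.random() >= spec.activation_prob:
                continue
            i, j = pairs[idx]
            start = int(rng.integers(1, p))  # lags start..start+1, start+1 <= p
            coeffs[start - 1, i, j] = draw_coeff()
            coeffs[start, i, j] = draw_coeff()
            links[i, j] = True
        model = VARModel(coeffs, spec.innov_var * np.eye(M), links=links,
                         meta={"study": "III"})
        stable, rho = is_stable(model)
        if stable:
            model.meta["spectral_radius"] = rho
            return model
    raise RuntimeError(
        f"no stable study-III network found in {MAX_STABILITY_ATTEMPTS} attempts")


if _HAVE_NUMBA:

    @njit(cache=False)
    def _var_recursion(stacked, innov, p, M):  # pragma: no cover - jitted
        T = innov.shape[0]
        out = np.zeros((T, M))
        for n in range(T):
            for k in range(min(p, n)):
                # lag k+1 block of the stacked (Mp x M) coefficient matrix
                for i in range(M):
                    for j in range(M):
                        out[n, j] += out[n - k - 1, i] * stacked[k * M + i, j]
            for j in range(M):
                out[n, j] += innov[n, j]
        return out

else:  # pragma: no cover - numpy fallback

    def _var_recursion(stacked, innov, p, M):
        T = innov.shape[0]
        out = np.zeros((T, M))
        for n in range(T):
            for k in range(min(p, n)):
                out[n] += out[n - k - 1] @ stacked[k * M:(k + 1) * M]
            out[n] += innov[n]
        return out


def simulate_var(model: VARModel, N: int, rng: np.random.Generator,
                 burn_in: int | None = None) -> TimeSeriesPanel:
    """Generate ``N`` rows of the VAR process with Gaussian innovations.

    The recursion starts from zeros and discards ``burn_in`` initial rows
    (default ``10 * p``) so the retained samples are effectively stationary.
    """
    stable, rho = is_stable(model)
    if not stable:
        raise ValueError(f"unstable model (spectral radius {rho:.3f})")
    if N <= model.p:
        raise ValueError("N must exceed the model order")
    if burn_in is None:
        burn_in = 10 * model.p
    T = N + burn_in
    innov = rng.multivariate_normal(
        np.zeros(model.M), model.innov_cov, size=T, method="cholesky")
    values = _var_recursion(model.stacked, innov, model.p, model.M)
    return TimeSeriesPanel(values[burn_in:])


def add_noise_snr(panel: TimeSeriesPanel, snr: float,
                  rng: np.random.Generator) -> TimeSeriesPanel:
    """Add white Gaussian measurement noise at a per-channel power ratio.

    ``snr`` is mean squared signal over mean squared noise; the noise is
    i.i.d. across channels with per-channel variance ``mean(y_j^2)/snr``.
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    power = np.mean(panel.values ** 2, axis=0)
    if np.any(power == 0):
        warnings.warn("zero-power channel: no noise added there")
    sigma = np.sqrt(power / snr)
    noise = rng.standard_normal(panel.values.shape) * sigma
    return TimeSeriesPanel(panel.values + noise, panel.sample_labels)
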