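"""Core containers for VAR-based Granger-causality analysis.

Conventions
-----------
All coefficient stacks follow the row-vector form of the VAR model

    Y_n = sum_k Y_{n-k} A_k + U_n,

so ``coeffs[k][i, j]`` is the influence of channel ``i`` at lag ``k+1`` on
channel ``j`` (driver = row, target = column).  The stacked ``Mp x M``
coefficient matrix is ``[A_1; ...; A_p]`` and multiplies the lagged row
``[Y_{n-1}, ..., Y_{n-p}]`` from the right.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "VARModel",
    "TimeSeriesPanel",
    "companion_matrix",
    "spectral_radius",
    "is_stable",
]


def _as_coeff_stack(coeffs: np.ndarray) -> np.ndarray:
    coeffs = np.asarray(coeffs, dtype=float)
    if coeffs.ndim != 3 or coeffs.shape[1] != coeffs.shape[2]:
        raise ValueError(f"coeffs must be (p, M, M), got {coeffs.shape}")
    return coeffs


@dataclass
class VARModel:
    """A vector autoregressive model of order ``p`` over ``M`` channels.

    Parameters
    ----------
    coeffs : (p, M, M) array
        Lag-coefficient stack, ``coeffs[k][i, j]`` = effect of driver ``i``
        at lag ``k+1`` on target ``j``.
    innov_cov : (M, M) array
        Innovation covariance (symmetric positive semi-definite).
    links : (M, M) bool array, optional
        Ground-truth off-diagonal causal links (set by the simulators).
    """

    coeffs: np.ndarray
    innov_cov: np.ndarray
    links: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coeffs = _as_coeff_stack(self.coeffs)
        self.innov_cov = np.asarray(self.innov_cov, dtype=float)
        M = self.coeffs.shape[1]
        if self.innov_cov.shape != (M, M):
            raise ValueError("innov_cov shape does not match channel count")
        if not np.allclose(self.innov_cov, self.innov_cov.T, atol=1e-10):
            raise ValueError("innov_cov must be symmetric")
        if self.links is not None:
            self.links = np.asarray(self.links, dtype=bool)
            if self.links.shape != (M, M):
                raise ValueError("links mask shape must be (M, M)")

    @property
    def M(self) -> int:
        return self.coeffs.shape[1]

    @property
    def p(self) -> int:
        return self.coeffs.shape[0]

    @property
    def stacked(self) -> np.ndarray:
        """The ``Mp x M`` stacked coefficient matrix ``[A_1; ...; A_p]``."""
        return self.coeffs.reshape(self.p * self.M, self.M)

    def coefficient_links(self, tol: float = 0.0) -> np.ndarray:
        """Off-diagonal support of the coefficient stack (driver i -> target j)."""
        mask = (np.abs(self.coeffs) > tol).any(axis=0)
        np.fill_diagonal(mask, False)
        return mask

    def link_mask(self) -> np.ndarray:
        """Ground-truth links if recorded, else the coefficient support."""
        return self.links if self.links is not None else self.coefficient_links()


@dataclass
class TimeSeriesPanel:
    """An ``N x M`` multichannel realization, rows ordered in time."""

    values: np.ndarray
    sample_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if not np.isfinite(self.values).all():
            raise ValueError("panel contains non-finite entries")
        if self.sample_labels is not None and len(self.sample_labels) != self.M:
            raise ValueError("one label per channel required")

    @property
    def N(self) -> int:
        return self.values.shape[0]

    @property
    def M(self) -> int:
        return self.values.shape[1]


def companion_matrix(model: VARModel) -> np.ndarray:
    """The ``Mp x Mp`` companion matrix in column (left-multiplication) form.

    With state ``x_n = [y_{n-1}; ...; y_{n-p}]`` (column vector), the VAR is
    ``x_{n+1} = A_c x_n + [u_n; 0; ...]``; the first block row of ``A_c``
    holds the transposed lag matrices ``A_k^T``.
    """
    M, p = model.M, model.p
    Ac = np.zeros((M * p, M * p))
    for k in range(p):
        Ac[:M, k * M:(k + 1) * M] = model.coeffs[k].T
    if p > 1:
        Ac[M:, :-M] = np.eye(M * (p - 1))
    return Ac


def spectral_radius(model: VARModel) -> float:
    """Magnitude of the dominant companion-matrix eigenvalue."""
    return float(np.max(np.abs(np.linalg.eigvals(companion_matrix(model)))))


def is_stable(model: VARModel) -> tuple[bool, float]:
    """Whether the VAR is asymptotically stable, with its spectral radius.

    Stability of a discrete-time VAR requires every companion eigenvalue to
    lie strictly inside the unit circle.
    """
    rho = spectral_radius(model)
    return rho < 1.0, rho
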