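"""Conditional and unconditional Granger causality through state space.

A stable VAR(p) has an exact innovations-form state-space (ISS)
representation with companion state; dropping channels from the
*observation* equation while keeping the state equation yields a submodel
whose innovation covariance — obtained by solving a discrete algebraic
Riccati equation (DARE) — contains the prediction-error variance of any
retained target given the past of exactly the retained channels.  One
full-model identification therefore yields every restricted-model variance
needed for Granger causality, without refitting truncated regressions.

The DARE is solved with a structure-preserving doubling algorithm
(quadratically convergent); absence of a stabilizing solution — singular
innovation covariance, unstable companion matrix, or numerical
non-convergence — surfaces as :class:`DareNonConvergenceError`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .models import VARModel, companion_matrix, is_stable

__all__ = [
    "ISSModel",
    "GCResult",
    "DareNonConvergenceError",
    "solve_dare",
    "var_to_iss",
    "submodel_variance",
    "conditional_gc",
    "unconditional_gc",
]


class DareNonConvergenceError(RuntimeError):
    """No stabilizing Riccati solution could be computed.

    Raised when the doubling iteration fails to converge, when the
    innovation covariance block is singular (e.g. an interpolating OLS fit
    at K = 1), or when the companion matrix is not stable — in each case a
    stabilizing DARE solution does not exist or cannot be found.
    """


@dataclass
class ISSModel:
    """Innovations-form state space (column convention internally).

    ``x_{n+1} = A x_n + K e_n``, ``y_n = C x_n + e_n`` with state dimension
    ``Mp``; for the full model the innovation covariance ``phi`` equals the
    VAR innovation covariance exactly.
    """

    A: np.ndarray      # (Mp, Mp) state matrix (companion)
    C: np.ndarray      # (M, Mp) observation matrix
    K: np.ndarray      # (Mp, M) Kalman gain
    phi: np.ndarray    # (M, M) innovation covariance

    @property
    def state_dim(self) -> int:
        return self.A.shape[0]

    @property
    def M(self) -> int:
        return self.C.shape[0]


@dataclass
class GCResult:
    """M x M Granger-causality magnitudes with their partial variances.

    ``gc[i, j]`` is the causality from driver ``i`` to target ``j`` (the
    diagonal is zero by convention); ``restricted[i, j]`` and
    ``full[i, j]`` store the variances whose log ratio defines it.
    """

    gc: np.ndarray
    restricted: np.ndarray
    full: np.ndarray
    method: str = "conditional"
    significance: np.ndarray | None = None


def solve_dare(A: np.ndarray, C: np.ndarray, Q: np.ndarray, R: np.ndarray,
               S: np.ndarray, tol: float = 1e-12, max_iter: int = 100
               ) -> tuple[np.ndarray, np.ndarray]:
    """Stabilizing solution of the Kalman-filter DARE with cross term.

    Solves ``P = A P A' - (A P C' + S)(C P C' + R)^{-1}(A P C' + S)' + Q``
    by first absorbing the cross term ``S`` and then running the
    structure-preserving doubling iteration.  Returns ``(P, V)`` where
    ``V = C P C' + R`` is the innovation covariance of the submodel.
    """
    n = A.shape[0]
    try:
        RinvC = np.linalg.solve(R, C)
        RinvSt = np.linalg.solve(R, S.T)
    except np.linalg.LinAlgError as exc:
        raise DareNonConvergenceError(
            "singular observation-noise covariance") from exc
    # cond guard: a numerically singular R passes np.linalg.solve silently
    if not np.isfinite(RinvC).all() or np.linalg.cond(R) > 1e12:
        raise DareNonConvergenceError("ill-conditioned observation-noise "
                                      "covariance")
    Ahat = A - S @ RinvC
    Qhat = Q - S @ RinvSt
    G = C.T @ RinvC
    # doubling iteration on X = A'X(I+GX)^{-1}A + H with A <- Ahat', H <- Qhat
    Ak = Ahat.T.copy()
    Gk = G.copy()
    Hk = Qhat.copy()
    I = np.eye(n)
    for _ in range(max_iter):
        W = I + Gk @ Hk
        try:
            sol = np.linalg.solve(W, np.concatenate([Ak, Gk], axis=1))
        except np.linalg.LinAlgError as exc:
            raise DareNonConvergenceError("doubling step singular") from exc
        WA, WG = sol[:, :n], sol[:, n:]
        Anew = Ak @ WA
        Hnew = Hk + Ak.T @ (Hk @ WA)
        Gnew = Gk + Ak @ WG @ Ak.T
        if not np.isfinite(Hnew).all():
            raise DareNonConvergenceError("doubling iteration diverged")
        delta = np.max(np.abs(Hnew - Hk)) / max(1.0, np.max(np.abs(Hnew)))
        Ak, Gk, Hk = Anew, Gnew, Hnew
        if delta < tol:
            P = (Hk + Hk.T) / 2.0
            V = C @ P @ C.T + R
            return P, V
    raise DareNonConvergenceError(
        f"no convergence in {max_iter} doubling iterations")


def var_to_iss(model: VARModel) -> ISSModel:
    """Exact ISS representation of a stable VAR model.

    The state is the stacked lag vector, the observation matrix is the
    first block row of the companion matrix, and the Kalman gain injects
    the innovation into the first block, so simulating the ISS and the VAR
    from the same innovation sequence gives identical observations.
    """
    stable, rho = is_stable(model)
    if not stable:
        raise DareNonConvergenceError(
            f"companion spectral radius {rho:.4f} >= 1: no stabilizing "
            "state-space solution exists for an unstable VAR")
    M, p = model.M, model.p
    A = companion_matrix(model)
    C = A[:M, :].copy()
    K = np.zeros((M * p, M))
    K[:M, :M] = np.eye(M)
    return ISSModel(A=A, C=C, K=K, phi=model.innov_cov.copy())


def _submodel_innovation_cov(iss: ISSModel,
                             observed: Sequence[int]) -> np.ndarray:
    """Innovation covariance of the submodel observing ``observed`` only."""
    obs = list(observed)
    Cs = iss.C[obs, :]
    Q = iss.K @ iss.phi @ iss.K.T
    R = iss.phi[np.ix_(obs, obs)]
    S = iss.K @ iss.phi[:, obs]
    _, V = solve_dare(iss.A, Cs, Q, R, S)
    return V


def submodel_variance(iss: ISSModel, observed: Sequence[int],
                      target: int) -> float:
    """Prediction-error variance of ``target`` given the past of ``observed``.

    ``observed`` must contain ``target``.  When every channel is observed
    the submodel is already in innovations form and the variance is read
    from the full-model covariance directly.
    """
    obs = sorted(set(int(c) for c in observed))
    if target not in obs:
        raise ValueError("target must belong to the observed set")
    if not all(0 <= c < iss.M for c in obs):
        raise ValueError("observed channel out of range")
    if len(obs) == iss.M:
        return float(iss.phi[target, target])
    V = _submodel_innovation_cov(iss, obs)
    return float(V[obs.index(target), obs.index(target)])


def conditional_gc(model: VARModel) -> GCResult:
    """Conditional Granger causality for every ordered channel pair.

    For pair (i, j) the full-model variance is the (j, j) innovation
    covariance entry and the restricted variance comes from the submodel
    that observes every channel except the driver ``i`` — one DARE solve
    per excluded driver serves all targets.
    """
    if model.M < 2:
        raise ValueError("conditional GC needs at least two channels")
    iss = var_to_iss(model)
    M = model.M
    gc = np.zeros((M, M))
    restricted = np.zeros((M, M))
    full = np.zeros((M, M))
    for i in range(M):
        keep = [c for c in range(M) if c != i]
        try:
            V = _submodel_innovation_cov(iss, keep)
        except DareNonConvergenceError as exc:
            raise DareNonConvergenceError(
                f"restricted model excluding channel {i}: {exc}") from exc
        for pos, j in enumerate(keep):
            lam_full = iss.phi[j, j]
            lam_rest = V[pos, pos]
            restricted[i, j] = lam_rest
            full[i, j] = lam_full
            gc[i, j] = float(np.log(lam_rest / lam_full))
    return GCResult(gc=gc, restricted=restricted, full=full,
                    method="conditional")


def unconditional_gc(model: VARModel, i: int, j: int) -> float:
    """Unconditional (pairwise) Granger causality from ``i`` to ``j``.

    ``ln(lambda_{j|j} / lambda_{j|ij})`` with both variances obtained from
    observation submodels of the same full-model state space.
    """
    if i == j:
        raise ValueError("driver and target must differ")
    iss = var_to_iss(model)
    lam_j = submodel_variance(iss, [j], j)
    lam_ij = submodel_variance(iss, [i, j], j)
    return float(np.log(lam_j / lam_ij))


def unconditional_gc_matrix(model: VARModel) -> GCResult:
    """Unconditional GC for every ordered pair (used for the ring analysis)."""
    iss = var_to_iss(model)
    M = model.M
    gc = np.zeros((M, M))
    restricted = np.zeros((M, M))
    full = np.zeros((M, M))
    lam_self = np.array([submodel_variance(iss, [j], j) for j in range(M)])
    for i in range(M):
        for j in range(M):
            if i == j:
                continue
            lam_ij = submodel_variance(iss, [i, j], j)
            restricted[i, j] = lam_self[j]
            full[i, j] = lam_ij
            gc[i, j] = float(np.log(lam_self[j] / lam_ij))
    return GCResult(gc=gc, restricted=restricted, full=full,
                    method="unconditional")
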