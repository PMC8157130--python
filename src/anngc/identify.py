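"""VAR identification: closed-form OLS and sparse neural-network training.

The "neural network" is a single linear layer mapping the ``Mp`` lagged
inputs to the ``M`` present outputs; its weight matrix coincides with the
stacked VAR coefficient matrix, so training it with full-batch gradient
descent under an L1 cumulative penalty (SGD-L1) yields a sparse VAR
estimate in which exact-zero weight blocks encode absent causal links.

The cumulative-penalty scheme keeps, for every weight, the total L1
penalty it could have received (``u``, identical for all weights) and the
signed penalty it actually absorbed (``q``); after each gradient step the
weight is clipped toward zero by the outstanding difference, never past
zero.  This produces exact zeros without subgradient ambiguity.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .models import TimeSeriesPanel, VARModel

__all__ = [
    "RegressorSet",
    "TrainConfig",
    "TrainState",
    "LambdaSelection",
    "build_regression",
    "ols_fit",
    "init_weights",
    "sgdl1_train",
    "select_lambda",
    "bic_order",
    "fit_ann",
]

_DIVERGENCE_BOUND = 1e8


@dataclass
class RegressorSet:
    """Paired targets ``y`` ((N-p) x M) and lagged design ``y^p`` ((N-p) x Mp).

    Design column ``k*M + i`` holds channel ``i`` at lag ``k+1``, matching
    the stacked-coefficient layout of :class:`~anngc.models.VARModel`.
    """

    targets: np.ndarray
    design: np.ndarray
    p: int
    M: int

    def __post_init__(self) -> None:
        self.targets = np.asarray(self.targets, dtype=float)
        self.design = np.asarray(self.design, dtype=float)
        if self.targets.shape[0] != self.design.shape[0]:
            raise ValueError("targets and design row counts differ")
        if self.design.shape[1] != self.M * self.p:
            raise ValueError("design must have M*p columns")

    @property
    def n_rows(self) -> int:
        return self.targets.shape[0]


@dataclass
class TrainConfig:
    """Gradient-descent settings for SGD-L1 training.

    ``lr`` is the constant learning rate, ``n_iter`` the number of
    full-batch iterations, ``lam`` the L1 regularization parameter
    (``lam = 0`` disables clipping and the training converges to OLS).
    """

    lr: float = 1e-3
    n_iter: int = 1000
    lam: float = 0.0
    init: str = "glorot-uniform"
    seed: int | None = None
    normalize: bool = True

    def __post_init__(self) -> None:
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        if self.lam < 0:
            raise ValueError("lambda must be non-negative")


@dataclass
class TrainState:
    """Weights plus cumulative-penalty bookkeeping after training.

    ``eta_eff`` is the effective per-iteration step actually applied (the
    nominal per-sample rate times the batch size, spectrally capped).
    """

    W: np.ndarray
    u: float
    q: np.ndarray
    iteration: int
    eta_eff: float = float("nan")

    @property
    def n_nonzero(self) -> int:
        return int(np.count_nonzero(self.W))


@dataclass
class LambdaSelection:
    """Outcome of the hold-out search for the regularization parameter."""

    lam: float
    state: TrainState
    grid: np.ndarray
    rss: np.ndarray
    n_nonzero: np.ndarray
    train_rows: np.ndarray
    test_rows: np.ndarray

    def __iter__(self):  # allows ``lam, state = select_lambda(...)``
        return iter((self.lam, self.state))


def build_regression(panel: TimeSeriesPanel, p: int) -> RegressorSet:
    """Stack lagged rows into the regression pair (targets, design).

    Row ``n`` of the design is ``[Y_{n-1}, ..., Y_{n-p}]`` for target row
    ``Y_n``, ``n = p+1 .. N``.
    """
    if p < 1:
        raise ValueError("order p must be >= 1")
    Y = panel.values
    N, M = Y.shape
    if N <= p:
        raise ValueError(f"need N > p rows, got N={N}, p={p}")
    if N <= M * p:
        warnings.warn(
            f"N={N} <= M*p={M * p}: the regression is underdetermined",
            stacklevel=2)
    design = np.concatenate([Y[p - k - 1:N - k - 1] for k in range(p)], axis=1)
    return RegressorSet(targets=Y[p:], design=design, p=p, M=M)


def _unstack(W: np.ndarray, p: int, M: int) -> np.ndarray:
    return W.reshape(p, M, M)


def ols_fit(reg: RegressorSet, *, allow_singular: bool = False) -> VARModel:
    """Closed-form least-squares VAR estimate.

    Solves ``min_A ||y - y^p A||^2``; the innovation covariance is the
    residual covariance with divisor ``N - p`` (the row count).  A
    rank-deficient design raises unless ``allow_singular`` enables the
    minimum-norm pseudo-inverse solution (with a warning).
    """
    X, y = reg.design, reg.targets
    A, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        if not allow_singular:
            raise np.linalg.LinAlgError(
                f"singular normal equations (rank {rank} < {X.shape[1]}); "
                "pass allow_singular=True for the pseudo-inverse solution")
        warnings.warn("rank-deficient design: using minimum-norm solution",
                      stacklevel=2)
    resid = y - X @ A
    innov_cov = resid.T @ resid / reg.n_rows
    return VARModel(_unstack(A, reg.p, reg.M), innov_cov,
                    meta={"method": "ols", "rank": int(rank)})


def init_weights(rows: int, cols: int, scheme: str,
                 rng: np.random.Generator) -> np.ndarray:
    """Initial weight matrix under a named fan-scaled scheme."""
    if rows < 1 or cols < 1:
        raise ValueError("dimensions must be positive")
    if scheme == "zeros":
        return np.zeros((rows, cols))
    if scheme == "glorot-uniform":
        limit = math.sqrt(6.0 / (rows + cols))
        return rng.uniform(-limit, limit, size=(rows, cols))
    if scheme == "glorot-normal":
        std = math.sqrt(2.0 / (rows + cols))
        return rng.standard_normal((rows, cols)) * std
    raise ValueError(f"unknown init scheme {scheme!r}")


def sgdl1_train(reg: RegressorSet, cfg: TrainConfig,
                W0: np.ndarray | None = None) -> TrainState:
    """Full-batch gradient descent with the L1 cumulative penalty.

    One iteration stands for one pass of the reference per-sample update
    loop over the data: a per-sample learning rate ``lr`` accumulates a
    step of ``lr * N`` (N = training rows) on the mean-squared-error
    gradient per pass, so the full-batch step is ``eta_eff = lr * N``,
    capped at the largest spectrally stable value for the quadratic loss.
    Each iteration then advances the cumulative penalty ``u`` by
    ``lam * eta_eff / N`` and clips every weight toward zero by the
    penalty it has not yet absorbed; clipped weights land exactly on zero
    and never overshoot.
    """
    X, y = reg.design, reg.targets
    n = reg.n_rows
    if W0 is None:
        rng = np.random.default_rng(cfg.seed)
        W = init_weights(X.shape[1], y.shape[1], cfg.init, rng)
    else:
        W = np.array(W0, dtype=float, copy=True)
    # Precomputed Gram matrices make each full-batch step O((Mp)^2 M)
    # instead of O(N Mp M).
    G = X.T @ X / n
    H = X.T @ y / n
    # loss curvature is 2G; steps beyond ~1/(2 lam_max) lose monotone
    # descent, so the one-pass step lr*n is capped there
    lam_max = float(np.linalg.eigvalsh(G)[-1])
    eta_eff = min(cfg.lr * n, 0.45 / max(lam_max, 1e-12))
    q = np.zeros_like(W)
    u = 0.0
    du = cfg.lam * eta_eff / n
    for j in range(1, cfg.n_iter + 1):
        W_half = W - eta_eff * 2.0 * (G @ W - H)
        u += du
        if cfg.lam > 0.0:
            pos = W_half > 0.0
            neg = W_half < 0.0
            W = np.where(pos, np.maximum(0.0, W_half - (u + q)),
                         np.where(neg, np.minimum(0.0, W_half + (u - q)), 0.0))
            q += W - W_half
        else:
            W = W_half
        if j % 100 == 0 or j == cfg.n_iter:
            if not np.isfinite(W).all() or np.abs(W).max() > _DIVERGENCE_BOUND:
                raise FloatingPointError(
                    f"training diverged at iteration {j} "
                    f"(lr={cfg.lr}, lam={cfg.lam}); reduce the learning rate")
    return TrainState(W=W, u=u, q=q, iteration=cfg.n_iter, eta_eff=eta_eff)


def _zscore(mat: np.ndarray, mean: np.ndarray, std: np.ndarray) -> np.ndarray:
    return (mat - mean) / std


def _split_stats(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = mat.mean(axis=0)
    std = mat.std(axis=0)
    std = np.where(std > 0, std, 1.0)
    return mean, std


def find_lambda_upper(reg: RegressorSet, cfg: TrainConfig,
                      lam0: float = 1e-3, max_doublings: int = 60) -> float:
    """Smallest power-of-two multiple of ``lam0`` giving all-zero weights."""
    lam = lam0
    for _ in range(max_doublings):
        state = sgdl1_train(reg, _with_lam(cfg, lam))
        if state.n_nonzero == 0:
            return lam
        lam *= 2.0
    raise RuntimeError("could not bracket the all-zero regularization level")


def _with_lam(cfg: TrainConfig, lam: float) -> TrainConfig:
    return TrainConfig(lr=cfg.lr, n_iter=cfg.n_iter, lam=lam, init=cfg.init,
                       seed=cfg.seed, normalize=cfg.normalize)


def select_lambda(reg: RegressorSet, cfg_base: TrainConfig,
                  grid_size: int = 300,
                  rng: np.random.Generator | None = None,
                  se_fraction: float = 0.5) -> LambdaSelection:
    """Hold-out selection of the L1 regularization parameter.

    A random 10% of the rows is held out; both splits are z-scored with
    training-split statistics.  Training runs once per grid value on a
    log-spaced grid between the maximum-density and maximum-sparseness
    endpoints.  The winner is chosen by a standard-error parsimony rule:
    the sparsest (largest) lambda whose hold-out RSS is within
    ``se_fraction`` standard errors of the grid minimum; all-zero
    solutions are excluded.  The default margin is half a standard error —
    the 10% hold-out split makes a full SE wide enough to over-sparsify in
    data-paucity regimes.  The per-lambda RSS and nonzero counts are
    returned for inspection.
    """
    if grid_size < 2:
        raise ValueError("grid_size must be >= 2")
    rng = np.random.default_rng(cfg_base.seed) if rng is None else rng
    if cfg_base.seed is None:  # pin the init so the search is reproducible
        cfg_base = _with_lam(cfg_base, cfg_base.lam)
        cfg_base.seed = int(rng.integers(2 ** 31))
    n = reg.n_rows
    perm = rng.permutation(n)
    n_test = max(1, int(round(0.1 * n)))
    test_rows, train_rows = perm[:n_test], perm[n_test:]
    mean_x, std_x = _split_stats(reg.design[train_rows])
    mean_y, std_y = _split_stats(reg.targets[train_rows])
    train = RegressorSet(
        _zscore(reg.targets[train_rows], mean_y, std_y),
        _zscore(reg.design[train_rows], mean_x, std_x), reg.p, reg.M)
    X_test = _zscore(reg.design[test_rows], mean_x, std_x)
    y_test = _zscore(reg.targets[test_rows], mean_y, std_y)

    lam_u = find_lambda_upper(train, cfg_base)
    lam_l = lam_u / 1e4
    grid = np.geomspace(lam_l, lam_u, grid_size)
    rss = np.empty(grid_size)
    rss_se = np.empty(grid_size)
    nnz = np.empty(grid_size, dtype=int)
    states: list[TrainState] = []
    for g, lam in enumerate(grid):
        state = sgdl1_train(train, _with_lam(cfg_base, lam))
        states.append(state)
        nnz[g] = state.n_nonzero
        sq = (y_test - X_test @ state.W) ** 2
        rss[g] = float(sq.sum())
        rss_se[g] = float(np.sqrt(sq.size) * sq.std())
    valid = np.flatnonzero(nnz > 0)
    if valid.size == 0:
        raise RuntimeError("every grid value produced an all-zero weight matrix")
    g_min = valid[np.argmin(rss[valid])]
    eligible = valid[rss[valid] <= rss[g_min] + se_fraction * rss_se[g_min]]
    g_star = int(eligible.max())  # sparsest lambda within one SE of the best
    return LambdaSelection(lam=float(grid[g_star]), state=states[g_star],
                           grid=grid, rss=rss, n_nonzero=nnz,
                           train_rows=train_rows, test_rows=test_rows)


@dataclass
class ANNFit:
    """A trained sparse VAR estimate plus its selection trace."""

    model: VARModel
    state: TrainState
    selection: LambdaSelection | None
    scale_x: np.ndarray = field(default_factory=lambda: np.empty(0))
    scale_y: np.ndarray = field(default_factory=lambda: np.empty(0))


def fit_ann(panel: TimeSeriesPanel, p: int, cfg: TrainConfig,
            grid_size: int = 300, lam: float | None = None,
            rng: np.random.Generator | None = None) -> ANNFit:
    """End-to-end sparse identification of a VAR model from a panel.

    Builds the regression, selects the regularization parameter on a
    hold-out split (unless ``lam`` is fixed), and maps the trained weights
    back to the original units.  Zero weights stay exactly zero under the
    rescaling, so the sparsity pattern is unit-independent.  The innovation
    covariance is the residual covariance of the final model over all rows.
    """
    reg = build_regression(panel, p)
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    if cfg.seed is None:
        cfg = _with_lam(cfg, cfg.lam)
        cfg.seed = int(rng.integers(2 ** 31))
    if lam is None:
        sel = select_lambda(reg, cfg_base=cfg, grid_size=grid_size, rng=rng)
        state = sel.state
        rows = sel.train_rows
    else:
        sel = None
        rows = np.arange(reg.n_rows)
        mean_x, std_x = _split_stats(reg.design[rows])
        mean_y, std_y = _split_stats(reg.targets[rows])
        norm = RegressorSet(_zscore(reg.targets, mean_y, std_y),
                            _zscore(reg.design, mean_x, std_x), reg.p, reg.M)
        state = sgdl1_train(norm, _with_lam(cfg, lam))
    mean_x, std_x = _split_stats(reg.design[rows])
    mean_y, std_y = _split_stats(reg.targets[rows])
    # weights learned on z-scored columns: A_orig = diag(1/std_x) W diag(std_y)
    W_orig = (state.W / std_x[:, None]) * std_y[None, :]
    resid = (reg.targets - reg.targets.mean(axis=0)) - \
        (reg.design - reg.design.mean(axis=0)) @ W_orig
    innov_cov = resid.T @ resid / reg.n_rows
    model = VARModel(_unstack(W_orig, reg.p, reg.M), innov_cov,
                     meta={"method": "ann", "lam": sel.lam if sel else lam,
                           "lr": cfg.lr, "n_iter": cfg.n_iter})
    return ANNFit(model=model, state=state, selection=sel,
                  scale_x=std_x, scale_y=std_y)


def bic_order(panel: TimeSeriesPanel, p_max: int) -> int:
    """Model order minimizing the multivariate Bayesian Information Criterion.

    All candidate orders are fitted on the common window ``p_max+1..N`` so
    their likelihoods are comparable; BIC = ln det(residual covariance) +
    ln(n)/n * M^2 * p.
    """
    if p_max < 1:
        raise ValueError("p_max must be >= 1")
    Y = panel.values
    N, M = Y.shape
    if N <= M * p_max:
        raise ValueError("insufficient samples for the requested p_max")
    n = N - p_max
    y = Y[p_max:]
    best_p, best_bic = 1, np.inf
    for p in range(1, p_max + 1):
        X = np.concatenate(
            [Y[p_max - k - 1:N - k - 1] for k in range(p)], axis=1)
        A, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ A
        sigma = resid.T @ resid / n
        sign, logdet = np.linalg.slogdet(sigma)
        if sign <= 0:
            continue
        bic = logdet + math.log(n) / n * (M * M * p)
        if bic < best_bic:
            best_p, best_bic = p, bic
    return best_p
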