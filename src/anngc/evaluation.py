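"""Scoring of estimated GC magnitude and topology against ground truth.

Magnitude accuracy is measured by the mean absolute GC error split over
null and non-null links (BIAS0 / BIAS1); topology recovery by FNR, FPR and
a single-operating-point trapezoidal AUC; and the overall score S averages
the normalized non-null bias and 1-AUC across sample-size (K) conditions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .identify import TrainConfig, fit_ann, ols_fit, build_regression
from .models import VARModel
from .significance import significance_ann, significance_ols
from .simulate import (SimulationSpec, add_noise_snr, generate_network_sim1,
                       generate_network_sim3, k_ratio_to_length, simulate_var)
from .state_space import DareNonConvergenceError, conditional_gc

__all__ = [
    "PerformanceReport",
    "bias_measures",
    "classification_rates",
    "auc_trapezoid",
    "s_parameter",
    "run_benchmark",
]


def _offdiag(M: int) -> np.ndarray:
    return ~np.eye(M, dtype=bool)


def bias_measures(gc_true: np.ndarray, gc_est: np.ndarray,
                  links: np.ndarray) -> tuple[float, float]:
    """Mean absolute GC error over null links (BIAS0) and links (BIAS1)."""
    gc_true = np.asarray(gc_true, float)
    gc_est = np.asarray(gc_est, float)
    links = np.asarray(links, bool)
    if not gc_true.shape == gc_est.shape == links.shape:
        raise ValueError("shape mismatch")
    off = _offdiag(links.shape[0])
    err = np.abs(gc_true - gc_est)
    null_sel = off & ~links
    link_sel = off & links
    if not null_sel.any() or not link_sel.any():
        raise ValueError("both null and non-null link classes must be nonempty")
    return float(err[null_sel].mean()), float(err[link_sel].mean())


def classification_rates(links_true: np.ndarray, links_est: np.ndarray
                         ) -> tuple[float, float, float]:
    """(FNR, FPR, TPR) of an estimated link mask against the ground truth.

    Degenerate truths (no links, or all links) leave the undefined rate as
    NaN and return the defined one.
    """
    truth = np.asarray(links_true, bool)
    est = np.asarray(links_est, bool)
    off = _offdiag(truth.shape[0])
    pos = truth & off
    neg = ~truth & off
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    fnr = float((pos & ~est).sum() / n_pos) if n_pos else float("nan")
    fpr = float((neg & est).sum() / n_neg) if n_neg else float("nan")
    tpr = 1.0 - fnr if n_pos else float("nan")
    return fnr, fpr, tpr


def auc_trapezoid(fpr: float, tpr: float) -> float:
    """Area under the polyline (0,0) -> (FPR, TPR) -> (1,1) in ROC space."""
    if not (0.0 <= fpr <= 1.0 and 0.0 <= tpr <= 1.0):
        raise ValueError("rates must lie in [0, 1]")
    return fpr * tpr / 2.0 + (1.0 - fpr) * (tpr + 1.0) / 2.0


def s_parameter(norm_bias1: np.ndarray, auc: np.ndarray) -> float:
    """Overall score: mean over K of normalized BIAS1 and of 1-AUC, averaged."""
    b = np.asarray(norm_bias1, float)
    a = np.asarray(auc, float)
    if b.shape != a.shape:
        raise ValueError("per-K arrays must align")
    return float((b.mean() + (1.0 - a).mean()) / 2.0)


@dataclass
class PerformanceReport:
    """Per-cell benchmark outcome: raw per-network values plus summaries."""

    study: str
    method: str
    K: float
    snr: float | None
    lr: float
    n_train: int
    n_networks: int
    seed: int
    bias0: np.ndarray = field(default_factory=lambda: np.empty(0))
    bias1: np.ndarray = field(default_factory=lambda: np.empty(0))
    norm_bias1: np.ndarray = field(default_factory=lambda: np.empty(0))
    fnr: np.ndarray = field(default_factory=lambda: np.empty(0))
    fpr: np.ndarray = field(default_factory=lambda: np.empty(0))
    auc: np.ndarray = field(default_factory=lambda: np.empty(0))
    n_dare_failures: int = 0

    def mean(self, name: str) -> float:
        vals = getattr(self, name)
        vals = vals[np.isfinite(vals)]
        return float(vals.mean()) if vals.size else float("nan")

    def ci95(self, name: str, n_boot: int = 2000, seed: int = 0
             ) -> tuple[float, float]:
        """Percentile-bootstrap 95% interval of the mean."""
        vals = getattr(self, name)
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            return float("nan"), float("nan")
        rng = np.random.default_rng(seed)
        boots = rng.choice(vals, size=(n_boot, vals.size)).mean(axis=1)
        lo, hi = np.percentile(boots, [2.5, 97.5])
        return float(lo), float(hi)

    def summary(self) -> dict:
        out = {"study": self.study, "method": self.method, "K": self.K,
               "snr": self.snr, "lr": self.lr, "n_train": self.n_train,
               "n_networks": self.n_networks,
               "n_dare_failures": self.n_dare_failures}
        for name in ("bias0", "bias1", "norm_bias1", "fnr", "fpr", "auc"):
            out[f"{name}_mean"] = self.mean(name)
            out[f"{name}_ci95"] = self.ci95(name)
        return out


def _generate(study: str, K: float, snr: float | None,
              rng: np.random.Generator) -> tuple[VARModel, SimulationSpec]:
    if study in ("I", "II"):
        spec = SimulationSpec(study="I", K_ratio=K, snr=snr)
        return generate_network_sim1(spec, rng), spec
    if study == "III":
        spec = SimulationSpec(study="III", M=10, p=6, K_ratio=K, snr=snr)
        return generate_network_sim3(spec, rng), spec
    raise ValueError(f"unknown study {study!r}")


def evaluate_network(study: str, method: str, K: float, snr: float | None,
                     cfg: TrainConfig, rng: np.random.Generator,
                     lambda_grid: int = 50, n_surr: int = 100,
                     compute_gc: bool = True) -> dict:
    """One network end to end: generate, simulate, identify, score.

    Returns per-network metrics; DARE failures on the estimated model are
    reported in the ``failed`` field rather than raised, except that they
    always leave the magnitude metrics NaN.
    """
    model, _spec = _generate(study, K, snr, rng)
    N = k_ratio_to_length(K, model.M, model.p)
    panel = simulate_var(model, N, rng)
    if snr is not None:
        panel = add_noise_snr(panel, snr, rng)
    links = model.link_mask()
    out: dict = {"links": links, "failed": False,
                 "bias0": np.nan, "bias1": np.nan, "norm_bias1": np.nan}

    if method == "ann":
        fit = fit_ann(panel, model.p, cfg, grid_size=lambda_grid, rng=rng)
        mask = significance_ann(fit.state.W, model.p, model.M)
        est_model = fit.model
    elif method == "ols":
        if compute_gc:
            ens = significance_ols(panel, model.p, n_surr=n_surr, rng=rng)
            mask = ens.mask
            est_model = None
            gc_est = ens.gc
        else:
            est_model = ols_fit(build_regression(panel, model.p),
                                allow_singular=True)
            mask = None
    else:
        raise ValueError(f"unknown method {method!r}")

    if compute_gc:
        gc_true = conditional_gc(model).gc
        try:
            if method == "ann":
                gc_est = conditional_gc(est_model).gc
            b0, b1 = bias_measures(gc_true, gc_est, links)
            out["bias0"], out["bias1"] = b0, b1
            denom = gc_true[links & _offdiag(model.M)].mean()
            out["norm_bias1"] = b1 / denom if denom > 0 else np.nan
        except DareNonConvergenceError:
            out["failed"] = True
    if mask is not None:
        fnr, fpr, tpr = classification_rates(links, mask)
        out["fnr"], out["fpr"] = fnr, fpr
        out["auc"] = auc_trapezoid(fpr, tpr)
    return out


def run_benchmark(study: str, method: str, K_values, snr_values=None,
                  lr: float = 1e-3, n_train: int = 1000,
                  n_networks: int = 10, seed: int = 0,
                  lambda_grid: int = 50, n_surr: int = 100,
                  compute_gc: bool = True) -> list[PerformanceReport]:
    """Scaled-down reproduction of one benchmark grid.

    For each (K, SNR) cell, ``n_networks`` ground-truth networks are
    generated, simulated, identified with the requested estimator, and
    scored against the truth.  For the OLS path at K = 1 the expected DARE
    non-convergence is recorded per cell instead of aborting the sweep.
    """
    aliases = {"1": "I", "2": "II", "3": "III"}
    study = aliases.get(str(study), str(study).upper())
    if study not in ("I", "II", "III"):
        raise ValueError(f"unknown study {study!r}")
    snr_list = list(snr_values) if snr_values is not None else [None]
    cfg = TrainConfig(lr=lr, n_iter=n_train)
    reports = []
    ss = np.random.SeedSequence(seed)
    for K in K_values:
        for snr in snr_list:
            rep = PerformanceReport(study=study, method=method, K=K, snr=snr,
                                    lr=lr, n_train=n_train,
                                    n_networks=n_networks, seed=seed)
            rows: dict[str, list] = {k: [] for k in
                                     ("bias0", "bias1", "norm_bias1",
                                      "fnr", "fpr", "auc")}
            children = ss.spawn(n_networks)
            for child in children:
                rng = np.random.default_rng(child)
                try:
                    res = evaluate_network(study, method, K, snr, cfg, rng,
                                           lambda_grid=lambda_grid,
                                           n_surr=n_surr,
                                           compute_gc=compute_gc)
                except DareNonConvergenceError:
                    rep.n_dare_failures += 1
                    continue
                if res.get("failed"):
                    rep.n_dare_failures += 1
                for k in rows:
                    rows[k].append(res.get(k, np.nan))
            for k, vals in rows.items():
                setattr(rep, k, np.asarray(vals, float))
            reports.append(rep)
    return reports
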