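"""State-space GC: ISS construction, DARE solutions, oracle equivalence."""

import numpy as np
import pytest
from scipy.linalg import solve_discrete_are

from anngc.identify import build_regression, ols_fit
from anngc.models import VARModel
from anngc.simulate import simulate_var
from anngc.state_space import (DareNonConvergenceError, conditional_gc,
                               solve_dare, submodel_variance, unconditional_gc,
                               var_to_iss)


def _random_stable_bivariate(seed: int, p: int = 1) -> VARModel:
    rng = np.random.default_rng(seed)
    for _ in range(100):
        coeffs = rng.uniform(-0.7, 0.7, size=(p, 2, 2))
        m = VARModel(coeffs, np.diag(rng.uniform(0.5, 2.0, size=2)))
        from anngc.models import is_stable
        if is_stable(m)[0]:
            return m
    raise RuntimeError


def _restricted_variance_by_regression(panel, keep, target, order):
    """Brute-force oracle: long-order OLS on the kept channels only."""
    sub = panel.values[:, keep]
    from anngc.models import TimeSeriesPanel
    reg = build_regression(TimeSeriesPanel(sub), order)
    est = ols_fit(reg)
    return est.innov_cov[keep.index(target), keep.index(target)]


class TestVarToIss:
    def test_univariate_ar1(self):
        m = VARModel(np.array([[[0.5]]]), np.array([[1.0]]))
        iss = var_to_iss(m)
        assert iss.state_dim == 1
        assert iss.A[0, 0] == 0.5 and iss.C[0, 0] == 0.5
        assert iss.phi[0, 0] == 1.0

    def test_phi_equals_sigma(self, sim1_model):
        iss = var_to_iss(sim1_model)
        np.testing.assert_array_equal(iss.phi, sim1_model.innov_cov)

    def test_iss_simulation_matches_var(self, bivariate_coupled):
        """Driving ISS and VAR with one innovation sequence gives the same y."""
        m = bivariate_coupled
        iss = var_to_iss(m)
        rng = np.random.default_rng(0)
        T = 200
        e = rng.standard_normal((T, 2))
        # VAR recursion (row convention)
        y_var = np.zeros((T, 2))
        for n in range(T):
            if n >= 1:
                y_var[n] = y_var[n - 1] @ m.coeffs[0]
            y_var[n] += e[n]
        # ISS recursion (column convention internally)
        x = np.zeros(iss.state_dim)
        y_iss = np.zeros((T, 2))
        for n in range(T):
            y_iss[n] = iss.C @ x + e[n]
            x = iss.A @ x + iss.K @ e[n]
        np.testing.assert_allclose(y_iss, y_var, atol=1e-12)

    def test_unstable_model_raises(self):
        m = VARModel(np.array([[[1.01]]]), np.array([[1.0]]))
        with pytest.raises(DareNonConvergenceError):
            var_to_iss(m)


class TestSolveDare:
    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_scipy(self, seed):
        """Doubling solver vs scipy.linalg.solve_discrete_are (oracle)."""
        rng = np.random.default_rng(seed)
        m = _random_stable_bivariate(seed, p=3)
        iss = var_to_iss(m)
        keep = [1]
        Cs = iss.C[keep, :]
        Q = iss.K @ iss.phi @ iss.K.T
        R = iss.phi[np.ix_(keep, keep)]
        S = iss.K @ iss.phi[:, keep]
        P, V = solve_dare(iss.A, Cs, Q, R, S)
        P_ref = solve_discrete_are(iss.A.T, Cs.T, Q, R, s=S)
        np.testing.assert_allclose(P, P_ref, rtol=1e-8, atol=1e-10)

    def test_singular_r_raises(self):
        m = VARModel(np.array([[[0.5, 0.2], [0.0, 0.4]]]), np.zeros((2, 2)))
        iss_like_phi = np.zeros((2, 2))
        iss = var_to_iss(VARModel(m.coeffs, np.eye(2)))
        with pytest.raises(DareNonConvergenceError):
            solve_dare(iss.A, iss.C[:1], iss.K @ iss_like_phi @ iss.K.T,
                       iss_like_phi[:1, :1], iss.K @ iss_like_phi[:, :1])


class TestSubmodelVariance:
    def test_full_observation_returns_sigma_exactly(self, sim1_model):
        iss = var_to_iss(sim1_model)
        for j in range(sim1_model.M):
            assert submodel_variance(iss, range(10), j) == \
                sim1_model.innov_cov[j, j]

    def test_independent_channels(self):
        coeffs = np.zeros((1, 2, 2))
        coeffs[0, 0, 0], coeffs[0, 1, 1] = 0.6, 0.4
        m = VARModel(coeffs, np.diag([1.0, 2.0]))
        iss = var_to_iss(m)
        # observing only channel 1: still its own univariate innovation
        assert submodel_variance(iss, [1], 1) == pytest.approx(2.0, rel=1e-9)

    def test_restricted_variance_matches_long_regression(self,
                                                         bivariate_coupled):
        """DARE variance vs an order-50 restricted OLS on 4e5 samples."""
        panel = simulate_var(bivariate_coupled, 400_000,
                             np.random.default_rng(21))
        iss = var_to_iss(bivariate_coupled)
        lam_ss = submodel_variance(iss, [1], 1)
        lam_reg = _restricted_variance_by_regression(panel, [1], 1, order=50)
        assert lam_ss == pytest.approx(lam_reg, rel=0.01)

    def test_target_must_be_observed(self, bivariate_coupled):
        iss = var_to_iss(bivariate_coupled)
        with pytest.raises(ValueError):
            submodel_variance(iss, [0], 1)


class TestConditionalGC:
    def test_diagonal_model_gives_zero(self):
        coeffs = np.zeros((2, 3, 3))
        for j in range(3):
            coeffs[0, j, j] = 0.5
        res = conditional_gc(VARModel(coeffs, np.eye(3)))
        np.testing.assert_allclose(res.gc, 0.0, atol=1e-10)

    def test_m2_conditional_equals_unconditional(self, bivariate_coupled):
        res = conditional_gc(bivariate_coupled)
        for i, j in ((0, 1), (1, 0)):
            assert res.gc[i, j] == pytest.approx(
                unconditional_gc(bivariate_coupled, i, j), abs=1e-10)

    def test_support_matches_ground_truth(self, sim1_model):
        res = conditional_gc(sim1_model)
        off = ~np.eye(10, dtype=bool)
        assert np.abs(res.gc[off & ~sim1_model.links]).max() <= 1e-10
        assert res.gc[sim1_model.links].min() > 1e-10
        # non-negativity of the theoretical measure
        assert res.gc.min() >= -1e-10

    def test_full_variance_is_sigma_diagonal(self, sim1_model):
        res = conditional_gc(sim1_model)
        off = ~np.eye(10, dtype=bool)
        for i, j in zip(*np.nonzero(off)):
            assert res.full[i, j] == sim1_model.innov_cov[j, j]

    def test_orientation_unidirectional(self, bivariate_coupled):
        # coupling is 0 -> 1: F(0->1) positive, F(1->0) ~ 0
        res = conditional_gc(bivariate_coupled)
        assert res.gc[0, 1] > 0.05
        assert abs(res.gc[1, 0]) < 1e-10


class TestUnconditionalGC:
    def test_independent_channels_zero(self):
        coeffs = np.zeros((1, 2, 2))
        coeffs[0, 0, 0], coeffs[0, 1, 1] = 0.5, -0.3
        m = VARModel(coeffs, np.eye(2))
        assert abs(unconditional_gc(m, 0, 1)) < 1e-8
        assert abs(unconditional_gc(m, 1, 0)) < 1e-8

    def test_bracketed_by_closed_forms_no_self_dynamics(self):
        """a_jj = 0, coupling c: ln(1 + c^2 var(Y_i)) bounds F from above.

        The upper bound treats the target's own past as useless; because
        the driver is autocorrelated, the target's past is mildly
        informative, so the true F sits strictly between the one-step
        bound with lag-1-only restriction and that upper bound.
        """
        c = 0.4
        coeffs = np.zeros((1, 2, 2))
        coeffs[0, 0, 0] = 0.5
        coeffs[0, 0, 1] = c
        m = VARModel(coeffs, np.eye(2))
        var_i = 1.0 / (1 - 0.25)   # AR(1) stationary variance of the driver
        upper = np.log(1 + c * c * var_i)
        f = unconditional_gc(m, 0, 1)
        assert 0.5 * upper < f < upper
        # and the exact value agrees with a long-order restricted regression
        panel = simulate_var(m, 400_000, np.random.default_rng(77))
        lam_j = _restricted_variance_by_regression(panel, [1], 1, order=30)
        lam_ij = _restricted_variance_by_regression(panel, [0, 1], 1, order=5)
        assert f == pytest.approx(np.log(lam_j / lam_ij), rel=0.02)

    @pytest.mark.parametrize("seed", range(6))
    def test_dual_regression_oracle(self, seed):
        """SS-based GC vs the naive two-regression estimate (order 5p)."""
        m = _random_stable_bivariate(seed)
        gc_ss = unconditional_gc(m, 0, 1)
        panel = simulate_var(m, 300_000, np.random.default_rng(seed + 50))
        lam_j = _restricted_variance_by_regression(panel, [1], 1, order=5)
        lam_ij = _restricted_variance_by_regression(panel, [0, 1], 1, order=5)
        gc_reg = np.log(lam_j / lam_ij)
        if gc_ss > 0.01:
            assert gc_ss == pytest.approx(gc_reg, rel=0.02)
        else:
            assert abs(gc_ss - gc_reg) < 0.005

    def test_estimation_consistency(self, bivariate_coupled):
        """OLS-identified GC on a long realization converges to theory."""
        panel = simulate_var(bivariate_coupled, 100_000,
                             np.random.default_rng(33))
        est = ols_fit(build_regression(panel, 1))
        truth = conditional_gc(bivariate_coupled).gc
        got = conditional_gc(est).gc
        assert np.abs(got - truth).max() < 0.005


class TestOLSFailureMode:
    def test_interpolating_fit_raises_dare_error(self):
        """K = 1 geometry: rows < coefficients, singular residuals."""
        from anngc.simulate import SimulationSpec, generate_network_sim3, \
            k_ratio_to_length
        spec = SimulationSpec(study="III", p=6, K_ratio=1)
        m = generate_network_sim3(spec, np.random.default_rng(5))
        N = k_ratio_to_length(1, 10, 6)
        panel = simulate_var(m, N, np.random.default_rng(6))
        with pytest.warns(UserWarning):
            est = ols_fit(build_regression(panel, 6), allow_singular=True)
        with pytest.raises(DareNonConvergenceError):
            conditional_gc(est)
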