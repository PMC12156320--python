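import numpy as np
import pytest
from scipy.optimize import approx_fprime

from ure import (
    Ensemble,
    ObservableClass,
    ObservableSet,
    bias_potential,
    chi2,
    cost,
    deviation_matrix,
    kl_forward,
    kl_reverse,
    optimize_k,
    regularization_path,
    weights_from_k,
)
from ure.core import _cost_and_grad

from .oracles import grid_search_k, grid_search_k_2d


def _obs(exp, calc, sigma, cls=ObservableClass.SHIFT, preconditioned=False):
    exp = np.atleast_1d(np.asarray(exp, float))
    calc = np.atleast_2d(np.asarray(calc, float))
    return ObservableSet(
        labels=tuple(f"o{i}" for i in range(exp.size)),
        obs_class=(cls,) * exp.size,
        exp_value=exp,
        sigma=np.atleast_1d(np.asarray(sigma, float)),
        calc_matrix=calc,
        noe_preconditioned=preconditioned,
    )


class TestDeviationMatrix:
    def test_unit_deviation_column(self):
        d2 = deviation_matrix(_obs([1.0], [[0.0], [1.0]], [1.0]))
        np.testing.assert_allclose(d2.ravel(), [1.0, 0.0])

    def test_sigma_scaling(self):
        d2 = deviation_matrix(_obs([2.0], [[0.0]], [2.0]))
        np.testing.assert_allclose(d2, [[1.0]])

    def test_perfect_agreement_is_zero(self):
        d2 = deviation_matrix(_obs([3.0], [[3.0], [3.0]], [0.5]))
        np.testing.assert_allclose(d2, 0.0)

    def test_noe_one_sided_gates_satisfied_bounds(self):
        # preconditioned NOE: exp = bound^-6; calc >= exp means r <= bound
        obs = _obs(
            [4.0**-6],
            [[3.0**-6], [5.0**-6]],
            [1e-4],
            cls=ObservableClass.NOE_UPPER,
            preconditioned=True,
        )
        d2 = deviation_matrix(obs, noe_one_sided=True)
        assert d2[0, 0] == 0.0  # 3 A satisfies a 4 A upper bound
        assert d2[1, 0] > 0.0  # 5 A violates it
        d2_two = deviation_matrix(obs, noe_one_sided=False)
        assert d2_two[0, 0] > 0.0

    def test_requires_preconditioned_noe(self):
        obs = _obs([4.0], [[3.0], [5.0]], [0.5], cls=ObservableClass.NOE_UPPER)
        with pytest.raises(ValueError, match="precondition"):
            deviation_matrix(obs)


class TestBiasPotential:
    def test_zero_k_gives_zero_potential(self):
        d2 = np.random.default_rng(0).uniform(0, 4, (5, 3))
        np.testing.assert_allclose(bias_potential(np.zeros(3), d2), 0.0)

    def test_direct_evaluation(self):
        np.testing.assert_allclose(
            bias_potential(np.array([2.0]), np.array([[1.0], [0.0]])), [1.0, 0.0]
        )

    def test_additivity_across_observables(self):
        V = bias_potential(np.array([1.0, 1.0]), np.ones((4, 2)))
        np.testing.assert_allclose(V, 1.0)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            bias_potential(np.ones(2), np.ones((4, 3)))


class TestWeightsFromK:
    def test_identity_at_k_zero(self, micro):
        prior, obs = micro
        w = weights_from_k(np.zeros(1), prior, deviation_matrix(obs))
        np.testing.assert_allclose(w.weights, prior.weights, atol=1e-15)

    def test_logistic_hand_value(self, micro):
        prior, obs = micro
        w = weights_from_k(np.array([2.0]), prior, deviation_matrix(obs))
        np.testing.assert_allclose(w.weights, [0.26894, 0.73106], atol=1e-4)

    def test_constant_bias_cancels(self):
        prior = Ensemble(np.array([0.5, 0.5]))
        d2 = np.array([[1.0], [1.0]])
        for k in (0.5, 3.0, -2.0):
            w = weights_from_k(np.array([k]), prior, d2)
            np.testing.assert_allclose(w.weights, [0.5, 0.5], atol=1e-14)

    def test_overflow_guarded(self):
        prior = Ensemble(np.array([0.5, 0.5]))
        d2 = np.array([[2000.0], [0.0]])
        w = weights_from_k(np.array([5.0]), prior, d2)
        assert np.isfinite(w.weights).all()
        assert w.weights.sum() == pytest.approx(1.0)

    def test_prior_zeros_stay_zero_and_support_stays_positive(self):
        prior = Ensemble(np.array([0.0, 0.3, 0.7]))
        d2 = np.array([[0.0], [9.0], [1.0]])
        w = weights_from_k(np.array([4.0]), prior, d2)
        assert w.weights[0] == 0.0
        assert (w.weights[1:] > 0).all()


class TestChi2:
    def test_perfect_fit_is_zero(self, micro):
        prior, obs = micro
        w = Ensemble(np.array([0.0, 1.0]))
        assert chi2(w, obs) == pytest.approx(0.0, abs=1e-15)

    def test_unit_residual(self):
        obs = _obs([1.0], [[0.0], [0.0]], [1.0])
        assert chi2(Ensemble(np.array([0.5, 0.5])), obs) == pytest.approx(1.0)

    def test_micro_hand_value(self, micro):
        _, obs = micro
        w = Ensemble(np.array([0.26894, 0.73106]))
        assert chi2(w, obs) == pytest.approx(0.07233, abs=1e-4)

    def test_noe_one_sided_zero_when_satisfied(self):
        # ensemble-averaged r^-6 above the preconditioned bound => satisfied
        obs = _obs(
            [4.0**-6],
            [[3.0**-6], [3.5**-6]],
            [1e-4],
            cls=ObservableClass.NOE_UPPER,
            preconditioned=True,
        )
        assert chi2(Ensemble(np.array([0.5, 0.5])), obs) == 0.0
        # two-sided treatment penalizes the same ensemble
        assert chi2(Ensemble(np.array([0.5, 0.5])), obs, noe_one_sided=False) > 0


class TestKLDivergences:
    def test_zero_iff_equal(self):
        p = Ensemble(np.array([0.3, 0.7]))
        assert kl_forward(p, p) == 0.0
        assert kl_reverse(p, p) == 0.0

    def test_forward_hand_values(self):
        p = np.array([0.5, 0.5])
        q = np.array([0.26894, 0.73106])
        assert kl_forward(p, q) == pytest.approx(0.1201, abs=1e-3)
        assert kl_forward(np.array([1.0, 0.0]), np.array([0.5, 0.5])) == (
            pytest.approx(np.log(2))
        )

    def test_reverse_hand_values(self):
        assert kl_reverse(
            np.array([1.0, 0.0, 0.0, 0.0]), np.full(4, 0.25)
        ) == pytest.approx(np.log(4))
        assert kl_reverse(
            np.array([0.26894, 0.73106]), np.array([0.5, 0.5])
        ) == pytest.approx(0.1109, abs=1e-3)

    def test_forward_infinite_off_support(self):
        assert kl_forward(np.array([0.5, 0.5]), np.array([1.0, 0.0])) == np.inf

    def test_zero_prior_terms_ignored(self):
        assert kl_forward(np.array([0.0, 1.0]), np.array([0.5, 0.5])) == (
            pytest.approx(np.log(2))
        )


class TestCost:
    def test_k_zero_is_chi2_init(self, micro):
        prior, obs = micro
        assert cost(np.zeros(1), 1.0, prior, obs) == pytest.approx(
            chi2(prior, obs)
        )

    def test_micro_sum_of_derived_values(self, micro):
        prior, obs = micro
        assert cost(np.array([2.0]), 1.0, prior, obs) == pytest.approx(
            0.1201 + 0.0723, abs=1e-3
        )

    def test_theta_must_be_positive(self, micro):
        prior, obs = micro
        with pytest.raises(ValueError):
            cost(np.zeros(1), 0.0, prior, obs)


class TestGradient:
    @pytest.mark.parametrize("direction", ["forward", "reverse"])
    def test_analytic_gradient_matches_finite_differences(
        self, small_grid_fixture, direction
    ):
        fix = small_grid_fixture
        d2 = deviation_matrix(fix.obs)
        w0 = fix.prior.weights
        logw0 = np.log(w0)
        k = np.linspace(-0.5, 1.5, fix.obs.n_observables)

        def f(kk):
            return _cost_and_grad(
                kk, 0.3, w0, logw0, d2, fix.obs, direction, True
            )[0]

        g_num = approx_fprime(k, f, 1e-7)
        g_ana = _cost_and_grad(k, 0.3, w0, logw0, d2, fix.obs, direction, True)[1]
        np.testing.assert_allclose(g_ana, g_num, atol=1e-4)


class TestOptimizeK:
    def test_perfect_prior_returns_identity(self):
        prior = Ensemble(np.array([0.4, 0.6]))
        calc = np.array([[1.0], [2.0]])
        exp = [float(prior.weights @ calc.ravel())]
        res = optimize_k(0.5, prior, _obs(exp, calc, [0.3]))
        np.testing.assert_allclose(res.k_opt, 0.0)
        np.testing.assert_allclose(res.weights_opt.weights, prior.weights)
        assert res.chi2_init == 0.0

    def test_matches_dense_grid_search(self, micro):
        prior, obs = micro
        res = optimize_k(0.2, prior, obs)
        k_star, c_star = grid_search_k(0.2, prior, obs)
        assert res.cost == pytest.approx(c_star, abs=1e-3)
        assert res.k_opt[0] == pytest.approx(k_star[0], abs=0.05)
        assert res.k_opt[0] == pytest.approx(2.8, abs=0.1)
        assert res.cost == pytest.approx(0.0846, abs=1e-3)

    def test_matches_2d_grid_search(self):
        # two observables, four conformers
        prior = Ensemble(np.full(4, 0.25))
        calc = np.array([[0.0, 1.0], [1.0, 0.0], [1.0, 1.0], [0.0, 0.0]])
        obs = _obs([1.0, 1.0], calc, [0.8, 0.8])
        res = optimize_k(0.1, prior, obs)
        _, c_star = grid_search_k_2d(0.1, prior, obs)
        assert res.cost == pytest.approx(c_star, abs=1e-3)

    def test_huge_theta_is_underfitting_limit(self, small_grid_fixture):
        fix = small_grid_fixture
        res = optimize_k(1e6, fix.prior, fix.obs)
        assert abs(res.chi2_opt - res.chi2_init) < 1e-4
        assert res.ensemble_preservation > 99.9

    def test_never_worse_than_prior(self, small_grid_fixture):
        fix = small_grid_fixture
        for theta in (1e-3, 0.1, 10.0):
            res = optimize_k(theta, fix.prior, fix.obs)
            assert res.chi2_opt <= res.chi2_init + 1e-12
            assert res.cost <= res.chi2_init + 1e-12

    def test_deterministic(self, small_grid_fixture):
        fix = small_grid_fixture
        r1 = optimize_k(0.2, fix.prior, fix.obs)
        r2 = optimize_k(0.2, fix.prior, fix.obs)
        np.testing.assert_array_equal(r1.k_opt, r2.k_opt)
        np.testing.assert_array_equal(r1.weights_opt.weights, r2.weights_opt.weights)

    def test_nonnegative_constraint(self, small_grid_fixture):
        fix = small_grid_fixture
        res = optimize_k(0.05, fix.prior, fix.obs, nonnegative=True)
        assert (res.k_opt >= 0).all()

    def test_diagnostics_populated(self, micro):
        prior, obs = micro
        res = optimize_k(0.2, prior, obs)
        assert res.converged
        assert res.n_iterations > 0
        assert 0 < res.ensemble_preservation <= 100
        assert res.dkl_forward > 0 and res.dkl_reverse > 0
        assert res.theta == 0.2


class TestParameterRecovery:
    def test_recovers_target_averages_at_small_theta(self, grid_fixture):
        """Ensemble averages return to within 2 sigma of the generating targets."""
        fix = grid_fixture
        res = optimize_k(1e-3, fix.prior, fix.obs)
        means = fix.obs.calc_matrix.T @ res.weights_opt.weights
        dev = np.abs(means - fix.target_means) / fix.obs.sigma
        assert (dev < 2.0).all()


class TestRegularizationPath:
    def test_monotone_dkl_and_chi2(self, small_grid_fixture):
        fix = small_grid_fixture
        grid = np.logspace(-3, 2, 15)
        path = regularization_path(grid, fix.prior, fix.obs)
        dkl = np.array([r.dkl_forward for r in path])
        chi = np.array([r.chi2_opt for r in path])
        assert (np.diff(dkl) <= 1e-6).all()
        assert (np.diff(chi) >= -1e-6).all()

    def test_at_least_as_good_as_cold_start(self, small_grid_fixture):
        fix = small_grid_fixture
        grid = np.logspace(-2, 1, 7)
        path = regularization_path(grid, fix.prior, fix.obs)
        for theta, r in zip(grid, path):
            cold = optimize_k(theta, fix.prior, fix.obs)
            assert r.cost <= cold.cost + 1e-10
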