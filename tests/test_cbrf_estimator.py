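"""The weighted squared-hinge objective, its solver and CV selection."""

import numpy as np
import pytest
from scipy import optimize

from cbrf import neurosim, stimgen
from cbrf.datamodel import StimulusEnsemble, binarize_counts, build_lagged_design
from cbrf.estimator import (
    CbrfConfig,
    class_prior_weights,
    fit_cbrf,
    fit_cbrf_at_lambda,
    objective_and_gradient,
    select_lambda_by_auc,
)
from cbrf.evalbench import filter_correlation, roc_auc


class TestClassPriorWeights:
    def test_balanced_gives_unit_weights(self):
        y = np.array([1, -1] * 10)
        assert class_prior_weights(y) == (1.0, 1.0)

    def test_inverse_prior_ratio(self):
        y = np.array([1] * 10 + [-1] * 90)
        w_plus, w_minus = class_prior_weights(y)
        assert np.isclose(w_plus / w_minus, 9.0)

    def test_sparse_spike_values(self):
        y = np.array([1] * 2 + [-1] * 98)
        w_plus, w_minus = class_prior_weights(y)
        assert np.isclose(w_plus, 25.0)
        assert np.isclose(w_minus, 0.51020408, atol=1e-6)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both spike"):
            class_prior_weights(np.ones(10))


class TestObjective:
    def test_inactive_hinge_leaves_only_regularizer(self):
        # all margins >= 1: y * (k.x - theta) = 2 for every example
        X = np.array([[2.0], [-2.0]])
        y = np.array([1, -1])
        k = np.array([1.0])
        J, g = objective_and_gradient(k, 0.0, X, y, lam=1.0)
        assert np.isclose(J, 0.5)
        assert np.isclose(g[-1], 0.0)

    def test_single_example_substitution(self):
        X = np.array([[1.0, 0.0]])
        y = np.array([1])
        J, _ = objective_and_gradient(np.zeros(2), 0.0, X, y, lam=1.0)
        C = 1.0 / (2.0 * 1.0 * 1)
        assert np.isclose(J, C)

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((30, 5))
        y = np.where(rng.random(30) < 0.3, 1, -1)
        w = class_prior_weights(y)
        p0 = rng.standard_normal(6) * 0.5

        def f(p):
            return objective_and_gradient(p[:-1], p[-1], X, y, 0.7, w)[0]

        _, g = objective_and_gradient(p0[:-1], p0[-1], X, y, 0.7, w)
        g_fd = optimize.approx_fprime(p0, f, 1e-7)
        assert np.max(np.abs(g - g_fd)) / max(np.max(np.abs(g_fd)), 1) < 1e-5

    def test_rejects_nonpositive_lambda(self):
        with pytest.raises(ValueError):
            objective_and_gradient(np.zeros(1), 0.0, np.ones((2, 1)),
                                   np.array([1, -1]), 0.0)

    def test_convexity_along_random_segments(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((40, 4))
        y = np.where(rng.random(40) < 0.4, 1, -1)
        w = class_prior_weights(y)
        for _ in range(10):
            p1, p2 = rng.standard_normal((2, 5))
            J1 = objective_and_gradient(p1[:-1], p1[-1], X, y, 0.5, w)[0]
            J2 = objective_and_gradient(p2[:-1], p2[-1], X, y, 0.5, w)[0]
            for a in np.linspace(0, 1, 7):
                pm = a * p1 + (1 - a) * p2
                Jm = objective_and_gradient(pm[:-1], pm[-1], X, y, 0.5, w)[0]
                assert Jm <= a * J1 + (1 - a) * J2 + 1e-10


class TestSolver:
    def test_separable_toy_reaches_perfect_auc(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(2, 0.3, (30, 2)), rng.normal(-2, 0.3, (30, 2))])
        y = np.array([1] * 30 + [-1] * 30)
        k, theta, _, _ = fit_cbrf_at_lambda(X, y, 0.01)
        assert roc_auc(X @ k, y) == 1.0

    def test_shrinkage_is_monotone_in_lambda(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((200, 6))
        y = np.where(X[:, 0] + 0.5 * rng.standard_normal(200) > 1, 1, -1)
        norms = []
        for lam in [0.01, 1.0, 100.0, 10000.0]:
            k, _, _, _ = fit_cbrf_at_lambda(X, y, lam)
            norms.append(np.linalg.norm(k))
        assert all(a >= b - 1e-9 for a, b in zip(norms, norms[1:]))
        assert norms[-1] < 1e-2 * norms[0]

    def test_optimum_matches_derivative_free_minimizer(self):
        """Tiny instance: trust-region Newton-CG vs Nelder-Mead."""
        rng = np.random.default_rng(4)
        X = rng.standard_normal((40, 3))
        y = np.where(X[:, 0] - X[:, 2] + 0.3 * rng.standard_normal(40) > 0.5,
                     1, -1)
        w = class_prior_weights(y)
        k, theta, _, _ = fit_cbrf_at_lambda(X, y, 0.3, w, grad_tol=1e-10)
        J_opt = objective_and_gradient(k, theta, X, y, 0.3, w)[0]

        res = optimize.minimize(
            lambda p: objective_and_gradient(p[:-1], p[-1], X, y, 0.3, w)[0],
            np.zeros(4), method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
        assert abs(J_opt - res.fun) / abs(res.fun) < 1e-6
        assert J_opt <= res.fun + 1e-10   # convexity: ours is the optimum


class TestSelection:
    def test_singleton_grid_is_selected(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((300, 4))
        y = np.where(X[:, 0] > 1, 1, -1)
        ens = StimulusEnsemble(X, 1, 4)
        rep = fit_cbrf(ens, y, CbrfConfig(lambda_grid=[0.37], n_folds=3))
        assert rep.selected_hyperparam == 0.37

    def test_pure_noise_cv_auc_near_half(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((2000, 5))
        y = np.where(rng.random(2000) < 0.2, 1, -1)
        lam, curve = select_lambda_by_auc(
            X, y, CbrfConfig(lambda_grid=[0.1, 10.0], n_folds=5, seed=0),
            class_prior_weights(y))
        # permutation null: AUC ~ 0.5 +- 3 * SE
        se = np.sqrt(2000 / (4 * 400 * 1600))
        assert np.all(np.abs(curve["mean"] - 0.5) < 3 * se + 0.02)

    def test_lnp_recovery_with_cv_selection(self):
        """Spectro-temporal filter recovery from an LNP simulation; the
        CV-selected filter must correlate >= 0.8 with ground truth and beat
        both grid endpoints."""
        rng = np.random.default_rng(7)
        series = rng.standard_normal((20_000, 10))
        ens = build_lagged_design(series, 10)
        gt = stimgen.make_ground_truth("strf_onset", 10, 10)
        nl = neurosim.calibrate_rate(
            ens, gt.filter,
            neurosim.Nonlinearity("sigmoid", {"slope_per_sd": 4.0,
                                              "midpoint_quantile": 0.95}),
            0.05)
        resp = binarize_counts(neurosim.lnp_simulate(ens, gt.filter, nl, 8))
        grid = np.logspace(-3, 3, 5)
        rep = fit_cbrf(ens, resp.labels,
                       CbrfConfig(lambda_grid=grid, n_folds=3, seed=1))
        corr_sel = filter_correlation(rep.filter, gt.filter)
        assert corr_sel >= 0.8
        from cbrf.datamodel import center_design
        Xc, _ = center_design(ens.X)
        w = class_prior_weights(resp.labels)
        for lam_end in (grid[0], grid[-1]):
            if rep.selected_hyperparam == lam_end:
                continue
            k_end, *_ = fit_cbrf_at_lambda(Xc, resp.labels, lam_end, w)
            assert corr_sel >= filter_correlation(k_end, gt.filter.k) - 0.02


class TestFullPipeline:
    def test_label_flip_negates_solution(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((500, 4))
        y = np.where(X[:, 1] + 0.3 * rng.standard_normal(500) > 0.8, 1, -1)
        ens = StimulusEnsemble(X, 1, 4)
        cfg = CbrfConfig(lambda_grid=[1.0], n_folds=3)
        rep_pos = fit_cbrf(ens, y, cfg)
        rep_neg = fit_cbrf(ens, -y, cfg)
        np.testing.assert_allclose(rep_neg.filter.k, -rep_pos.filter.k,
                                   atol=1e-4)
        assert np.isclose(rep_neg.filter.theta, -rep_pos.filter.theta,
                          atol=1e-4)

    def test_balanced_classes_make_weighting_irrelevant(self):
        rng = np.random.default_rng(9)
        X = rng.standard_normal((400, 3))
        y = np.where(X[:, 0] > np.median(X[:, 0]), 1, -1)
        ens = StimulusEnsemble(X, 1, 3)
        rep_w = fit_cbrf(ens, y, CbrfConfig(lambda_grid=[1.0],
                                            class_weighting="inverse_prior"))
        rep_u = fit_cbrf(ens, y, CbrfConfig(lambda_grid=[1.0],
                                            class_weighting="uniform"))
        np.testing.assert_allclose(rep_w.filter.k, rep_u.filter.k, atol=1e-5)

    def test_direction_consistency_improves_with_data(self, ):
        """Under the generative threshold model the estimated direction
        converges: median angular error shrinks with sample size."""
        from cbrf.recipes import angular_error

        errs = {T: [] for T in (1000, 20000)}
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            k_true = rng.standard_normal(6)
            k_true /= np.linalg.norm(k_true)
            from cbrf.datamodel import LinearFilter
            filt = LinearFilter(k_true, 0.8, 1, 6)
            for T in errs:
                X = rng.standard_normal((T, 6))
                ens = StimulusEnsemble(X, 1, 6)
                resp = neurosim.binary_threshold_simulate(ens, filt, 0.5,
                                                          seed=200 + seed)
                rep = fit_cbrf(ens, resp.labels,
                               CbrfConfig(lambda_grid=[1.0], n_folds=3))
                errs[T].append(angular_error(rep.filter, filt))
        assert np.median(errs[20000]) < np.median(errs[1000])

    def test_weighted_class_error_contributions_balance(self):
        """Symmetric influence of the two classes under inverse-prior
        weighting: (a) the weighted 0/1 error mass of each class in the
        trivial high/low-threshold limits is exactly 1/2, and (b) at the
        fitted solution the weighted hinge-residual masses of the spike and
        non-spike classes agree (the threshold stationarity condition)."""
        rng = np.random.default_rng(11)
        X = rng.standard_normal((50_000, 6))
        ens = StimulusEnsemble(X, 1, 6)
        k_true = rng.standard_normal(6)
        k_true /= np.linalg.norm(k_true)
        from cbrf.datamodel import LinearFilter
        filt = LinearFilter(k_true, 1.2, 1, 6)
        resp = neurosim.binary_threshold_simulate(ens, filt, 0.6, seed=12)
        y = resp.labels
        w_plus, w_minus = class_prior_weights(y)
        T = y.size

        # (a) threshold -> +inf misclassifies every spike; -> -inf every
        # non-spike; inverse-prior weighting equalizes both masses at 1/2
        assert np.isclose(w_plus * np.mean(y == 1), 0.5)
        assert np.isclose(w_minus * np.mean(y == -1), 0.5)

        # (b) balance of weighted residual mass at the optimum
        rep = fit_cbrf(ens, y, CbrfConfig(lambda_grid=[1.0], n_folds=3))
        m = y * (rep.filter.project(ens) - rep.filter.theta)
        r = np.maximum(0.0, 1.0 - m)
        s_plus = w_plus * r[y == 1].sum() / T
        s_minus = w_minus * r[y == -1].sum() / T
        assert abs(s_plus - s_minus) / s_plus < 1e-4
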