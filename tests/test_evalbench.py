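"""Evaluation metrics and protocols."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cbrf import baselines, evalbench, neurosim
from cbrf.datamodel import BinaryResponse, LinearFilter, StimulusEnsemble
from cbrf.evalbench import (
    convergence_protocol,
    estimate_nonlinearity,
    filter_correlation,
    population_protocol,
    projection_mi,
    roc_auc,
)


def exhaustive_auc(z, y):
    """Wilcoxon-Mann-Whitney statistic by explicit pair enumeration."""
    pos = z[y == 1]
    neg = z[y == -1]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        z = np.array([0.0, 0.1, 1.0, 2.0])
        y = np.array([-1, -1, 1, 1])
        assert roc_auc(z, y) == 1.0

    def test_four_point_example(self):
        assert roc_auc(np.array([0.1, 0.4, 0.35, 0.8]),
                       np.array([-1, -1, 1, 1])) == 0.75

    def test_independent_labels_near_half(self):
        rng = np.random.default_rng(0)
        z = rng.standard_normal(10_000)
        y = np.where(rng.random(10_000) < 0.2, 1, -1)
        n1, n0 = (y == 1).sum(), (y == -1).sum()
        se = np.sqrt((n1 + n0 + 1) / (12 * n1 * n0))
        assert abs(roc_auc(z, y) - 0.5) < 3 * se

    @given(st.integers(0, 10_000))
    @settings(max_examples=20, deadline=None)
    def test_equals_exhaustive_pair_counting(self, seed):
        rng = np.random.default_rng(seed)
        T = rng.integers(10, 200)
        z = rng.integers(0, 8, T).astype(float)  # ties are common
        y = np.where(rng.random(T) < 0.3, 1, -1)
        if len(np.unique(y)) < 2:
            y[0], y[1] = 1, -1
        assert np.isclose(roc_auc(z, y), exhaustive_auc(z, y))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.arange(4.0), np.ones(4))


class TestProjectionMi:
    def test_identical_distributions_give_zero(self):
        z = np.tile(np.linspace(0, 1, 100), 2)
        y = np.array([1] * 100 + [-1] * 100)
        assert projection_mi(z, y, n_bins=5) == 0.0

    def test_disjoint_halves_give_one_bit(self):
        z = np.concatenate([np.zeros(500), np.ones(500)])
        y = np.array([-1] * 500 + [1] * 500)
        assert np.isclose(projection_mi(z, y, n_bins=2), 1.0)

    def test_top_fifth_occupancy_gives_log2_five(self):
        """Spikes exactly in the top fifth of a uniform projection with 10
        equal bins: plug-in MI is log2(5) bits."""
        z = (np.arange(10_000) + 0.5) / 10_000
        y = np.where(z > 0.8, 1, -1)
        assert np.isclose(projection_mi(z, y, n_bins=10), np.log2(5))

    def test_invariant_under_monotone_transform_with_quantile_bins(self):
        rng = np.random.default_rng(1)
        z = rng.standard_normal(5000)
        y = np.where(z + 0.5 * rng.standard_normal(5000) > 1, 1, -1)
        mi1 = projection_mi(z, y, n_bins=11, binning="quantile")
        mi2 = projection_mi(np.exp(z), y, n_bins=11, binning="quantile")
        assert np.isclose(mi1, mi2, atol=1e-12)

    def test_rejects_degenerate_bins(self):
        with pytest.raises(ValueError):
            projection_mi(np.arange(4.0), np.array([1, -1, 1, -1]), n_bins=1)


class TestFilterCorrelation:
    def test_scaling_and_sign_invariance(self):
        k = np.random.default_rng(2).standard_normal(30)
        assert np.isclose(filter_correlation(k, 3 * k), 1.0)
        assert np.isclose(filter_correlation(k, -k), 1.0)

    def test_orthogonal_high_dim_near_zero(self):
        rng = np.random.default_rng(3)
        a, b = rng.standard_normal((2, 900))
        b -= (b @ a) / (a @ a) * a  # exactly orthogonal after mean removal? no: raw
        assert filter_correlation(a, b) < 0.1

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            filter_correlation(np.ones(5), np.arange(5.0))


class TestEstimateNonlinearity:
    def _sim(self, kind, params, seed=4):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((40_000, 6))
        ens = StimulusEnsemble(X, 1, 6)
        k = rng.standard_normal(6)
        k /= np.linalg.norm(k)
        filt = LinearFilter(k, 0.0, 1, 6)
        nl = neurosim.calibrate_rate(ens, filt,
                                     neurosim.Nonlinearity(kind, params), 0.1)
        from cbrf.datamodel import binarize_counts
        counts = neurosim.lnp_simulate(ens, filt, nl, seed + 1)
        return ens, filt, binarize_counts(counts)

    def test_sigmoid_ratio_is_monotone(self):
        ens, filt, resp = self._sim("sigmoid", {"slope_per_sd": 3.0,
                                                "midpoint_quantile": 0.8})
        centers, ratio = estimate_nonlinearity(ens, resp.labels, filt)
        occupied = ratio[ratio > 0]
        assert np.all(np.diff(ratio) > -0.15 * ratio.max())

    def test_independent_labels_give_flat_unit_ratio(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((30_000, 4))
        ens = StimulusEnsemble(X, 1, 4)
        y = np.where(rng.random(30_000) < 0.1, 1, -1)
        filt = LinearFilter(np.ones(4), 0.0, 1, 4)
        # quantile bins give equal occupancy, so every bin's ratio estimate
        # has comparable Monte-Carlo error
        _, ratio = estimate_nonlinearity(ens, y, filt, n_bins=7,
                                         binning="quantile")
        assert np.all(np.abs(ratio - 1.0) < 0.25)

    def test_hard_threshold_step_shape(self, threshold_model_data):
        ens, filt, _ = threshold_model_data
        resp = neurosim.binary_threshold_simulate(ens, filt, 0.0, seed=0)
        centers, ratio = estimate_nonlinearity(ens, resp.labels, filt,
                                               n_bins=11)
        below = centers < filt.theta - 0.3
        above = centers > filt.theta + 0.3
        assert np.all(ratio[below] < 0.05 * ratio[above].mean())
        rel_spread = ratio[above].std() / ratio[above].mean()
        assert rel_spread < 0.2


class TestProtocols:
    @pytest.fixture(scope="class")
    def small_sim(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((6000, 8))
        ens = StimulusEnsemble(X, 1, 8)
        k = rng.standard_normal(8)
        k /= np.linalg.norm(k)
        filt = LinearFilter(k, 1.0, 1, 8)
        resp = neurosim.binary_threshold_simulate(ens, filt, 0.5, seed=7)
        return ens, filt, resp

    def test_oracle_filter_dominates_fitted_methods(self, small_sim):
        ens, filt, resp = small_sim
        methods = {
            "oracle": lambda e, r: filt,
            "sta": lambda e, r: baselines.fit_sta(e, r),
        }
        table = population_protocol(ens, resp, methods, n_folds=5, seed=0)
        assert (table.loc["oracle", "mean"]
                >= table.loc["sta", "mean"] - table["sd"].max())

    def test_pure_noise_mi_below_shuffled_null(self, small_sim):
        ens, _, resp = small_sim
        rng = np.random.default_rng(8)
        y_noise = rng.permutation(resp.labels)
        noise_resp = BinaryResponse(labels=y_noise,
                                    counts=(y_noise == 1).astype(np.int64))
        table = population_protocol(
            ens, noise_resp, {"sta": lambda e, r: baselines.fit_sta(e, r)},
            n_folds=5, seed=0)
        # shuffled-label null at the same evaluation size as one test fold
        # (the plug-in MI bias scales with the held-out spike count)
        n_test = ens.n_samples // 5
        z = (ens.X @ baselines.fit_sta(ens, noise_resp).k)[:n_test]
        null = [projection_mi(z, rng.permutation(y_noise[:n_test]))
                for _ in range(60)]
        assert table.loc["sta", "mean"] < np.quantile(null, 0.95) + 0.01

    def test_convergence_reaches_one_at_full_fraction(self, small_sim):
        ens, _, resp = small_sim
        table = convergence_protocol(
            ens, resp, {"sta": lambda e, r: baselines.fit_sta(e, r)},
            fractions=(0.25, 1.0))
        assert np.isclose(table.loc[1.0, "sta"], 1.0)

    def test_unsorted_fractions_rejected(self, small_sim):
        ens, _, resp = small_sim
        with pytest.raises(ValueError):
            convergence_protocol(ens, resp, {}, fractions=(0.5, 0.25))


class TestRecipes:
    def test_same_seed_reproducible(self):
        from cbrf.recipes import run_experiment

        r1 = run_experiment("weighting_demo_2d", seed=3)
        r2 = run_experiment("weighting_demo_2d", seed=3)
        pd.testing.assert_frame_equal(r1["angular_error"], r2["angular_error"])

    def test_unknown_recipe_lists_alternatives(self):
        from cbrf.recipes import run_experiment

        with pytest.raises(ValueError, match="skewed_noise"):
            run_experiment("nonexistent")
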