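"""Estimator formulas, closed-form anchors and cross-checks against WLS."""

import math

import numpy as np
import pytest
from scipy import stats

from mrscreen import estimators
from mrscreen.instruments import DegenerateInstrumentError

from conftest import make_iset


class TestWaldRatios:
    def test_ratio_and_first_order_se(self):
        iset = make_iset([0.5], [0.25], [0.1])
        theta, sigma = estimators.wald_ratios(iset)
        assert theta[0] == pytest.approx(0.5)
        assert sigma[0] == pytest.approx(0.2)

    def test_zero_exposure_effect_names_the_variant(self):
        iset = make_iset([0.0], [0.1], [0.1])
        with pytest.raises(DegenerateInstrumentError, match="rs0"):
            estimators.wald_ratios(iset)


class TestIVW:
    def test_single_instrument_reduces_to_wald_ratio(self):
        iset = make_iset([0.5], [0.25], [0.1])
        est = estimators.ivw(iset)
        assert est.beta == pytest.approx(0.5)
        assert est.se == pytest.approx(0.2)
        assert est.model == "fixed"

    def test_unit_weight_hand_calculation(self):
        # ratios {0.1, 0.2, 0.3} with per-SNP ratio SEs of 1
        iset = make_iset([1.0, 1.0, 1.0], [0.1, 0.2, 0.3], [1.0])
        est = estimators.ivw(iset)
        assert est.beta == pytest.approx(0.2)
        assert est.se == pytest.approx(3 ** -0.5, rel=1e-6)
        assert est.Q == pytest.approx(0.02)
        assert est.model == "fixed"

    def test_homogeneous_ratios_have_zero_q(self):
        iset = make_iset([1.0, 2.0, 4.0], [0.3, 0.6, 1.2], [1.0])
        est = estimators.ivw(iset)
        assert est.Q == pytest.approx(0.0, abs=1e-12)
        assert est.i2 == 0.0

    def test_equals_weighted_through_origin_regression(self, rng):
        """IVW must match the 1/se_out^2-weighted regression of beta_out on
        beta_exp through the origin (independent closed-form oracle)."""
        for _ in range(50):
            j = rng.integers(2, 30)
            x = rng.normal(0.2, 0.1, j)
            x[x == 0] = 0.1
            y = rng.normal(0.1, 0.2, j)
            s = rng.uniform(0.05, 0.5, j)
            iset = make_iset(x, y, s)
            w = 1.0 / s**2
            slope = np.sum(w * x * y) / np.sum(w * x * x)
            assert estimators.ivw(iset).beta == pytest.approx(slope, abs=1e-10)

    def test_matches_statsmodels_wls_through_origin(self, rng):
        import statsmodels.api as sm

        x = rng.normal(0.2, 0.1, 20)
        y = 0.4 * x + rng.normal(0, 0.05, 20)
        s = rng.uniform(0.05, 0.2, 20)
        fit = sm.WLS(y, x, weights=1.0 / s**2).fit()
        assert estimators.ivw(make_iset(x, y, s)).beta == pytest.approx(
            float(fit.params[0]), abs=1e-10
        )

    def test_sign_equivariance(self, rng):
        x = rng.normal(0.2, 0.05, 10)
        y = rng.normal(0.1, 0.05, 10)
        s = rng.uniform(0.05, 0.2, 10)
        a = estimators.ivw(make_iset(x, y, s))
        b = estimators.ivw(make_iset(x, -y, s))
        assert b.beta == pytest.approx(-a.beta, rel=1e-12)
        assert b.se == pytest.approx(a.se, rel=1e-12)
        assert b.Q == pytest.approx(a.Q, rel=1e-9)

    def test_fixed_se_never_exceeds_random_se(self, rng):
        for _ in range(20):
            j = int(rng.integers(3, 25))
            iset = make_iset(
                rng.normal(0.2, 0.05, j), rng.normal(0.1, 0.2, j), rng.uniform(0.02, 0.3, j)
            )
            est = estimators.ivw(iset)
            w = (iset.beta_exp / iset.se_out) ** 2
            se_fixed = float(np.sum(w) ** -0.5)
            assert est.se >= se_fixed - 1e-15
            assert 0.0 <= est.i2 < 1.0
            assert est.Q >= 0.0

    def test_random_model_selected_under_strong_heterogeneity(self):
        iset = make_iset([1.0] * 4, [0.0, 1.0, 2.0, 10.0], [0.01])
        est = estimators.ivw(iset)
        assert est.model == "random"
        assert est.se > float(4 * (1 / 0.01**2)) ** -0.5


class TestEgger:
    def test_closed_form_equal_weights(self):
        iset = make_iset([1.0, 2.0, 3.0], [1.1, 2.1, 3.1], [1.0])
        est = estimators.egger(iset)
        assert est.beta == pytest.approx(1.0)
        assert est.egger_intercept == pytest.approx(0.1)

    def test_exact_proportionality_gives_zero_intercept(self):
        iset = make_iset([1.0, 2.0, 3.0], [0.7, 1.4, 2.1], [1.0])
        est = estimators.egger(iset)
        assert est.egger_intercept == pytest.approx(0.0, abs=1e-12)
        assert est.beta == pytest.approx(0.7)

    def test_two_snps_omitted(self):
        assert estimators.egger(make_iset([1.0, 2.0], [1.0, 2.0], [1.0])) is None

    def test_matches_statsmodels_weighted_fit(self, rng):
        import statsmodels.api as sm

        x = np.abs(rng.normal(0.2, 0.1, 15)) + 0.01
        y = 0.02 + 0.4 * x + rng.normal(0, 0.03, 15)
        s = rng.uniform(0.05, 0.2, 15)
        fit = sm.WLS(y, sm.add_constant(x), weights=1.0 / s**2).fit()
        est = estimators.egger(make_iset(x, y, s))
        assert est.egger_intercept == pytest.approx(float(fit.params[0]), abs=1e-10)
        assert est.beta == pytest.approx(float(fit.params[1]), abs=1e-10)
        # statsmodels estimates the dispersion freely; ours floors it at 1
        disp = math.sqrt(max(1.0, fit.mse_resid))
        assert est.se == pytest.approx(float(fit.bse[1]) / math.sqrt(fit.mse_resid) * disp,
                                       rel=1e-8)

    def test_orientation_step_makes_recoding_invisible(self, rng):
        x = rng.normal(0.2, 0.1, 12)
        y = 0.05 + 0.3 * x + rng.normal(0, 0.02, 12)
        s = rng.uniform(0.05, 0.2, 12)
        flip = rng.choice([-1.0, 1.0], 12)
        a = estimators.egger(make_iset(x, y, s))
        b = estimators.egger(make_iset(x * flip, y * flip, s))
        assert b.beta == pytest.approx(a.beta, rel=1e-12)
        assert b.egger_intercept == pytest.approx(a.egger_intercept, rel=1e-12)


class TestWeightedMedian:
    def test_equal_weights_is_plain_median(self):
        iset = make_iset([1.0, 1.0, 1.0], [1.0, 2.0, 3.0], [1.0])
        est = estimators.weighted_median(iset, n_boot=100, seed=0)
        assert est.beta == pytest.approx(2.0)

    def test_hand_interpolation_with_unequal_weights(self):
        # ratios {1,2,4}, normalized weights {0.25, 0.25, 0.5}
        # breakpoints {0.125, 0.375, 0.75} -> 2 + 2*(0.5-0.375)/0.375 = 8/3
        se_out = [1.0, 1.0, 1.0 / math.sqrt(2.0)]
        iset = make_iset([1.0, 1.0, 1.0], [1.0, 2.0, 4.0], se_out)
        est = estimators.weighted_median(iset, n_boot=100, seed=0)
        assert est.beta == pytest.approx(8.0 / 3.0, rel=1e-9)

    def test_dominant_weight_pins_the_estimate(self):
        # one SNP holds ~90% of the weight
        iset = make_iset([1.0, 1.0, 1.0], [1.0, 2.0, 5.0], [1.0, 1.0, 0.1])
        est = estimators.weighted_median(iset, n_boot=100, seed=0)
        assert abs(est.beta - 5.0) < 1.5

    def test_estimate_within_ratio_range(self, rng):
        for _ in range(20):
            j = int(rng.integers(3, 20))
            iset = make_iset(
                rng.normal(0.3, 0.05, j), rng.normal(0.1, 0.2, j), rng.uniform(0.05, 0.3, j)
            )
            theta = iset.beta_out / iset.beta_exp
            est = estimators.weighted_median(iset, n_boot=20, seed=1)
            assert theta.min() - 1e-12 <= est.beta <= theta.max() + 1e-12

    def test_bootstrap_se_is_seed_deterministic(self):
        iset = make_iset([1.0, 1.2, 0.8, 1.1], [0.5, 0.65, 0.35, 0.5], [0.1])
        a = estimators.weighted_median(iset, n_boot=200, seed=9)
        b = estimators.weighted_median(iset, n_boot=200, seed=9)
        assert a.se == b.se

    def test_two_snps_omitted(self):
        assert estimators.weighted_median(make_iset([1, 1], [1, 2], [1.0]), 10, 0) is None


class TestLeaveOneOut:
    def test_two_snps_each_entry_is_the_other_ratio(self):
        iset = make_iset([1.0, 1.0], [0.4, 0.8], [0.1])
        loo = estimators.leave_one_out(iset)
        assert loo[0][1].beta == pytest.approx(0.8)
        assert loo[1][1].beta == pytest.approx(0.4)

    def test_dropping_middle_of_unit_weight_triple(self):
        iset = make_iset([1.0, 1.0, 1.0], [0.1, 0.2, 0.3], [1.0])
        loo = dict(estimators.leave_one_out(iset))
        assert loo["rs1"].beta == pytest.approx(0.2)

    def test_homogeneous_set_invariant_under_dropping(self):
        iset = make_iset([1.0, 2.0, 4.0], [0.3, 0.6, 1.2], [1.0])
        full = estimators.ivw(iset).beta
        for _, est in estimators.leave_one_out(iset):
            assert est.beta == pytest.approx(full)


class TestWaldSummary:
    def test_null_effect(self):
        out = estimators.wald_summary(0.0, 0.5)
        assert out["odds_ratio"] == 1.0
        assert out["p"] == pytest.approx(1.0)

    def test_printed_triplet_reconstruction(self):
        # OR 1.776, 95% CI (1.380, 2.285): recomputed p ~ 8.0e-6
        beta = math.log(1.776)
        se = (math.log(2.285) - math.log(1.380)) / (2 * estimators.Z975)
        out = estimators.wald_summary(beta, se)
        assert out["p"] == pytest.approx(8.05e-6, rel=0.02)

    def test_ci_collapses_as_se_shrinks(self):
        out = estimators.wald_summary(0.5, 1e-6)
        assert out["ci_low"] == pytest.approx(out["ci_high"], rel=1e-4)
        assert out["p"] < 1e-300 or out["p"] == 0.0


class TestPower:
    def test_size_under_the_null(self):
        assert estimators.mr_power(400_000, 0.08, 0.05, 0.0) == pytest.approx(0.05, abs=1e-9)

    def test_eighty_percent_at_noncentrality_2p8(self):
        # lambda = |beta| * sqrt(N * R2 * K(1-K)) = 2.8 exactly
        n, k, r2 = 100_000, 0.5, 0.01
        beta = 2.8 / math.sqrt(n * r2 * k * (1 - k))
        assert estimators.mr_power(n, k, r2, beta) == pytest.approx(0.80, abs=0.005)

    def test_power_tends_to_one(self):
        assert estimators.mr_power(400_000, 0.08, 0.5, 5.0) == pytest.approx(1.0, abs=1e-9)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            estimators.mr_power(1000, 0.0, 0.1, 0.1)
        with pytest.raises(ValueError):
            estimators.mr_power(1000, 0.1, 0.0, 0.1)
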