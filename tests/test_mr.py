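import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from bpmr.harmonize import Action, HarmonizedInstrument
from bpmr.mr import (
    InsufficientInstrumentsError,
    bonferroni_flag,
    egger,
    ivw,
    scale_to_or,
    sd_scale,
    wald_ratio,
    weighted_median,
    weighted_median_point,
)
from conftest import random_harmonized_frame


def hi(beta_exp, se_exp, beta_out, se_out, rsid="rs"):
    return HarmonizedInstrument(rsid, beta_exp, se_exp, beta_out, se_out,
                                0.3, 0.3, Action.kept_as_is)


def frame(bx, sy, by, sx=None):
    bx = np.asarray(bx, float)
    return pd.DataFrame({
        "beta_exp": bx,
        "se_exp": np.full(len(bx), 0.01) if sx is None else np.asarray(sx, float),
        "beta_out": np.asarray(by, float),
        "se_out": np.asarray(sy, float),
    })


class TestWaldRatio:
    def test_ratio_and_first_order_se(self):
        est = wald_ratio(hi(0.5, 0.01, 0.05, 0.02))
        assert est.theta_hat == pytest.approx(0.10)
        assert est.se == pytest.approx(0.04)
        assert est.ci_low < est.theta_hat < est.ci_high

    def test_null_outcome_gives_zero(self):
        assert wald_ratio(hi(0.5, 0.01, 0.0, 0.02)).theta_hat == 0.0

    def test_gauge_invariance(self):
        a = wald_ratio(hi(0.5, 0.01, 0.05, 0.02))
        b = wald_ratio(hi(-0.5, 0.01, -0.05, 0.02))
        assert a.theta_hat == pytest.approx(b.theta_hat)
        assert a.se == pytest.approx(b.se)

    def test_zero_exposure_beta_rejected(self):
        with pytest.raises(InsufficientInstrumentsError):
            wald_ratio(hi(0.0, 0.01, 0.05, 0.02))


class TestIVW:
    def test_homogeneous_instruments(self):
        hs = frame([0.5, 0.25], [0.02, 0.02], [0.1, 0.05])
        est, het = ivw(hs)
        assert est.theta_hat == pytest.approx(0.2)
        assert het.Q == pytest.approx(0.0, abs=1e-24)

    def test_hand_evaluated_two_instrument_case(self):
        """theta_j = {0.1, 0.3} with equal weights 100 -> theta 0.2, Q 2.0."""
        # w = bx^2/sy^2 = 100 for bx=1, sy=0.1
        hs = frame([1.0, 1.0], [0.1, 0.1], [0.1, 0.3])
        est, het = ivw(hs)
        assert est.theta_hat == pytest.approx(0.2)
        assert het.Q == pytest.approx(2.0)
        assert het.df == 1

    def test_matches_wls_through_origin_oracle(self, rng):
        for _ in range(30):
            J = int(rng.integers(2, 51))
            hs = random_harmonized_frame(rng, J)
            est, _ = ivw(hs, random_effects=False)
            w = 1.0 / hs["se_out"] ** 2
            fit = sm.WLS(hs["beta_out"], hs["beta_exp"], weights=w).fit()
            assert est.theta_hat == pytest.approx(fit.params.iloc[0], rel=1e-10)

    def test_random_effects_se_never_below_fixed(self, rng):
        for _ in range(20):
            hs = random_harmonized_frame(rng, int(rng.integers(3, 30)))
            fe, het = ivw(hs, random_effects=False)
            re, _ = ivw(hs, random_effects=True)
            assert re.se >= fe.se - 1e-15
            assert re.theta_hat == pytest.approx(fe.theta_hat)
            if het.Q <= het.df:
                assert re.se == pytest.approx(fe.se)

    def test_single_instrument_signals_wald_ratio(self):
        with pytest.raises(InsufficientInstrumentsError, match="wald_ratio"):
            ivw(frame([0.5], [0.02], [0.1]))

    def test_additive_random_effects_flag(self, rng):
        hs = random_harmonized_frame(rng, 30, se_out_scale=0.2)
        dl, _ = ivw(hs, random_effects=True, additive=True)
        fe, _ = ivw(hs, random_effects=False)
        assert dl.method == "ivw_dl"
        assert dl.se >= fe.se - 1e-15


class TestEgger:
    def test_noiseless_fit_recovers_slope_and_intercept(self):
        bx = np.array([0.2, 0.4, 0.6, 0.8])
        by = 0.2 * bx  # intercept 0
        res = egger(frame(bx, [0.02] * 4, by))
        assert res.slope.theta_hat == pytest.approx(0.2)
        assert res.intercept == pytest.approx(0.0, abs=1e-12)

    def test_constant_shift_moves_only_intercept(self):
        bx = np.array([0.2, 0.4, 0.6, 0.8])
        res = egger(frame(bx, [0.02] * 4, 0.2 * bx + 0.03))
        assert res.intercept == pytest.approx(0.03)
        assert res.slope.theta_hat == pytest.approx(0.2)

    def test_matches_two_parameter_wls_oracle(self, rng):
        for _ in range(30):
            J = int(rng.integers(3, 51))
            hs = random_harmonized_frame(rng, J)
            res = egger(hs)
            bx = hs["beta_exp"].to_numpy().copy()
            by = hs["beta_out"].to_numpy().copy()
            flip = bx < 0
            bx[flip], by[flip] = -bx[flip], -by[flip]
            X = sm.add_constant(bx)
            fit = sm.WLS(by, X, weights=1.0 / hs["se_out"] ** 2).fit()
            assert res.intercept == pytest.approx(fit.params[0], rel=1e-10, abs=1e-12)
            assert res.slope.theta_hat == pytest.approx(fit.params[1], rel=1e-10)

    def test_exposure_orientation_invariance(self, rng):
        hs = random_harmonized_frame(rng, 20)
        flipped = hs.copy()
        flipped["beta_exp"] *= -1
        flipped["beta_out"] *= -1
        a, b = egger(hs), egger(flipped)
        assert a.slope.theta_hat == pytest.approx(b.slope.theta_hat)
        assert a.intercept == pytest.approx(b.intercept)

    def test_too_few_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            egger(frame([0.5, 0.6], [0.02, 0.02], [0.1, 0.12]))

    def test_collinear_exposure_rejected(self):
        with pytest.raises(InsufficientInstrumentsError, match="variance"):
            egger(frame([0.5, 0.5, 0.5], [0.02] * 3, [0.1, 0.11, 0.09]))


class TestWeightedMedian:
    def test_equal_weights_middle_order_statistic(self):
        # ratio estimates {0.1, 0.2, 0.3}, equal weights: percentile grid
        # {1/6, 1/2, 5/6} puts the estimate exactly at 0.2
        hs = frame([1.0, 1.0, 1.0], [0.1, 0.1, 0.1], [0.1, 0.2, 0.3])
        est = weighted_median(hs, n_boot=200, seed=1)
        assert est.theta_hat == pytest.approx(0.2)

    def test_identical_ratios_and_tiny_se(self):
        hs = frame([1.0, 1.0, 1.0], [1e-8, 1e-8, 1e-8], [0.2, 0.2, 0.2])
        est = weighted_median(hs, n_boot=200, seed=1)
        assert est.theta_hat == pytest.approx(0.2)
        assert est.se < 1e-7

    def test_interpolation_against_hand_enumeration(self):
        theta = np.array([0.05, 0.10, 0.20, 0.40, 0.80])
        w = np.array([1.0, 2.0, 3.0, 2.0, 1.0])
        # hand enumeration: S = [1,3,6,8,9]; p = (S - w/2)/9
        p = np.array([0.5, 2.0, 4.5, 7.0, 8.5]) / 9.0
        expected = np.interp(0.5, p, theta)
        assert weighted_median_point(theta, w) == pytest.approx(expected)

    def test_seed_required_and_reproducible(self):
        hs = frame([1.0, 0.9, 1.1, 0.8], [0.1] * 4, [0.1, 0.2, 0.3, 0.15])
        with pytest.raises(ValueError):
            weighted_median(hs, n_boot=200, seed=None)
        a = weighted_median(hs, n_boot=200, seed=7)
        b = weighted_median(hs, n_boot=200, seed=7)
        assert a.se == b.se


class TestScaling:
    def test_or_per_10mmhg_decrease(self):
        est = wald_ratio(hi(1.0, 0.01, 0.026236, 0.004))
        scaled = scale_to_or(est, 10)
        assert scaled.or_point == pytest.approx(np.exp(-10 * 0.026236))
        assert scaled.or_point == pytest.approx(0.769, abs=5e-4)
        assert scaled.or_low < scaled.or_point < scaled.or_high

    def test_null_maps_to_unity(self):
        est = wald_ratio(hi(1.0, 0.01, 0.0, 0.004))
        scaled = scale_to_or(est, 10)
        assert scaled.or_point == 1.0
        assert scaled.or_low == pytest.approx(1 / scaled.or_high)

    def test_zero_k_degenerate(self):
        est = wald_ratio(hi(1.0, 0.01, 0.3, 0.004))
        assert scale_to_or(est, 0).or_point == 1.0

    def test_monotone_in_theta(self):
        ests = [wald_ratio(hi(1.0, 0.01, t, 0.004)) for t in (0.01, 0.02, 0.03)]
        ors = [scale_to_or(e, 10).or_point for e in ests]
        assert ors[0] > ors[1] > ors[2]

    def test_half_sd_scale(self):
        est = wald_ratio(hi(1.0, 0.01, 0.4, 0.004))
        scaled = sd_scale(est)
        assert scaled.k == 0.5
        assert scaled.or_point == pytest.approx(np.exp(-0.2))


class TestBonferroni:
    def test_strict_threshold(self):
        flags = bonferroni_flag([0.0069, 0.007, 0.02], 0.007)
        assert flags == [True, False, False]

    def test_invalid_alpha(self):
        with pytest.raises(ValueError):
            bonferroni_flag([0.01], 1.0)
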