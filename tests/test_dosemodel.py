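"""Regression/dose-response models and the testing chain."""

import numpy as np
import pytest
from scipy import stats

from utrtune import synth
from utrtune.dosemodel import (
    StatConfig,
    anova_dunnett,
    cross_correlation,
    fit_linear,
    fit_logistic4,
    gc_pair_differential,
    predict_fc,
    segmented_response,
    significance_flag,
)

# hand-computed OLS oracle for x=[1,2,3,5], y=[2,3,5,6] via normal equations:
# Sxy = 9.0, Sxx = 8.75 -> slope 36/35, intercept 4 - slope*2.75, r2 = 0.92571...
OLS_X = np.array([1.0, 2.0, 3.0, 5.0])
OLS_Y = np.array([2.0, 3.0, 5.0, 6.0])
OLS_SLOPE = 9.0 / 8.75
OLS_INTERCEPT = 4.0 - OLS_SLOPE * 2.75
OLS_R2 = 1.0 - 0.7428571428571429 / 10.0


class TestFitLinear:
    def test_hand_computed_four_points(self):
        fit = fit_linear(OLS_X, OLS_Y)
        assert fit.params["slope"] == pytest.approx(OLS_SLOPE)
        assert fit.params["intercept"] == pytest.approx(OLS_INTERCEPT)
        assert fit.r2 == pytest.approx(OLS_R2)

    def test_collinear_r2_one(self):
        fit = fit_linear([0, 1, 2, 3], [5, 7, 9, 11])
        assert fit.r2 == pytest.approx(1.0)

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(3)
        order = rng.permutation(len(OLS_X))
        fit1 = fit_linear(OLS_X, OLS_Y)
        fit2 = fit_linear(OLS_X[order], OLS_Y[order])
        assert fit2.params == pytest.approx(fit1.params)

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_linear([2, 2, 2, 2], [1, 2, 3, 4])

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            fit_linear([1, 2], [1, 2])


class TestFitLogistic4:
    @staticmethod
    def _curve(x, a=1.1, d=0.02, g50=-30.0, b=5.0):
        return d + (a - d) / (1 + np.exp((x - g50) / b))

    def test_noise_free_parameter_recovery(self):
        x = np.linspace(-50, -5, 25)
        fit = fit_logistic4(x, self._curve(x))
        assert fit.params["a"] == pytest.approx(1.1, abs=1e-4)
        assert fit.params["d"] == pytest.approx(0.02, abs=1e-4)
        assert fit.params["g50"] == pytest.approx(-30.0, abs=1e-4)
        assert fit.params["b"] == pytest.approx(5.0, abs=1e-4)

    def test_noisy_g50_recovery(self):
        rng = np.random.default_rng(4)
        x = np.linspace(-50, -5, 30)
        y = self._curve(x) + rng.normal(0, 0.05, len(x))
        fit = fit_logistic4(x, y)
        assert abs(fit.params["g50"] + 30.0) < 2.0

    def test_monotone_when_b_positive(self):
        x = np.linspace(-50, -5, 20)
        fit = fit_logistic4(x, self._curve(x))
        grid = fit.predict(np.linspace(-60, 0, 200))
        # with a > d and b > 0 the curve falls monotonically from a to d
        if fit.params["b"] > 0 and fit.params["a"] > fit.params["d"]:
            assert (np.diff(grid) <= 1e-9).all()

    def test_sse_not_worse_than_linear(self):
        rng = np.random.default_rng(5)
        x = np.linspace(-50, -5, 20)
        y = self._curve(x) + rng.normal(0, 0.03, len(x))
        lin = fit_linear(x, y)
        log4 = fit_logistic4(x, y)
        assert (log4.residuals ** 2).sum() <= (lin.residuals ** 2).sum() + 1e-9

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            fit_logistic4([1, 2, 3, 4], [1, 2, 3, 4])


class TestPredictFc:
    def test_training_point_within_residual(self):
        fit = fit_linear(OLS_X, OLS_Y)
        resid_max = np.abs(fit.residuals).max()
        assert abs(predict_fc(fit, 3.0) - 5.0) <= resid_max + 1e-12

    def test_logistic_asymptotes(self):
        x = np.linspace(-50, -5, 25)
        fit = fit_logistic4(x, TestFitLogistic4._curve(x))
        with pytest.warns(UserWarning, match="extrapolat"):
            low = predict_fc(fit, -1000.0)
        with pytest.warns(UserWarning, match="extrapolat"):
            high = predict_fc(fit, 1000.0)
        assert low == pytest.approx(fit.params["a"], abs=1e-6)
        assert high == pytest.approx(fit.params["d"], abs=1e-6)

    def test_steepest_change_in_plausible_window(self):
        # synthetic panel shaped like a typical dG/FC dose relation
        x = np.array([-46, -41, -32, -28, -22, -14, -6], dtype=float)
        y = np.array([0.02, 0.05, 0.35, 0.50, 0.65, 0.85, 1.10])
        fit = fit_logistic4(x, y)
        grid = np.linspace(-50, -5, 400)
        slope = np.gradient(fit.predict(grid), grid)
        steepest = grid[np.argmax(np.abs(slope))]
        assert -40 <= steepest <= -20

    def test_unfitted_rejected(self):
        with pytest.raises(ValueError):
            predict_fc("not a fit", -10.0)


class TestGcPairDifferential:
    def test_identical_pairs_zero(self):
        out = gc_pair_differential({"p": (0.5, 0.5)})
        assert out["diff"].tolist() == [0.0]

    def test_arithmetic_and_mean(self):
        out = gc_pair_differential({"a": (0.4, 0.5), "b": (0.6, 0.8)})
        assert out["diff"].tolist() == pytest.approx([-0.1, -0.2])
        assert out.attrs["mean_diff"] == pytest.approx(-0.15)

    def test_exclusion_kept_in_table_not_in_mean(self):
        out = gc_pair_differential({"a": (0.4, 0.5), "b": (0.6, 0.8),
                                    "RgE12:13": (0.5, 0.5)},
                                   exclusions=("RgE12:13",))
        assert len(out) == 3
        assert not out.set_index("pair").loc["RgE12:13", "in_mean"]
        assert out.attrs["mean_diff"] == pytest.approx(-0.15)

    def test_empty_after_exclusion_errors(self):
        with pytest.raises(ValueError):
            gc_pair_differential({"a": (0.4, 0.5)}, exclusions=("a",))


class TestCrossCorrelation:
    def test_identity_r2_one(self):
        y = np.array([0.1, 0.5, 0.9, 1.2, 0.3])
        assert cross_correlation(y, y).r2 == pytest.approx(1.0)

    def test_independent_noise_low_r2(self):
        rng = np.random.default_rng(6)
        high = 0
        for _ in range(20):
            x, y = rng.normal(size=20), rng.normal(size=20)
            if cross_correlation(x, y).r2 >= 0.3:
                high += 1
        assert high <= 2

    def test_scale_invariance_of_r2(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=15)
        y = 0.8 * x + rng.normal(0, 0.3, 15)
        assert cross_correlation(x, 5.0 * y).r2 == pytest.approx(
            cross_correlation(x, y).r2)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            cross_correlation([1, 2, 3], [1, 2])


class TestSegmentedResponse:
    def test_noise_free_breakpoint_exact(self):
        cfg = synth.DoseResponseSimConfig(noise_sd=0.0, qp_noise_sd=0.0)
        d = synth.simulate_sumf1_dose_response(cfg)
        out = segmented_response(d["level"], d["specific_activity"],
                                 split="estimate")
        assert out["breakpoint"] == pytest.approx(0.4)
        assert out["plateau"] == pytest.approx(4.5)

    def test_noisy_recovery_across_seeds(self):
        est = [segmented_response(
            (d := synth.simulate_sumf1_dose_response(
                synth.DoseResponseSimConfig(seed=s)))["level"],
            d["specific_activity"], split="estimate")["breakpoint"]
            for s in range(50)]
        assert abs(np.median(est) - 0.4) <= 0.05

    def test_fixed_split_matches_closed_form_ols(self):
        d = synth.simulate_sumf1_dose_response(synth.DoseResponseSimConfig(seed=3))
        out = segmented_response(d["level"], d["specific_activity"], split=0.4)
        low = d[d["level"] < 0.4]
        lr = stats.linregress(low["level"], low["specific_activity"])
        assert out["low"].params["slope"] == pytest.approx(lr.slope)
        assert out["low"].r2 == pytest.approx(lr.rvalue ** 2)

    def test_estimator_consistency_with_n(self):
        def err(n, seed):
            levels = tuple(np.linspace(0.05, 1.2, n))
            d = synth.simulate_sumf1_dose_response(synth.DoseResponseSimConfig(
                sumf1_levels=levels, seed=seed))
            got = segmented_response(d["level"], d["specific_activity"],
                                     split="estimate")["breakpoint"]
            return abs(got - 0.4)
        small = np.mean([err(8, s) for s in range(20)])
        large = np.mean([err(60, s) for s in range(20)])
        assert large <= small + 0.01

    def test_estimate_needs_six_points(self):
        with pytest.raises(ValueError):
            segmented_response([0.1, 0.5, 1.0], [1, 2, 2], split="estimate")

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            segmented_response([0.5, 0.6, 0.7], [1, 2, 3], split=0.4)


class TestAnovaDunnett:
    def test_identical_groups_nothing_significant(self):
        g = {"CMV": [1.0, 1.1, 0.9], "a": [1.0, 1.1, 0.9], "b": [1.0, 1.1, 0.9]}
        out = anova_dunnett(g)
        assert not out["comparisons"]["significant"].any()

    def test_large_shift_significant(self):
        rng = np.random.default_rng(8)
        base = rng.normal(0, 1, 3)
        g = {"CMV": base, "shifted": base + 10.0, "same": rng.normal(0, 1, 3)}
        out = anova_dunnett(g)
        comp = out["comparisons"].set_index("group")
        assert comp.loc["shifted", "significant"]
        assert not comp.loc["same", "significant"]

    def test_flags_monotone_in_effect_size(self):
        base = np.array([0.0, 0.05, -0.05, 0.02])
        order = ["n.s.", "#", "*", "**", "***"]
        ranks = []
        for shift in (0.0, 1.0, 3.0, 10.0):
            g = {"CMV": base, "t": base + shift}
            flag = anova_dunnett(g)["comparisons"]["flag"].iloc[0]
            ranks.append(order.index(flag))
        assert ranks == sorted(ranks)

    def test_monte_carlo_dunnett_oracle(self):
        # compare the adjusted p-value against a direct Monte-Carlo null
        # of the max-|t| statistic (balanced, 2 treatments + control, n=4)
        rng = np.random.default_rng(9)
        n, k = 4, 2
        obs = {"CMV": np.array([0.1, -0.2, 0.05, 0.0]),
               "t1": np.array([0.9, 1.1, 0.7, 1.2]),
               "t2": np.array([0.0, 0.3, -0.1, 0.2])}
        out = anova_dunnett(obs)
        arrays = [obs["t1"], obs["t2"]]
        ctrl = obs["CMV"]
        sp2 = np.sum([(a - a.mean()) ** 2 for a in arrays + [ctrl]]) / (3 * (n - 1))
        t_obs = [abs(a.mean() - ctrl.mean()) / np.sqrt(sp2 * 2 / n) for a in arrays]
        draws = rng.normal(size=(20000, k + 1, n))
        means = draws.mean(axis=2)
        ss = ((draws - means[:, :, None]) ** 2).sum(axis=(1, 2)) / (3 * (n - 1))
        tmax = np.abs(means[:, :k] - means[:, k:]) / np.sqrt(ss * 2 / n)[:, None]
        null_max = tmax.max(axis=1)
        for t, p in zip(t_obs, out["comparisons"]["p_value"]):
            mc_p = (null_max >= t).mean()
            assert abs(p - mc_p) < 0.03

    def test_missing_control_errors(self):
        with pytest.raises(ValueError, match="control"):
            anova_dunnett({"a": [1, 2], "b": [1, 2]})

    def test_single_replicate_errors(self):
        with pytest.raises(ValueError, match="replicates"):
            anova_dunnett({"CMV": [1.0], "a": [1, 2]})

    def test_levene_and_anova_reported(self):
        g = {"CMV": [1.0, 1.2, 0.8], "a": [2.0, 2.2, 1.8]}
        out = anova_dunnett(g)
        assert 0 <= out["levene_p"] <= 1
        assert out["anova_p"] < 0.05


def test_significance_flags():
    assert significance_flag(0.5) == "n.s."
    assert significance_flag(0.07) == "#"
    assert significance_flag(0.03) == "*"
    assert significance_flag(0.005) == "**"
    assert significance_flag(0.0005) == "***"


def test_stat_config_alpha_validated():
    with pytest.raises(ValueError):
        StatConfig(alpha=1.5)
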