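import numpy as np
import pandas as pd
import pytest

from rootscreen.stats_compare import (
    add_factor_columns,
    adjust_bh,
    fit_trend,
    summarize_treatment_curves,
    ttest_groups,
    ttest_per_timepoint,
    two_way_anova,
)


def factorial_table(rng, effects=None, n_per_cell=6, days=(9,)):
    """Balanced-ish 2x2(xDAI) table with additive cell effects."""
    effects = effects or {}
    rows = []
    for tr in ("Amb-Ctl", "Amb-PsJN", "HT-Ctl", "HT-PsJN"):
        for day in days:
            for i in range(n_per_cell):
                rows.append({
                    "plant_id": f"{tr}-{i}", "treatment": tr, "dai": day,
                    "y": effects.get(tr, 0.0) + rng.normal(0.0, 1.0),
                })
    return pd.DataFrame(rows)


class TestTTest:
    def test_hand_computed_example(self):
        # pooled-variance t with df = 4: t = -3/(1 * sqrt(2/3)) = -3.6742
        r = ttest_groups([1, 2, 3], [4, 5, 6])
        assert r.t_statistic == pytest.approx(-3.6742, abs=5e-4)
        assert r.p_value == pytest.approx(0.0213, abs=5e-5)

    def test_identical_groups(self):
        r = ttest_groups([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])
        assert r.t_statistic == 0.0
        assert r.p_value == 1.0
        assert not r.significant

    def test_swap_negates_t_preserves_p(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 10), rng.normal(0.5, 1, 12)
        r1, r2 = ttest_groups(a, b), ttest_groups(b, a)
        assert r1.t_statistic == pytest.approx(-r2.t_statistic)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_welch_differs_under_unequal_variance(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 0.2, 8), rng.normal(0.5, 3.0, 30)
        student = ttest_groups(a, b)
        welch = ttest_groups(a, b, welch=True)
        assert student.p_value != welch.p_value

    def test_too_small_group_rejected(self):
        with pytest.raises(ValueError):
            ttest_groups([1.0], [2.0, 3.0])

    def test_per_timepoint_groups_inoculation_within_temperature(self):
        rng = np.random.default_rng(2)
        table = factorial_table(rng, {"Amb-PsJN": 3.0})
        r = ttest_per_timepoint(table, "y", 9, "ambient")
        assert r.significant and r.mean_a > r.mean_b
        r_ht = ttest_per_timepoint(table, "y", 9, "high")
        assert not r_ht.significant

    def test_per_timepoint_skips_tiny_group_with_warning(self):
        rng = np.random.default_rng(3)
        table = factorial_table(rng, n_per_cell=1)
        with pytest.warns(UserWarning):
            assert ttest_per_timepoint(table, "y", 9, "ambient") is None


class TestAnova:
    def test_identical_cell_samples_give_zero_f(self):
        # every cell holds the same sample, so all factor sums of squares
        # vanish while residual variance stays positive
        table = factorial_table(np.random.default_rng(4))
        table["y"] = np.tile([1.0, 2.0, 3.0, 4.0, 5.0, 6.0], 4)
        res = two_way_anova(table, "y", "per_day", dai=9)
        for eff in res.effects.values():
            assert eff["F"] == pytest.approx(0.0, abs=1e-12)

    def test_pure_temperature_effect_detected(self):
        rng = np.random.default_rng(5)
        table = factorial_table(rng, {"HT-Ctl": 4.0, "HT-PsJN": 4.0},
                                n_per_cell=10)
        res = two_way_anova(table, "y", "per_day", dai=9)
        assert res.p("temperature") < 1e-6
        assert res.p("microbe") > 0.05

    def test_interaction_detected_when_effect_only_at_ambient(self):
        rng = np.random.default_rng(6)
        table = factorial_table(rng, {"Amb-PsJN": 3.0}, n_per_cell=10)
        res = two_way_anova(table, "y", "per_day", dai=9)
        assert res.p("interaction") < 0.01

    def test_whole_period_blocks_on_day(self):
        rng = np.random.default_rng(7)
        table = factorial_table(rng, {"HT-Ctl": 2.0, "HT-PsJN": 2.0},
                                days=(5, 9, 14))
        table["y"] += table["dai"] * 0.5        # strong day trend
        res = two_way_anova(table, "y", "whole_period")
        assert res.p("temperature") < 1e-6

    def test_empty_cell_named_in_error(self):
        rng = np.random.default_rng(8)
        table = factorial_table(rng)
        table = table[table["treatment"] != "HT-PsJN"]
        with pytest.raises(ValueError, match="temperature=high"):
            two_way_anova(table, "y", "per_day", dai=9)

    def test_balanced_sums_of_squares_add_up(self):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(9)
        table = add_factor_columns(
            factorial_table(rng, {"Amb-PsJN": 1.0, "HT-Ctl": -1.0}))
        model = smf.ols("y ~ C(inoculation) * C(temperature)", table).fit()
        aov = sm.stats.anova_lm(model, typ=2)
        total_ss = float(((table["y"] - table["y"].mean()) ** 2).sum())
        assert aov["sum_sq"].sum() == pytest.approx(total_ss)


class TestTrendFits:
    def test_noiseless_exponential_recovered(self):
        x = np.linspace(1, 8, 12)
        f = fit_trend(x, 2.0 * np.exp(0.3 * x), "exponential")
        a, b = f.coefficients
        assert (a, b) == (pytest.approx(2.0), pytest.approx(0.3))
        assert f.r_squared == pytest.approx(1.0)
        assert f.r_squared_scale == "log"

    def test_noiseless_quadratic_recovered(self):
        x = np.linspace(-3, 5, 15)
        f = fit_trend(x, 1.5 * x**2 - 2 * x + 0.5, "polynomial")
        assert f.r_squared == pytest.approx(1.0)
        assert f.coefficients[0] == pytest.approx(1.5)

    def test_constant_y_exponential_flat(self):
        # no growth: rate coefficient ~0 and nothing to explain (R^2 = 0)
        f = fit_trend(np.arange(1.0, 9.0), np.full(8, 3.0), "exponential")
        assert f.coefficients[1] == pytest.approx(0.0, abs=1e-12)
        assert f.r_squared == pytest.approx(0.0, abs=1e-9)

    def test_nonpositive_y_rejected_for_exponential(self):
        with pytest.raises(ValueError):
            fit_trend([1, 2, 3, 4], [1.0, 0.0, 2.0, 3.0], "exponential")

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_trend([1, 2], [1, 2], "polynomial")


class TestSummaries:
    def test_mean_and_se(self):
        table = pd.DataFrame({
            "plant_id": list("abc"), "treatment": "Amb-Ctl", "dai": 9,
            "y": [2.0, 4.0, 6.0],
        })
        s = summarize_treatment_curves(table, ["y"])
        assert s.iloc[0]["mean"] == pytest.approx(4.0)
        assert s.iloc[0]["se"] == pytest.approx(2.0 / np.sqrt(3))
        assert s.iloc[0]["n"] == 3

    def test_single_observation_se_missing(self):
        table = pd.DataFrame({"plant_id": ["a"], "treatment": ["HT-Ctl"],
                              "dai": [9], "y": [2.0]})
        s = summarize_treatment_curves(table, ["y"])
        assert np.isnan(s.iloc[0]["se"])

    def test_bh_adjustment_monotone_and_bounded(self):
        p = np.array([0.001, 0.01, 0.04, 0.2, 0.9])
        q = adjust_bh(p)
        assert np.all(q >= p) and np.all(q <= 1.0)
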