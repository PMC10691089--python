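import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from nodulegrowth.stats import (
    DegenerateTableError,
    InsufficientDataError,
    compare_categorical,
    compare_continuous,
    contingency_coefficient,
    fit_logistic,
    format_p,
    percent_half_up,
    summarize_groups,
    univariable_screen,
)


class TestPresentation:
    @pytest.mark.parametrize(
        "count,total,expected",
        [(11, 27, 40.7), (37, 52, 71.2), (27, 119, 22.7), (1, 8, 12.5), (1, 800, 0.1)],
    )
    def test_percent_half_up(self, count, total, expected):
        assert percent_half_up(count, total) == expected

    def test_half_up_not_bankers(self):
        # 0.125 -> 12.5% -> one decimal half-up gives 12.5; 5/40=12.5 exact;
        # the interesting case: 0.145 must round up, not to even
        assert percent_half_up(29, 200) == 14.5
        assert percent_half_up(145, 1000) == 14.5
        assert percent_half_up(1, 16) == 6.3  # 6.25 rounds up

    @pytest.mark.parametrize(
        "p,expected", [(0.0005, "<0.001"), (0.0011, "0.001"), (0.04997, "0.050"),
                       (float("nan"), "NA")]
    )
    def test_format_p(self, p, expected):
        assert format_p(p) == expected


class TestSummarizeGroups:
    def test_categorical_counts_and_percentages(self):
        df = pd.DataFrame(
            {"grp": ["A"] * 27 + ["B"] * 52,
             "ln": ["yes"] * 11 + ["no"] * 16 + ["yes"] * 15 + ["no"] * 37}
        )
        out = summarize_groups(df, "grp", categorical=["ln"])
        row = out[(out.variable == "ln") & (out.level == "yes")].iloc[0]
        assert row["A"] == "11(40.7)"

    def test_continuous_mean_sd_and_constant_variable(self):
        df = pd.DataFrame({"grp": ["A"] * 3, "x": [5.0, 5.0, 5.0]})
        out = summarize_groups(df, "grp", continuous=["x"])
        assert out.iloc[0]["A"] == "5.00 ± 0.00"

    def test_empty_group_zero_counts(self):
        df = pd.DataFrame({"grp": pd.Categorical(["A", "A"], categories=["A", "B"]),
                           "v": ["x", "y"]})
        out = summarize_groups(df, "grp", categorical=["v"])
        assert not out.empty  # no exception; group B simply absent from data


class TestCompareContinuous:
    def test_identical_tied_groups_mann_whitney(self):
        res = compare_continuous([3.0, 3.0, 3.0], [3.0, 3.0, 3.0], "mann_whitney")
        assert res["p"] == 1.0 and res["effect"] == 0.0

    def test_extreme_separation_welch(self):
        res = compare_continuous([1, 2, 3], [101, 102, 103], "welch_t")
        assert res["p"] < 0.001 and res["method"] == "welch_t"

    def test_welch_t_matches_independent_implementation(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0.0, 1.0, 50)
        y = rng.normal(1.0, 1.0, 50)
        res = compare_continuous(x, y, "welch_t")
        # independent route: Welch statistic and Satterthwaite df by hand
        vx, vy = x.var(ddof=1) / len(x), y.var(ddof=1) / len(y)
        t = (x.mean() - y.mean()) / np.sqrt(vx + vy)
        df = (vx + vy) ** 2 / (vx**2 / (len(x) - 1) + vy**2 / (len(y) - 1))
        p = 2 * sps.t.sf(abs(t), df)
        assert res["p"] == pytest.approx(p, abs=1e-6)

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            compare_continuous([1.0], [2.0, 3.0])


class TestCompareCategorical:
    def test_identical_proportions_chi2_zero(self):
        res = compare_categorical([[10, 20], [20, 40]])
        assert res["chi2"] == pytest.approx(0.0, abs=1e-12)
        assert res["p"] == pytest.approx(1.0)

    def test_chi2_equals_hand_formula(self):
        obs = np.array([[10.0, 20.0], [5.0, 40.0]])
        res = compare_categorical(obs)
        n = obs.sum()
        expected = np.outer(obs.sum(1), obs.sum(0)) / n
        hand = ((obs - expected) ** 2 / expected).sum()
        assert res["chi2"] == pytest.approx(hand, rel=1e-12)
        assert res["df"] == 1

    def test_three_by_two_df(self):
        res = compare_categorical([[15, 37], [7, 58], [3, 24]])
        assert res["df"] == 2
        assert res["p"] < 0.05  # nodule texture differs across size classes

    def test_degenerate_table(self):
        with pytest.raises(DegenerateTableError):
            compare_categorical([[0, 0], [5, 10]])


class TestContingencyCoefficient:
    def test_independence_gives_zero(self):
        assert contingency_coefficient([[10, 20], [20, 40]]) == pytest.approx(0.0, abs=1e-9)

    def test_perfect_association_two_by_two(self):
        # chi2 = n for a perfectly associated 2x2: C = sqrt(1/2)
        assert contingency_coefficient([[50, 0], [0, 50]]) == pytest.approx(
            np.sqrt(0.5), rel=1e-12
        )

    def test_pathology_by_nodal_status(self):
        c = contingency_coefficient([[3, 0], [19, 0], [95, 27]])
        assert round(c, 2) == 0.20

    def test_permutation_invariance_and_bound(self):
        t = np.array([[3, 0], [19, 0], [95, 27]])
        c = contingency_coefficient(t)
        assert contingency_coefficient(t[::-1]) == pytest.approx(c, rel=1e-12)
        assert contingency_coefficient(t[:, ::-1]) == pytest.approx(c, rel=1e-12)
        assert 0 <= c < 1


class TestUnivariableScreen:
    def test_null_type_one_error_rate(self):
        # outcome independent of a continuous variable: over replicates the
        # rejection rate at alpha=0.05 stays near 5%
        rng = np.random.default_rng(7)
        n_rep, n = 1000, 60
        x = rng.normal(size=(n_rep, n))
        y = np.tile(np.repeat([0, 1], n // 2), (n_rep, 1))
        res = sps.ttest_ind(
            np.where(y == 0, x, np.nan), np.where(y == 1, x, np.nan),
            equal_var=False, axis=1, nan_policy="omit",
        )
        rate = np.mean(res.pvalue < 0.05)
        assert 0.03 < rate < 0.07
        # and the screen itself agrees with the per-variable test on one draw
        df = pd.DataFrame({"x": x[0], "y": y[0]})
        out = univariable_screen(df, "y", ["x"])
        assert out.p.iloc[0] == pytest.approx(res.pvalue[0], abs=1e-12)

    def test_constant_variable_flagged(self):
        df = pd.DataFrame({"x": [1.0] * 10, "y": [0, 1] * 5})
        out = univariable_screen(df, "y", ["x"])
        assert out.flag.iloc[0] == "constant" and np.isnan(out.p.iloc[0])

    def test_empty_variable_list(self):
        df = pd.DataFrame({"y": [0, 1, 0, 1]})
        assert univariable_screen(df, "y", []).empty

    def test_mixed_kinds_ordered_report(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(
            {"y": rng.integers(0, 2, 80),
             "cont": rng.normal(size=80),
             "cat": rng.choice(["a", "b"], 80)}
        )
        out = univariable_screen(df, "y", ["cat", "cont"])
        assert list(out.variable) == ["cat", "cont"]
        assert list(out.kind) == ["categorical", "continuous"]


class TestFitLogistic:
    def test_two_by_two_odds_ratio_cross_product(self):
        # 2x2 design [[10,20],[5,40]]: OR = (10*40)/(20*5) = 4
        rows = ([{"x": 1, "y": 1}] * 10 + [{"x": 1, "y": 0}] * 20
                + [{"x": 0, "y": 1}] * 5 + [{"x": 0, "y": 0}] * 40)
        fit = fit_logistic(pd.DataFrame(rows), "y", ["x"])
        assert fit.reliable
        assert fit.table.or_.iloc[0] == pytest.approx(4.0, rel=1e-8)

    def test_intercept_only_recovers_prevalence(self):
        df = pd.DataFrame({"y": [1] * 30 + [0] * 70})
        fit = fit_logistic(df, "y", [])
        prevalence = 1 / (1 + np.exp(-fit.intercept))
        assert prevalence == pytest.approx(0.30, rel=1e-6)

    def test_separation_detected_and_flagged(self):
        df = pd.DataFrame({"x": np.r_[np.zeros(20), np.ones(20)],
                           "y": np.r_[np.zeros(20), np.ones(20)].astype(int)})
        fit = fit_logistic(df, "y", ["x"])
        assert fit.separation and not fit.reliable

    def test_null_coverage_of_wald_interval(self):
        # covariate independent of outcome: the 95% CI covers OR=1 at ~95%
        rng = np.random.default_rng(11)
        covered = 0
        n_rep = 200
        for _ in range(n_rep):
            df = pd.DataFrame(
                {"x": rng.normal(size=120), "y": rng.integers(0, 2, 120)}
            )
            fit = fit_logistic(df, "y", ["x"])
            row = fit.table.iloc[0]
            covered += row.ci_low <= 1.0 <= row.ci_high
        assert 0.90 <= covered / n_rep <= 0.99
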