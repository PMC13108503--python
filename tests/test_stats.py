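import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from netseg import (
    ThresholdSweepResult,
    TestResult,
    build_composite,
    chi_square_2x2,
    levene_center_median,
    mann_whitney,
    rank_anova,
    robust_group_regression,
    shapiro_wilk,
    spearman_partial,
    threshold_consistency,
    variance_ratio,
)


class TestBuildComposite:
    @pytest.fixture
    def fixture6(self):
        scores = pd.DataFrame(
            {
                "t1": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
                "t2": [2.0, 1.0, 4.0, 3.0, 6.0, 5.0],
                "t3": [1.0, 3.0, np.nan, 2.0, 6.0, 4.0],
            }
        )
        groups = pd.Series(["y", "y", "y", "o", "o", "o"])
        return scores, groups

    def test_group_mean_imputation_hand_computed(self, fixture6):
        scores, groups = fixture6
        comp = build_composite(scores, {"t1": 1, "t2": 1, "t3": 1}, groups)

        def z(col):
            return (col - col.mean()) / col.std(ddof=1)

        z1, z2, z3 = z(scores.t1), z(scores.t2), z(scores.t3)
        fill = z3[[0, 1]].mean()  # young-group mean of observed z3
        expected = (z1[2] + z2[2] + fill) / 3
        assert comp[2] == pytest.approx(expected, abs=1e-12)
        # fully observed subject: plain mean of z's
        assert comp[0] == pytest.approx((z1[0] + z2[0] + z3[0]) / 3, abs=1e-12)

    def test_inverse_orientation_lowers_composite(self, fixture6):
        scores, groups = fixture6
        plus = build_composite(scores, {"t1": 1}, groups)
        minus = build_composite(scores, {"t1": -1}, groups)
        np.testing.assert_allclose(minus, -plus)
        # larger raw value on an inverse test lowers the composite
        assert minus[5] < minus[0]

    def test_zero_variance_test_contributes_zero(self, fixture6):
        scores, groups = fixture6
        scores = scores.assign(flat=1.0)
        with_flat = build_composite(
            scores, {"t1": 1, "flat": 1}, groups
        )
        alone = build_composite(scores, {"t1": 1}, groups)
        np.testing.assert_allclose(with_flat, alone / 2)

    def test_subject_missing_all_tests_gets_missing_composite(self):
        scores = pd.DataFrame({"t1": [1.0, np.nan, 3.0, 4.0]})
        groups = pd.Series(["y", "y", "o", "o"])
        comp = build_composite(scores, {"t1": 1}, groups)
        assert np.isnan(comp[1])


class TestDistributionGates:
    def test_levene_calibrated_under_null(self):
        rng = np.random.default_rng(77)
        groups = np.repeat(["a", "b"], 200)
        rejects = sum(
            levene_center_median(rng.standard_normal(400), groups).pvalue < 0.05
            for _ in range(200)
        )
        assert 2 <= rejects <= 20  # ~5% of 200

    def test_levene_constant_samples_rejected(self):
        with pytest.raises(ValueError):
            levene_center_median(np.ones(20), np.repeat(["a", "b"], 10))

    def test_shapiro_power_on_heavy_tails(self):
        rng = np.random.default_rng(78)
        rejects = sum(
            shapiro_wilk(rng.standard_t(df=3, size=100)).pvalue < 0.05
            for _ in range(100)
        )
        assert rejects >= 80

    def test_shapiro_needs_three_observations(self):
        with pytest.raises(ValueError):
            shapiro_wilk([1.0, 2.0])


class TestRankAnova:
    def test_identical_groups_give_zero_f(self):
        y = np.tile(np.arange(10.0), 2)
        group = np.repeat(["g1", "g2"], 10)
        sex = np.tile(np.repeat(["f", "m"], 5), 2)
        res = rank_anova(y, group, sex)
        assert res.statistic == pytest.approx(0.0, abs=1e-20)

    def test_matches_statsmodels_type2_anova_on_ranks(self):
        """Independent oracle: statsmodels OLS + anova_lm (type II) on the
        mid-ranked outcome."""
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        rng = np.random.default_rng(5)
        n = 120
        df = pd.DataFrame(
            {
                "g": rng.choice(["old", "young"], n),
                "s": rng.choice(["f", "m"], n),
            }
        )
        df["y"] = rng.standard_normal(n) + (df.g == "old") * 0.8
        res = rank_anova(df.y, df.g, df.s)
        df["r"] = sps.rankdata(df.y)
        fit = ols("r ~ C(g) + C(s)", data=df).fit()
        tab = sm.stats.anova_lm(fit, typ=2)
        assert res.statistic == pytest.approx(tab.loc["C(g)", "F"], abs=1e-10)
        assert res.pvalue == pytest.approx(tab.loc["C(g)", "PR(>F)"], abs=1e-10)
        assert res.df == (1.0, float(n - 3))

    def test_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(6)
        y = rng.standard_normal(80)
        g = rng.choice(["a", "b"], 80)
        s = rng.choice(["f", "m"], 80)
        f1 = rank_anova(y, g, s).statistic
        f2 = rank_anova(np.exp(3 * y), g, s).statistic
        assert f1 == pytest.approx(f2, rel=1e-12)

    def test_constant_outcome_rejected(self):
        with pytest.raises(ValueError):
            rank_anova(np.ones(20), np.repeat(["a", "b"], 10),
                       np.tile(["f", "m"], 10))


class TestSpearmanPartial:
    def test_reduces_to_ordinary_spearman_without_covariates(self):
        rng = np.random.default_rng(7)
        x, y = rng.standard_normal(50), rng.standard_normal(50)
        res = spearman_partial(x, y)
        rho, p = sps.spearmanr(x, y)
        assert res.statistic == pytest.approx(rho, abs=1e-12)
        assert res.pvalue == pytest.approx(p, abs=1e-6)

    def test_perfect_monotone_association(self):
        x = np.linspace(0, 1, 30)
        assert spearman_partial(x, np.exp(x)).statistic == pytest.approx(1.0)

    def test_matches_pingouin_partial_corr(self):
        """Independent oracle: pingouin's rank partial correlation."""
        import pingouin as pg

        rng = np.random.default_rng(8)
        z = rng.standard_normal(30)
        x = z + rng.standard_normal(30)
        y = 0.5 * z + rng.standard_normal(30)
        res = spearman_partial(x, y, [z])
        df = pd.DataFrame({"x": x, "y": y, "z": z})
        want = pg.partial_corr(df, x="x", y="y", covar="z",
                               method="spearman")
        assert res.statistic == pytest.approx(want["r"].iloc[0], abs=1e-10)
        assert res.pvalue == pytest.approx(want["p_val"].iloc[0], abs=1e-8)

    def test_symmetric_and_monotone_invariant(self):
        rng = np.random.default_rng(9)
        x, y, z = (rng.standard_normal(40) for _ in range(3))
        a = spearman_partial(x, y, [z]).statistic
        b = spearman_partial(y, x, [z]).statistic
        c = spearman_partial(np.exp(x), y, [z]).statistic
        assert a == pytest.approx(b, abs=1e-12)
        assert a == pytest.approx(c, abs=1e-12)

    def test_collinear_covariates_rejected(self):
        rng = np.random.default_rng(10)
        x, y = rng.standard_normal(30), rng.standard_normal(30)
        z = rng.standard_normal(30)
        with pytest.raises(ValueError, match="collinear"):
            spearman_partial(x, y, [z, 2 * z])


class TestRobustRegression:
    @staticmethod
    def _frame(n, rng, effect=1.0):
        g = np.repeat([0.0, 1.0], n // 2)
        s = rng.integers(0, 2, n).astype(float)
        y = 0.5 + effect * g + 0.2 * s + rng.standard_normal(n) * 0.5
        return pd.DataFrame({"group": g, "sex": s}), y

    def test_matches_ols_on_clean_data(self):
        # bounded noise keeps every residual inside the Huber threshold, so
        # no observation is downweighted and the M-estimate is exactly OLS
        rng = np.random.default_rng(11)
        n = 200
        g = np.repeat([0.0, 1.0], n // 2)
        s = rng.integers(0, 2, n).astype(float)
        eps = np.clip(rng.standard_normal(n), -1, 1) * 0.3
        y = 0.5 + 1.0 * g + 0.2 * s + eps
        X = pd.DataFrame({"group": g, "sex": s})
        tab = robust_group_regression(y, X)
        coef_ols = np.linalg.lstsq(
            np.column_stack([np.ones(n), g, s]), y, rcond=None
        )[0]
        np.testing.assert_allclose(tab["coef"], coef_ols, atol=1e-6)

    def test_resists_gross_outliers_better_than_ols(self):
        rng = np.random.default_rng(12)
        X, y = self._frame(400, rng, effect=1.0)
        y_dirty = y.copy()
        out = rng.choice(400, size=20, replace=False)
        y_dirty[out] += rng.choice([-1, 1], 20) * 30
        D = np.column_stack([np.ones(400), X.group, X.sex])
        ols_bias = abs(np.linalg.lstsq(D, y_dirty, rcond=None)[0][1] - 1.0)
        rob_bias = abs(robust_group_regression(y_dirty, X).loc["group", "coef"]
                       - 1.0)
        assert rob_bias < ols_bias / 2

    def test_null_effect_ci_coverage(self):
        rng = np.random.default_rng(13)
        covered = 0
        for _ in range(100):
            X, y = self._frame(120, rng, effect=0.0)
            row = robust_group_regression(y, X).loc["group"]
            lo, hi = row.coef - 1.96 * row.se, row.coef + 1.96 * row.se
            covered += lo <= 0 <= hi
        assert covered >= 93


class TestChiSquare:
    @pytest.mark.parametrize(
        "table,expected",
        [
            ([[27, 152], [34, 83]], 8.45),     # recruitment site by age group
            ([[101, 52], [107, 8]], 27.61),    # White vs other, no "not provided"
            ([[32, 121], [2, 113]], 21.79),    # Asian
            ([[15, 138], [3, 112]], 5.43),     # Black
        ],
    )
    def test_reconstructed_demographic_tables(self, table, expected):
        res = chi_square_2x2(table)
        assert res.statistic == pytest.approx(expected, abs=0.005)

    def test_proportional_table_gives_zero(self):
        assert chi_square_2x2([[10, 20], [30, 60]]).statistic == pytest.approx(0)

    def test_invariant_to_transposition_and_swaps(self):
        t = np.array([[27, 152], [34, 83]])
        base = chi_square_2x2(t).statistic
        for variant in (t.T, t[::-1], t[:, ::-1]):
            assert chi_square_2x2(variant).statistic == pytest.approx(base)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi_square_2x2([[0, 0], [3, 5]])


class TestMannWhitneyAndVarianceRatio:
    def test_u_matches_pair_counting_oracle(self):
        a = np.array([1.0, 3.0, 5.0])
        b = np.array([2.0, 3.0, 8.0])
        vals = np.concatenate([a, b])
        groups = np.repeat(["a", "b"], 3)
        res = mann_whitney(vals, groups)
        u = sum(
            1.0 if x > y else (0.5 if x == y else 0.0) for x in a for y in b
        )
        assert res.statistic == pytest.approx(u)

    def test_shift_detected_with_correct_direction(self):
        rng = np.random.default_rng(14)
        a = rng.standard_normal(80)
        b = a + 1.0
        res = mann_whitney(np.concatenate([a, b]), np.repeat(["a", "b"], 80))
        assert res.pvalue < 0.001
        assert res.direction > 0  # second group higher

    def test_variance_ratio_near_one_under_equal_variance(self):
        rng = np.random.default_rng(15)
        fs = [
            variance_ratio(rng.standard_normal(200),
                           np.repeat(["a", "b"], 100)).statistic
            for _ in range(200)
        ]
        # the dispersion F is right-skewed; its mean sits near 1 but above it
        assert 0.7 < np.mean(fs) < 1.6
        assert np.median(fs) < 1.0


class TestThresholdConsistency:
    @staticmethod
    def _sweep(pvals):
        return {
            0.05 * (i + 1): TestResult("F", 1.0, (1.0, 10.0), p)
            for i, p in enumerate(pvals)
        }

    def test_two_of_ten_not_consistent(self):
        pvals = [0.01, 0.02] + [0.5] * 8
        assert threshold_consistency(self._sweep(pvals)) is False

    def test_three_of_ten_consistent(self):
        pvals = [0.01, 0.02, 0.04] + [0.5] * 7
        assert threshold_consistency(self._sweep(pvals)) is True

    def test_no_significant_thresholds(self):
        assert threshold_consistency(self._sweep([0.9] * 10)) is False

    def test_sweep_result_counts(self):
        sw = ThresholdSweepResult(self._sweep([0.01] * 4 + [0.5] * 6))
        assert sw.n_significant == 4 and sw.consistent
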