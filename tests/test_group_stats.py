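"""Gated two-sample tests, effect sizes, regression and the robust ANOVA."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from instaphen import (
    build_comparison_table,
    cohens_d,
    d_confidence_interval,
    gated_comparison,
    hedges_g,
    mann_whitney_u,
    normality_gate,
    ols_regression,
    robust_mixed_anova,
    spearman_corr,
    welch_t,
    welch_t_from_stats,
)


class TestNormalityGate:
    def test_gaussian_pair_uses_welch(self):
        rng = np.random.default_rng(0)
        assert normality_gate(rng.normal(0, 1, 34), rng.normal(0, 1, 34)) == "welch_t"

    def test_extreme_outlier_forces_rank_test(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 34)
        q1, q3 = np.percentile(x, [25, 75])
        x[0] = q3 + 10 * (q3 - q1)
        assert normality_gate(x, rng.normal(0, 1, 34)) == "mann_whitney"

    def test_lognormal_sample_detected(self):
        # strong skew at n=34: Shapiro-Wilk rejects with probability ~1
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x = rng.lognormal(0, 1.0, 34)
            y = rng.normal(10, 1, 34)
            hits += normality_gate(x, y) == "mann_whitney"
        assert hits == 20

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            normality_gate([1, 2], [1, 2, 3])


class TestWelch:
    def test_published_saturation_summaries(self):
        t, df, p = welch_t_from_stats(77.63, 13.53, 34, 83.9, 9.88, 34)
        assert t == pytest.approx(-2.182, abs=0.005)
        assert df == pytest.approx(60.41, abs=0.05)
        assert 0.03 < p < 0.04

    def test_identical_samples(self):
        t, df, p = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0
        assert p == pytest.approx(1.0)

    def test_hand_computed_small_case(self):
        t, df, p = welch_t([1, 2, 3], [4, 5, 6])
        assert t == pytest.approx(-3 / math.sqrt(2 / 3))
        assert df == pytest.approx(4.0)

    def test_zero_variance_both_rejected(self):
        with pytest.raises(ValueError):
            welch_t([1, 1, 1], [2, 2, 2])


class TestMannWhitney:
    def test_complete_separation(self):
        u, _ = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0

    def test_identical_multisets(self):
        u, p = mann_whitney_u([1, 2, 3, 4], [1, 2, 3, 4])
        assert u == 8.0  # n1*n2/2

    def test_interleaved(self):
        assert mann_whitney_u([1, 3, 5], [2, 4, 6])[0] == 3.0

    def test_brute_force_exhaustive_small_alphabet(self):
        """U equals pairwise wins + half-ties for every pair of size-3 samples
        over a 4-value alphabet; U1 + U2 = n1*n2."""
        alphabet = [0.0, 1.0, 2.0, 3.0]
        for x in itertools.product(alphabet, repeat=3):
            for y in itertools.product(alphabet, repeat=3):
                u1 = mann_whitney_u(list(x), list(y))[0]
                wins = sum(a > b for a in x for b in y)
                ties = sum(a == b for a in x for b in y)
                assert u1 == wins + 0.5 * ties
                u2 = mann_whitney_u(list(y), list(x))[0]
                assert u1 + u2 == 9.0


class TestEffectSizes:
    def test_published_colorfulness_row(self):
        d = cohens_d(37.25, 7.51, 34, 41.86, 5.51, 34)
        assert d == pytest.approx(-0.70, abs=0.005)
        assert hedges_g(d, 68) == pytest.approx(-0.69, abs=0.005)

    def test_identical_groups(self):
        assert cohens_d(5, 1, 10, 5, 1, 10) == 0.0

    def test_pooled_sd_one(self):
        assert cohens_d(2, 1, 3, 5, 1, 3) == pytest.approx(-3.0)

    def test_hedges_closed_form(self):
        assert hedges_g(1.0, 10) == pytest.approx(1 - 3 / 31)
        assert hedges_g(0.0, 100) == 0.0

    def test_antisymmetry_and_shrinkage(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            m1, m2 = rng.normal(0, 5, 2)
            s1, s2 = rng.uniform(0.5, 3, 2)
            d = cohens_d(m1, s1, 12, m2, s2, 15)
            assert cohens_d(m2, s2, 15, m1, s1, 12) == pytest.approx(-d)
            g = hedges_g(d, 27)
            assert abs(g) < abs(d) or d == 0
            assert np.sign(g) == np.sign(d)

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            x = rng.normal(0, 1, 8)
            y = rng.normal(0.5, 2, 11)
            d = cohens_d(x.mean(), x.std(ddof=1), 8, y.mean(), y.std(ddof=1), 11)
            sp = math.sqrt((7 * x.var(ddof=1) + 10 * y.var(ddof=1)) / 17)
            assert d == pytest.approx((x.mean() - y.mean()) / sp)

    def test_ci_symmetric_at_zero_and_shrinks(self):
        lo, hi = d_confidence_interval(0.0, 34, 34)
        assert lo == pytest.approx(-hi)
        lo2, hi2 = d_confidence_interval(-0.70, 34, 34)
        assert (lo2, hi2) == pytest.approx((-1.19, -0.21), abs=0.01)
        w1 = hi - lo
        lo3, hi3 = d_confidence_interval(0.0, 340, 340)
        assert hi3 - lo3 < w1


class TestSpearman:
    def test_perfect_monotone(self):
        assert spearman_corr([1, 2, 3, 4], [10, 20, 40, 80])[0] == pytest.approx(1.0)

    def test_rank_formula(self):
        assert spearman_corr([1, 2, 3], [3, 1, 2])[0] == pytest.approx(-0.5)

    def test_constant_input_missing(self):
        rho, p = spearman_corr([1, 1, 1], [1, 2, 3])
        assert math.isnan(rho)

    def test_null_distribution(self):
        rng = np.random.default_rng(0)
        rhos = [
            spearman_corr(rng.normal(size=68), rng.normal(size=68))[0]
            for _ in range(200)
        ]
        assert abs(np.mean(rhos)) < 0.03
        assert np.std(rhos) == pytest.approx(1 / math.sqrt(67), rel=0.2)


class TestRegression:
    def _design(self, rng, n=68):
        return pd.DataFrame(
            {
                "group": rng.integers(0, 2, n),
                "sex": rng.integers(0, 2, n),
                "age": rng.uniform(15, 35, n),
                "race_b": rng.integers(0, 2, n),
                "race_c": rng.integers(0, 2, n),
                "race_d": rng.integers(0, 2, n),
            }
        )

    def test_exact_linear_fit(self):
        rng = np.random.default_rng(2)
        x = self._design(rng)
        y = 2.0 + 0.3 * x["age"]
        res = ols_regression(y, x)
        assert res.r_squared == pytest.approx(1.0)

    def test_study_degrees_of_freedom(self):
        rng = np.random.default_rng(3)
        x = self._design(rng, n=68)
        res = ols_regression(rng.normal(size=68), x)
        assert (res.df1, res.df2) == (6, 61)

    def test_rank_deficiency_named(self):
        rng = np.random.default_rng(4)
        x = self._design(rng)
        x["dup"] = x["age"]
        with pytest.raises(ValueError, match="collinear"):
            ols_regression(rng.normal(size=68), x)

    def test_residual_orthogonality(self):
        rng = np.random.default_rng(5)
        x = self._design(rng)
        y = rng.normal(size=68)
        res = ols_regression(y, x)
        coef = np.array([res.coefficients[c][0] for c in ["const", *x.columns]])
        design = np.column_stack([np.ones(68), x.to_numpy(float)])
        resid = y - design @ coef
        assert np.max(np.abs(design.T @ resid)) < 1e-8

    def test_null_f_p_roughly_uniform(self):
        rng = np.random.default_rng(6)
        ps = []
        for _ in range(100):
            x = self._design(rng)
            ps.append(ols_regression(rng.normal(size=68), x).f_pvalue)
        assert 0.35 < np.mean(ps) < 0.65


def _long(groups):
    rows = []
    for gname, mat in groups.items():
        for i, row in enumerate(mat):
            for k, v in enumerate(row):
                rows.append((f"{gname}{i}", gname, k, float(v)))
    return pd.DataFrame(rows, columns=["subject", "group", "condition", "value"])


class TestRobustMixedAnova:
    def test_trim_range_enforced(self):
        rng = np.random.default_rng(0)
        df = _long({"A": rng.normal(size=(12, 4)), "B": rng.normal(size=(12, 4))})
        with pytest.raises(ValueError):
            robust_mixed_anova(df, trim=0.5)

    def test_null_calibration_gaussian(self):
        rng = np.random.default_rng(1)
        rej = {"within": 0, "between": 0, "interaction": 0}
        n_rep = 200
        for _ in range(n_rep):
            df = _long({"A": rng.normal(size=(20, 4)), "B": rng.normal(size=(20, 4))})
            res = robust_mixed_anova(df)
            for eff in rej:
                rej[eff] += getattr(res, eff).pvalue < 0.05
        for eff, k in rej.items():
            assert 0.01 < k / n_rep < 0.11, eff

    def test_condition_effect_detected_group_null(self):
        # strong shared condition profile, no group difference
        rng = np.random.default_rng(2)
        shape = np.array([0.0, 0.5, 1.0, 0.2])
        df = _long(
            {
                "A": shape + rng.normal(0, 0.5, size=(25, 4)),
                "B": shape + rng.normal(0, 0.5, size=(25, 4)),
            }
        )
        res = robust_mixed_anova(df)
        assert res.within.pvalue < 0.01
        assert res.between.pvalue > 0.01

    def test_trim_zero_tracks_classical_mixed_anova(self):
        import pingouin as pg
        from scipy.stats import spearmanr

        rng = np.random.default_rng(3)
        mine, classical = [], []
        for _ in range(12):
            df = _long(
                {
                    "A": rng.normal(size=(20, 4)) + 0.2 * rng.standard_normal(4),
                    "B": rng.normal(size=(20, 4)),
                }
            )
            res = robust_mixed_anova(df, trim=0.0)
            aov = pg.mixed_anova(
                data=df, dv="value", within="condition",
                subject="subject", between="group",
            )
            mine.append(res.interaction.statistic)
            classical.append(
                float(aov.loc[aov["Source"] == "Interaction", "F"].iloc[0])
            )
        assert spearmanr(mine, classical).statistic > 0.9

    def test_group_shift_detected(self):
        rng = np.random.default_rng(4)
        df = _long(
            {
                "A": rng.normal(1.0, 0.5, size=(25, 4)),
                "B": rng.normal(0.0, 0.5, size=(25, 4)),
            }
        )
        assert robust_mixed_anova(df).between.pvalue < 0.001


class TestComparisonTable:
    def _features(self, rng, n=20, shift=0.0):
        return pd.DataFrame(
            {
                "group": ["SSD"] * n + ["HV"] * n,
                "f1": np.r_[rng.normal(shift, 1, n), rng.normal(0, 1, n)],
                "f2": rng.normal(0, 1, 2 * n),
            }
        )

    def test_one_row_per_feature(self):
        table = build_comparison_table(self._features(np.random.default_rng(0)))
        assert list(table["feature"]) == ["f1", "f2"]

    def test_null_cohort_rarely_large_d(self):
        rng = np.random.default_rng(1)
        big = 0
        for _ in range(30):
            table = build_comparison_table(self._features(rng, n=34))
            big += (table["cohens_d"].abs() > 0.8).sum()
        assert big / (30 * 2) < 0.05

    def test_detects_injected_shift_with_sign(self):
        table = build_comparison_table(
            self._features(np.random.default_rng(2), n=34, shift=-1.0)
        )
        row = table.set_index("feature").loc["f1"]
        assert row["p"] < 0.01
        assert row["cohens_d"] < 0
        assert row["test_used"] in {"welch_t", "mann_whitney"}
        assert (row["df"] is None) == (row["test_used"] == "mann_whitney") or np.isnan(
            row["df"]
        ) == (row["test_used"] == "mann_whitney")

    def test_missing_group_flagged_not_fatal(self):
        df = self._features(np.random.default_rng(3))
        df.loc[df["group"] == "SSD", "f2"] = np.nan
        table = build_comparison_table(df)
        row = table.set_index("feature").loc["f2"]
        assert row["test_used"] == "insufficient_data"

    def test_bh_column_monotone(self):
        table = build_comparison_table(
            self._features(np.random.default_rng(4)), benjamini_hochberg=True
        )
        assert (table["p_bh"] >= table["p"] - 1e-12).all()

    def test_gated_comparison_hedges_consistency(self):
        rng = np.random.default_rng(5)
        cmp_ = gated_comparison(rng.normal(0, 1, 30), rng.normal(1, 1, 30))
        assert cmp_.hedges_g == pytest.approx(
            cmp_.cohens_d * (1 - 3 / (4 * 60 - 9))
        )
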