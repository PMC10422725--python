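"""Statistics layer against brute-force oracles and reference values."""

import numpy as np
import pandas as pd
import pytest

from rootmorph.mesh_core import ValidationError
from rootmorph import stats as st


def toy_table(groups: dict, variable="v", grouping="g") -> pd.DataFrame:
    rows = [{grouping: k, variable: x} for k, vals in groups.items() for x in vals]
    return pd.DataFrame(rows)


class TestNormalityVariance:
    def test_shapiro_matches_reference_implementation(self):
        # W frozen from an independent implementation (R stats::shapiro.test)
        table = toy_table({"a": [1, 2, 3, 4, 5], "b": [2.0, 2.5, 3.0, 3.5, 4.0]})
        res = st.normality_and_variance(table, "v", "g")
        w_a = float(res.loc[res.group == "a", "shapiro_w"].iloc[0])
        assert w_a == pytest.approx(0.9867621554, abs=1e-6)

    def test_shapiro_matches_reference_n8(self):
        x = [2.1, 3.4, 1.9, 5.6, 4.4, 2.2, 3.3, 4.8]
        table = toy_table({"a": x, "b": list(np.arange(8.0))})
        res = st.normality_and_variance(table, "v", "g")
        assert float(res.loc[res.group == "a", "shapiro_w"].iloc[0]) == pytest.approx(
            0.9222528785, abs=1e-6
        )

    def test_levene_oracle(self):
        # Levene on absolute deviations from group means == one-way ANOVA
        # on those deviations; brute-force that here
        a, b = [1.0, 3.0, 5.0, 9.0], [2.0, 2.5, 3.0, 8.0]
        table = toy_table({"a": a, "b": b})
        res = st.normality_and_variance(table, "v", "g")
        za = np.abs(np.array(a) - np.mean(a))
        zb = np.abs(np.array(b) - np.mean(b))
        grand = np.mean(np.r_[za, zb])
        ssb = 4 * (za.mean() - grand) ** 2 + 4 * (zb.mean() - grand) ** 2
        ssw = ((za - za.mean()) ** 2).sum() + ((zb - zb.mean()) ** 2).sum()
        f_oracle = (ssb / 1) / (ssw / 6)
        assert res["levene_stat"].iloc[0] == pytest.approx(f_oracle, abs=1e-9)

    def test_constant_groups_flagged(self):
        table = toy_table({"a": [1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0]})
        res = st.normality_and_variance(table, "v", "g")
        assert bool(res.loc[res.group == "a", "degenerate"].iloc[0])
        with pytest.raises(ValidationError, match="constant"):
            st.normality_and_variance(
                toy_table({"a": [1.0] * 3, "b": [2.0] * 3}), "v", "g"
            )

    def test_same_variance_calibration(self):
        """Levene should rarely reject when variances truly match."""
        rng = np.random.default_rng(42)
        hits = 0
        for _ in range(100):
            table = toy_table(
                {"a": rng.normal(0, 1, 50), "b": rng.normal(1, 1, 50)}
            )
            res = st.normality_and_variance(table, "v", "g")
            hits += res["levene_p"].iloc[0] > 0.05
        assert hits >= 90


class TestAnova:
    def test_identical_groups(self):
        table = toy_table({k: [1.0, 2.0, 3.0] for k in "abc"})
        res = st.anova_bonferroni(table, "v", "g")
        assert res["F"] == pytest.approx(0.0, abs=1e-12)
        assert res["p"] == pytest.approx(1.0)

    def test_separated_groups(self):
        table = toy_table({"a": [0, 0.01, -0.01, 0.02], "b": [10, 10.01, 9.99, 10.02]})
        assert st.anova_bonferroni(table, "v", "g")["p"] < 1e-6

    def test_f_matches_sums_of_squares_oracle(self):
        groups = {"a": [1.0, 2.0, 4.0], "b": [3.0, 5.0, 7.0], "c": [2.0, 2.5, 9.0]}
        res = st.anova_bonferroni(toy_table(groups), "v", "g")
        allv = np.concatenate([np.asarray(v, float) for v in groups.values()])
        grand = allv.mean()
        ssb = sum(len(v) * (np.mean(v) - grand) ** 2 for v in groups.values())
        ssw = sum(((np.asarray(v) - np.mean(v)) ** 2).sum() for v in groups.values())
        f_oracle = (ssb / 2) / (ssw / 6)
        assert res["F"] == pytest.approx(f_oracle, abs=1e-9)

    def test_bonferroni_dominance(self):
        rng = np.random.default_rng(1)
        table = toy_table({k: rng.normal(i, 1, 8) for i, k in enumerate("abcd")})
        res = st.anova_bonferroni(table, "v", "g")
        pw = res["pairwise"]
        assert (pw["p_bonferroni"] >= pw["p_raw"] - 1e-15).all()
        assert (pw["p_bonferroni"] <= 1.0).all()

    def test_single_level_rejected(self):
        with pytest.raises(ValidationError, match="two factor levels"):
            st.anova_bonferroni(toy_table({"a": [1.0, 2.0]}), "v", "g")


class TestTwoSampleT:
    def test_identical_groups(self):
        table = toy_table({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        res = st.two_sample_t(table, "v", "g")
        assert res["t"] == pytest.approx(0.0, abs=1e-12)
        assert res["p"] == pytest.approx(1.0)

    def test_formula_oracle(self):
        a, b = np.array([1.2, 3.4, 2.2, 4.8]), np.array([2.0, 5.5, 6.1])
        res = st.two_sample_t(toy_table({"a": a, "b": b}), "v", "g")
        sp2 = (
            ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
        ) / (len(a) + len(b) - 2)
        t_oracle = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / len(a) + 1 / len(b)))
        assert res["t"] == pytest.approx(t_oracle, abs=1e-12)
        assert res["df"] == 5
        assert res["ci"][0] < res["mean_diff"] < res["ci"][1]

    def test_insufficient_n(self):
        with pytest.raises(ValidationError):
            st.two_sample_t(toy_table({"a": [1.0], "b": [1.0, 2.0]}), "v", "g")

    def test_side_pooling_pretest_flags(self):
        rng = np.random.default_rng(0)
        table = toy_table({"L": rng.normal(0, 1, 30), "R": rng.normal(0, 1, 30)}, grouping="side")
        res = st.side_pooling_pretest(table, "v")
        assert res["poolable"] == (res["p"] > 0.05)


class TestChiSquare:
    def test_proportional_table_zero(self):
        res = st.chi_square_counts([[10, 20], [5, 10]])
        assert res["chi2"] == pytest.approx(0.0, abs=1e-12)

    def test_gender_balance_not_significant(self):
        # a 17/23 overall male/female split across two equal groups
        assert st.chi_square_counts([[9, 11], [8, 12]])["p"] > 0.05

    def test_hand_computation(self):
        obs = np.array([[12.0, 8.0], [6.0, 14.0]])
        res = st.chi_square_counts(obs)
        exp = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
        chi2_oracle = ((obs - exp) ** 2 / exp).sum()
        assert res["chi2"] == pytest.approx(chi2_oracle, abs=1e-12)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValidationError, match="marginal"):
            st.chi_square_counts([[0, 0], [3, 4]])


class TestRegression:
    def test_exact_linear_recovery(self):
        rng = np.random.default_rng(3)
        x1, x2 = rng.normal(size=30), rng.normal(size=30)
        table = pd.DataFrame({"y": 2.0 + 3.0 * x1 - 1.5 * x2, "x1": x1, "x2": x2})
        res = st.err_regression(table, "y", ["x1", "x2"])
        coef = res.coef.set_index("predictor")["B"]
        assert coef["const"] == pytest.approx(2.0, abs=1e-9)
        assert coef["x1"] == pytest.approx(3.0, abs=1e-9)
        assert coef["x2"] == pytest.approx(-1.5, abs=1e-9)
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_normal_equations_oracle(self):
        table = pd.DataFrame(
            {
                "y": [1.0, 2.5, 2.0, 4.1, 3.7, 5.2],
                "x1": [0.0, 1.0, 1.5, 2.0, 3.0, 4.0],
                "x2": [1.0, 0.5, 2.0, 1.5, 0.0, 2.5],
            }
        )
        res = st.err_regression(table, "y", ["x1", "x2"])
        x = np.column_stack([np.ones(6), table["x1"], table["x2"]])
        beta_oracle = np.linalg.solve(x.T @ x, x.T @ table["y"])
        assert np.allclose(res.coef["B"].to_numpy(), beta_oracle, atol=1e-10)

    def test_standardized_beta_definition(self):
        rng = np.random.default_rng(8)
        x1 = rng.normal(size=40)
        x2 = rng.normal(size=40) * 5
        y = x1 - 0.2 * x2 + rng.normal(size=40)
        table = pd.DataFrame({"y": y, "x1": x1, "x2": x2})
        res = st.err_regression(table, "y", ["x1", "x2"])
        row = res.coef.set_index("predictor")
        assert row.loc["x1", "beta"] == pytest.approx(
            row.loc["x1", "B"] * x1.std(ddof=1) / y.std(ddof=1), abs=1e-12
        )

    def test_ci_definition(self):
        from scipy import stats as sps

        rng = np.random.default_rng(2)
        x1 = rng.normal(size=20)
        table = pd.DataFrame({"y": 1 + x1 + rng.normal(size=20), "x1": x1})
        res = st.err_regression(table, "y", ["x1"])
        row = res.coef.set_index("predictor").loc["x1"]
        tcrit = sps.t.ppf(0.975, 18)
        assert row["ci_low"] == pytest.approx(row["B"] - tcrit * row["se"], abs=1e-9)

    def test_collinear_predictor_named(self):
        rng = np.random.default_rng(5)
        x1 = rng.normal(size=12)
        table = pd.DataFrame({"y": rng.normal(size=12), "x1": x1, "x2": 2 * x1})
        with pytest.raises(ValidationError, match="x1|x2"):
            st.err_regression(table, "y", ["x1", "x2"])


class TestIcc:
    def test_duplicate_ratings(self):
        x = np.tile(np.arange(8.0)[:, None], (1, 2))
        assert st.icc(x).icc == pytest.approx(1.0)

    def test_variance_components_oracle(self):
        x = np.array(
            [[9.0, 2.0], [1.0, 1.5], [8.0, 7.5], [2.0, 2.5], [10.0, 9.0], [4.0, 4.5]]
        )
        res = st.icc(x)
        try:
            import pingouin as pg
        except ImportError:
            pytest.skip("pingouin unavailable for the cross-check")
        n, k = x.shape
        df = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(n), k),
                "rater": np.tile(np.arange(k), n),
                "score": x.reshape(-1),
            }
        )
        ref = pg.intraclass_corr(df, targets="subject", raters="rater", ratings="score")
        icc2 = float(ref.loc[ref["Type"] == "ICC(A,1)", "ICC"].iloc[0])
        assert res.icc == pytest.approx(icc2, abs=1e-9)

    def test_independent_ratings_near_zero(self):
        # single-replicate ICC at n=50 scatters with SD ~0.14; average a
        # few replicates to test the (un)biasedness of the estimator
        rng = np.random.default_rng(11)
        vals = [st.icc(rng.normal(size=(50, 2))).icc for _ in range(20)]
        assert abs(np.mean(vals)) < 0.15

    def test_incomplete_rejected(self):
        x = np.ones((6, 2))
        x[0, 0] = np.nan
        with pytest.raises(ValidationError, match="missing"):
            st.icc(x)


class TestSampleSize:
    def test_equal_diff_and_sd(self):
        # the classic benchmark: d = 1 needs 17 per group at 80% power
        assert st.sample_size_two_means(1.0, 1.0, 1.0) == 17

    def test_matches_statsmodels_power_solver(self):
        from statsmodels.stats.power import TTestIndPower
        import math

        for diff, sd in ((0.5, 1.0), (2.0, 3.0)):
            n = st.sample_size_two_means(diff, sd, sd)
            ref = TTestIndPower().solve_power(
                effect_size=diff / sd, alpha=0.05, power=0.8, alternative="two-sided"
            )
            assert n == math.ceil(ref)

    def test_huge_effect_needs_minimum_n(self):
        assert st.sample_size_two_means(1e9, 1.0, 1.0) == 2

    def test_doubling_sd_roughly_quadruples_n(self):
        n1 = st.sample_size_two_means(1.0, 2.0, 2.0)
        n2 = st.sample_size_two_means(1.0, 4.0, 4.0)
        assert n2 == pytest.approx(4 * n1, rel=0.1)

    def test_invalid_inputs(self):
        with pytest.raises(ValidationError):
            st.sample_size_two_means(1.0, -1.0, 1.0)
        with pytest.raises(ValidationError):
            st.sample_size_two_means(0.0, 1.0, 1.0)
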