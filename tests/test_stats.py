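"""Outlier fencing, ANCOVA, Tukey-Kramer and gated correlations vs oracles."""

import math

import numpy as np
import pandas as pd
import pytest

from semnav.stats import (
    ancova_oneway,
    cohens_d,
    compare_groups,
    correlate_clinical,
    remove_outliers,
    tukey_posthoc_effects,
)


class TestRemoveOutliers:
    def test_quartile_oracle_no_removal(self):
        vals = np.arange(1, 11, dtype=float)
        kept, removed = remove_outliers(vals)
        # Q1=3.25, Q3=7.75, IQR=4.5 -> fences [-10.25, 21.25]
        assert removed.size == 0
        np.testing.assert_array_equal(kept, vals)

    def test_quartile_oracle_removes_extreme(self):
        vals = [1.0, 2.0, 3.0, 4.0, 100.0]
        kept, removed = remove_outliers(vals)
        # Q1=2, Q3=4, IQR=2 -> upper fence 4 + 3*2 = 10
        assert removed.tolist() == [4]
        assert kept.tolist() == [1.0, 2.0, 3.0, 4.0]

    def test_constant_vector_unchanged(self):
        kept, removed = remove_outliers([5.0] * 6)
        assert removed.size == 0 and kept.size == 6

    def test_partition_and_fence_invariants(self):
        rng = np.random.default_rng(3)
        vals = rng.standard_t(df=2, size=200)  # heavy tails force removals
        kept, removed = remove_outliers(vals)
        assert len(kept) + len(removed) == len(vals)
        q1, q3 = np.percentile(vals, [25, 75])
        iqr = q3 - q1
        assert kept.min() >= q1 - 3 * iqr and kept.max() <= q3 + 3 * iqr


class TestAncova:
    def _toy(self, seed=0, n=20, effect=0.0, cov_coef=0.0):
        rng = np.random.default_rng(seed)
        groups = np.repeat(["a", "b", "c"], n)
        cov = rng.normal(10, 3, size=3 * n)
        shift = {"a": 0.0, "b": effect, "c": -effect}
        y = np.array([shift[g] for g in groups]) + cov_coef * cov + rng.standard_normal(3 * n)
        return y, groups, cov

    def test_zero_covariate_balanced_matches_plain_anova(self):
        from scipy.stats import f_oneway

        y, groups, cov = self._toy(seed=1, effect=1.0)
        res = ancova_oneway(y, groups, None)
        f_ref, p_ref = f_oneway(y[groups == "a"], y[groups == "b"], y[groups == "c"])
        assert res.f_statistic == pytest.approx(f_ref, abs=1e-10)
        assert res.p_value == pytest.approx(p_ref, abs=1e-10)

    def test_identical_groups_f_near_zero(self):
        base = np.arange(10, dtype=float)
        y = np.concatenate([base, base, base])
        groups = np.repeat(["a", "b", "c"], 10)
        res = ancova_oneway(y, groups, None)
        assert res.f_statistic == pytest.approx(0.0, abs=1e-10)

    def test_matches_statsmodels_oracle(self):
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        y, groups, cov = self._toy(seed=2, effect=0.8, cov_coef=0.5)
        res = ancova_oneway(y, groups, cov)
        frame = pd.DataFrame({"y": y, "g": groups, "cov": cov})
        fit = ols("y ~ C(g) + cov", data=frame).fit()
        table = sm.stats.anova_lm(fit, typ=2)
        assert res.f_statistic == pytest.approx(table.loc["C(g)", "F"], rel=1e-8)
        assert res.p_value == pytest.approx(table.loc["C(g)", "PR(>F)"], rel=1e-6)
        eta_ref = table.loc["C(g)", "sum_sq"] / (
            table.loc["C(g)", "sum_sq"] + table.loc["Residual", "sum_sq"]
        )
        assert res.partial_eta_squared == pytest.approx(eta_ref, rel=1e-8)

    def test_hand_constructed_normal_equations_oracle(self):
        y = np.array([1.0, 2.0, 2.5, 4.0, 4.5, 6.0])
        groups = np.array(["a", "a", "b", "b", "c", "c"])
        cov = np.array([0.0, 1.0, 0.5, 1.5, 1.0, 2.0])
        res = ancova_oneway(y, groups, cov)

        def rss(x):
            beta = np.linalg.solve(x.T @ x, x.T @ y)
            r = y - x @ beta
            return r @ r

        ones = np.ones(6)
        x_red = np.column_stack([ones, cov])
        x_full = np.column_stack([ones, cov, groups == "b", groups == "c"]).astype(float)
        ss_g = rss(x_red) - rss(x_full)
        f_ref = (ss_g / 2) / (rss(x_full) / 2)
        assert res.f_statistic == pytest.approx(f_ref, rel=1e-10)

    def test_collinear_covariate_errors(self):
        y = np.arange(8, dtype=float)
        groups = np.repeat(["a", "b"], 4)
        cov = (groups == "a").astype(float)
        with pytest.raises(ValueError, match="rank"):
            ancova_oneway(y, groups, cov)

    def test_null_type_one_error_calibrated(self):
        """Omnibus p-values are uniform under the null (alpha=.05 in [0.03,0.07])."""
        rng = np.random.default_rng(12345)
        sizes = [20, 16, 26]
        groups = np.concatenate([np.repeat(lab, n) for lab, n in zip("abc", sizes)])
        hits = 0
        n_sim = 1000
        for _ in range(n_sim):
            y = rng.standard_normal(62)
            cov = rng.normal(12, 4, size=62)
            if ancova_oneway(y, groups, cov).p_value < 0.05:
                hits += 1
        assert 0.03 <= hits / n_sim <= 0.07


class TestTukey:
    def test_identical_groups_null(self):
        vals = np.concatenate([np.arange(8.0), np.arange(8.0)])
        groups = np.repeat(["a", "b"], 8)
        (ph,) = tukey_posthoc_effects(vals, groups)
        assert ph.cohens_d == pytest.approx(0.0)
        assert ph.p_value > 0.99

    def test_cohens_d_definition(self):
        assert cohens_d([0.0, 2.0], [1.0, 3.0]) == pytest.approx(-1.0 / np.sqrt(2))
        a = np.array([1.0, 2.0, 3.0])
        assert cohens_d(a + 1, a) == pytest.approx(1.0)

    def test_antisymmetry_and_relabel_invariance(self):
        rng = np.random.default_rng(5)
        vals = rng.standard_normal(30)
        groups = rng.choice(["x", "y", "z"], size=30)
        res = {ph.pair: ph for ph in tukey_posthoc_effects(vals, groups)}
        relabeled = {ph.pair: ph for ph in tukey_posthoc_effects(vals[::-1], groups[::-1])}
        for pair, ph in res.items():
            assert relabeled[pair].p_value == pytest.approx(ph.p_value)
        d_ab = cohens_d(vals[groups == "x"], vals[groups == "y"])
        d_ba = cohens_d(vals[groups == "y"], vals[groups == "x"])
        assert d_ab == pytest.approx(-d_ba)

    def test_matches_statsmodels_tukeyhsd_oracle(self):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        rng = np.random.default_rng(8)
        vals = np.concatenate(
            [rng.normal(0, 1, 20), rng.normal(0.8, 1, 16), rng.normal(0.3, 1, 26)]
        )
        groups = np.concatenate([np.repeat(g, n) for g, n in zip("abc", [20, 16, 26])])
        ours = {tuple(sorted(ph.pair)): ph.p_value for ph in tukey_posthoc_effects(vals, groups)}
        ref = pairwise_tukeyhsd(vals, groups)
        for row, p_ref in zip(ref.summary().data[1:], ref.pvalues):
            pair = tuple(sorted((row[0], row[1])))
            assert ours[pair] == pytest.approx(p_ref, abs=1e-6)


class TestCorrelations:
    def test_perfect_linear_gaussian_is_pearson(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(60)
        res = correlate_clinical(x, 2 * x)
        assert res.method == "pearson"
        assert res.coefficient == pytest.approx(1.0)

    def test_monotone_heavy_tail_is_spearman(self):
        rng = np.random.default_rng(3)
        x = rng.standard_t(df=1, size=80)
        res = correlate_clinical(x, np.exp(np.clip(x, -20, 20)))
        assert res.method == "spearman"
        assert res.coefficient == pytest.approx(1.0)

    def test_partial_removes_shared_covariate(self):
        rng = np.random.default_rng(4)
        z = rng.standard_normal(500)
        x = z + 0.4 * rng.standard_normal(500)
        y = z + 0.4 * rng.standard_normal(500)
        raw = correlate_clinical(x, y)
        partial = correlate_clinical(x, y, covariate=z, covariate_name="z")
        assert abs(raw.coefficient) > 0.5
        assert abs(partial.coefficient) < 0.1

    def test_partial_matches_pingouin_oracle(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(6)
        z = rng.standard_normal(80)
        x = 0.6 * z + rng.standard_normal(80)
        y = 0.3 * z + rng.standard_normal(80)
        res = correlate_clinical(x, y, covariate=z, covariate_name="z")
        frame = pd.DataFrame({"x": x, "y": y, "z": z})
        ref = pingouin.partial_corr(frame, x="x", y="y", covar="z", method=res.method)
        assert res.coefficient == pytest.approx(float(ref["r"].iloc[0]), abs=1e-6)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError, match="variance"):
            correlate_clinical([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])


def test_compare_groups_end_to_end(default_matrix):
    """The injected concreteness shift is detected on a full synthetic cohort."""
    matrix, _, _ = default_matrix
    res = compare_groups(matrix, "concreteness", covariate_col="education")
    assert res.n_used + res.n_outliers_removed == len(matrix)
    assert res.p_value < 0.05
    pairs = {tuple(sorted(ph.pair)) for ph in res.posthoc}
    assert pairs == {("HC", "PD"), ("HC", "bvFTD"), ("PD", "bvFTD")}
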