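"""Group-level inference: rmANOVA with omega-squared, Bayes factors,
nonparametric tests, correlations, robust regression and outlier screening."""

import itertools

import numpy as np
import pytest

from betalat import stats as st


def brute_force_f(values):
    """Independent oracle: 2x2 within-subject F via the paired-t identity.

    Main-effect F equals the squared paired t on the factor's marginal
    means; the interaction F equals the squared paired t on the
    double-difference contrast.
    """
    from scipy.stats import ttest_rel

    y = np.asarray(values, float)
    hemi = y.mean(axis=2)
    pred = y.mean(axis=1)
    t_h = ttest_rel(hemi[:, 0], hemi[:, 1]).statistic
    t_p = ttest_rel(pred[:, 0], pred[:, 1]).statistic
    inter = y[:, 0, 0] - y[:, 0, 1] - y[:, 1, 0] + y[:, 1, 1]
    t_i = inter.mean() / (inter.std(ddof=1) / np.sqrt(len(inter)))
    return t_h**2, t_p**2, t_i**2


class TestRMAnova:
    def test_constant_cells_give_zero_f(self):
        y = np.tile(np.arange(5)[:, None, None], (1, 2, 2)).astype(float)
        res = st.rm_anova_2x2(y)
        for e in res.effects():
            assert e.F == pytest.approx(0.0)

    def test_matches_paired_t_identity_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            y = rng.standard_normal((12, 2, 2))
            res = st.rm_anova_2x2(y)
            f_h, f_p, f_i = brute_force_f(y)
            assert res.hemisphere.F == pytest.approx(f_h, rel=1e-9)
            assert res.predictability.F == pytest.approx(f_p, rel=1e-9)
            assert res.interaction.F == pytest.approx(f_i, rel=1e-9)
            assert res.hemisphere.df == (1, 11)

    def test_matches_pingouin_reference(self):
        import pandas as pd
        from pingouin import rm_anova

        rng = np.random.default_rng(1)
        y = rng.standard_normal((10, 2, 2)) + np.array([[0.5, 0], [0, 0]])
        rows = [
            (s, h, p, y[s, i, j])
            for s in range(10)
            for i, h in enumerate("LR")
            for j, p in enumerate(["high", "low"])
        ]
        df = pd.DataFrame(rows, columns=["subject", "hemi", "pred", "value"])
        ref = rm_anova(data=df, dv="value", within=["hemi", "pred"],
                       subject="subject", detailed=True)
        res = st.rm_anova_2x2(y)
        got = {"hemi": res.hemisphere, "pred": res.predictability,
               "hemi * pred": res.interaction}
        for _, row in ref.iterrows():
            assert got[row["Source"]].F == pytest.approx(row["F"], rel=1e-6)
            assert got[row["Source"]].p == pytest.approx(row["p_unc"], rel=1e-6)

    def test_planted_hemisphere_effect(self):
        rng = np.random.default_rng(2)
        rejections = 0
        null_ps = []
        for _ in range(40):
            y = rng.standard_normal((20, 2, 2)) * 0.5
            y[:, 0, :] += 1.0
            res = st.rm_anova_2x2(y)
            rejections += res.hemisphere.p < 0.05
            null_ps.append(res.predictability.p)
        assert rejections >= 38
        # the absent predictability effect keeps its p roughly uniform
        assert 0.25 < np.mean(null_ps) < 0.75

    def test_missing_cells_rejected(self):
        y = np.ones((5, 2, 2))
        y[0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            st.rm_anova_2x2(y)

    def test_omega2_labels(self):
        assert st.omega2_label(0.2) == "large"
        assert st.omega2_label(0.1) == "medium"
        assert st.omega2_label(0.03) == "small"
        assert st.omega2_label(-0.01) == "negligible"


class TestBayesFactors:
    def test_equal_bics_give_unity(self):
        assert st.bf_bic_approx(10.0, 10.0).bf10 == pytest.approx(1.0)

    def test_delta_two_gives_e(self):
        assert st.bf_bic_approx(8.0, 10.0).bf10 == pytest.approx(np.e)

    def test_reciprocity(self):
        res = st.bf_bic_approx(8.0, 10.0)
        assert res.bf01 == pytest.approx(1 / res.bf10)

    @pytest.mark.parametrize(
        "bf,label",
        [(0.05, "strong"), (0.2, "moderate"), (0.5, "anecdotal"),
         (2.0, "anecdotal"), (5.0, "moderate"), (20.0, "strong")],
    )
    def test_evidence_bands_partition(self, bf, label):
        assert st.bf_label(bf) == label

    def test_interaction_bf_prefers_true_interaction(self):
        rng = np.random.default_rng(0)
        y = rng.standard_normal((20, 2, 2)) * 0.2
        y[:, 0, 0] += 2.0  # strong crossover component
        y[:, 1, 1] += 2.0
        with_int = st.anova_interaction_bf(y)
        assert with_int.bf10 > 3
        y0 = rng.standard_normal((20, 2, 2)) * 0.2  # no interaction
        assert st.anova_interaction_bf(y0).bf10 < 1


class TestNonparametric:
    def test_friedman_identical_columns(self):
        chi2, df, p = st.friedman_test(np.ones((8, 3)))
        assert chi2 == 0.0 and df == 2 and p == 1.0

    def test_friedman_detects_shift(self):
        rng = np.random.default_rng(0)
        y = rng.standard_normal((15, 3))
        y[:, 0] += 3.0
        chi2, df, p = st.friedman_test(y)
        assert p < 0.01

    def test_wilcoxon_z_sign_flips_under_swap(self):
        rng = np.random.default_rng(1)
        a = rng.standard_normal(12) + 0.8
        b = rng.standard_normal(12)
        _, z_ab, _ = st.wilcoxon_signed_rank(a, b)
        _, z_ba, _ = st.wilcoxon_signed_rank(b, a)
        assert z_ab == pytest.approx(-z_ba)
        assert z_ab > 0

    def test_wilcoxon_matches_exact_enumeration(self):
        # n=8 pairs without ties: p from the exact 2^8 sign distribution
        rng = np.random.default_rng(2)
        d = rng.standard_normal(8) + 0.6
        w, z, p = st.wilcoxon_signed_rank(d, np.zeros(8), method="exact")
        ranks = np.argsort(np.argsort(np.abs(d))) + 1
        w_obs = min(ranks[d > 0].sum(), ranks[d < 0].sum())
        count = sum(
            min(sum(r for r, s in zip(ranks, signs) if s),
                sum(r for r, s in zip(ranks, signs) if not s)) <= w_obs
            for signs in itertools.product([True, False], repeat=8)
        )
        assert p == pytest.approx(count / 256, abs=1e-12)

    def test_paired_t(self):
        t, df, p = st.paired_t([1.0, 2.0, 3.0, 4.0], [0.0, 1.0, 2.0, 3.0])
        assert df == 3
        assert t == pytest.approx(np.inf) or t > 1e6


class TestCorrelations:
    def test_identity_line(self):
        x = np.arange(10.0)
        r, p = st.correlate(x, x)
        assert r == pytest.approx(1.0)

    def test_monotone_transform_separates_methods(self):
        x = np.linspace(1, 5, 20)
        y = np.exp(x)
        rs, _ = st.correlate(x, y, method="spearman")
        rp, _ = st.correlate(x, y, method="pearson")
        assert rs == pytest.approx(1.0)
        assert rp < 1.0

    def test_one_tailed_halves_p_for_aligned_direction(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(30)
        y = x + rng.standard_normal(30)
        _, p2 = st.correlate(x, y, tail="two-sided")
        _, p1 = st.correlate(x, y, tail="greater")
        assert p1 == pytest.approx(p2 / 2, rel=1e-9)

    def test_zero_variance_flagged(self):
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            r, p = st.correlate(np.ones(6), np.arange(6.0))
        assert np.isnan(r)

    def test_estimator_consistency_bivariate_normal(self):
        rng = np.random.default_rng(1)
        rs = []
        cov = [[1, 0.5], [0.5, 1]]
        for _ in range(200):
            xy = rng.multivariate_normal([0, 0], cov, size=26)
            r, _ = st.correlate(xy[:, 0], xy[:, 1])
            rs.append(r)
        assert abs(np.mean(rs) - 0.5) < 0.1


class TestRobustRegression:
    def test_exact_line_recovered(self):
        x = np.arange(10.0)
        y = 2.0 * x + 1.0
        fit = st.robust_regression(x, y)
        assert fit.slope == pytest.approx(2.0, abs=1e-8)
        assert fit.intercept == pytest.approx(1.0, abs=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_more_resistant_than_ols_to_gross_outlier(self):
        rng = np.random.default_rng(0)
        x = np.linspace(0, 10, 25)
        y = -0.5 * x + rng.normal(0, 0.1, 25)
        y[-1] += 20.0
        robust = st.robust_regression(x, y)
        ols_slope = np.polyfit(x, y, 1)[0]
        assert abs(robust.slope - (-0.5)) < abs(ols_slope - (-0.5))

    def test_planted_negative_relation_significant(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(30)
        y = -1.5 * x + rng.normal(0, 0.5, 30)
        fit = st.robust_regression(x, y)
        assert fit.slope < 0 and fit.p < 0.01


class TestOutlierScreen:
    def test_equal_values_keep_everyone(self):
        assert st.zscore_outlier_screen(np.full(10, 2.0)).all()

    def test_gross_outlier_excluded(self):
        rng = np.random.default_rng(0)
        v = rng.normal(0, 1, 30)
        v[7] = v.std() * 25
        mask = st.zscore_outlier_screen(v)
        assert not mask[7]
        assert mask.sum() == 29

    def test_normal_exclusion_rate(self):
        rng = np.random.default_rng(1)
        excluded = [
            (~st.zscore_outlier_screen(rng.standard_normal(30))).sum()
            for _ in range(300)
        ]
        # expected ~30 * 0.0027 = 0.08 exclusions per dataset
        assert 0.0 <= np.mean(excluded) < 0.3


def test_attention_modulation_strength():
    assert st.attention_modulation_strength(0.05, -0.05) == pytest.approx(0.10)
    assert st.attention_modulation_strength([0.1, 0.3], [0.1, 0.3]) == 0.0
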