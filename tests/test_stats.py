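"""Touch scoring and the frequentist/Bayesian statistics layer."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as hst
from scipy import integrate, stats as sps

from nocilab import stats as st, synthetic as syn
from nocilab.errors import ValidationError


class TestTouchScoring:
    def _table(self, flag_matrix):
        rows = []
        for s, trials in enumerate(flag_matrix):
            for t, flags in enumerate(trials):
                rows.append([s, t, *flags])
        return pd.DataFrame(rows, columns=["subject", "trial", *st.BEHAVIOR_COLUMNS])

    def test_all_behaviors_max_score(self):
        table = self._table([[[1, 1, 1, 1]] * 3] * 4)
        s = st.score_touch(table)
        assert (s.subject_sums == 12).all()
        assert (s.per_trial_scores == 4).all().all()

    def test_no_behaviors_zero(self):
        s = st.score_touch(self._table([[[0, 0, 0, 0]] * 3] * 4))
        assert (s.subject_sums == 0).all()

    def test_mixed_trial_sum(self):
        s = st.score_touch(self._table([[[1, 1, 0, 0], [1, 1, 1, 0], [1, 0, 0, 0]]]))
        assert s.subject_sums.iloc[0] == 6
        assert list(s.trial_means) == [2, 3, 1]

    def test_wrong_trial_count_rejected(self):
        table = self._table([[[1, 0, 0, 0]] * 2])
        with pytest.raises(ValidationError, match="3 trials"):
            st.score_touch(table)

    def test_generated_table_roundtrip(self):
        table, truth = syn.generate_touch_table(20, (0.7, 0.3, 0.5, 0.9), seed=5)
        s = st.score_touch(table)
        assert list(s.subject_sums) == truth["subject_sums"]


class TestZTest:
    def test_equal_proportions_null(self):
        r = st.ztest_two_proportions(st.ProportionSample(15, 30), st.ProportionSample(15, 30))
        assert r.statistic == 0.0 and r.p_raw == pytest.approx(1.0)

    def test_extreme_split(self):
        r = st.ztest_two_proportions(st.ProportionSample(30, 30), st.ProportionSample(0, 30))
        assert r.statistic == pytest.approx(math.sqrt(60))
        assert r.p_raw < 1e-13

    def test_one_tailed_is_half_of_two_tailed(self):
        a, b = st.ProportionSample(5, 30), st.ProportionSample(15, 30)
        two = st.ztest_two_proportions(a, b, tails="two")
        one = st.ztest_two_proportions(a, b, tails="one", direction="less")
        assert two.p_raw == pytest.approx(2 * one.p_raw)

    def test_matches_statsmodels(self):
        from statsmodels.stats.proportion import proportions_ztest

        a, b = st.ProportionSample(9, 25), st.ProportionSample(17, 30)
        mine = st.ztest_two_proportions(a, b)
        z, p = proportions_ztest([a.k, b.k], [a.n, b.n])
        assert mine.statistic == pytest.approx(z)
        assert mine.p_raw == pytest.approx(p)

    def test_type_one_error_calibration(self):
        """Under H0 (p=0.5, n=30/arm), rejection rate is 5% +/- 1%."""
        rng = np.random.default_rng(2024)
        n, reps = 30, 10_000
        k1 = rng.binomial(n, 0.5, reps)
        k2 = rng.binomial(n, 0.5, reps)
        rejections = 0
        for a, b in zip(k1, k2):
            r = st.ztest_two_proportions(st.ProportionSample(int(a), n), st.ProportionSample(int(b), n))
            rejections += r.p_raw < st.ALPHA
        assert abs(rejections / reps - 0.05) <= 0.01


class TestBonferroni:
    def test_scaling_and_cap(self):
        assert st.bonferroni([0.01], m=5)[0] == pytest.approx(0.05)
        assert st.bonferroni([0.5], m=3)[0] == 1.0
        assert st.bonferroni([0.2], m=1)[0] == pytest.approx(0.2)

    def test_dominance(self):
        p = np.array([0.001, 0.2, 0.9])
        adj = st.bonferroni(p)
        assert np.all(adj >= p) and np.all(adj <= 1.0)

    def test_family_misspecification_warns(self):
        with pytest.warns(UserWarning):
            st.bonferroni([0.1, 0.2, 0.3], m=2)


class TestTTest:
    def test_identical_samples_null(self):
        r = st.ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.statistic == pytest.approx(0.0) and r.p_raw == pytest.approx(1.0)

    def test_large_shift_significant(self):
        r = st.ttest([1.0, 2.0, 3.0], [101.0, 102.0, 103.0], variant="student")
        assert r.p_raw < 1e-4

    def test_student_equals_welch_when_balanced(self):
        x = [1.0, 2.0, 3.0, 4.0]
        y = [2.0, 3.0, 4.0, 5.0]
        assert st.ttest(x, y, "student").statistic == pytest.approx(
            st.ttest(x, y, "welch").statistic
        )

    def test_degenerate_equal_constants(self):
        r = st.ttest([2.0, 2.0], [2.0, 2.0])
        assert r.p_raw == 1.0


class TestDunnett:
    def test_identical_groups(self):
        g = [1.0, 2.0, 3.0]
        res = st.anova_dunnett([g, g, g], control_index=0, reps=10_000, seed=1)
        assert res["anova_F"] == pytest.approx(0.0)
        assert all(c.p_adjusted == 1.0 for c in res["comparisons"])

    def test_family_wise_dominance(self):
        rng = np.random.default_rng(3)
        groups = [rng.normal(loc, 1.0, 8) for loc in (0.0, 0.5, 1.0, 0.2)]
        res = st.anova_dunnett(groups, control_index=0, reps=50_000, seed=2)
        for c in res["comparisons"]:
            assert c.p_adjusted >= c.p_raw - 1e-12

    def test_two_group_case_reduces_to_ttest(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(0, 1, 12), rng.normal(0.6, 1, 12)
        res = st.anova_dunnett([x, y], control_index=0, reps=200_000, seed=3)
        tt = st.ttest(y, x, variant="student")
        c = res["comparisons"][0]
        assert c.p_adjusted == pytest.approx(tt.p_raw, abs=4 * c.detail["mc_se"] + 1e-3)

    def test_matches_scipy_dunnett(self):
        from scipy.stats import dunnett as scipy_dunnett

        rng = np.random.default_rng(5)
        ctrl = rng.normal(0, 1, 10)
        g2 = rng.normal(0.4, 1, 10)
        g3 = rng.normal(0.9, 1, 10)
        res = st.anova_dunnett([ctrl, g2, g3], control_index=0, reps=200_000, seed=6)
        ref = scipy_dunnett(g2, g3, control=ctrl)
        for c, p_ref in zip(res["comparisons"], ref.pvalue):
            assert c.p_adjusted == pytest.approx(p_ref, abs=0.01)

    def test_control_index_checked(self):
        with pytest.raises(ValidationError):
            st.anova_dunnett([[1.0, 2.0], [2.0, 3.0]], control_index=5)


class TestRMAnova:
    def test_constant_trials_null(self):
        m = np.tile([[3.0], [5.0], [4.0]], (1, 4))
        r = st.rm_anova_within(m)
        assert r.statistic == 0.0 and r.p_raw == 1.0

    def test_textbook_fixture_matches_manual_ss(self):
        # hand-computed sums of squares for this 5x3 layout give F(2,8) = 61
        m = np.array([[8, 7, 6], [9, 8, 8], [6, 5, 4], [7, 6, 5], [8, 7, 6]], float)
        r = st.rm_anova_within(m)
        assert r.statistic == pytest.approx(61.0)
        assert r.detail["df2"] == 8

    def test_matches_pingouin(self):
        import pingouin as pg

        rng = np.random.default_rng(7)
        m = rng.normal(size=(8, 4)) + np.array([0.0, 0.3, 0.1, 0.5])
        r = st.rm_anova_within(m)
        df = pd.DataFrame(m, columns=list("abcd")).reset_index().melt("index")
        ref = pg.rm_anova(data=df, dv="value", within="variable", subject="index")
        assert r.statistic == pytest.approx(float(ref["F"].iloc[0]))

    def test_missing_cells_rejected(self):
        m = np.array([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(ValidationError):
            st.rm_anova_within(m)


class TestJZS:
    def test_zero_effect_supports_null(self):
        bf = st.bf_ttest_jzs(0.0, 30, 30)
        assert bf.bf10 < 1
        assert bf.category == "null hypothesis supported"

    def test_sign_symmetry(self):
        assert st.bf_ttest_jzs(2.2, 20, 20).bf10 == pytest.approx(
            st.bf_ttest_jzs(-2.2, 20, 20).bf10
        )

    def test_monotone_in_t(self):
        bfs = [st.bf_ttest_jzs(t, 15, 15).bf10 for t in (0.0, 1.0, 2.0, 3.0, 5.0)]
        assert bfs == sorted(bfs)

    def test_matches_pingouin(self):
        import pingouin as pg

        for t, n in [(2.5, 30), (1.2, 12)]:
            mine = st.bf_ttest_jzs(t, n, n).bf10
            ref = float(pg.bayesfactor_ttest(t, nx=n, ny=n, r=0.707))
            assert mine == pytest.approx(ref, rel=1e-6)

    def test_matches_mc_integration(self):
        """Quadrature agrees with Monte-Carlo integration over the g prior."""
        t, n1, n2, r = 2.5, 30, 30, 0.707
        rng = np.random.default_rng(11)
        N = n1 * n2 / (n1 + n2)
        nu = n1 + n2 - 2
        g = sps.invgamma.rvs(0.5, scale=r**2 / 2, size=1_000_000, random_state=rng)
        c = 1 + N * g
        mc = np.mean(c**-0.5 * (1 + t**2 / (c * nu)) ** (-(nu + 1) / 2)) / (
            (1 + t**2 / nu) ** (-(nu + 1) / 2)
        )
        assert st.bf_ttest_jzs(t, n1, n2).bf10 == pytest.approx(mc, rel=0.01)


class TestABBayes:
    def test_identical_zero_counts_favor_null(self):
        bf = st.bf_ab_proportions(st.ProportionSample(0, 10), st.ProportionSample(0, 10))
        assert bf.bf10 < 1

    def test_group_swap_symmetry(self):
        a, b = st.ProportionSample(18, 30), st.ProportionSample(6, 30)
        assert st.bf_ab_proportions(a, b).bf10 == pytest.approx(st.bf_ab_proportions(b, a).bf10)

    def test_closed_form_matches_quadrature(self):
        a, b = st.ProportionSample(18, 30), st.ProportionSample(7, 30)

        def lik(p, k, n):
            return p**k * (1 - p) ** (n - k)

        m1 = (
            integrate.quad(lambda p: lik(p, a.k, a.n), 0, 1)[0]
            * integrate.quad(lambda p: lik(p, b.k, b.n), 0, 1)[0]
        )
        m0 = integrate.quad(lambda p: lik(p, a.k + b.k, a.n + b.n), 0, 1)[0]
        assert st.bf_ab_proportions(a, b).bf10 == pytest.approx(m1 / m0, rel=1e-6)


class TestInterpretBF:
    @pytest.mark.parametrize(
        "bf,label",
        [
            (0.5, "null hypothesis supported"),
            (1.0, "weak"),
            (2.99, "weak"),
            (3.0, "substantial"),
            (5.0, "substantial"),
            (10.0, "strong"),
            (30.0, "very strong"),
            (100.0, "decisive"),
            (150.0, "decisive"),
        ],
    )
    def test_category_scheme(self, bf, label):
        assert st.interpret_bf(bf) == label

    @settings(max_examples=200, derandomize=True)
    @given(hst.floats(min_value=1e-8, max_value=1e8, allow_nan=False))
    def test_every_positive_bf_has_exactly_one_category(self, bf):
        labels = {
            "null hypothesis supported",
            "weak",
            "substantial",
            "strong",
            "very strong",
            "decisive",
        }
        assert st.interpret_bf(bf) in labels

    def test_nonpositive_rejected(self):
        with pytest.raises(ValidationError):
            st.interpret_bf(0.0)


class TestReport:
    def test_glyph_conventions(self):
        t = st.TestResult(2.5, 0.01, 0.01)
        bf = st.BayesFactorResult(12.0)
        rep = st.report(t, bf)
        assert rep["glyph"] == st.GLYPH_SIGNIFICANT
        assert rep["bf_glyph"] == st.GLYPH_SUBSTANTIAL_BF
        weak = st.report(st.TestResult(1.0, 0.3, 0.3), st.BayesFactorResult(1.5))
        assert weak["glyph"] == "" and weak["bf_glyph"] == st.GLYPH_WEAK_BF
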