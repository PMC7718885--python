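"""ROC/AUC, exact binomial CIs, and the normality-gated test facade."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from uromir.diagnostics import (
    compare_subgroups,
    correlate,
    exact_binomial_ci,
    ks_then_compare,
    percent,
    roc_auc,
    roc_curve,
    sens_spec_at_cutoff,
)
from uromir.panel import SEVEN_PARAM_SUBSET, panel_sum


@pytest.fixture(scope="module")
def discovery_scores(discovery_derivs):
    scores = panel_sum(discovery_derivs, SEVEN_PARAM_SUBSET).to_numpy()
    case = (discovery_derivs.groups == "ccRCC").to_numpy()
    return scores, case


class TestAuc:
    def test_perfect_separation(self):
        auc, _ = roc_auc([1, 2, 3, 10, 11, 12], [True] * 3 + [False] * 3)
        assert auc == 1.0

    def test_all_ties_give_half(self):
        auc, _ = roc_auc([5.0] * 6, [True] * 3 + [False] * 3)
        assert auc == 0.5

    def test_discovery_concordance_fraction(self, discovery_scores):
        """13 x 14 pairs, 174 concordant (ties half) -> 0.956 -> 0.96."""
        scores, case = discovery_scores
        auc, p = roc_auc(scores, case)
        assert auc == pytest.approx(174 / 182)
        assert p < 1e-4

    def test_complement_identity(self, discovery_scores):
        scores, case = discovery_scores
        a1, _ = roc_auc(scores, case, positive_is_low=True)
        a2, _ = roc_auc(scores, case, positive_is_low=False)
        assert a1 + a2 == pytest.approx(1.0)

    def test_monotone_transform_invariance(self, discovery_scores):
        scores, case = discovery_scores
        base, _ = roc_auc(scores, case)
        for f in (lambda x: 3 * x - 7, np.tanh, lambda x: x**3):
            auc, _ = roc_auc(f(scores), case)
            assert auc == pytest.approx(base)

    def test_single_class_errors(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc([1, 2, 3], [True, True, True])

    def test_roc_curve_endpoints(self, discovery_scores):
        scores, case = discovery_scores
        curve = roc_curve(scores, case)
        assert (curve.iloc[0][["fpr", "tpr"]] == 0).all()
        assert (curve.iloc[-1][["fpr", "tpr"]] == 1).all()


class TestSensSpec:
    def test_discovery_cutoff(self, discovery_scores):
        scores, case = discovery_scores
        m = sens_spec_at_cutoff(scores, case, cutoff=-6.7)
        assert (m.tp, m.fn, m.tn, m.fp) == (13, 0, 12, 2)
        assert percent(m.sensitivity) == 100
        assert percent(m.specificity) == 86

    def test_extreme_cutoffs(self, discovery_scores):
        scores, case = discovery_scores
        below = sens_spec_at_cutoff(scores, case, cutoff=scores.min() - 1)
        assert below.sensitivity == 0.0 and below.specificity == 1.0
        above = sens_spec_at_cutoff(scores, case, cutoff=scores.max() + 1)
        assert above.sensitivity == 1.0 and above.specificity == 0.0

    def test_any_cutoff_between_separated_groups_is_perfect(self):
        rng = np.random.default_rng(5)
        case = np.sort(rng.uniform(-30, -10, 13))
        control = np.sort(rng.uniform(-5, 30, 14))
        labels = np.r_[np.ones(13, bool), np.zeros(14, bool)]
        for cutoff in (-9.0, -7.0, -6.0):
            m = sens_spec_at_cutoff(np.r_[case, control], labels, cutoff=cutoff)
            assert m.sensitivity == 1.0 and m.specificity == 1.0


class TestExactCi:
    def test_all_successes_closed_form(self):
        lo, hi = exact_binomial_ci(13, 13)
        assert lo == pytest.approx(0.025 ** (1 / 13))
        assert hi == 1.0
        assert (percent(lo), percent(hi)) == (75, 100)

    def test_twelve_of_fourteen_beta_quantiles(self):
        lo, hi = exact_binomial_ci(12, 14)
        assert lo == pytest.approx(stats.beta.ppf(0.025, 12, 3))
        assert hi == pytest.approx(stats.beta.ppf(0.975, 13, 2))
        assert (percent(lo), percent(hi)) == (57, 98)

    def test_zero_successes(self):
        lo, hi = exact_binomial_ci(0, 10)
        assert lo == 0.0 and hi < 1.0

    def test_errors(self):
        with pytest.raises(ValueError):
            exact_binomial_ci(1, 0)
        with pytest.raises(ValueError):
            exact_binomial_ci(5, 4)

    @given(n=st.integers(1, 60), frac=st.floats(0, 1))
    @settings(max_examples=60, deadline=None)
    def test_interval_contains_point_estimate(self, n, frac):
        x = round(frac * n)
        lo, hi = exact_binomial_ci(x, n)
        assert lo - 1e-12 <= x / n <= hi + 1e-12

    def test_width_shrinks_with_n(self):
        widths = []
        for n in (10, 40, 160):
            lo, hi = exact_binomial_ci(int(0.8 * n), n)
            widths.append(hi - lo)
        assert widths == sorted(widths, reverse=True)

    def test_percent_rounds_half_up(self):
        assert percent(12 / 14) == 86
        assert percent(0.855) == 86
        assert percent(0.5) == 50


class TestKsGatedComparisons:
    def test_identical_paired_samples_degenerate(self):
        res = ks_then_compare([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0], paired=True)
        assert res.p_value == 1.0 and res.warning is not None

    def test_normal_samples_take_t_test(self):
        rng = np.random.default_rng(12)
        a, b = rng.normal(0, 1, 30), rng.normal(0.5, 1, 30)
        res = ks_then_compare(a, b)
        assert res.test_used == "unpaired_t"
        t, p = stats.ttest_ind(a, b)
        assert res.p_value == pytest.approx(p)

    def test_bimodal_sample_fails_gate(self):
        rng = np.random.default_rng(12)
        a = np.r_[rng.normal(-8, 0.1, 25), rng.normal(8, 0.1, 25)]
        b = rng.normal(0, 1, 50)
        res = ks_then_compare(a, b)
        assert res.test_used == "mann_whitney"

    def test_paired_flavours(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, 20)
        res = ks_then_compare(a, a + rng.normal(0.3, 0.2, 20), paired=True)
        assert res.test_used in ("paired_t", "wilcoxon_signed_rank")
        with pytest.raises(ValueError, match="equal-length"):
            ks_then_compare(a, a[:-1], paired=True)

    def test_small_samples_error(self):
        with pytest.raises(ValueError, match="fewer than 3"):
            ks_then_compare([1.0, 2.0], [1.0, 2.0, 3.0])


class TestSubgroups:
    def test_two_groups_delegate(self):
        rng = np.random.default_rng(8)
        values = np.r_[rng.normal(0, 1, 15), rng.normal(1, 1, 15)]
        groups = np.array(["a"] * 15 + ["b"] * 15)
        direct = ks_then_compare(values[:15], values[15:])
        via = compare_subgroups(values, groups)
        assert via.test_used == direct.test_used
        assert via.p_value == pytest.approx(direct.p_value)

    def test_shifted_group_flagged_in_posthoc(self):
        rng = np.random.default_rng(21)
        values = np.r_[
            rng.normal(0, 1, 12), rng.normal(0, 1, 12), rng.normal(10, 1, 12)
        ]
        groups = np.array(["g1"] * 12 + ["g2"] * 12 + ["g3"] * 12)
        res = compare_subgroups(values, groups)
        assert res.p_value < 1e-6
        assert res.posthoc is not None
        ph = res.posthoc
        if res.test_used == "anova_tukey":
            involved = ph[(ph["group1"] == "g3") | (ph["group2"] == "g3")]
            assert involved["reject"].astype(bool).all()
        else:
            involved = ph[(ph["group1"] == "g3") | (ph["group2"] == "g3")]
            assert (involved["p_adj"] < 0.05).all()

    def test_empty_level_errors(self):
        with pytest.raises(ValueError, match="at least two"):
            compare_subgroups([1.0, 2.0, 3.0], ["a", "a", "a"])


class TestCorrelate:
    def test_perfect_correlations(self):
        x = np.arange(10, dtype=float)
        assert correlate(x, x).coefficient == pytest.approx(1.0)
        assert correlate(x, -x).coefficient == pytest.approx(-1.0)

    def test_bivariate_normal_recovers_rho(self):
        rng = np.random.default_rng(9)
        x = rng.normal(0, 1, 200)
        y = 0.8 * x + np.sqrt(1 - 0.64) * rng.normal(0, 1, 200)
        res = correlate(x, y)
        assert res.test_used == "pearson"
        assert res.coefficient == pytest.approx(0.8, abs=0.1)

    def test_constant_vector_errors(self):
        with pytest.raises(ValueError, match="constant"):
            correlate([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])
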