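import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from amyloid_cutpoint import (
    InvalidInputError,
    accuracy,
    chisq_2x2,
    clopper_pearson,
    confusion,
    holm_adjust,
    pairwise_comparisons,
    percent_agreement,
    round_half_up,
    sensitivity,
    specificity,
)
from amyloid_cutpoint.metrics import ConfusionSummary


class TestConfusion:
    def test_identical_lists_have_no_errors(self):
        cs = confusion(["positive", "negative"] * 5, ["positive", "negative"] * 5)
        assert (cs.fp, cs.fn) == (0, 0)

    def test_all_positive_prediction(self):
        cs = confusion(["positive"] * 6, ["positive", "negative"] * 3)
        assert (cs.tn, cs.fn) == (0, 0)
        assert (cs.tp, cs.fp) == (3, 3)

    def test_indeterminate_pairs_excluded_and_counted(self):
        cs = confusion(
            ["positive", "indeterminate", "negative"],
            ["positive", "positive", None],
        )
        assert cs.n == 1 and cs.excluded_missing == 2

    def test_no_determinate_pairs_errors(self):
        with pytest.raises(InvalidInputError):
            confusion(["indeterminate"], ["positive"])


class TestClopperPearson:
    @pytest.mark.parametrize(
        "x, n, expected",
        [
            (49, 53, (82, 98)),
            (24, 25, (80, 100)),
            (15, 25, (39, 79)),
        ],
    )
    def test_reproduces_published_intervals_as_integer_percent(self, x, n, expected):
        est = clopper_pearson(x, n)
        rounded = (round_half_up(100 * est.ci_low), round_half_up(100 * est.ci_high))
        assert rounded == expected

    def test_degenerate_endpoints(self):
        assert clopper_pearson(0, 10).ci_low == 0.0
        assert clopper_pearson(10, 10).ci_high == 1.0

    def test_contains_point_exhaustively(self):
        """Interval contains the point estimate for all 0 <= x <= n <= 200."""
        for n in range(1, 201):
            x = np.arange(n + 1)
            lo = np.where(x > 0, stats.beta.ppf(0.025, x, n - x + 1), 0.0)
            hi = np.where(x < n, stats.beta.ppf(0.975, x + 1, n - x), 1.0)
            p = x / n
            assert np.all(lo <= p + 1e-12) and np.all(p <= hi + 1e-12)
        # spot-check the vectorized oracle against the implementation
        for x, n in [(0, 7), (3, 7), (7, 7), (60, 200)]:
            est = clopper_pearson(x, n)
            assert est.ci_low <= est.point <= est.ci_high

    def test_matches_statsmodels_beta_interval(self):
        from statsmodels.stats.proportion import proportion_confint

        for x, n in [(49, 53), (1, 30), (15, 25), (0, 12), (12, 12)]:
            lo, hi = proportion_confint(x, n, alpha=0.05, method="beta")
            est = clopper_pearson(x, n)
            assert est.ci_low == pytest.approx(lo, abs=1e-10)
            assert est.ci_high == pytest.approx(hi, abs=1e-10)

    def test_empirical_coverage_at_least_nominal(self):
        """95% interval covers the true p in >= 95% of simulated draws."""
        rng = np.random.default_rng(2024)
        n = 25
        for p in (0.1, 0.5, 0.9):
            x = rng.binomial(n, p, size=10_000)
            lo = np.where(x > 0, stats.beta.ppf(0.025, x, n - x + 1), 0.0)
            hi = np.where(x < n, stats.beta.ppf(0.975, x + 1, n - x), 1.0)
            coverage = np.mean((lo <= p) & (p <= hi))
            assert coverage >= 0.95

    def test_invalid_counts_error(self):
        with pytest.raises(InvalidInputError):
            clopper_pearson(5, 4)


class TestRateEstimates:
    def test_sensitivity_specificity_accuracy_points(self):
        cs = ConfusionSummary(tp=49, fp=10, tn=15, fn=4)
        assert round_half_up(100 * sensitivity(cs).point) == 92
        assert round_half_up(100 * specificity(cs).point) == 60
        assert accuracy(cs).point == pytest.approx(64 / 78)

    def test_zero_denominator_is_undefined(self):
        cs = ConfusionSummary(tp=0, fp=2, tn=3, fn=0)
        with pytest.raises(InvalidInputError):
            sensitivity(cs)


class TestPercentAgreement:
    def test_identical_and_complementary_lists(self):
        a = ["positive", "negative"] * 4
        assert percent_agreement(a, a).point == 1.0
        b = ["negative", "positive"] * 4
        assert percent_agreement(a, b).point == 0.0

    def test_symmetric_and_excludes_indeterminate(self):
        a = ["positive", "negative", "indeterminate", "positive"]
        b = ["positive", "positive", "negative", None]
        est = percent_agreement(a, b)
        assert (est.numerator, est.denominator) == (1, 2)
        rev = percent_agreement(b, a)
        assert rev.point == est.point


class TestChisq:
    def test_identical_proportions_zero_statistic(self):
        c = chisq_2x2(50, 100, 50, 100)
        assert c.statistic == pytest.approx(0.0)
        assert c.p_raw == pytest.approx(1.0)

    def test_hand_computed_pearson_value(self):
        # closed-form Pearson on [[65,13],[74,4]]; the published comparison
        # prints 5.36 for these agreement counts, the exact statistic is 5.35
        c = chisq_2x2(65, 78, 74, 78)
        assert c.statistic == pytest.approx(5.347, abs=0.001)
        assert c.p_raw == pytest.approx(0.0208, abs=0.001)

    def test_extreme_difference_significant(self):
        c = chisq_2x2(0, 10, 10, 10)
        assert c.statistic == pytest.approx(20.0)
        assert c.p_raw < 0.05

    @pytest.mark.parametrize("seed", range(4))
    def test_equals_generic_pearson_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(250):
            n_a, n_b = rng.integers(2, 60, size=2)
            c_a = int(rng.integers(1, n_a))
            c_b = int(rng.integers(1, n_b))
            ours = chisq_2x2(c_a, n_a, c_b, n_b)
            table = [[c_a, n_a - c_a], [c_b, n_b - c_b]]
            ref = stats.chi2_contingency(table, correction=False)
            assert ours.statistic == pytest.approx(ref.statistic)
            assert ours.p_raw == pytest.approx(ref.pvalue)

    def test_zero_expected_cell_is_undefined(self):
        c = chisq_2x2(10, 10, 8, 8)  # no incorrect calls anywhere
        assert np.isnan(c.statistic)


def holm_oracle(p):
    """Textbook step-down adjustment: sort, multiply by (m - rank), cummax."""
    p = np.asarray(p, float)
    order = np.argsort(p, kind="stable")
    m = len(p)
    stepped = np.maximum.accumulate((m - np.arange(m)) * p[order])
    out = np.empty(m)
    out[order] = np.minimum(stepped, 1.0)
    return out


class TestHolm:
    def test_textbook_example(self):
        out = holm_adjust([0.01, 0.04, 0.03])
        assert out == pytest.approx([0.03, 0.06, 0.06])

    def test_single_p_unchanged(self):
        assert holm_adjust([0.2]) == pytest.approx([0.2])

    def test_all_equal_p(self):
        assert holm_adjust([0.05, 0.05, 0.05]) == pytest.approx([0.15, 0.15, 0.15])

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=8))
    @settings(max_examples=100, deadline=None)
    def test_dominates_raw_dominated_by_bonferroni_matches_oracle(self, p):
        adj = holm_adjust(p)
        p_arr = np.asarray(p)
        assert np.all(adj >= p_arr - 1e-12)
        assert np.all(adj <= np.minimum(len(p) * p_arr, 1.0) + 1e-12)
        assert adj == pytest.approx(holm_oracle(p))
        # monotone in the raw ordering
        order = np.argsort(p_arr, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-12)


def test_pairwise_comparisons_adjusts_within_family():
    comps = pairwise_comparisons(["A", "B", "C"], [50, 40, 20], [60, 60, 60])
    raw = [c.p_raw for c in comps]
    adj = [c.p_adjusted for c in comps]
    assert np.all(np.asarray(adj) >= np.asarray(raw))
    assert all(c.significant == (c.p_adjusted < 0.05) for c in comps)
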