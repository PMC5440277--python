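import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from amyloid_cutpoint import (
    CutpointModel,
    InvalidInputError,
    auc,
    build_roc,
    generate_cutoff_table,
    youden_optimal,
)
from amyloid_cutpoint.cutpoint import midpoint_roc


def pairwise_auc_oracle(scores, labels):
    """O(n^2) Mann-Whitney probability: P(pos > neg) + 0.5 P(tie)."""
    pos = [s for s, y in zip(scores, labels) if y]
    neg = [s for s, y in zip(scores, labels) if not y]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def counting_oracle(scores, labels, threshold):
    """Exhaustive sensitivity/specificity counts at one threshold."""
    pos = [s for s, y in zip(scores, labels) if y]
    neg = [s for s, y in zip(scores, labels) if not y]
    return (
        sum(s >= threshold for s in pos) / len(pos),
        sum(s < threshold for s in neg) / len(neg),
    )


def youden_scan_oracle(scores, labels):
    """Best J over an exhaustive scan of candidate thresholds."""
    best = -2.0
    for t in sorted(set(scores)) + [max(scores) + 1]:
        sens, spec = counting_oracle(scores, labels, t)
        best = max(best, sens + spec - 1)
    return best


class TestBuildRoc:
    def test_perfect_separation_endpoint(self):
        roc = build_roc([1.0, 2.0], ["negative", "positive"])
        i = list(roc.thresholds).index(2.0)
        assert roc.sens_at[i] == 1.0 and roc.spec_at[i] == 1.0

    def test_endpoints_cover_both_corners(self):
        roc = build_roc([1.1, 1.3, 1.5, 1.9], [0, 1, 0, 1])
        assert roc.sens_at[0] == 1.0 and roc.spec_at[0] == 0.0  # below all scores
        assert roc.sens_at[-1] == 0.0 and roc.spec_at[-1] == 1.0  # above all

    def test_monotone_sens_spec_along_thresholds(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(size=40)
        labels = rng.random(40) < 0.5
        roc = build_roc(scores, labels)
        assert np.all(np.diff(roc.sens_at) <= 1e-12)
        assert np.all(np.diff(roc.spec_at) >= -1e-12)

    def test_matches_counting_oracle_on_mixed_scores(self):
        scores = [1.0, 1.2, 1.2, 1.5, 1.7, 1.9]
        labels = [0, 0, 1, 0, 1, 1]
        roc = build_roc(scores, labels)
        for t, sens, spec in zip(roc.thresholds[:-1], roc.sens_at, roc.spec_at):
            o_sens, o_spec = counting_oracle(scores, labels, t)
            assert sens == pytest.approx(o_sens)
            assert spec == pytest.approx(o_spec)

    def test_single_class_truth_errors(self):
        with pytest.raises(InvalidInputError, match="negative"):
            build_roc([1.0, 2.0], ["positive", "positive"])
        with pytest.raises(InvalidInputError, match="positive"):
            build_roc([1.0, 2.0], ["negative", "negative"])


class TestAuc:
    def test_perfect_separation_is_one(self):
        assert auc(build_roc([1, 2, 3, 4], [0, 0, 1, 1])) == pytest.approx(1.0)

    def test_identical_scores_is_half(self):
        assert auc(build_roc([1.3] * 6, [0, 1, 0, 1, 0, 1])) == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_pairwise_oracle_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        scores = np.round(rng.normal(1.4, 0.25, 30), 1)  # rounding forces ties
        labels = rng.random(30) < 0.5
        if labels.all() or not labels.any():
            labels[0] = not labels[0]
        assert auc(build_roc(scores, labels)) == pytest.approx(
            pairwise_auc_oracle(scores, labels)
        )

    def test_matches_sklearn_on_tie_free_data(self):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(11)
        scores = rng.normal(1.4, 0.3, 60)
        labels = rng.random(60) < 0.5
        expected = sklearn_metrics.roc_auc_score(labels, scores)
        assert auc(build_roc(scores, labels)) == pytest.approx(expected)

    @given(st.integers(0, 1000))
    @settings(max_examples=25, deadline=None)
    def test_invariant_under_strictly_increasing_transform(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(0, 1, 25)
        labels = rng.random(25) < 0.5
        if labels.all() or not labels.any():
            labels[0] = not labels[0]
        base = auc(build_roc(scores, labels))
        warped = auc(build_roc(np.exp(scores) + 3 * scores, labels))
        assert warped == pytest.approx(base, abs=1e-9)


class TestYoudenOptimal:
    def test_perfect_separation_picks_smallest_positive(self):
        scores = [1.0, 1.1, 1.2, 1.5, 1.6]
        labels = [0, 0, 0, 1, 1]
        res = youden_optimal(build_roc(scores, labels))
        assert res.cutoff == pytest.approx(1.5)
        assert res.youden_j == pytest.approx(1.0)

    def test_all_equal_scores_tie_rule(self):
        roc = build_roc([1.3] * 4, [0, 1, 0, 1])
        res = youden_optimal(roc)
        assert res.youden_j == pytest.approx(0.0)
        # specificity-first tie-break selects the all-negative operating point
        assert res.specificity == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_scan_on_random_instances(self, seed):
        rng = np.random.default_rng(100 + seed)
        scores = np.round(rng.normal(1.4, 0.3, 20), 2)
        labels = rng.random(20) < 0.5
        if labels.all() or not labels.any():
            labels[0] = not labels[0]
        res = youden_optimal(build_roc(scores, labels))
        assert res.youden_j == pytest.approx(
            youden_scan_oracle(list(scores), list(labels))
        )

    def test_self_consistency_recovers_generative_threshold(self):
        rng = np.random.default_rng(7)
        scores = rng.uniform(0.8, 2.0, 50)
        t = float(np.sort(scores)[20])
        labels = scores >= t
        res = youden_optimal(build_roc(scores, labels))
        assert res.cutoff == pytest.approx(t)
        assert res.youden_j == pytest.approx(1.0)


class TestCutpointModel:
    def test_fit_results_api(self):
        model = CutpointModel(
            [1.2, 1.25, 1.3, 1.6, 1.7, 1.8],
            ["negative"] * 3 + ["positive"] * 3,
            target_region="composite",
            reference_region="GCER",
            sot="visual_bapl",
        )
        res = model.fit()
        assert res.cutoff == pytest.approx(1.6)
        assert res.auc == pytest.approx(1.0)
        assert "GCER" in res.summary()
        assert [s.value for s in res.classify([1.55, 1.65])] == ["negative", "positive"]

    def test_from_dataframe(self):
        df = pd.DataFrame({"suvr": [1.0, 2.0], "truth": ["negative", "positive"]})
        assert CutpointModel.from_dataframe(df).fit().cutoff == pytest.approx(2.0)

    def test_midpoint_candidates_same_operating_point(self):
        scores = [1.2, 1.3, 1.6, 1.7]
        labels = [0, 0, 1, 1]
        obs = CutpointModel(scores, labels).fit(candidates="observed")
        mid = CutpointModel(scores, labels).fit(candidates="midpoint")
        assert obs.result.youden_j == mid.result.youden_j == pytest.approx(1.0)
        assert 1.3 < mid.cutoff < 1.6  # strictly between the classes


class TestGenerateCutoffTable:
    def _suvr_frame(self, scores, rr="GCER", target="composite"):
        return pd.DataFrame(
            {
                "subject_id": [f"S{i}" for i in range(len(scores))],
                "reference_region": rr,
                "target_region": target,
                "suvr": scores,
            }
        )

    def test_degenerate_two_subject_cohort(self):
        suvr = self._suvr_frame([1.2, 1.8])
        truth = pd.DataFrame({"subject_id": ["S0", "S1"], "status": ["negative", "positive"]})
        out = generate_cutoff_table(suvr, truth)
        assert out["cutoff"].iloc[0] == pytest.approx(1.8)

    def test_no_cross_region_information_leak(self):
        """Permuting another reference region's scores leaves a region's
        cutoff unchanged."""
        rng = np.random.default_rng(3)
        scores = rng.normal(1.4, 0.3, 30)
        truth = pd.DataFrame(
            {
                "subject_id": [f"S{i}" for i in range(30)],
                "status": np.where(scores > 1.43, "positive", "negative"),
            }
        )
        gcer = self._suvr_frame(scores, rr="GCER")
        other = self._suvr_frame(rng.permutation(scores), rr="WCER")
        base = generate_cutoff_table(pd.concat([gcer, other]), truth)
        shuffled_other = self._suvr_frame(rng.permutation(scores), rr="WCER")
        again = generate_cutoff_table(pd.concat([gcer, shuffled_other]), truth)
        g0 = base[base["reference_region"] == "GCER"]["cutoff"].iloc[0]
        g1 = again[again["reference_region"] == "GCER"]["cutoff"].iloc[0]
        assert g0 == g1
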