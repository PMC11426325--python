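import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sargmap.evaluation import (ConfusionMatrix, bootstrap_ci,
                                confusion_matrix, evaluate_pairs, fbeta,
                                merge_to_binary, precision, recall, summarize)


def cm_from_counts(tp, fp, fn, tn):
    """Binary matrix in merged order [other, sargassum]."""
    return ConfusionMatrix(np.array([[tn, fn], [fp, tp]], dtype=np.int64))


class TestConfusionMatrix:
    def test_perfect_prediction_is_diagonal(self, rng):
        truth = rng.integers(0, 3, (16, 16)).astype(np.uint8)
        cm = confusion_matrix(truth, truth)
        assert cm.counts.sum() == cm.counts.trace() == 256

    def test_all_sargassum_vs_all_sand(self):
        pred = np.full((2, 2), 2, np.uint8)
        truth = np.full((2, 2), 1, np.uint8)
        cm = confusion_matrix(pred, truth)
        assert cm.counts[2, 1] == 4 and cm.counts.sum() == 4

    def test_matches_per_pixel_oracle(self, rng):
        pred = rng.integers(0, 3, (20, 20)).astype(np.uint8)
        truth = rng.integers(0, 3, (20, 20)).astype(np.uint8)
        cm = confusion_matrix(pred, truth)
        oracle = np.zeros((3, 3), dtype=int)
        for p, t in zip(pred.ravel(), truth.ravel()):
            oracle[p, t] += 1
        assert np.array_equal(cm.counts, oracle)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion_matrix(np.zeros((2, 2), np.uint8),
                             np.zeros((3, 2), np.uint8))


class TestMerge:
    def test_total_conserved(self, rng):
        cm = ConfusionMatrix(rng.integers(0, 50, (3, 3)))
        assert merge_to_binary(cm).total == cm.total

    def test_diagonal_merges_sand_into_other(self):
        cm = ConfusionMatrix(np.diag([5, 7, 11]))
        merged = merge_to_binary(cm)
        assert np.array_equal(merged.counts, np.diag([12, 11]))

    def test_elementwise_summation_oracle(self, rng):
        c = rng.integers(0, 100, (3, 3))
        merged = merge_to_binary(ConfusionMatrix(c)).counts
        assert merged[0, 0] == c[:2, :2].sum()
        assert merged[0, 1] == c[0, 2] + c[1, 2]
        assert merged[1, 0] == c[2, 0] + c[2, 1]
        assert merged[1, 1] == c[2, 2]

    @settings(deadline=None, max_examples=30)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_merged_sargassum_metrics_equal_three_class(self, seed):
        c = np.random.default_rng(seed).integers(0, 1000, (3, 3))
        cm3 = ConfusionMatrix(c)
        cm2 = merge_to_binary(cm3)
        assert precision(cm2, 1) == precision(cm3, 2)
        assert recall(cm2, 1) == recall(cm3, 2)


class TestPrecisionRecall:
    def test_simple_values(self):
        cm = cm_from_counts(tp=9, fp=1, fn=0, tn=5)
        assert precision(cm, 1) == pytest.approx(0.9)
        assert recall(cm, 1) == 1.0

    def test_class_absent_everywhere_is_one(self):
        cm = cm_from_counts(tp=0, fp=0, fn=0, tn=10)
        assert precision(cm, 1) == 1.0 and recall(cm, 1) == 1.0

    def test_absent_only_in_prediction(self):
        cm = cm_from_counts(tp=0, fp=0, fn=4, tn=10)
        assert precision(cm, 1) == 0.0    # never predicted
        assert recall(cm, 1) == 0.0


class TestFBeta:
    @pytest.mark.parametrize("beta", [0.5, 1.0, 2.0, 10.0])
    def test_equal_precision_recall_identity(self, beta):
        for p in (0.1, 0.5, 0.93):
            assert fbeta(p, p, beta) == pytest.approx(p)

    def test_beta_zero_is_precision(self):
        assert fbeta(0.8, 0.4, 0.0) == 0.8

    def test_direct_evaluation(self):
        assert fbeta(0.8, 0.4, 0.5) == pytest.approx(0.6667, abs=5e-5)

    def test_large_beta_tends_to_recall(self):
        assert abs(fbeta(0.8, 0.4, 1e6) - 0.4) < 1e-6

    def test_negative_beta_rejected(self):
        with pytest.raises(ValueError):
            fbeta(0.5, 0.5, -1)

    @settings(deadline=None, max_examples=50)
    @given(st.floats(0.01, 1), st.floats(0.01, 1),
           st.sampled_from([0.5, 2.0]))
    def test_bounded_by_min_max(self, p, r, beta):
        f = fbeta(p, r, beta)
        assert min(p, r) - 1e-12 <= f <= max(p, r) + 1e-12

    def test_monotone_in_each_argument(self):
        for beta in (0.5, 2.0):
            grid = np.linspace(0.05, 1, 20)
            f_p = [fbeta(p, 0.6, beta) for p in grid]
            f_r = [fbeta(0.6, r, beta) for r in grid]
            assert all(np.diff(f_p) >= -1e-12)
            assert all(np.diff(f_r) >= -1e-12)

    def test_underestimation_signature(self):
        # growing false negatives (missed sargassum) hurts recall -> the
        # recall-weighted f2 drops below f0.5; growing false positives does
        # the opposite
        def scores(fp, fn):
            cm = cm_from_counts(tp=100, fp=fp, fn=fn, tn=1000)
            p, r = precision(cm, 1), recall(cm, 1)
            return fbeta(p, r, 0.5), fbeta(p, r, 2.0)

        for fn in (10, 50, 200):
            f05, f2 = scores(fp=5, fn=fn)
            assert f05 > f2
        for fp in (10, 50, 200):
            f05, f2 = scores(fp=fp, fn=5)
            assert f2 > f05


class TestEvaluatePairs:
    def test_hand_computed_summary(self):
        # craft two binary-like masks whose sargassum f0.5 are 0.4 and 0.6:
        # easier to inject via summarize directly
        s = summarize([0.4, 0.6])
        assert s.mean == pytest.approx(0.5)
        assert s.median == pytest.approx(0.5)
        assert s.max == 0.6
        assert s.sd == pytest.approx(0.14142, abs=1e-4)
        assert s.mad == pytest.approx(0.1)

    def test_all_perfect_predictions(self, rng):
        truths = [rng.integers(0, 3, (8, 8)).astype(np.uint8) for _ in range(4)]
        _, summ = evaluate_pairs(truths, truths)
        for cls in range(3):
            for metric in ("precision", "recall", "f0.5", "f2"):
                assert summ[f"class_{cls}"][metric]["mean"] == 1.0
                assert summ[f"class_{cls}"][metric]["sd"] == 0.0

    def test_permutation_invariant_summaries(self, rng):
        preds = [rng.integers(0, 3, (8, 8)).astype(np.uint8) for _ in range(6)]
        truths = [rng.integers(0, 3, (8, 8)).astype(np.uint8) for _ in range(6)]
        _, a = evaluate_pairs(preds, truths)
        _, b = evaluate_pairs(preds[::-1], truths[::-1])
        assert a == b

    def test_degenerate_flagging(self):
        pred = np.zeros((4, 4), np.uint8)
        truth = np.zeros((4, 4), np.uint8)
        records, _ = evaluate_pairs([pred], [truth])
        assert records[0].degenerate[2] is True       # sargassum absent
        assert records[0].precision[2] == 1.0

    def test_exclude_degenerate_policy(self):
        perfect = np.zeros((4, 4), np.uint8)
        mixed = np.array([[2, 2], [0, 0]], np.uint8).repeat(2, 0).repeat(2, 1)
        _, incl = evaluate_pairs([perfect, mixed], [perfect, mixed])
        _, excl = evaluate_pairs([perfect, mixed], [perfect, mixed],
                                 exclude_degenerate=True)
        assert incl["class_2"]["f0.5"]["n"] == 2
        assert excl["class_2"]["f0.5"]["n"] == 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            evaluate_pairs([], [])


class TestBootstrap:
    def test_constant_data_zero_width(self):
        res = bootstrap_ci([0.7] * 20, seed=0)
        assert res.ci_low == res.ci_high == res.point_mean == pytest.approx(0.7)

    def test_seeded_determinism(self, rng):
        vals = rng.uniform(0, 1, 100)
        a = bootstrap_ci(vals, seed=42)
        b = bootstrap_ci(vals, seed=42)
        assert a == b
        c = bootstrap_ci(vals, seed=43)
        assert (c.ci_low, c.ci_high) != (a.ci_low, a.ci_high)

    def test_bootstrap_mean_near_sample_mean(self, rng):
        vals = rng.uniform(0, 1, 500)
        res = bootstrap_ci(vals, n_resamples=2000, seed=1)
        center = 0.5 * (res.ci_low + res.ci_high)
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(center - vals.mean()) < 3 * se

    def test_levels_nest_on_same_resamples(self, rng):
        vals = rng.normal(0, 1, 80)
        inner = bootstrap_ci(vals, level=0.90, seed=5)
        outer = bootstrap_ci(vals, level=0.99, seed=5)
        assert outer.ci_low <= inner.ci_low <= inner.ci_high <= outer.ci_high

    def test_needs_two_values(self):
        with pytest.raises(ValueError):
            bootstrap_ci([1.0])
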