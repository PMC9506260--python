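"""Confusion tallies, headline metrics, and the stack/case detection
criteria."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from hypothesis.extra import numpy as hnp

import rcmseg as r
from rcmseg.metrics import (ConfusionCounts, StackCriteria, aggregate_rates,
                            case_detected, confusion, pixel_metrics,
                            slice_lesion_recall, stack_detected)

# Pooled pixel tallies of the full-scale validation (the published
# confusion matrix), used as plain inputs to the metric formulas.
TABLE2 = ConfusionCounts(tp=49_387_779, fp=40_618_083,
                         tn=233_794_335, fn=58_199_803)


def _brute_force(pred, truth):
    tp = fp = tn = fn = 0
    for i in range(pred.shape[0]):
        for j in range(pred.shape[1]):
            if pred[i, j] and truth[i, j]:
                tp += 1
            elif pred[i, j] and not truth[i, j]:
                fp += 1
            elif not pred[i, j] and truth[i, j]:
                fn += 1
            else:
                tn += 1
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


class TestConfusion:
    def test_perfect_prediction(self):
        ones = np.ones((10, 10), np.uint8)
        c = confusion(ones, ones)
        assert (c.tp, c.fp, c.tn, c.fn) == (100, 0, 0, 0)

    def test_complement_prediction(self):
        truth = np.zeros((6, 6), np.uint8)
        truth[:3] = 1
        c = confusion(1 - truth, truth)
        assert c.tp == 0 and c.tn == 0
        assert c.fp == 18 and c.fn == 18

    def test_counts_sum_to_total(self):
        rng = np.random.default_rng(0)
        pred = (rng.uniform(size=(16, 16)) < 0.5).astype(np.uint8)
        truth = (rng.uniform(size=(16, 16)) < 0.3).astype(np.uint8)
        assert confusion(pred, truth).total == 256

    def test_matches_double_loop_tally(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            pred = (rng.uniform(size=(16, 16)) < rng.uniform()).astype(np.uint8)
            truth = (rng.uniform(size=(16, 16)) < rng.uniform()).astype(np.uint8)
            assert confusion(pred, truth) == _brute_force(pred, truth)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            confusion(np.zeros((4, 4)), np.zeros((4, 5)))

    def test_pooling_consistency(self):
        """Counts summed over slices equal counts on concatenated masks."""
        rng = np.random.default_rng(2)
        preds = [(rng.uniform(size=(8, 8)) < 0.5).astype(np.uint8) for _ in range(4)]
        truths = [(rng.uniform(size=(8, 8)) < 0.5).astype(np.uint8) for _ in range(4)]
        summed = sum((confusion(p, t) for p, t in zip(preds, truths)),
                     ConfusionCounts())
        pooled = confusion(np.concatenate(preds), np.concatenate(truths))
        assert summed == pooled


class TestPixelMetrics:
    def test_published_confusion_matrix_reproduced(self):
        m = pixel_metrics(TABLE2)
        assert round(m.sensitivity, 2) == 0.46
        assert round(m.specificity, 2) == 0.85
        (tn, fp), (fn, tp) = m.row_normalized
        assert (round(tn, 2), round(fp, 2)) == (0.85, 0.15)
        assert (round(fn, 2), round(tp, 2)) == (0.54, 0.46)

    def test_rows_sum_to_one(self):
        m = pixel_metrics(TABLE2)
        for row in m.row_normalized:
            assert abs(sum(row) - 1.0) <= 1e-9

    def test_balanced_counts_give_half_sensitivity(self):
        m = pixel_metrics(ConfusionCounts(tp=7, fn=7, tn=1, fp=1))
        assert m.sensitivity == 0.5

    def test_perfect_counts(self):
        m = pixel_metrics(ConfusionCounts(tp=10, tn=20))
        assert m.sensitivity == 1.0 and m.specificity == 1.0

    def test_empty_positive_class_flagged_not_zeroed(self):
        m = pixel_metrics(ConfusionCounts(tn=5, fp=5))
        assert np.isnan(m.sensitivity)
        assert "sensitivity" in m.undefined
        assert m.specificity == 0.5

    @given(st.integers(0, 50), st.integers(0, 50), st.integers(0, 50),
           st.integers(0, 50))
    def test_metrics_bounded(self, tp, fp, tn, fn):
        m = pixel_metrics(ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn))
        for v in (m.sensitivity, m.specificity):
            assert np.isnan(v) or 0.0 <= v <= 1.0


class TestDetectionCriteria:
    def test_recall_one_when_pred_covers_truth(self):
        truth = np.zeros((8, 8), np.uint8)
        truth[2:4, 2:4] = 1
        assert slice_lesion_recall(np.ones_like(truth), truth) == 1.0

    def test_recall_zero_on_disjoint_prediction(self):
        truth = np.zeros((8, 8), np.uint8)
        truth[:2] = 1
        pred = np.zeros_like(truth)
        pred[6:] = 1
        assert slice_lesion_recall(pred, truth) == 0.0

    def test_forty_percent_coverage_counts_as_detected(self):
        truth = np.zeros((10, 10), np.uint8)
        truth[0, :10] = 1  # 10 lesion pixels
        pred = np.zeros_like(truth)
        pred[0, :4] = 1    # exactly 40% of them
        assert slice_lesion_recall(pred, truth) == 0.40
        outcome = stack_detected([pred] * 3, [truth] * 3, StackCriteria())
        assert outcome.detected

    def test_lesion_free_slice_is_undefined(self):
        with pytest.raises(ValueError, match="no lesion"):
            slice_lesion_recall(np.ones((4, 4), np.uint8),
                                np.zeros((4, 4), np.uint8))

    def test_three_of_ten_slices_detects_stack(self):
        truth = np.ones((4, 4), np.uint8)
        hit = np.ones_like(truth)
        miss = np.zeros_like(truth)
        preds = [hit] * 3 + [miss] * 7
        assert stack_detected(preds, [truth] * 10).detected

    def test_two_slices_not_enough(self):
        truth = np.ones((4, 4), np.uint8)
        preds = [np.ones_like(truth)] * 2 + [np.zeros_like(truth)] * 8
        assert not stack_detected(preds, [truth] * 10).detected

    def test_lesion_free_stack_not_evaluable(self):
        truth = np.zeros((4, 4), np.uint8)
        outcome = stack_detected([np.ones_like(truth)] * 3, [truth] * 3)
        assert not outcome.detected
        assert not outcome.evaluable

    def test_case_detected_by_any_stack(self):
        hit = stack_detected([np.ones((4, 4), np.uint8)] * 3,
                             [np.ones((4, 4), np.uint8)] * 3)
        miss = stack_detected([np.zeros((4, 4), np.uint8)] * 3,
                              [np.ones((4, 4), np.uint8)] * 3)
        assert case_detected([hit, miss])
        assert not case_detected([miss, miss])

    def test_aggregate_rates_count_correctly(self):
        ones = np.ones((4, 4), np.uint8)
        zeros = np.zeros((4, 4), np.uint8)
        hit = stack_detected([ones] * 3, [ones] * 3)
        miss = stack_detected([zeros] * 3, [ones] * 3)
        results = {f"case{i}": [hit] for i in range(7)}
        results.update({f"case{7 + i}": [miss] for i in range(2)})
        stack_rate, case_rate = aggregate_rates(results)
        assert stack_rate == pytest.approx(7 / 9)
        assert case_rate == pytest.approx(7 / 9)

    @given(hnp.arrays(np.uint8, (6, 6), elements=st.integers(0, 1)),
           hnp.arrays(np.uint8, (6, 6), elements=st.integers(0, 1)))
    def test_recall_equals_confusion_ratio(self, pred, truth):
        if truth.sum() == 0:
            return
        c = confusion(pred, truth)
        assert slice_lesion_recall(pred, truth) == pytest.approx(
            c.tp / (c.tp + c.fn))
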