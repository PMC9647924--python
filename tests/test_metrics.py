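"""Evaluation metrics: DSC/JI against pixel-counting oracles, rectangle IoU
against rasterization, detection/numbering ratios, and classifier stats."""

import numpy as np
import pytest

from dentalchart.extraction import ToothBox
from dentalchart.metrics import (ConfusionMatrix, DetectionEval, box_ji, dsc,
                                 evaluate_detection, ji, numbering_accuracy,
                                 position_accuracy, sensitivity_specificity)


def _random_mask(rng, shape=(24, 24), p=0.3):
    return rng.random(shape) < p


class TestMaskOverlap:
    def test_identical_and_disjoint(self):
        a = np.zeros((10, 10), bool)
        a[2:6, 2:6] = True
        b = np.zeros((10, 10), bool)
        b[7:9, 7:9] = True
        assert dsc(a, a) == 1.0 and ji(a, a) == 1.0
        assert dsc(a, b) == 0.0 and ji(a, b) == 0.0

    def test_hand_counted_overlap(self):
        a = np.zeros((4, 4), bool)
        b = np.zeros((4, 4), bool)
        a[0, 0:4] = True  # |A| = 4
        b[0, 2:4] = b[1, 0:2] = True  # |B| = 4, overlap 2, union 6
        assert dsc(a, b) == pytest.approx(0.5)
        assert ji(a, b) == pytest.approx(1 / 3)

    def test_both_empty_defined_as_one(self):
        empty = np.zeros((5, 5), bool)
        assert dsc(empty, empty) == 1.0 and ji(empty, empty) == 1.0

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            dsc(np.zeros((4, 4), bool), np.zeros((5, 5), bool))

    def test_matches_pixel_counting_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            a, b = _random_mask(rng), _random_mask(rng)
            inter = int((a & b).sum())
            assert dsc(a, b) == pytest.approx(
                1.0 if not (a.any() or b.any())
                else 2 * inter / (a.sum() + b.sum()))
            union = int((a | b).sum())
            assert ji(a, b) == pytest.approx(1.0 if union == 0 else inter / union)

    def test_dsc_ji_identity(self):
        """DSC = 2 JI / (1 + JI) for every mask pair."""
        rng = np.random.default_rng(1)
        for _ in range(200):
            a, b = _random_mask(rng), _random_mask(rng)
            j = ji(a, b)
            assert dsc(a, b) == pytest.approx(2 * j / (1 + j))


class TestBoxJI:
    def test_identical_and_disjoint(self):
        a = ToothBox(2, 2, 10, 10)
        assert box_ji(a, a) == 1.0
        assert box_ji(a, ToothBox(20, 20, 30, 30)) == 0.0

    def test_equals_rasterized_ji(self):
        """Closed-form rectangle IoU equals mask JI of the painted boxes."""
        rng = np.random.default_rng(2)
        for _ in range(200):
            x0, y0 = rng.integers(0, 20, 2)
            x1, y1 = x0 + rng.integers(1, 12), y0 + rng.integers(1, 12)
            u0, v0 = rng.integers(0, 20, 2)
            u1, v1 = u0 + rng.integers(1, 12), v0 + rng.integers(1, 12)
            grid = np.zeros((2, 40, 40), bool)
            grid[0, y0:y1, x0:x1] = True
            grid[1, v0:v1, u0:u1] = True
            assert box_ji((x0, y0, x1, y1), (u0, v0, u1, v1)) == \
                pytest.approx(ji(grid[0], grid[1]))


class TestEvaluateDetection:
    def _boxes(self, n, offset=0):
        return [ToothBox(20 * i + offset, 10, 20 * i + 15 + offset, 40)
                for i in range(n)]

    def test_perfect_agreement(self):
        gold = [(b, 10 + i) for i, b in enumerate(self._boxes(5))]
        ev = evaluate_detection(gold, gold)
        assert (ev.detection_precision, ev.detection_recall,
                ev.numbering_precision, ev.numbering_recall) == (1, 1, 1, 1)

    def test_hand_evaluated_ratios(self):
        """4 predictions, 5 gold, 2 successful, 2 correct numbers ->
        DP 0.5, DR 0.4, NP 0.5, NR 0.4."""
        gold_boxes = self._boxes(5)
        gold = [(b, 11 + i) for i, b in enumerate(gold_boxes)]
        pred = [
            (gold_boxes[0], 11),  # successful, correct number
            (gold_boxes[1], 12),  # successful, correct number
            (ToothBox(200, 200, 215, 230), 13),  # no gold overlap
            (ToothBox(300, 200, 315, 230), 14),  # no gold overlap
        ]
        ev = evaluate_detection(pred, gold)
        assert ev.n_successful == 2 and ev.n_true_number == 2
        assert ev.detection_precision == pytest.approx(0.5)
        assert ev.detection_recall == pytest.approx(0.4)
        assert ev.numbering_precision == pytest.approx(0.5)
        assert ev.numbering_recall == pytest.approx(0.4)

    def test_zero_predictions_precision_undefined(self):
        gold = [(b, 11) for b in self._boxes(3)]
        ev = evaluate_detection([], gold)
        assert ev.detection_precision is None
        assert ev.detection_recall == 0.0

    def test_threshold_is_strict(self):
        a = ToothBox(0, 0, 10, 10)
        b = ToothBox(0, 0, 10, 7)  # JI exactly 0.7
        assert box_ji(a, b) == pytest.approx(0.7)
        ev = evaluate_detection([(a, 11)], [(b, 11)])
        assert ev.n_successful == 0

    def test_greedy_one_to_one(self):
        # one prediction overlapping two golds is matched once
        gold = [(ToothBox(0, 0, 10, 10), 11), (ToothBox(1, 0, 11, 10), 12)]
        pred = [(ToothBox(0, 0, 10, 10), 11)]
        ev = evaluate_detection(pred, gold)
        assert ev.n_successful == 1 and ev.n_true_number == 1

    def test_invariants_on_random_inputs(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            def mk(n):
                out = []
                for _ in range(n):
                    x0, y0 = rng.integers(0, 30, 2)
                    out.append((ToothBox(x0, y0, x0 + rng.integers(2, 12),
                                         y0 + rng.integers(2, 12)),
                                int(rng.integers(11, 19))))
                return out
            ev = evaluate_detection(mk(rng.integers(0, 6)),
                                    mk(rng.integers(0, 6)))
            assert ev.n_successful <= min(ev.n_detected, ev.n_gold)
            assert ev.n_true_number <= ev.n_successful
            for v in (ev.detection_precision, ev.detection_recall,
                      ev.numbering_precision, ev.numbering_recall):
                assert v is None or 0.0 <= v <= 1.0


class TestAccuracies:
    def test_numbering_accuracy(self):
        assert numbering_accuracy([(11, 11), (12, 12)]) == 1.0
        assert numbering_accuracy([(11, 12), (12, 11)]) == 0.0
        assert numbering_accuracy([(11, 11), (12, 12), (13, 13), (14, 11)]) == 0.75
        with pytest.raises(ValueError):
            numbering_accuracy([])

    def test_position_accuracy(self):
        recs = [("maxilla", "maxilla"), ("mandible", "bitewing")]
        assert position_accuracy(recs) == 0.5
        assert position_accuracy([("maxilla", "maxilla")]) == 1.0
        with pytest.raises(ValueError):
            position_accuracy([])


class TestSensitivitySpecificity:
    def test_diagonal_matrix_perfect(self):
        cm = ConfusionMatrix(counts=np.diag([5, 7, 9]), classes=(1, 2, 3))
        for c in (1, 2, 3):
            assert sensitivity_specificity(cm, c) == (1.0, 1.0)

    def test_two_class_example(self):
        cm = ConfusionMatrix(counts=[[8, 2], [1, 9]], classes=(1, 2))
        sens, spec = sensitivity_specificity(cm, 1)
        assert sens == pytest.approx(0.8)
        assert spec == pytest.approx(0.9)

    def test_zero_support_undefined(self):
        cm = ConfusionMatrix(counts=[[0, 0], [1, 9]], classes=(1, 2))
        sens, _ = sensitivity_specificity(cm, 1)
        assert sens is None

    def test_unknown_class(self):
        cm = ConfusionMatrix(counts=[[1, 0], [0, 1]], classes=(1, 2))
        with pytest.raises(ValueError):
            sensitivity_specificity(cm, 3)

    def test_from_records_and_validation(self):
        cm = ConfusionMatrix.from_records([(1, 1), (1, 2), (2, 2)])
        assert cm.counts.tolist() == [[1, 1], [0, 1]]
        with pytest.raises(ValueError):
            ConfusionMatrix(counts=[[1, -1], [0, 1]])
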