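import itertools

import numpy as np
import pandas as pd
import pytest

from camuquant import (
    StageLabel,
    detection_pr,
    mape,
    stage_confusion,
    stagewise_report,
    system_vs_laboratory_table,
)
from camuquant.evaluation import box_iou, round_half_up


class TestMape:
    def test_identical_vectors_give_zero(self):
        y = np.array([1.0, 250.0, 1e4])
        assert mape(y, y) == 0.0

    @pytest.mark.parametrize(
        "lab,system,printed,decimals",
        [
            (1790.37, 1576.42, 11.95, 2),
            (2033.32, 2110.55, 3.8, 1),
            (2187.50, 2309.21, 5.56, 2),
        ],
    )
    def test_reference_stage_pairs_round_to_printed_values(
        self, lab, system, printed, decimals
    ):
        value = mape(np.array([lab]), np.array([system]))
        assert round_half_up(value, decimals) == printed

    def test_hand_arithmetic_two_pairs(self):
        assert mape(np.array([100.0, 100.0]), np.array([110.0, 90.0])) == pytest.approx(10.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(12)
        y = rng.uniform(10, 100, size=8)
        y_hat = y * rng.uniform(0.8, 1.2, size=8)
        for k in rng.uniform(0.01, 50, size=5):
            assert mape(k * y, k * y_hat) == pytest.approx(mape(y, y_hat), rel=1e-9)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            mape(np.array([0.0, 1.0]), np.array([1.0, 1.0]))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            mape(np.array([]), np.array([]))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="same length"):
            mape(np.array([1.0]), np.array([1.0, 2.0]))


class TestStagewiseReport:
    def test_shipped_table_reproduces_reference_errors(self):
        result = stagewise_report(system_vs_laboratory_table())
        rounded = {
            StageLabel.PINTON_GREEN: round_half_up(
                result.per_stage_mape[StageLabel.PINTON_GREEN], 2
            ),
            StageLabel.RIPE_PINTON: round_half_up(
                result.per_stage_mape[StageLabel.RIPE_PINTON], 1
            ),
            StageLabel.RIPE: round_half_up(result.per_stage_mape[StageLabel.RIPE], 2),
        }
        assert rounded == {
            StageLabel.PINTON_GREEN: 11.95,
            StageLabel.RIPE_PINTON: 3.8,
            StageLabel.RIPE: 5.56,
        }
        assert round_half_up(result.mean_mape, 1) == 7.1

    def test_single_stage_mean_equals_that_stage(self):
        table = pd.DataFrame(
            {
                "stage": ["Ripe"],
                "laboratory_mg_per_100g": [2000.0],
                "system_mg_per_100g": [1900.0],
            }
        )
        result = stagewise_report(table)
        assert result.mean_mape == pytest.approx(result.per_stage_mape[StageLabel.RIPE])
        assert result.mean_mape == pytest.approx(5.0)

    def test_replicate_pairs_within_a_stage(self):
        table = pd.DataFrame(
            {
                "stage": ["Ripe", "Ripe"],
                "laboratory_mg_per_100g": [100.0, 100.0],
                "system_mg_per_100g": [110.0, 90.0],
            }
        )
        assert stagewise_report(table).per_stage_mape[StageLabel.RIPE] == pytest.approx(10.0)

    def test_green_dropped_silently_by_default(self):
        table = pd.DataFrame(
            {
                "stage": ["Green", "Ripe"],
                "laboratory_mg_per_100g": [1539.40, 2187.50],
                "system_mg_per_100g": [1000.0, 2187.50],
            }
        )
        result = stagewise_report(table)
        assert StageLabel.GREEN not in result.per_stage_mape
        assert result.mean_mape == 0.0

    def test_green_inclusion_warns(self):
        table = pd.DataFrame(
            {
                "stage": ["Green"],
                "laboratory_mg_per_100g": [1539.40],
                "system_mg_per_100g": [1539.40],
            }
        )
        with pytest.warns(UserWarning, match="Green"):
            result = stagewise_report(table, include_green=True)
        assert result.per_stage_mape[StageLabel.GREEN] == 0.0

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="columns"):
            stagewise_report(pd.DataFrame({"stage": ["Ripe"]}))


def optimal_assignment_pr(gt_boxes, pred_boxes, iou_threshold):
    """Exhaustive oracle: the one-to-one assignment maximizing true positives."""
    n_gt, n_pred = len(gt_boxes), len(pred_boxes)
    if not gt_boxes and not pred_boxes:
        return 1.0, 1.0, 1.0
    feasible = {
        (i, j)
        for i in range(n_pred)
        for j in range(n_gt)
        if box_iou(pred_boxes[i], gt_boxes[j]) >= iou_threshold
    }
    best_tp = 0
    for k in range(min(n_gt, n_pred), 0, -1):
        for preds in itertools.combinations(range(n_pred), k):
            for gts in itertools.permutations(range(n_gt), k):
                if all((i, j) in feasible for i, j in zip(preds, gts)):
                    best_tp = k
                    break
            if best_tp:
                break
        if best_tp:
            break
    precision = best_tp / n_pred if n_pred else 0.0
    recall = best_tp / n_gt if n_gt else 1.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if (precision + recall)
        else 0.0
    )
    return precision, recall, f1


def sample_detection_instance(rng):
    """Random non-overlapping ground truth plus jittered/spurious predictions."""
    n_gt = int(rng.integers(0, 5))
    gt = []
    tries = 0
    while len(gt) < n_gt and tries < 200:
        tries += 1
        box = (rng.uniform(0, 80), rng.uniform(0, 80), rng.uniform(8, 20), rng.uniform(8, 20))
        if all(box_iou(box, g) == 0.0 for g in gt):
            gt.append(box)
    pred, scores = [], []
    for g in gt:
        if rng.random() < 0.85:  # detected, with localization jitter
            dx, dy = rng.uniform(-3, 3, size=2)
            sw, sh = rng.uniform(0.8, 1.2, size=2)
            pred.append((g[0] + dx, g[1] + dy, g[2] * sw, g[3] * sh))
            scores.append(float(rng.uniform(0.5, 1.0)))
    for _ in range(int(rng.integers(0, 3))):  # spurious boxes
        pred.append(
            (rng.uniform(0, 80), rng.uniform(0, 80), rng.uniform(5, 15), rng.uniform(5, 15))
        )
        scores.append(float(rng.uniform(0.1, 0.6)))
    return gt, pred, scores


class TestDetectionPr:
    def test_perfect_predictions(self):
        boxes = [(0, 0, 10, 10), (20, 20, 5, 8)]
        assert detection_pr(boxes, list(boxes)) == (1.0, 1.0, 1.0)

    def test_no_predictions_gives_zero_recall(self):
        gt = [(0, 0, 10, 10)] * 1 + [(30, 0, 10, 10), (0, 30, 10, 10), (30, 30, 10, 10), (60, 0, 10, 10)]
        p, r, f1 = detection_pr(gt, [])
        assert (p, r, f1) == (0.0, 0.0, 0.0)

    def test_one_hit_of_two_targets(self):
        gt = [(0, 0, 10, 10), (50, 50, 10, 10)]
        p, r, f1 = detection_pr(gt, [(0, 0, 10, 10)])
        assert (p, r) == (1.0, 0.5)
        assert f1 == pytest.approx(2 / 3)

    def test_both_empty_is_vacuously_perfect(self):
        assert detection_pr([], []) == (1.0, 1.0, 1.0)

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError, match="iou_threshold"):
            detection_pr([], [], iou_threshold=1.5)

    def test_malformed_box_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            detection_pr([(0, 0, 0, 10)], [(0, 0, 5, 5)])

    def test_matches_exhaustive_oracle_on_small_instances(self):
        rng = np.random.default_rng(2024)
        for _ in range(100):
            gt, pred, scores = sample_detection_instance(rng)
            assert detection_pr(gt, pred, scores) == pytest.approx(
                optimal_assignment_pr(gt, pred, 0.5)
            )


class TestStageConfusion:
    def test_identical_lists_are_diagonal(self):
        labels = [StageLabel.GREEN, StageLabel.RIPE, StageLabel.RIPE_PINTON]
        cm, metrics = stage_confusion(labels, labels)
        assert np.trace(cm) == 3
        assert metrics["accuracy"] == 1.0

    def test_all_wrong_gives_zero_accuracy(self):
        cm, metrics = stage_confusion(
            [StageLabel.GREEN, StageLabel.RIPE],
            [StageLabel.RIPE, StageLabel.GREEN],
        )
        assert metrics["accuracy"] == 0.0
        assert np.trace(cm) == 0

    def test_three_of_four_correct(self):
        g, r = StageLabel.GREEN, StageLabel.RIPE
        cm, metrics = stage_confusion([g, g, r, r], [g, r, r, r])
        assert metrics["accuracy"] == pytest.approx(0.75)
        assert cm[0, 0] == 1 and cm[0, 3] == 1 and cm[3, 3] == 2

    def test_row_sums_are_truth_counts(self):
        rng = np.random.default_rng(5)
        stages = sorted(StageLabel, key=lambda s: s.ordinal)
        gt = [stages[i] for i in rng.integers(0, 4, size=40)]
        pred = [stages[i] for i in rng.integers(0, 4, size=40)]
        cm, _ = stage_confusion(gt, pred)
        for i, stage in enumerate(stages):
            assert cm[i].sum() == sum(s is stage for s in gt)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="align"):
            stage_confusion([StageLabel.RIPE], [])


class TestRounding:
    @pytest.mark.parametrize(
        "value,ndigits,expected",
        [(3.7982, 1, 3.8), (11.9500438, 2, 11.95), (7.104, 1, 7.1), (2.5, 0, 3.0), (0.125, 2, 0.13)],
    )
    def test_half_up_matches_printed_tables(self, value, ndigits, expected):
        assert round_half_up(value, ndigits) == expected
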