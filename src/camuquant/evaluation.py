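"""Error analysis and detection/staging metrics.

The headline accuracy metric is the mean absolute percentage error between
laboratory (DCPIP) and system ascorbate concentrations,

    MAPE = (1/n) * sum_i |y_i - yhat_i| / y_i * 100,

computed per ripeness stage and averaged (unweighted) over the commercial
stages; green fruits are not commercialized and are excluded by default.
Detection quality is summarized by precision/recall/F1 under greedy
one-to-one IoU matching, staging quality by a 4x4 confusion matrix with
macro-averaged metrics.
"""

from __future__ import annotations

import decimal
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support

from .calibration import StageLabel

__all__ = [
    "mape",
    "round_half_up",
    "stagewise_report",
    "detection_pr",
    "stage_confusion",
    "system_vs_laboratory_table",
    "EvalResult",
]


def mape(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Mean absolute percentage error, in percent.

    ``y`` holds the laboratory reference values, ``y_hat`` the system
    estimates.  Every reference value must be nonzero.
    """
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.size == 0:
        raise ValueError("MAPE needs at least one pair")
    if y.shape != y_hat.shape:
        raise ValueError("y and y_hat must have the same length")
    if np.any(y == 0):
        raise ValueError("MAPE is undefined when a reference value is zero")
    return float(np.mean(np.abs((y - y_hat) / y)) * 100.0)


def round_half_up(x: float, ndigits: int) -> float:
    """Round with ties away from zero, matching hand-rounded printed tables."""
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_UP))


@lru_cache(maxsize=1)
def system_vs_laboratory_table() -> pd.DataFrame:
    """The shipped per-stage system vs laboratory concentration pairs (mg/100 g)."""
    with resources.files("camuquant.data").joinpath(
        "system_vs_laboratory.csv"
    ).open() as fh:
        return pd.read_csv(fh)


@dataclass
class EvalResult:
    """Evaluation summary; unused sections stay None."""

    per_stage_mape: dict[StageLabel, float] | None = None
    mean_mape: float | None = None
    detection: dict[str, float] | None = None  # precision / recall / f1 / iou_threshold
    confusion: np.ndarray | None = None  # 4x4, rows = truth in ordinal order
    staging: dict[str, float] | None = None  # accuracy + macro P/R/F1
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        out: dict = {}
        if self.per_stage_mape is not None:
            out["per_stage_mape_percent"] = {
                s.value: v for s, v in self.per_stage_mape.items()
            }
        if self.mean_mape is not None:
            out["mean_mape_percent"] = self.mean_mape
        if self.detection is not None:
            out["detection"] = self.detection
        if self.confusion is not None:
            out["confusion_matrix"] = self.confusion.tolist()
            out["confusion_stage_order"] = [
                s.value for s in sorted(StageLabel, key=lambda s: s.ordinal)
            ]
        if self.staging is not None:
            out["staging"] = self.staging
        if self.notes:
            out["notes"] = list(self.notes)
        return out


def stagewise_report(
    pairs: pd.DataFrame, include_green: bool = False
) -> EvalResult:
    """Per-stage MAPE and the unweighted mean across included stages.

    ``pairs`` needs columns ``stage``, ``laboratory_mg_per_100g`` and
    ``system_mg_per_100g``; a stage may contribute any number of pairs.
    Green rows are dropped unless ``include_green`` is set (with a warning,
    since green fruit is not commercialized).
    """
    required = {"stage", "laboratory_mg_per_100g", "system_mg_per_100g"}
    if not required <= set(pairs.columns):
        raise ValueError(f"pairs table needs columns {sorted(required)}")
    df = pairs.copy()
    df["stage"] = df["stage"].map(lambda s: StageLabel.from_name(str(s)))
    has_green = (df["stage"] == StageLabel.GREEN).any()
    if has_green:
        if include_green:
            warnings.warn(
                "including Green fruits in the error analysis; they are "
                "normally excluded (non-commercial stage)",
                stacklevel=2,
            )
        else:
            df = df[df["stage"] != StageLabel.GREEN]
    if df.empty:
        raise ValueError("no stage pairs left to evaluate")
    per_stage: dict[StageLabel, float] = {}
    for stage in sorted(df["stage"].unique(), key=lambda s: s.ordinal):
        sub = df[df["stage"] == stage]
        per_stage[stage] = mape(
            sub["laboratory_mg_per_100g"].to_numpy(),
            sub["system_mg_per_100g"].to_numpy(),
        )
    mean = float(np.mean(list(per_stage.values())))
    return EvalResult(per_stage_mape=per_stage, mean_mape=mean)


# ---------------------------------------------------------------------------
# Detection metrics


def box_iou(a, b) -> float:
    """IoU of two (x, y, w, h) boxes (half-open pixel intervals)."""
    ax, ay, aw, ah = a
    bx, by, bw, bh = b
    if min(aw, ah, bw, bh) <= 0:
        raise ValueError("boxes must have positive width and height")
    ix = max(0.0, min(ax + aw, bx + bw) - max(ax, bx))
    iy = max(0.0, min(ay + ah, by + bh) - max(ay, by))
    inter = ix * iy
    union = aw * ah + bw * bh - inter
    return inter / union


def detection_pr(
    gt_boxes: list,
    pred_boxes: list,
    scores: list[float] | None = None,
    iou_threshold: float = 0.5,
) -> tuple[float, float, float]:
    """Precision, recall and F1 of predicted boxes against ground truth.

    Predictions are matched one-to-one to ground truth greedily: in order
    of descending confidence, each prediction takes the unmatched ground
    truth box of highest IoU, provided it reaches ``iou_threshold``.
    Conventions at the edges: with no predictions and nonempty ground
    truth, precision is 0; with both lists empty all three metrics are 1
    (nothing to find, nothing found).
    """
    if not 0.0 < iou_threshold < 1.0:
        raise ValueError("iou_threshold must lie in (0, 1)")
    if scores is None:
        scores = [1.0] * len(pred_boxes)
    if len(scores) != len(pred_boxes):
        raise ValueError("one score per predicted box required")
    if not gt_boxes and not pred_boxes:
        return 1.0, 1.0, 1.0
    order = sorted(range(len(pred_boxes)), key=lambda i: -scores[i])
    matched_gt: set[int] = set()
    tp = 0
    for i in order:
        best_j, best_iou = None, 0.0
        for j, g in enumerate(gt_boxes):
            if j in matched_gt:
                continue
            iou = box_iou(pred_boxes[i], g)
            if iou >= iou_threshold and iou > best_iou:
                best_j, best_iou = j, iou
        if best_j is not None:
            matched_gt.add(best_j)
            tp += 1
    fp = len(pred_boxes) - tp
    fn = len(gt_boxes) - tp
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    recall = tp / (tp + fn) if (tp + fn) else 1.0
    f1 = 2 * precision * recall / (precision + recall) if (precision + recall) else 0.0
    return precision, recall, f1


def stage_confusion(
    gt_stages: list[StageLabel], pred_stages: list[StageLabel]
) -> tuple[np.ndarray, dict[str, float]]:
    """4x4 stage confusion matrix (rows = truth, ordinal order) + macro metrics."""
    if len(gt_stages) != len(pred_stages):
        raise ValueError("gt and predicted label lists must align")
    order = [s.ordinal for s in sorted(StageLabel, key=lambda s: s.ordinal)]
    y_true = [s.ordinal for s in gt_stages]
    y_pred = [s.ordinal for s in pred_stages]
    cm = confusion_matrix(y_true, y_pred, labels=order)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # absent classes yield 0-division warnings
        p, r, f1, _ = precision_recall_fscore_support(
            y_true, y_pred, labels=order, average="macro", zero_division=0
        )
    acc = float(np.trace(cm) / cm.sum()) if cm.sum() else 1.0
    return cm, {
        "accuracy": acc,
        "macro_precision": float(p),
        "macro_recall": float(r),
        "macro_f1": float(f1),
    }
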