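"""Counting and detection metrics.

Counting accuracy is the absolute-error formula
``(1 - |N_gt - N_measured| / N_gt) * 100`` — symmetric in over- and
under-counting and possibly negative for gross errors. Detection quality is
scored Pascal-VOC style: predictions are matched greedily in descending
confidence order against at most one ground-truth box each at a fixed IoU
threshold (0.5 by convention), yielding TP/FP/FN tallies and all-point
interpolated average precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np

from .geometry import Box, iou

__all__ = [
    "CountEvaluation",
    "DetectionMatch",
    "counting_accuracy",
    "evaluate_count",
    "match_detections",
    "average_precision",
    "aggregate_accuracy",
]


@dataclass(frozen=True)
class CountEvaluation:
    num_gt: int
    num_measured: int
    accuracy: float  # percent


@dataclass
class DetectionMatch:
    """TP/FP/FN tallies for one frame at a stated IoU threshold.

    Invariants: tp + fn == number of ground-truth boxes, and
    tp + fp == number of predictions.
    """

    tp: int = 0
    fp: int = 0
    fn: int = 0
    iou_threshold: float = 0.5
    # (prediction index, ground-truth index) for each TP
    pairs: List[Tuple[int, int]] = field(default_factory=list)
    # confidence-descending prediction order with TP/FP flag, for AP pooling
    flags: List[Tuple[float, bool]] = field(default_factory=list)


def counting_accuracy(num_gt: int, num_measured: int) -> float:
    """Percent counting accuracy from the absolute count error.

    Equals 100 iff the counts agree; symmetric under over- vs. under-count
    of the same magnitude; negative when the error exceeds the truth.

    Raises
    ------
    ValueError
        If ``num_gt`` is not at least 1 (the metric is undefined).
    """
    if num_gt < 1:
        raise ValueError("counting accuracy is undefined for num_gt < 1")
    return (1.0 - abs(num_gt - num_measured) / num_gt) * 100.0


def evaluate_count(num_gt: int, num_measured: int) -> CountEvaluation:
    return CountEvaluation(
        num_gt=num_gt,
        num_measured=num_measured,
        accuracy=counting_accuracy(num_gt, num_measured),
    )


def match_detections(
    gt: Sequence[Box],
    pred: Sequence[Tuple[Box, float]],
    iou_threshold: float = 0.5,
) -> DetectionMatch:
    """Match predictions to ground truth within one frame.

    Predictions are visited in descending confidence (ties by input order);
    each claims the free ground-truth box of highest IoU if that IoU reaches
    the threshold (TP), otherwise it is an FP. Ground-truth boxes left
    unclaimed are FNs — so a plant detected as two fragments scores one TP
    plus one FP.
    """
    if not 0.0 < iou_threshold <= 1.0:
        raise ValueError("iou_threshold must lie in (0, 1]")

    order = sorted(range(len(pred)), key=lambda i: (-pred[i][1], i))
    taken = [False] * len(gt)
    result = DetectionMatch(iou_threshold=iou_threshold)

    for pi in order:
        box, conf = pred[pi]
        best_iou, best_gi = 0.0, -1
        for gi, gbox in enumerate(gt):
            if taken[gi]:
                continue
            overlap = iou(box, gbox)
            if overlap > best_iou:
                best_iou, best_gi = overlap, gi
        if best_gi >= 0 and best_iou >= iou_threshold:
            taken[best_gi] = True
            result.tp += 1
            result.pairs.append((pi, best_gi))
            result.flags.append((conf, True))
        else:
            result.fp += 1
            result.flags.append((conf, False))
    result.fn = len(gt) - result.tp
    return result


def average_precision(
    gt_frames: Sequence[Sequence[Box]],
    pred_frames: Sequence[Sequence[Tuple[Box, float]]],
    iou_threshold: float = 0.5,
) -> float:
    """All-point interpolated average precision over a frame sequence, in %.

    Predictions from every frame are pooled, sorted by confidence, and
    scored against the per-frame greedy matching; AP is the area under the
    precision envelope as a function of recall.

    Raises
    ------
    ValueError
        If there are no ground-truth boxes at all (recall undefined).
    """
    if len(gt_frames) != len(pred_frames):
        raise ValueError("ground-truth and prediction streams differ in length")
    n_gt = sum(len(g) for g in gt_frames)
    if n_gt == 0:
        raise ValueError("average precision is undefined with no ground truth")

    flags: List[Tuple[float, bool]] = []
    for gt, pred in zip(gt_frames, pred_frames):
        flags.extend(match_detections(gt, pred, iou_threshold).flags)
    if not flags:
        return 0.0

    flags.sort(key=lambda cf: -cf[0])
    tp_flags = np.array([is_tp for _, is_tp in flags], dtype=float)
    tp_cum = np.cumsum(tp_flags)
    fp_cum = np.cumsum(1.0 - tp_flags)
    recall = tp_cum / n_gt
    precision = tp_cum / (tp_cum + fp_cum)

    # precision envelope, then sum over recall increments
    recall = np.concatenate(([0.0], recall, [recall[-1]]))
    precision = np.concatenate(([1.0], precision, [0.0]))
    for i in range(len(precision) - 2, -1, -1):
        precision[i] = max(precision[i], precision[i + 1])
    ap = float(np.sum(np.diff(recall) * precision[1:]))
    return 100.0 * ap


def aggregate_accuracy(accuracies: Sequence[float]) -> Tuple[float, float]:
    """Mean and standard deviation of per-row counting accuracies."""
    arr = np.asarray(accuracies, dtype=float)
    if arr.size == 0:
        raise ValueError("no accuracies to aggregate")
    return float(arr.mean()), float(arr.std(ddof=1)) if arr.size > 1 else 0.0
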