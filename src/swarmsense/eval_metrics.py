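"""Confusion matrices and derived detection/classification measures.

The detector is scored as a binary problem (fish present / detected) and
the swarm-pattern classifier as a 4-class problem.  All measures are kept
as exact floating ratios internally; percentage formatting is a display
concern (:func:`format_percent`).

A note on published figures: a 4-class confusion matrix whose cells sum
to ``N`` with diagonal ``D`` has accuracy ``D/N`` by definition
(trace over total).  When a report prints an accuracy that is not
derivable from its own printed matrix, this module's functions return
the derivable value; see :func:`multiclass_accuracy`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion_matrix

__all__ = [
    "BinaryConfusion",
    "MeasureSet",
    "binary_measures",
    "multiclass_accuracy",
    "confusion_from_labels",
    "format_percent",
    "DetectionScore",
    "score_detections",
]


@dataclass(frozen=True)
class BinaryConfusion:
    """2x2 tally: rows = actual (present yes/no), columns = detected yes/no."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "fp", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be a nonnegative count")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def positives(self) -> int:
        """Actual positives P = TP + FN."""
        return self.tp + self.fn

    @property
    def negatives(self) -> int:
        """Actual negatives N = FP + TN."""
        return self.fp + self.tn


@dataclass(frozen=True)
class MeasureSet:
    """Accuracy, sensitivity, specificity, precision as proportions.

    A ratio with a zero denominator is *undefined* and reported as
    ``None`` — deliberately distinct from 0.0, which would conflate
    "no positives existed" with "the classifier found none".
    """

    accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    precision: float | None


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def binary_measures(cm: BinaryConfusion) -> MeasureSet:
    """Standard confusion-matrix measures.

    ACC = (TP+TN)/(P+N), TPR = TP/(TP+FN), SPC = TN/(FP+TN),
    PPV = TP/(TP+FP).
    """
    if cm.n == 0:
        raise ValueError("confusion matrix is all zero; measures undefined")
    return MeasureSet(
        accuracy=_ratio(cm.tp + cm.tn, cm.n),
        sensitivity=_ratio(cm.tp, cm.tp + cm.fn),
        specificity=_ratio(cm.tn, cm.fp + cm.tn),
        precision=_ratio(cm.tp, cm.tp + cm.fp),
    )


def multiclass_accuracy(cm: np.ndarray) -> float:
    """Trace over total of a KxK count matrix (rows = actual).

    This is the only accuracy derivable from the matrix itself.
    """
    cm = np.asarray(cm)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1] or cm.size == 0:
        raise ValueError("confusion matrix must be a nonempty square matrix")
    if (cm < 0).any():
        raise ValueError("confusion matrix entries must be nonnegative")
    total = cm.sum()
    if total == 0:
        raise ValueError("confusion matrix is all zero; accuracy undefined")
    return float(np.trace(cm) / total)


def confusion_from_labels(truth, predicted, labels=None):
    """Tally a confusion matrix from paired label lists.

    Parameters
    ----------
    truth, predicted : sequences of equal length
        Actual and classified labels.
    labels : sequence, optional
        The declared label set, fixing row/column order.  With exactly
        two labels the result is a :class:`BinaryConfusion` (the first
        label is the positive class); otherwise a KxK numpy count matrix
        with rows = actual, columns = classified.
    """
    truth = list(truth)
    predicted = list(predicted)
    if len(truth) != len(predicted):
        raise ValueError(
            f"label lists differ in length: {len(truth)} vs {len(predicted)}"
        )
    if labels is None:
        labels = sorted(set(truth) | set(predicted))
    labels = list(labels)
    unknown = (set(truth) | set(predicted)) - set(labels)
    if unknown:
        raise ValueError(f"labels outside the declared set: {sorted(unknown)!r}")
    mat = _sk_confusion_matrix(truth, predicted, labels=labels)
    if len(labels) == 2:
        # positive class first: rows/cols ordered [pos, neg]
        return BinaryConfusion(
            tp=int(mat[0, 0]), fn=int(mat[0, 1]),
            fp=int(mat[1, 0]), tn=int(mat[1, 1]),
        )
    return mat


@dataclass(frozen=True)
class DetectionScore:
    """Detector accuracy against ground truth over a frame range."""

    recall: float
    precision: float
    mean_centroid_error: float  # px, over matched pairs
    n_truth: int
    n_detected: int
    n_matched: int


def score_detections(truth, detected, gate: float = 10.0) -> DetectionScore:
    """Match detections to ground truth frame by frame and score them.

    Frames are aligned by ``frame_index``; within a frame, detections
    and true fish are paired by minimum-cost assignment on centroid
    distance, and pairs farther apart than ``gate`` pixels are rejected.
    Recall = matched/truth, precision = matched/detected.
    """
    from scipy.optimize import linear_sum_assignment

    det_by_frame = {d.frame_index: d for d in detected}
    n_truth = n_det = n_matched = 0
    errors: list[float] = []
    for truth_set in truth:
        det_set = det_by_frame.get(truth_set.frame_index)
        if det_set is None:
            n_truth += len(truth_set)
            continue
        t_xy = truth_set.centroids()
        d_xy = det_set.centroids()
        n_truth += len(t_xy)
        n_det += len(d_xy)
        if len(t_xy) == 0 or len(d_xy) == 0:
            continue
        cost = np.hypot(
            t_xy[:, None, 0] - d_xy[None, :, 0],
            t_xy[:, None, 1] - d_xy[None, :, 1],
        )
        rows, cols = linear_sum_assignment(cost)
        for i, j in zip(rows, cols):
            if cost[i, j] <= gate:
                n_matched += 1
                errors.append(float(cost[i, j]))
    return DetectionScore(
        recall=n_matched / n_truth if n_truth else float("nan"),
        precision=n_matched / n_det if n_det else float("nan"),
        mean_centroid_error=float(np.mean(errors)) if errors else float("nan"),
        n_truth=n_truth,
        n_detected=n_det,
        n_matched=n_matched,
    )


def format_percent(value: float | None, decimals: int = 2) -> str:
    """Render a proportion as a percentage string, round-half-even.

    ``None`` (undefined ratio) renders as ``"undefined"``.
    """
    if value is None:
        return "undefined"
    quantized = np.round(value * 100.0, decimals)
    return f"{quantized:.{decimals}f}%"
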