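"""Detection and counting evaluation.

Implements the standard detection metrics — IoU, greedy one-to-one
matching at an IoU threshold, precision, recall, F1, per-class average
precision (area under the precision–recall staircase) and mAP — plus
replicate count summaries (mean ± standard error).

Zero-denominator conventions: precision, recall and F1 are defined as 0
when their denominators vanish; AP of a class with no ground truth is 0
when predictions exist (all are false positives) and vacuously 1 when
there are none.  All such cases are logged — well-posed evaluations
never hit them.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from phenoseed.types import BoundingBox, Detection, GroundTruth, InvalidInputError

logger = logging.getLogger(__name__)


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection over union of two boxes; 0 when disjoint.

    With half-open boxes the continuous area equals the pixel count for
    integer coordinates, so this agrees with pixel-level overlap.
    """
    ix = min(a.x_max, b.x_max) - max(a.x_min, b.x_min)
    iy = min(a.y_max, b.y_max) - max(a.y_min, b.y_min)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    return inter / (a.area + b.area - inter)


@dataclass
class MatchResult:
    """Outcome of matching predictions to ground truth on one image."""

    tp: int
    fp: int
    fn: int
    assignments: list[tuple[int, int, float]] = field(default_factory=list)
    #: per-prediction TP flags in descending-confidence order, with the
    #: confidence — the ranked input to average precision
    ranked: list[tuple[float, bool]] = field(default_factory=list)


def match_detections(
    preds: list[Detection],
    gt: GroundTruth,
    iou_thresh: float = 0.5,
    class_agnostic: bool = False,
) -> MatchResult:
    """Greedy one-to-one matching of predictions to ground-truth boxes.

    Predictions are processed in descending confidence; each one matches
    the not-yet-matched same-class ground-truth box of highest IoU, and
    counts as a true positive if that IoU reaches ``iou_thresh``, else
    as a false positive.  Ground-truth boxes left unmatched are false
    negatives.
    """
    order = sorted(range(len(preds)), key=lambda i: (-preds[i].confidence, i))
    matched_gt: set[int] = set()
    assignments: list[tuple[int, int, float]] = []
    ranked: list[tuple[float, bool]] = []
    for i in order:
        p = preds[i]
        best_j, best_iou = -1, 0.0
        for j, (box, class_id) in enumerate(gt.boxes):
            if j in matched_gt:
                continue
            if not class_agnostic and class_id != p.class_id:
                continue
            v = iou(p.bbox, box)
            if v > best_iou:
                best_j, best_iou = j, v
        is_tp = best_j >= 0 and best_iou >= iou_thresh
        if is_tp:
            matched_gt.add(best_j)
            assignments.append((i, best_j, best_iou))
        ranked.append((p.confidence, is_tp))
    tp = len(matched_gt)
    return MatchResult(
        tp=tp, fp=len(preds) - tp, fn=len(gt.boxes) - tp,
        assignments=assignments, ranked=ranked,
    )


def _check_counts(*counts: int) -> None:
    if any(c < 0 for c in counts):
        raise InvalidInputError("TP/FP/FN counts must be non-negative")


def precision(tp: int, fp: int) -> float:
    """TP / (TP + FP); 0 when no positives were predicted."""
    _check_counts(tp, fp)
    if tp + fp == 0:
        logger.info("precision undefined (no predictions); reporting 0")
        return 0.0
    return tp / (tp + fp)


def recall(tp: int, fn: int) -> float:
    """TP / (TP + FN); 0 when there are no actual positives."""
    _check_counts(tp, fn)
    if tp + fn == 0:
        logger.info("recall undefined (no ground truth); reporting 0")
        return 0.0
    return tp / (tp + fn)


def f1_score(p: float, r: float) -> float:
    """Harmonic mean of precision and recall; 0 when both vanish."""
    if not (0.0 <= p <= 1.0 and 0.0 <= r <= 1.0):
        raise InvalidInputError("precision and recall must lie in [0, 1]")
    if p + r == 0.0:
        return 0.0
    return 2.0 * p * r / (p + r)


def average_precision(
    ranked: list[tuple[float, bool]],
    n_gt: int,
    interpolation: str = "all_point",
) -> float:
    """Area under the precision–recall staircase for one class.

    ``ranked`` holds (confidence, is_true_positive) per prediction in
    descending confidence order; ``n_gt`` is the number of ground-truth
    boxes of the class.  The precision curve is first made monotonically
    non-increasing from the right (the upper envelope), then integrated
    over recall — exactly for ``"all_point"`` interpolation, or sampled
    at recalls {0, 0.1, …, 1} for the legacy ``"eleven_point"`` variant.
    """
    if n_gt < 0:
        raise InvalidInputError("n_gt must be non-negative")
    if interpolation not in ("all_point", "eleven_point"):
        raise InvalidInputError(f"unknown interpolation {interpolation!r}")
    if n_gt == 0:
        if ranked:
            logger.info("AP of class with no ground truth but predictions: 0")
            return 0.0
        logger.info("AP of empty class (no ground truth, no predictions): vacuous 1")
        return 1.0
    if not ranked:
        return 0.0
    confs = [c for c, _ in ranked]
    if any(confs[i] < confs[i + 1] for i in range(len(confs) - 1)):
        raise InvalidInputError("ranked predictions must be in descending confidence")

    tps = np.cumsum([1 if is_tp else 0 for _, is_tp in ranked])
    fps = np.cumsum([0 if is_tp else 1 for _, is_tp in ranked])
    rec = tps / n_gt
    prec = tps / (tps + fps)

    # upper envelope: precision at recall r is the max precision at any rank
    # with recall >= r
    env = np.maximum.accumulate(prec[::-1])[::-1]

    if interpolation == "eleven_point":
        total = 0.0
        for r_level in np.linspace(0.0, 1.0, 11):
            above = env[rec >= r_level - 1e-12]
            total += float(above.max()) if above.size else 0.0
        return total / 11.0

    ap = 0.0
    prev_r = 0.0
    for k in range(len(rec)):
        if rec[k] > prev_r:
            ap += (rec[k] - prev_r) * env[k]
            prev_r = rec[k]
    return float(ap)


def mean_ap(ap_per_class: dict[int, float]) -> float:
    """Arithmetic mean of per-class average precisions."""
    if not ap_per_class:
        raise InvalidInputError("need at least one class AP")
    return float(np.mean(list(ap_per_class.values())))


@dataclass(frozen=True)
class MetricsReport:
    """Aggregate detection metrics over an image set."""

    precision: float
    recall: float
    f1: float
    ap_per_class: dict[int, float]
    map50: float
    n_classes: int
    tp: int = 0
    fp: int = 0
    fn: int = 0

    def to_dict(self) -> dict:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "ap_per_class": {str(k): v for k, v in self.ap_per_class.items()},
            "map50": self.map50,
            "n_classes": self.n_classes,
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
        }


def evaluate_detections(
    predictions: list[list[Detection]],
    truths: list[GroundTruth],
    iou_thresh: float = 0.5,
    class_agnostic: bool = False,
    interpolation: str = "all_point",
) -> MetricsReport:
    """Micro-averaged P/R/F1 and per-class AP over paired image lists.

    Matching is per image; AP pools ranked predictions of each class
    across images against the pooled ground-truth count, the PASCAL
    convention.  ``class_agnostic=True`` treats all seeds as one class.
    """
    if len(predictions) != len(truths):
        raise InvalidInputError("predictions and truths must pair one-to-one")
    tp = fp = fn = 0
    per_class_ranked: dict[int, list[tuple[float, bool]]] = {}
    per_class_ngt: dict[int, int] = {}
    for preds, gt in zip(predictions, truths):
        m = match_detections(preds, gt, iou_thresh, class_agnostic=class_agnostic)
        tp, fp, fn = tp + m.tp, fp + m.fp, fn + m.fn
        order = sorted(range(len(preds)), key=lambda i: (-preds[i].confidence, i))
        for rank, i in enumerate(order):
            cid = 0 if class_agnostic else preds[i].class_id
            per_class_ranked.setdefault(cid, []).append(m.ranked[rank])
        for _, cid in gt.boxes:
            key = 0 if class_agnostic else cid
            per_class_ngt[key] = per_class_ngt.get(key, 0) + 1

    ap_per_class: dict[int, float] = {}
    for cid in sorted(set(per_class_ranked) | set(per_class_ngt)):
        ranked = sorted(per_class_ranked.get(cid, []), key=lambda t: -t[0])
        ap_per_class[cid] = average_precision(
            ranked, per_class_ngt.get(cid, 0), interpolation=interpolation
        )

    p = precision(tp, fp)
    r = recall(tp, fn)
    return MetricsReport(
        precision=p,
        recall=r,
        f1=f1_score(p, r),
        ap_per_class=ap_per_class,
        map50=mean_ap(ap_per_class) if ap_per_class else 0.0,
        n_classes=len(ap_per_class),
        tp=tp, fp=fp, fn=fn,
    )


@dataclass(frozen=True)
class CountSummary:
    """Replicate count statistics: mean ± standard error of the mean."""

    mean: float
    se: float
    n_replicates: int
    mean_abs_deviation: float | None = None   # vs. the true count, when known

    def __str__(self) -> str:
        return f"{self.mean:.2f} ± {self.se:.2f} (n={self.n_replicates})"


def count_summary(counts: list[float], true_count: float | None = None) -> CountSummary:
    """Mean and standard error over replicate counts.

    SE is the sample standard deviation (n − 1 denominator) divided by
    √n; with a single replicate the SE is reported as 0.  When the true
    count is known, the mean absolute deviation from it is included.
    """
    if not counts:
        raise InvalidInputError("need at least one replicate count")
    arr = np.asarray(counts, dtype=np.float64)
    n = len(arr)
    se = float(arr.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    mad = float(np.abs(arr - true_count).mean()) if true_count is not None else None
    return CountSummary(
        mean=float(arr.mean()), se=se, n_replicates=n, mean_abs_deviation=mad
    )
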