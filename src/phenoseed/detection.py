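"""Post-processing of raw object-detector output.

A detector emits a grid of candidate records — normalized box centre
and size, an objectness score and per-class probabilities.  This module
implements the deployment-side chain that turns that grid into a seed
count: decode records to pixel boxes, filter by class confidence, apply
greedy non-maximum suppression, count the survivors.  No network is
included; :class:`RawDetectionGrid` is an interchange format and the
generator in :mod:`phenoseed.simulate` can emit grids (perfect,
jittered, duplicated, spurious) from ground truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from phenoseed.metrics import iou
from phenoseed.types import BoundingBox, Detection, InvalidInputError

logger = logging.getLogger(__name__)


@dataclass
class RawDetectionGrid:
    """Raw detector output: one row per candidate.

    ``boxes`` has shape (N, 4) with normalized (cx, cy, w, h) in [0, 1];
    ``objectness`` shape (N,) in [0, 1]; ``class_probs`` shape (N, C)
    in [0, 1] with C >= 1 constant across rows (rows need not sum to 1).
    """

    boxes: np.ndarray
    objectness: np.ndarray
    class_probs: np.ndarray
    class_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.boxes = np.atleast_2d(np.asarray(self.boxes, dtype=np.float64))
        self.objectness = np.atleast_1d(np.asarray(self.objectness, dtype=np.float64))
        self.class_probs = np.atleast_2d(np.asarray(self.class_probs, dtype=np.float64))
        n = len(self.objectness)
        if self.boxes.shape != (n, 4) and n > 0:
            raise InvalidInputError(
                f"boxes shape {self.boxes.shape} inconsistent with {n} records"
            )
        if n > 0 and (self.class_probs.shape[0] != n or self.class_probs.shape[1] < 1):
            raise InvalidInputError("class_probs must be (N, C) with C >= 1")
        for name, arr in (
            ("boxes", self.boxes),
            ("objectness", self.objectness),
            ("class_probs", self.class_probs),
        ):
            if arr.size and (arr.min() < 0.0 or arr.max() > 1.0):
                raise InvalidInputError(f"{name} contains values outside [0, 1]")
        if not self.class_names:
            n_classes = self.class_probs.shape[1] if self.class_probs.size else 1
            self.class_names = [f"class{i}" for i in range(n_classes)]

    def __len__(self) -> int:
        return 0 if self.boxes.size == 0 else self.boxes.shape[0]


def decode_raw(
    grid: RawDetectionGrid,
    image_w: int,
    image_h: int,
    confidence_mode: str = "product",
) -> list[Detection]:
    """Decode normalized records into pixel-space detections.

    Per record: class = argmax of the class probabilities; confidence is
    objectness × max class probability (the detector-family convention;
    ``confidence_mode="objectness"`` uses the objectness alone); the box
    (cx − w/2, cy − h/2, cx + w/2, cy + h/2) is scaled to pixels and
    clipped to the image.  Records whose box has zero width or height
    after clipping cannot form a valid detection and are dropped.
    """
    if image_w < 1 or image_h < 1:
        raise InvalidInputError("image dimensions must be >= 1")
    if confidence_mode not in ("product", "objectness"):
        raise InvalidInputError(f"unknown confidence_mode {confidence_mode!r}")
    detections: list[Detection] = []
    for i in range(len(grid)):
        cx, cy, w, h = grid.boxes[i]
        probs = grid.class_probs[i]
        class_id = int(np.argmax(probs))
        conf = float(grid.objectness[i])
        if confidence_mode == "product":
            conf *= float(probs[class_id])
        x_min = max(0.0, (cx - w / 2.0) * image_w)
        y_min = max(0.0, (cy - h / 2.0) * image_h)
        x_max = min(float(image_w), (cx + w / 2.0) * image_w)
        y_max = min(float(image_h), (cy + h / 2.0) * image_h)
        if x_max <= x_min or y_max <= y_min:
            logger.debug("record %d: degenerate box after clipping, dropped", i)
            continue
        detections.append(
            Detection(
                bbox=BoundingBox(x_min, y_min, x_max, y_max),
                confidence=conf,
                class_id=class_id,
                class_name=grid.class_names[class_id],
            )
        )
    return detections


def filter_confidence(dets: list[Detection], tau: float) -> list[Detection]:
    """Keep detections with confidence strictly greater than ``tau``.

    The inequality is strict: a detection at exactly the threshold is
    discarded.  Input order is preserved.
    """
    return [d for d in dets if d.confidence > tau]


def nms(dets: list[Detection], iou_thresh: float = 0.45, class_agnostic: bool = False) -> list[Detection]:
    """Greedy non-maximum suppression.

    Repeatedly selects the highest-confidence remaining detection and
    suppresses all same-class detections whose IoU with it exceeds
    ``iou_thresh``.  Confidence ties are broken toward the larger box
    area, then the earlier input index.  ``class_agnostic=True``
    suppresses across classes (useful when every seed in an image is the
    same species).
    """
    order = sorted(
        range(len(dets)),
        key=lambda i: (-dets[i].confidence, -dets[i].bbox.area, i),
    )
    suppressed = [False] * len(dets)
    survivors_idx: list[int] = []
    for i in order:
        if suppressed[i]:
            continue
        survivors_idx.append(i)
        for j in order:
            if j == i or suppressed[j]:
                continue
            if not class_agnostic and dets[j].class_id != dets[i].class_id:
                continue
            if iou(dets[j].bbox, dets[i].bbox) > iou_thresh:
                suppressed[j] = True
    return [dets[i] for i in sorted(survivors_idx)]


def detections_to_count(dets: list[Detection]) -> int:
    """The seed count: number of detections surviving the chain, all classes."""
    return len(dets)


def postprocess(
    grid: RawDetectionGrid,
    image_w: int,
    image_h: int,
    conf_threshold: float = 0.25,
    nms_iou: float = 0.45,
    class_agnostic: bool = False,
    confidence_mode: str = "product",
) -> list[Detection]:
    """Full chain: decode → confidence filter → NMS."""
    dets = decode_raw(grid, image_w, image_h, confidence_mode=confidence_mode)
    dets = filter_confidence(dets, conf_threshold)
    return nms(dets, nms_iou, class_agnostic=class_agnostic)
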