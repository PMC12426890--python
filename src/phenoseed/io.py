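"""Readers and writers for the supported interchange formats.

* PNG/JPEG images (via Pillow),
* YOLO-format annotation text: one object per line,
  ``class cx cy w h [confidence]`` with coordinates normalized to the
  image dimensions (6-decimal precision on write),
* raw detection grids as CSV (``cx,cy,w,h,objectness,p_class0,...``)
  or JSON,
* count / metrics reports as JSON and flat CSV.

All box coordinates in reports are 0-based half-open pixel boxes,
x = column, y = row, origin top-left; every report embeds the resolved
run configuration and the library version for provenance.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Any, Sequence

import numpy as np
from PIL import Image, ImageDraw

from phenoseed.types import (
    BoundingBox,
    Detection,
    GroundTruth,
    InvalidInputError,
    RasterImage,
)

_COORD_DECIMALS = 6


class FormatError(InvalidInputError):
    """A file does not conform to its documented dialect."""


def load_image(path: str | Path) -> RasterImage:
    """Read a PNG or JPEG into an 8-bit RGB raster."""
    try:
        with Image.open(path) as im:
            return RasterImage(np.asarray(im.convert("RGB"), dtype=np.uint8))
    except (OSError, ValueError) as exc:
        raise InvalidInputError(f"cannot read image {path}: {exc}") from exc


def save_image(img: RasterImage, path: str | Path) -> None:
    Image.fromarray(img.pixels, mode="RGB").save(path)


def _parse_norm(token: str, path: Path, lineno: int, name: str) -> float:
    try:
        v = float(token)
    except ValueError:
        raise FormatError(f"{path}:{lineno}: {name} {token!r} is not a number") from None
    if not 0.0 <= v <= 1.0:
        raise FormatError(f"{path}:{lineno}: {name} {v} outside [0, 1]")
    return v


def read_yolo_annotations(
    path: str | Path, image_w: int, image_h: int
) -> tuple[GroundTruth, list[Detection]]:
    """Read a YOLO annotation file.

    Returns both views of the file: the ground truth (boxes + count) and
    the same boxes as :class:`Detection` objects, with confidence taken
    from the optional sixth column (1.0 when absent).
    """
    path = Path(path)
    boxes: list[tuple[BoundingBox, int]] = []
    dets: list[Detection] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) not in (5, 6):
                raise FormatError(
                    f"{path}:{lineno}: expected 5 or 6 fields "
                    f"(class cx cy w h [conf]), got {len(fields)}"
                )
            try:
                class_id = int(fields[0])
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: class id {fields[0]!r} is not an integer"
                ) from None
            cx = _parse_norm(fields[1], path, lineno, "cx")
            cy = _parse_norm(fields[2], path, lineno, "cy")
            w = _parse_norm(fields[3], path, lineno, "w")
            h = _parse_norm(fields[4], path, lineno, "h")
            conf = _parse_norm(fields[5], path, lineno, "confidence") if len(fields) == 6 else 1.0
            box = BoundingBox(
                max(0.0, (cx - w / 2) * image_w),
                max(0.0, (cy - h / 2) * image_h),
                min(float(image_w), (cx + w / 2) * image_w),
                min(float(image_h), (cy + h / 2) * image_h),
            )
            boxes.append((box, class_id))
            dets.append(Detection(bbox=box, confidence=conf, class_id=class_id))
    return GroundTruth(boxes=boxes, true_count=len(boxes)), dets


def write_yolo_annotations(
    path: str | Path,
    boxes: Sequence[tuple[BoundingBox, int]],
    image_w: int,
    image_h: int,
    confidences: Sequence[float] | None = None,
) -> None:
    """Write boxes as YOLO-format lines, 6-decimal normalized coordinates."""
    lines = []
    for i, (box, class_id) in enumerate(boxes):
        cx = (box.x_min + box.x_max) / 2 / image_w
        cy = (box.y_min + box.y_max) / 2 / image_h
        w = box.width / image_w
        h = box.height / image_h
        parts = [str(class_id)] + [f"{v:.{_COORD_DECIMALS}f}" for v in (cx, cy, w, h)]
        if confidences is not None:
            parts.append(f"{confidences[i]:.{_COORD_DECIMALS}f}")
        lines.append(" ".join(parts))
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_raw_grid(path: str | Path):
    """Read a raw detection grid from CSV (by header) or JSON."""
    from phenoseed.detection import RawDetectionGrid

    path = Path(path)
    if path.suffix.lower() == ".json":
        data = json.loads(path.read_text())
        return RawDetectionGrid(
            boxes=np.array(data["boxes"], dtype=np.float64).reshape(-1, 4),
            objectness=np.array(data["objectness"], dtype=np.float64),
            class_probs=np.array(data["class_probs"], dtype=np.float64),
            class_names=data.get("class_names", []),
        )
    with open(path) as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty raw-grid file") from None
        expected_prefix = ["cx", "cy", "w", "h", "objectness"]
        if [c.strip() for c in header[:5]] != expected_prefix:
            raise FormatError(
                f"{path}:1: header must start with {','.join(expected_prefix)}"
            )
        n_classes = len(header) - 5
        if n_classes < 1:
            raise FormatError(f"{path}:1: need at least one p_class column")
        boxes, obj, probs = [], [], []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 5 + n_classes:
                raise FormatError(
                    f"{path}:{lineno}: expected {5 + n_classes} fields, got {len(row)}"
                )
            vals = []
            for name, tok in zip(header, row):
                vals.append(_parse_norm(tok.strip(), path, lineno, name.strip()))
            boxes.append(vals[:4])
            obj.append(vals[4])
            probs.append(vals[5:])
    if not boxes:
        return RawDetectionGrid(
            boxes=np.zeros((0, 4)), objectness=np.zeros(0),
            class_probs=np.zeros((0, n_classes)),
        )
    return RawDetectionGrid(
        boxes=np.array(boxes), objectness=np.array(obj), class_probs=np.array(probs)
    )


def write_raw_grid(grid, path: str | Path) -> None:
    """Write a raw grid as CSV (or JSON when the path ends in .json)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = {
            "boxes": np.round(grid.boxes, _COORD_DECIMALS).tolist(),
            "objectness": np.round(grid.objectness, _COORD_DECIMALS).tolist(),
            "class_probs": np.round(grid.class_probs, _COORD_DECIMALS).tolist(),
            "class_names": grid.class_names,
        }
        path.write_text(json.dumps(payload, indent=1))
        return
    n_classes = grid.class_probs.shape[1] if grid.class_probs.size else 1
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["cx", "cy", "w", "h", "objectness"] + [f"p_class{i}" for i in range(n_classes)])
        for i in range(len(grid)):
            row = list(grid.boxes[i]) + [grid.objectness[i]] + list(grid.class_probs[i])
            writer.writerow([f"{v:.{_COORD_DECIMALS}f}" for v in row])


_PROVENANCE_NOTE = "boxes are 0-based half-open pixel coords, x=column, y=row, origin top-left"


def _provenance(run_config: dict[str, Any] | None) -> dict[str, Any]:
    from phenoseed import __version__

    return {
        "phenoseed_version": __version__,
        "coordinate_convention": _PROVENANCE_NOTE,
        "config": run_config or {},
    }


def write_count_report(
    result, path: str | Path, run_config: dict[str, Any] | None = None
) -> None:
    """Write a per-image count report as JSON."""
    payload = result.to_dict()
    payload["provenance"] = _provenance(run_config)
    Path(path).write_text(json.dumps(payload, indent=1))


def write_seed_csv(result, path: str | Path) -> None:
    """Write one CSV row per counted seed."""
    with open(path, "w", newline="") as fh:
        fh.write(f"# {_PROVENANCE_NOTE}\n")
        writer = csv.writer(fh)
        writer.writerow(
            ["id", "x_min", "y_min", "x_max", "y_max",
             "length_mm", "width_mm", "aspect_ratio", "area_px",
             "centroid_x", "centroid_y"]
        )
        for f in result.features:
            writer.writerow(
                [f.seed_id, *f.bbox.as_tuple(),
                 f"{f.length_mm:.4f}", f"{f.width_mm:.4f}", f"{f.aspect_ratio:.4f}",
                 f.area_px, f"{f.centroid[0]:.2f}", f"{f.centroid[1]:.2f}"]
            )


def write_metrics_report(
    report, path: str | Path, run_config: dict[str, Any] | None = None,
    count_summaries: dict | None = None,
) -> None:
    """Write a metrics report as JSON (CSV twin alongside for .csv paths)."""
    path = Path(path)
    payload = report.to_dict()
    if count_summaries:
        payload["count_summaries"] = count_summaries
    payload["provenance"] = _provenance(run_config)
    if path.suffix.lower() == ".csv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["metric", "value"])
            for key in ("precision", "recall", "f1", "map50", "tp", "fp", "fn"):
                writer.writerow([key, payload[key]])
            for cid, ap in payload["ap_per_class"].items():
                writer.writerow([f"ap_class_{cid}", ap])
    else:
        path.write_text(json.dumps(payload, indent=1))


def render_overlay(img: RasterImage, result, path: str | Path) -> None:
    """Save the image with numbered boxes drawn on each counted seed."""
    im = Image.fromarray(img.pixels, mode="RGB")
    draw = ImageDraw.Draw(im)
    for f in result.features:
        b = f.bbox
        draw.rectangle([b.x_min, b.y_min, b.x_max - 1, b.y_max - 1], outline=(255, 0, 0), width=2)
        draw.text((f.centroid[0], f.centroid[1]), str(f.seed_id), fill=(0, 0, 255))
    im.save(path)


def pair_by_stem(
    prediction_paths: Sequence[str | Path], truth_paths: Sequence[str | Path]
) -> list[tuple[Path, Path]]:
    """Pair prediction and truth files by filename stem; refuse strays."""
    preds = {Path(p).stem: Path(p) for p in prediction_paths}
    truths = {Path(t).stem: Path(t) for t in truth_paths}
    unmatched = sorted(set(preds) ^ set(truths))
    if unmatched:
        raise InvalidInputError(
            "unmatched prediction/truth stems: " + ", ".join(unmatched)
        )
    return [(preds[s], truths[s]) for s in sorted(preds)]
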