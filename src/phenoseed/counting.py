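"""Seed counting by connected-component analysis.

The counter segments a thresholded image into connected foreground
regions, rejects noise specks by area, orders regions top-to-bottom,
measures each surviving region (bounding box, length/width in mm via a
linear calibration, aspect ratio) and reports the region count as the
seed count.  Touching seeds merge into one region and are counted once;
this is a documented limitation (no watershed splitting) — oversized
regions are flagged instead.

External contours are traced per region (Moore border following,
interior holes ignored) and compressed by removing collinear vertices;
they serve feature reporting and overlays, not the count itself.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
from scipy import ndimage

from phenoseed.config import CountingConfig
from phenoseed.imaging import (
    DegenerateHistogramError,
    binarize,
    gaussian_blur,
    otsu_threshold,
    to_grayscale,
)
from phenoseed.types import (
    BinaryMask,
    BoundingBox,
    CalibrationScale,
    InvalidInputError,
    RasterImage,
)

logger = logging.getLogger(__name__)

_STRUCTURE = {
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool),
    8: np.ones((3, 3), dtype=bool),
}


@dataclass
class PixelRegion:
    """A connected foreground region: one candidate seed."""

    label: int
    pixels: np.ndarray              # (N, 2) array of (x, y) member coordinates
    bbox: BoundingBox

    def __post_init__(self) -> None:
        if len(self.pixels) < 1:
            raise InvalidInputError("region must contain at least one pixel")

    @property
    def pixel_count(self) -> int:
        return len(self.pixels)

    @property
    def pixel_set(self) -> set[tuple[int, int]]:
        return {(int(x), int(y)) for x, y in self.pixels}

    @property
    def centroid(self) -> tuple[float, float]:
        return (float(self.pixels[:, 0].mean()), float(self.pixels[:, 1].mean()))

    @property
    def contour(self) -> list[tuple[int, int]]:
        return trace_external_contour(self)


@dataclass(frozen=True)
class SeedFeature:
    """Measured descriptors of one counted seed."""

    seed_id: int                    # 1-based ordinal in sorted order
    bbox: BoundingBox
    length_mm: float                # longer bbox side × mm_per_px
    width_mm: float                 # shorter bbox side × mm_per_px
    aspect_ratio: float             # length / width, ≥ 1
    area_px: int
    centroid: tuple[float, float]

    def to_dict(self) -> dict[str, Any]:
        return {
            "id": self.seed_id,
            "bbox": self.bbox.as_tuple(),
            "length_mm": self.length_mm,
            "width_mm": self.width_mm,
            "aspect_ratio": self.aspect_ratio,
            "area_px": self.area_px,
            "centroid": self.centroid,
        }


@dataclass
class CountResult:
    """Outcome of the counting pipeline on one image."""

    count: int
    features: list[SeedFeature]
    mask: BinaryMask
    config_echo: dict[str, Any]
    threshold_used: int = 0
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        assert self.count == len(self.features)

    def to_dict(self) -> dict[str, Any]:
        return {
            "count": self.count,
            "threshold_used": self.threshold_used,
            "seeds": [f.to_dict() for f in self.features],
            "warnings": self.warnings,
            "config": self.config_echo,
        }


def label_components(mask: BinaryMask, connectivity: int = 8) -> list[PixelRegion]:
    """Partition foreground pixels into maximal connected regions.

    Labels carry no meaning before :func:`sort_regions`.  An empty mask
    yields an empty list.
    """
    if connectivity not in _STRUCTURE:
        raise InvalidInputError(f"connectivity must be 4 or 8, got {connectivity}")
    labeled, n = ndimage.label(mask.pixels, structure=_STRUCTURE[connectivity])
    regions: list[PixelRegion] = []
    slices = ndimage.find_objects(labeled)
    for lab, sl in enumerate(slices, start=1):
        if sl is None:
            continue
        ys, xs = np.nonzero(labeled[sl] == lab)
        ys = ys + sl[0].start
        xs = xs + sl[1].start
        bbox = BoundingBox(
            x_min=int(xs.min()), y_min=int(ys.min()),
            x_max=int(xs.max()) + 1, y_max=int(ys.max()) + 1,
        )
        regions.append(PixelRegion(label=lab, pixels=np.column_stack([xs, ys]), bbox=bbox))
    return regions


# Moore neighbourhood in clockwise screen order (y grows downward),
# starting west: W, NW, N, NE, E, SE, S, SW.
_MOORE = [(-1, 0), (-1, -1), (0, -1), (1, -1), (1, 0), (1, 1), (0, 1), (-1, 1)]


def trace_external_contour(region: PixelRegion) -> list[tuple[int, int]]:
    """Ordered outer boundary of a region by Moore border following.

    Interior holes are ignored: the trace follows only the outermost
    border.  The walk proceeds clockwise on screen (equivalently
    counter-clockwise in a y-up frame); a single-pixel region yields a
    degenerate one-vertex contour.  Vertices are (x, y) pixel centres.
    """
    members = region.pixel_set
    # start: topmost row, then leftmost column — its west neighbour is background
    start = min(members, key=lambda p: (p[1], p[0]))
    if len(members) == 1:
        return [start]

    def neighbors_from(p: tuple[int, int], prev: tuple[int, int]):
        dx, dy = prev[0] - p[0], prev[1] - p[1]
        i0 = _MOORE.index((dx, dy))
        for k in range(1, 9):
            d = _MOORE[(i0 + k) % 8]
            yield (p[0] + d[0], p[1] + d[1])

    contour = [start]
    backtrack = (start[0] - 1, start[1])
    p, prev = start, backtrack
    max_steps = 4 * len(members) + 8     # an outer border never exceeds this
    while max_steps > 0:
        max_steps -= 1
        nxt = None
        for cand in neighbors_from(p, prev):
            if cand in members:
                nxt = cand
                break
            prev = cand
        if nxt is None:                      # isolated pixel cluster of size 1
            break
        p = nxt
        if p == start and prev == backtrack:  # Jacob's stopping criterion
            break
        contour.append(p)
    return contour


def simplify_chain(polygon: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Drop vertices collinear with their neighbours in a closed polygon.

    Keeps only endpoints of straight-line runs; the traced shape is
    preserved exactly.  Spike vertices (direction reversals) are kept.
    """
    pts = [tuple(p) for p in polygon]
    if len(pts) <= 2:
        return pts
    changed = True
    while changed and len(pts) > 2:
        changed = False
        kept: list[tuple[int, int]] = []
        n = len(pts)
        for i in range(n):
            a = kept[-1] if kept else pts[i - 1]
            b, c = pts[i], pts[(i + 1) % n]
            ab = (b[0] - a[0], b[1] - a[1])
            bc = (c[0] - b[0], c[1] - b[1])
            cross = ab[0] * bc[1] - ab[1] * bc[0]
            dot = ab[0] * bc[0] + ab[1] * bc[1]
            if cross == 0 and dot > 0:       # forward collinear → redundant
                changed = True
                continue
            kept.append(b)
        pts = kept if kept else pts[:1]
    return pts


def filter_regions(
    regions: Sequence[PixelRegion],
    min_area_px: float = 0.0,
    max_area_px: float | None = None,
) -> list[PixelRegion]:
    """Keep regions with min_area_px <= area <= max_area_px."""
    if min_area_px < 0 or (max_area_px is not None and max_area_px < min_area_px):
        raise InvalidInputError("require 0 <= min_area_px <= max_area_px")
    kept = [
        r for r in regions
        if r.pixel_count >= min_area_px
        and (max_area_px is None or r.pixel_count <= max_area_px)
    ]
    removed = len(regions) - len(kept)
    if removed:
        logger.info("area filter removed %d of %d regions", removed, len(regions))
    return kept


def sort_regions(regions: Sequence[PixelRegion]) -> list[PixelRegion]:
    """Order regions top-to-bottom: ascending bbox y_min, then x_min, then label."""
    return sorted(regions, key=lambda r: (r.bbox.y_min, r.bbox.x_min, r.label))


def extract_features(
    region: PixelRegion, scale: CalibrationScale, seed_id: int
) -> SeedFeature:
    """Measure one region: bbox sides in mm (length = longer side) and L/W."""
    sides = (region.bbox.width, region.bbox.height)
    length_mm = max(sides) * scale.mm_per_px
    width_mm = min(sides) * scale.mm_per_px
    return SeedFeature(
        seed_id=seed_id,
        bbox=region.bbox,
        length_mm=length_mm,
        width_mm=width_mm,
        aspect_ratio=length_mm / width_mm,
        area_px=region.pixel_count,
        centroid=region.centroid,
    )


def count_seeds(img: RasterImage, config: CountingConfig | None = None) -> CountResult:
    """Run the full counting pipeline on one image.

    grayscale → Gaussian blur → threshold (Otsu unless fixed) →
    connected components → area filter → y-sort → features.  The count
    is the number of surviving regions; seed ids are assigned 1..count
    in sorted order.

    Border-touching regions are counted but flagged, and any region
    whose area exceeds ``cluster_area_factor`` × the median region area
    is flagged as a probable cluster of touching seeds.
    """
    cfg = config or CountingConfig()
    cfg.validate()

    gray = to_grayscale(img)
    blurred = gaussian_blur(gray, cfg.blur_kernel_px, cfg.blur_sigma)
    if cfg.threshold is not None:
        level = cfg.threshold
        mask = binarize(blurred, level, cfg.polarity)
    else:
        try:
            level = otsu_threshold(blurred)
        except DegenerateHistogramError:
            # a perfectly uniform image is an empty scene, not an error
            logger.warning("constant image: no threshold separates it; count 0")
            empty = BinaryMask(np.zeros_like(blurred.pixels))
            return CountResult(
                count=0, features=[], mask=empty,
                config_echo={"threshold": None, "note": "constant image"},
                threshold_used=int(blurred.pixels.flat[0]),
                warnings=["constant image: no foreground found"],
            )
        mask = binarize(blurred, level, cfg.polarity)

    regions = label_components(mask, cfg.connectivity)
    min_area = cfg.effective_min_area(img.height, img.width)
    regions = filter_regions(regions, min_area_px=min_area, max_area_px=cfg.max_area_px)
    regions = sort_regions(regions)

    scale = CalibrationScale(cfg.mm_per_px)
    features = [
        extract_features(region, scale, seed_id)
        for seed_id, region in enumerate(regions, start=1)
    ]

    warnings: list[str] = []
    h, w = img.height, img.width
    for f, r in zip(features, regions):
        b = r.bbox
        if b.x_min == 0 or b.y_min == 0 or b.x_max == w or b.y_max == h:
            warnings.append(f"seed {f.seed_id}: region touches the image border")
    if regions:
        median_area = float(np.median([r.pixel_count for r in regions]))
        for f, r in zip(features, regions):
            if r.pixel_count > cfg.cluster_area_factor * median_area:
                warnings.append(
                    f"seed {f.seed_id}: area {r.pixel_count} px² exceeds "
                    f"{cfg.cluster_area_factor}× the median ({median_area:.0f} px²); "
                    "possible cluster of touching seeds"
                )
    for msg in warnings:
        logger.warning("%s", msg)

    echo = {
        "blur_kernel_px": cfg.blur_kernel_px,
        "blur_sigma": cfg.blur_sigma,
        "threshold": cfg.threshold,
        "polarity": cfg.polarity,
        "connectivity": cfg.connectivity,
        "min_area_px_effective": min_area,
        "max_area_px": cfg.max_area_px,
        "mm_per_px": cfg.mm_per_px,
    }
    return CountResult(
        count=len(features),
        features=features,
        mask=mask,
        config_echo=echo,
        threshold_used=level,
        warnings=warnings,
    )
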