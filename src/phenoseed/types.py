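"""Shared domain types.

Coordinate conventions used throughout the package: images are addressed
row-major with the origin at the top-left corner; ``x`` is the column
index and ``y`` the row index, both 0-based.  Bounding boxes are
half-open, ``[x_min, x_max) × [y_min, y_max)``, so the box of a single
pixel at (3, 7) is ``BoundingBox(3, 7, 4, 8)`` and box area equals the
number of covered pixels for integer coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class InvalidInputError(ValueError):
    """An input violates a documented precondition."""


@dataclass(frozen=True)
class RasterImage:
    """An 8-bit RGB image, shape ``(H, W, 3)``, values in [0, 255]."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.pixels)
        if p.ndim != 3 or p.shape[2] != 3 or p.shape[0] < 1 or p.shape[1] < 1:
            raise InvalidInputError(f"expected H×W×3 pixel array, got shape {p.shape}")
        if p.dtype != np.uint8:
            if p.min() < 0 or p.max() > 255:
                raise InvalidInputError("channel values must lie in [0, 255]")
            p = p.astype(np.uint8)
        object.__setattr__(self, "pixels", p)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class GrayImage:
    """An 8-bit single-channel image, shape ``(H, W)``."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.pixels)
        if p.ndim != 2 or p.shape[0] < 1 or p.shape[1] < 1:
            raise InvalidInputError(f"expected H×W pixel array, got shape {p.shape}")
        if p.dtype != np.uint8:
            if p.min() < 0 or p.max() > 255:
                raise InvalidInputError("intensities must lie in [0, 255]")
            p = p.astype(np.uint8)
        object.__setattr__(self, "pixels", p)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class BinaryMask:
    """A {0, 1} foreground mask.

    ``foreground_polarity`` records whether foreground pixels were
    brighter (``"bright"``) or darker (``"dark"``) than the threshold
    that produced the mask, or ``"unknown"`` for masks of other origin.
    """

    pixels: np.ndarray
    foreground_polarity: str = "unknown"

    def __post_init__(self) -> None:
        p = np.asarray(self.pixels)
        if p.ndim != 2:
            raise InvalidInputError(f"expected H×W mask, got shape {p.shape}")
        if not np.isin(p, (0, 1)).all():
            raise InvalidInputError("mask values must be 0 or 1")
        object.__setattr__(self, "pixels", p.astype(np.uint8))

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    def foreground_fraction(self) -> float:
        return float(self.pixels.mean())


@dataclass(frozen=True)
class BoundingBox:
    """Half-open axis-aligned box in pixel coordinates."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise InvalidInputError(
                f"degenerate box ({self.x_min}, {self.y_min}, {self.x_max}, {self.y_max})"
            )

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        return ((self.x_min + self.x_max) / 2.0, (self.y_min + self.y_max) / 2.0)

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.x_min, self.y_min, self.x_max, self.y_max)


@dataclass(frozen=True)
class CalibrationScale:
    """Linear pixel → millimetre conversion factor.

    Built either directly from a known ``mm_per_px`` or from a reference
    object of known physical length measured in the image.
    """

    mm_per_px: float

    def __post_init__(self) -> None:
        if not self.mm_per_px > 0:
            raise InvalidInputError("mm_per_px must be positive")

    @classmethod
    def from_reference(cls, reference_mm: float, reference_px: float) -> "CalibrationScale":
        if reference_px <= 0 or reference_mm <= 0:
            raise InvalidInputError("reference lengths must be positive")
        return cls(mm_per_px=reference_mm / reference_px)


@dataclass(frozen=True)
class Detection:
    """A decoded detector candidate: pixel box, confidence, class."""

    bbox: BoundingBox
    confidence: float
    class_id: int = 0
    class_name: str = "seed"

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise InvalidInputError(f"confidence {self.confidence} outside [0, 1]")
        if self.class_id < 0:
            raise InvalidInputError("class_id must be non-negative")


@dataclass
class GroundTruth:
    """Per-image true boxes and the true seed count."""

    boxes: list[tuple[BoundingBox, int]] = field(default_factory=list)
    true_count: int | None = None

    def __post_init__(self) -> None:
        if self.true_count is None:
            self.true_count = len(self.boxes)
        elif self.boxes and self.true_count != len(self.boxes):
            raise InvalidInputError(
                f"true_count {self.true_count} != number of boxes {len(self.boxes)}"
            )
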