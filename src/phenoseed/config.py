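"""Run configuration: defaults, YAML loading, override precedence.

Every tunable of the imaging, counting, post-processing and metric
stages lives here with an explicit default, so a fully materialized
configuration can be echoed into every output artifact for provenance.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from phenoseed.types import InvalidInputError

#: Reference (native) sensor resolution used to scale the area filter.
NATIVE_AREA_PX = 3024 * 4032


@dataclass
class CountingConfig:
    """Parameters of the classical image-processing counter."""

    blur_kernel_px: int = 5
    blur_sigma: float = 1.0
    threshold: int | None = None        # None → Otsu's method
    polarity: str = "auto"              # bright | dark | auto
    connectivity: int = 8               # 4 | 8
    min_area_px: float | None = None    # absolute; None → min_area_native scaled
    min_area_native: float = 10.0       # px² at native 3024×4032 resolution
    max_area_px: float | None = None
    mm_per_px: float = 1.0              # 1.0 → lengths reported in pixels
    cluster_area_factor: float = 3.0    # flag regions larger than this × median

    def effective_min_area(self, image_h: int, image_w: int) -> float:
        """Absolute area floor for this image size.

        The native default removes single-pixel sensor specks at full
        resolution; it is scaled with image area so downsampled images
        keep an equivalent physical floor.
        """
        if self.min_area_px is not None:
            return self.min_area_px
        return max(1.0, self.min_area_native * (image_h * image_w) / NATIVE_AREA_PX)

    def validate(self) -> None:
        if self.connectivity not in (4, 8):
            raise InvalidInputError(f"connectivity must be 4 or 8, got {self.connectivity}")
        if self.blur_kernel_px < 1 or self.blur_kernel_px % 2 == 0:
            raise InvalidInputError("blur_kernel_px must be odd and >= 1")
        if self.polarity not in ("bright", "dark", "auto"):
            raise InvalidInputError(f"unknown polarity {self.polarity!r}")
        if self.threshold is not None and not 0 <= self.threshold <= 255:
            raise InvalidInputError("threshold must lie in [0, 255]")
        if not self.mm_per_px > 0:
            raise InvalidInputError("mm_per_px must be positive")


@dataclass
class PostprocessConfig:
    """Parameters of the detector post-processing chain."""

    conf_threshold: float = 0.25
    nms_iou: float = 0.45
    class_agnostic: bool = False
    confidence_mode: str = "product"    # product | objectness

    def validate(self) -> None:
        if not 0.0 <= self.conf_threshold <= 1.0:
            raise InvalidInputError("conf_threshold must lie in [0, 1]")
        if not 0.0 <= self.nms_iou <= 1.0:
            raise InvalidInputError("nms_iou must lie in [0, 1]")
        if self.confidence_mode not in ("product", "objectness"):
            raise InvalidInputError(f"unknown confidence_mode {self.confidence_mode!r}")


@dataclass
class MetricsConfig:
    """Parameters of detection evaluation."""

    iou_threshold: float = 0.5
    interpolation: str = "all_point"    # all_point | eleven_point
    class_agnostic: bool = False

    def validate(self) -> None:
        if not 0.0 <= self.iou_threshold <= 1.0:
            raise InvalidInputError("iou_threshold must lie in [0, 1]")
        if self.interpolation not in ("all_point", "eleven_point"):
            raise InvalidInputError(f"unknown interpolation {self.interpolation!r}")


@dataclass
class RunConfig:
    """Fully materialized configuration for one run."""

    counting: CountingConfig = field(default_factory=CountingConfig)
    postprocess: PostprocessConfig = field(default_factory=PostprocessConfig)
    metrics: MetricsConfig = field(default_factory=MetricsConfig)

    def validate(self) -> None:
        self.counting.validate()
        self.postprocess.validate()
        self.metrics.validate()

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "RunConfig":
        cfg = cls()
        for section_name, section in data.items():
            if not hasattr(cfg, section_name):
                raise InvalidInputError(f"unknown config section {section_name!r}")
            target = getattr(cfg, section_name)
            for key, value in section.items():
                if not hasattr(target, key):
                    raise InvalidInputError(
                        f"unknown config key {section_name}.{key!r}"
                    )
                setattr(target, key, value)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def apply_overrides(self, overrides: dict[str, Any]) -> "RunConfig":
        """Apply flat ``section.key`` → value overrides (CLI precedence)."""
        for dotted, value in overrides.items():
            if value is None:
                continue
            section_name, _, key = dotted.partition(".")
            target = getattr(self, section_name, None)
            if target is None or not hasattr(target, key):
                raise InvalidInputError(f"unknown config override {dotted!r}")
            setattr(target, key, value)
        self.validate()
        return self
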