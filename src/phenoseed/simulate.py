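"""Synthetic seed-image generation with exact ground truth.

Seeds are modeled as rotated filled ellipses with per-seed jitter in
size, elongation, orientation and fill colour, composited on a uniform
background (white A4 paper, an orange or a black table surface, or a
custom colour).  Optional degradations — additive Gaussian sensor
noise, a multiplicative left-to-right illumination gradient, and
injected small foreground specks — emulate the failure modes a desk
imaging setup exhibits.  Every sample carries its ground truth: tight
pre-noise bounding boxes, the true seed mask, and the true count.

The module also provides the replicate accuracy-experiment harness:
generate R images per target quantity, run a pluggable counter, and
summarize counts as mean ± SE.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from skimage.draw import ellipse as draw_ellipse

from phenoseed.metrics import CountSummary, count_summary
from phenoseed.types import (
    BinaryMask,
    BoundingBox,
    GroundTruth,
    InvalidInputError,
    RasterImage,
)

#: Named background colours (RGB) with the luminance ordering of the
#: emulated surfaces: black table < orange table < white A4 paper.
BACKGROUNDS: dict[str, tuple[int, int, int]] = {
    "white_a4": (247, 247, 244),
    "orange_table": (205, 125, 45),
    "black_table": (28, 26, 27),
}

#: Shape presets: (major-axis range px at the default canvas, aspect-ratio
#: range, fill-colour low RGB, fill-colour high RGB).
SHAPE_PRESETS: dict[str, tuple[tuple[float, float], tuple[float, float], tuple, tuple]] = {
    # mid-size oval seeds, dark brown — the generic default
    "default": ((22.0, 36.0), (1.2, 2.2), (60, 40, 22), (110, 78, 48)),
    # small dark round seeds
    "small_round": ((12.0, 18.0), (1.0, 1.3), (45, 30, 20), (80, 55, 35)),
    # large elongated seeds
    "large_elongated": ((40.0, 64.0), (2.0, 3.5), (120, 95, 55), (170, 140, 90)),
}

_PLACEMENT_ATTEMPTS = 10_000


class PlacementCapacityError(InvalidInputError):
    """Rejection sampling could not place all seeds."""


@dataclass
class SimConfig:
    """Generator parameters.

    The default canvas is 1008 × 1344 px — the native 3024 × 4032
    portrait sensor frame scaled by 1/3, preserving aspect ratio.
    ``min_separation_px=None`` resolves to the largest major axis plus
    twice the default blur kernel (5 px), which guarantees blurred
    seeds stay separable; it is ignored when ``allow_touching`` is set.
    Identical configs (including ``rng_seed``) produce bit-identical
    samples.
    """

    image_w: int = 1008
    image_h: int = 1344
    background: str | tuple[int, int, int] = "white_a4"
    n_seeds: int = 10
    major_axis_range: tuple[float, float] = (22.0, 36.0)
    aspect_range: tuple[float, float] = (1.2, 2.2)
    fill_color_low: tuple[int, int, int] = (60, 40, 22)
    fill_color_high: tuple[int, int, int] = (110, 78, 48)
    min_separation_px: float | None = None
    allow_touching: bool = False
    noise_sigma: float = 0.0
    illumination_gradient: float = 0.0
    speck_count: int = 0
    speck_size_px: int = 1
    rng_seed: int = 0

    def background_rgb(self) -> tuple[int, int, int]:
        if isinstance(self.background, str):
            try:
                return BACKGROUNDS[self.background]
            except KeyError:
                raise InvalidInputError(
                    f"unknown background {self.background!r}; "
                    f"choose from {sorted(BACKGROUNDS)} or give an RGB triple"
                ) from None
        return tuple(self.background)  # type: ignore[return-value]

    def resolved_min_separation(self) -> float:
        if self.min_separation_px is not None:
            return self.min_separation_px
        return self.major_axis_range[1] + 2 * 5  # largest seed + 2 × blur kernel

    def validate(self) -> None:
        if self.image_w < 1 or self.image_h < 1:
            raise InvalidInputError("canvas dimensions must be >= 1")
        if self.n_seeds < 0:
            raise InvalidInputError("n_seeds must be non-negative")
        lo, hi = self.major_axis_range
        if not 0 < lo <= hi:
            raise InvalidInputError("degenerate major_axis_range")
        alo, ahi = self.aspect_range
        if not 1.0 <= alo <= ahi:
            raise InvalidInputError("aspect_range must lie in [1, ∞)")
        if self.noise_sigma < 0 or not 0.0 <= self.illumination_gradient < 1.0:
            raise InvalidInputError("invalid noise_sigma or illumination_gradient")
        self.background_rgb()

    @classmethod
    def with_preset(cls, preset: str, **kwargs) -> "SimConfig":
        major, aspect, lo, hi = SHAPE_PRESETS[preset]
        return cls(
            major_axis_range=major, aspect_range=aspect,
            fill_color_low=lo, fill_color_high=hi, **kwargs,
        )


@dataclass
class SimSample:
    """One generated image with its ground truth."""

    image: RasterImage
    truth: GroundTruth
    true_mask: BinaryMask
    config: SimConfig


def _place_centers(cfg: SimConfig, rng: np.random.Generator) -> list[tuple[float, float, float, float, float]]:
    """Sample (cx, cy, major, minor, rotation) tuples by rejection sampling."""
    min_sep = 0.0 if cfg.allow_touching else cfg.resolved_min_separation()
    placed: list[tuple[float, float, float, float, float]] = []
    attempts = 0
    while len(placed) < cfg.n_seeds:
        if attempts >= _PLACEMENT_ATTEMPTS:
            raise PlacementCapacityError(
                f"placed only {len(placed)} of {cfg.n_seeds} seeds in "
                f"{_PLACEMENT_ATTEMPTS} attempts; n_seeds={cfg.n_seeds} with "
                f"min_separation_px={min_sep:.1f} exceeds the canvas capacity "
                f"({cfg.image_w}×{cfg.image_h})"
            )
        attempts += 1
        major = rng.uniform(*cfg.major_axis_range)
        aspect = rng.uniform(*cfg.aspect_range)
        minor = major / aspect
        rot = rng.uniform(0.0, np.pi)
        margin = major / 2.0 + 2.0
        if cfg.image_w <= 2 * margin or cfg.image_h <= 2 * margin:
            raise PlacementCapacityError(
                f"canvas {cfg.image_w}×{cfg.image_h} too small for seeds of "
                f"major axis {major:.0f} px"
            )
        cx = rng.uniform(margin, cfg.image_w - margin)
        cy = rng.uniform(margin, cfg.image_h - margin)
        if min_sep > 0 and any(
            (cx - px) ** 2 + (cy - py) ** 2 < min_sep**2 for px, py, *_ in placed
        ):
            continue
        placed.append((cx, cy, major, minor, rot))
    return placed


def generate_image(config: SimConfig) -> SimSample:
    """Render one synthetic seed image with exact ground truth.

    Seeds are drawn first; ground-truth boxes are tight to each
    ellipse's pixels before any degradation.  Additive Gaussian noise is
    then applied, followed by the multiplicative illumination gradient
    (darkest at the left edge).  Injected specks are foreground-coloured
    noise and never part of the ground truth.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    h, w = config.image_h, config.image_w
    canvas = np.empty((h, w, 3), dtype=np.float64)
    canvas[:] = config.background_rgb()
    true_mask = np.zeros((h, w), dtype=np.uint8)

    boxes: list[tuple[BoundingBox, int]] = []
    lo = np.asarray(config.fill_color_low, dtype=np.float64)
    hi = np.asarray(config.fill_color_high, dtype=np.float64)
    for cx, cy, major, minor, rot in _place_centers(config, rng):
        # skimage's ellipse rotation acts in (row, col); negate to get the
        # screen-frame angle measured from the x axis
        rr, cc = draw_ellipse(cy, cx, minor / 2.0, major / 2.0, shape=(h, w), rotation=-rot)
        color = lo + rng.uniform(size=3) * (hi - lo)
        canvas[rr, cc] = color
        true_mask[rr, cc] = 1
        boxes.append(
            (
                BoundingBox(int(cc.min()), int(rr.min()), int(cc.max()) + 1, int(rr.max()) + 1),
                0,
            )
        )

    # speck noise: small foreground-coloured squares, not in the ground truth
    s = max(1, config.speck_size_px)
    for _ in range(config.speck_count):
        x = int(rng.integers(0, w - s + 1))
        y = int(rng.integers(0, h - s + 1))
        canvas[y : y + s, x : x + s] = lo + rng.uniform(size=3) * (hi - lo)

    if config.noise_sigma > 0:
        canvas += rng.normal(0.0, config.noise_sigma, size=canvas.shape)
    if config.illumination_gradient > 0:
        g = config.illumination_gradient
        ramp = np.linspace(1.0 - g, 1.0, w)[None, :, None]
        canvas *= ramp

    image = RasterImage(np.clip(np.floor(canvas + 0.5), 0, 255).astype(np.uint8))
    truth = GroundTruth(boxes=boxes, true_count=config.n_seeds)
    return SimSample(image=image, truth=truth, true_mask=BinaryMask(true_mask), config=config)


@dataclass
class PerturbationSpec:
    """How to corrupt a perfect raw grid derived from ground truth.

    ``box_jitter_px`` shifts centres and resizes boxes by uniform
    offsets of that many pixels; ``duplicate_rate`` adds a near-copy of
    each true box with that probability (slightly offset, lower
    confidence); ``n_spurious`` adds small random boxes with confidence
    drawn from ``spurious_conf_range``.
    """

    box_jitter_px: float = 0.0
    duplicate_rate: float = 0.0
    n_spurious: int = 0
    conf_range: tuple[float, float] = (0.9, 0.99)
    spurious_conf_range: tuple[float, float] = (0.02, 0.2)
    rng_seed: int = 0


def raw_grid_from_truth(
    truth: GroundTruth,
    image_w: int,
    image_h: int,
    perturbation: PerturbationSpec | None = None,
    n_classes: int = 1,
):
    """Emit a raw detection grid from ground truth (a detector stand-in).

    With the default (zero) perturbation, decoding the grid recovers
    the truth boxes to within one pixel per image dimension.
    """
    from phenoseed.detection import RawDetectionGrid  # local import avoids a cycle

    spec = perturbation or PerturbationSpec()
    rng = np.random.default_rng(spec.rng_seed)
    rows_box: list[list[float]] = []
    rows_obj: list[float] = []
    rows_cls: list[np.ndarray] = []

    def add_row(box: BoundingBox, class_id: int, conf: float) -> None:
        cx = np.clip((box.x_min + box.x_max) / 2.0 / image_w, 0.0, 1.0)
        cy = np.clip((box.y_min + box.y_max) / 2.0 / image_h, 0.0, 1.0)
        bw = np.clip(box.width / image_w, 0.0, 1.0)
        bh = np.clip(box.height / image_h, 0.0, 1.0)
        probs = np.full(n_classes, 0.0)
        probs[min(class_id, n_classes - 1)] = 1.0
        rows_box.append([cx, cy, bw, bh])
        rows_obj.append(conf)
        rows_cls.append(probs)

    for box, class_id in truth.boxes:
        conf = float(rng.uniform(*spec.conf_range))
        b = box
        if spec.box_jitter_px > 0:
            j = spec.box_jitter_px
            dx, dy = rng.uniform(-j, j, size=2)
            b = BoundingBox(
                max(0.0, box.x_min + dx), max(0.0, box.y_min + dy),
                min(float(image_w), box.x_max + dx), min(float(image_h), box.y_max + dy),
            )
        add_row(b, class_id, conf)
        if spec.duplicate_rate > 0 and rng.uniform() < spec.duplicate_rate:
            dup = BoundingBox(
                max(0.0, b.x_min + 1), max(0.0, b.y_min + 1),
                min(float(image_w), b.x_max + 1), min(float(image_h), b.y_max + 1),
            )
            add_row(dup, class_id, conf * float(rng.uniform(0.6, 0.9)))

    for _ in range(spec.n_spurious):
        bw = float(rng.uniform(0.01, 0.05))
        bh = float(rng.uniform(0.01, 0.05))
        cx = float(rng.uniform(bw / 2, 1 - bw / 2))
        cy = float(rng.uniform(bh / 2, 1 - bh / 2))
        box = BoundingBox(
            (cx - bw / 2) * image_w, (cy - bh / 2) * image_h,
            (cx + bw / 2) * image_w, (cy + bh / 2) * image_h,
        )
        add_row(box, int(rng.integers(0, n_classes)), float(rng.uniform(*spec.spurious_conf_range)))

    if not rows_box:
        return RawDetectionGrid(
            boxes=np.zeros((0, 4)), objectness=np.zeros(0),
            class_probs=np.zeros((0, n_classes)),
        )
    return RawDetectionGrid(
        boxes=np.array(rows_box), objectness=np.array(rows_obj),
        class_probs=np.array(rows_cls),
    )


def derive_seed(master_seed: int, *indices: int) -> int:
    """Stable per-image seed below 2³¹ from a master seed and indices."""
    ss = np.random.SeedSequence([int(master_seed), *map(int, indices)])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class ExperimentRecord:
    quantity: int
    replicate: int
    rng_seed: int
    count: int
    true_count: int


@dataclass
class ExperimentResult:
    """Replicate counting experiment: per-image records and summaries."""

    records: list[ExperimentRecord]
    summaries: dict[int, CountSummary]  # quantity → mean ± SE

    def to_dict(self) -> dict:
        return {
            "records": [vars(r) for r in self.records],
            "summaries": {
                str(q): {
                    "mean": s.mean, "se": s.se, "n_replicates": s.n_replicates,
                    "mean_abs_deviation": s.mean_abs_deviation,
                }
                for q, s in self.summaries.items()
            },
        }


def run_accuracy_experiment(
    quantities: Sequence[int],
    replicates: int,
    config_template: SimConfig | None = None,
    counter: Callable[[SimSample], int] | None = None,
    master_seed: int = 0,
) -> ExperimentResult:
    """Replicate counting accuracy experiment on synthetic images.

    For each target quantity, generates ``replicates`` images under the
    template config (with per-image seeds derived deterministically from
    ``master_seed``), applies ``counter`` to each sample, and summarizes
    the counts as mean ± SE against the known truth.  The default
    counter runs the image-processing pipeline with default parameters.
    """
    from phenoseed.counting import count_seeds  # local import avoids a cycle

    if replicates < 2:
        raise InvalidInputError("need at least 2 replicates for a standard error")
    template = config_template or SimConfig()
    if counter is None:
        counter = lambda sample: count_seeds(sample.image).count  # noqa: E731

    records: list[ExperimentRecord] = []
    summaries: dict[int, CountSummary] = {}
    for qi, quantity in enumerate(quantities):
        counts: list[int] = []
        for rep in range(replicates):
            seed = derive_seed(master_seed, qi, rep)
            cfg = replace(template, n_seeds=int(quantity), rng_seed=seed)
            try:
                sample = generate_image(cfg)
                c = int(counter(sample))
            except Exception as exc:
                raise type(exc)(
                    f"{exc} [quantity={quantity}, replicate={rep}, seed={seed}]"
                ) from exc
            counts.append(c)
            records.append(
                ExperimentRecord(
                    quantity=int(quantity), replicate=rep, rng_seed=seed,
                    count=c, true_count=int(quantity),
                )
            )
        summaries[int(quantity)] = count_summary(counts, true_count=float(quantity))
    return ExperimentResult(records=records, summaries=summaries)
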