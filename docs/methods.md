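# Methods

## The counting model

`phenoseed` treats a seed-counting photograph as a two-class scene: a
near-uniform background and a minority of compact, roughly convex
foreground objects. Under that assumption counting reduces to
segmentation: after intensity thresholding, each connected foreground
component is one seed, and the count is the number of components that
survive a noise filter.

The IP pipeline is, in order:

1. **Grayscale** — BT.601 luma (0.299 R + 0.587 G + 0.114 B), rounded
   half-up to 8 bits. BT.601 is the bit-reproducible convention shared
   by mainstream imaging libraries; a gray pixel (v, v, v) maps to v.
2. **Gaussian blur** — separable convolution, default 5 × 5 kernel with
   σ = 1.0 px, kernel renormalized to sum 1, reflect border padding.
   The 5-px scale suppresses single-pixel sensor noise without eroding
   seed boundaries at the default working resolution; reflect padding
   avoids the dark frame a zero pad would create, which would otherwise
   bias thresholding near the image edge.
3. **Threshold** — Otsu's method on the 256-bin histogram (the level
   maximizing between-class variance; ties go to the smallest level),
   chosen because it is parameter-free and reproducible under the
   controlled lighting the setup assumes. A fixed level can be supplied
   instead. A perfectly constant image has no separating threshold and
   is reported as an empty scene (count 0, with a warning) rather than
   an error.
4. **Polarity** — `auto` by default: foreground is whichever side of
   the threshold occupies < 50 % of pixels. This handles both dark
   seeds on white paper and light seeds on a black table without user
   input; explicit `bright`/`dark` overrides exist.
5. **Connected components** — 8-connectivity by default (diagonal
   contact keeps a seed whole); 4-connectivity by configuration.
6. **Area filter** — regions below a floor are discarded as specks.
   The default floor is 10 px² *at the native 3024 × 4032 sensor
   frame*, scaled by the actual image area, so the same physical floor
   applies at any working resolution. An optional ceiling exists but is
   off by default.
7. **Ordering and features** — regions sort by bounding-box y, then x,
   then label; ids are assigned 1..N in that order. Each seed gets its
   tight half-open bounding box, length (longer box side × mm/px),
   width (shorter side), aspect ratio L/W ≥ 1, pixel area and centroid.
   Calibration is a single linear mm-per-pixel factor, given directly
   or derived from a reference object of known length
   (`CalibrationScale.from_reference`); with the default factor 1.0 the
   "mm" fields are simply pixels.

External contours are traced per region (Moore border following from
the topmost-leftmost pixel, interior holes ignored) and compressed by
deleting vertices that continue a straight run; they feed overlays and
reporting. The count itself is the component count — on external-only
contours the two notions coincide, and components make the contract
simpler.

**Touching seeds are not split.** There is no watershed stage; a
cluster of touching seeds is one region and counts once. The pipeline
flags any region whose area exceeds 3× the median region area (the
`cluster_area_factor`) as a probable cluster, and flags border-touching
regions, but neither flag changes the count. This is a deliberate
scope boundary: the degradation tests document that with clusters the
count is biased low, and with speck noise and the area filter disabled
it is biased high — the two failure directions a user should expect.

## Detector post-processing

The deployment chain for a single-stage detector's raw output grid:

* **Decode** — per record, class = argmax of class probabilities;
  confidence = objectness × max class probability (the detector-family
  convention for combining the two scores the format carries;
  objectness-only mode is available); box (cx ± w/2, cy ± h/2) scales
  to pixels and clips to the image. Records whose box degenerates to
  zero width/height after clipping are dropped.
* **Confidence filter** — keeps detections with confidence strictly
  greater than τ (default 0.25). The strictness at the boundary is part
  of the contract: a detection at exactly τ is discarded.
* **NMS** — greedy, class-wise by default (class-agnostic mode for
  single-species images): repeatedly take the highest-confidence
  survivor and suppress same-class detections with IoU > 0.45.
  Confidence ties break toward the larger box, then the earlier index,
  making the result deterministic.
* **Count** — the number of survivors across all classes.

Neither τ = 0.25 nor IoU = 0.45 is canonical; both are the common
defaults of this detector family and both are exposed as flags.

## Evaluation

Matching is PASCAL-style: predictions in descending confidence, each
taking the unmatched same-class ground-truth box of highest IoU,
counted as TP when that IoU ≥ 0.5 (the mAP50 convention), one-to-one.
AP uses all-point interpolation — the exact area under the
precision–recall staircase after imposing the monotone non-increasing
precision envelope — because it is deterministic and is the modern
convention; the legacy 11-point variant is available behind a flag.
mAP is the unweighted mean of per-class APs; a class-agnostic mode
pools all seeds into one class, since a counting image typically holds
a single species. Degenerate denominators (no predictions, no ground
truth) yield 0 (or a vacuous 1 for an empty class with no predictions)
and are logged; real evaluations never reach them.

Replicate counts are summarized as mean ± SE with SE = sample standard
deviation (n − 1) / √n. With six replicates of which one is off by one,
this yields the 10.17 ± 0.17 pattern characteristic of such tables.

## The synthetic generator

The generator emulates a desk imaging setup, not photorealism. Seeds
are rotated filled ellipses with per-seed uniform jitter in major axis
(default 22–36 px), aspect ratio (1.2–2.2), orientation (0–π) and fill
colour (a dark-brown RGB band); presets for small round and large
elongated seed habits ship alongside. Backgrounds are calibrated flat
colours for white A4 paper, an orange table and a black table, with the
luminance ordering black < orange < white. The default canvas is
1008 × 1344 px — the native 3024 × 4032 portrait frame at 1/3 scale,
keeping the full suite fast while preserving aspect ratio; any size is
accepted.

Placement is rejection sampling with a 10,000-attempt cap and an
explicit capacity error naming the limiting parameter. Unless touching
is allowed, centres keep a minimum separation that defaults to the
largest major axis plus twice the default blur kernel — enough that
blurred seeds can never merge, which is what makes the exact-count
guarantee hold. Degradations are applied after the ground truth is
fixed: additive Gaussian pixel noise, then a multiplicative
left-to-right illumination ramp (darkest at the left edge); both
default to 0 so the base suite is exact. Optional speck noise injects
small foreground-coloured squares that are *not* part of the ground
truth — they emulate debris/sensor specks and exercise the area filter.
Identical configurations (including the seed) are bit-identical.

What the generator does **not** emulate — shadows, specular
highlights, perspective and lens distortion, textured backgrounds,
seed-coat texture, non-elliptical seed outlines — bounds what passing
tests show: they validate the algorithmic chain under the two-class
scene assumption, not robustness to real-world photographic artifacts.

The experiment harness derives one RNG seed per image from a master
seed via `numpy.random.SeedSequence([master, quantity_index,
replicate])` (reduced below 2³¹), so each image is individually
reproducible. Replicate experiments default to 6 replicates at
quantities 10/70/100 — small, medium and large batches typical of
desk counting.

## Numerical choices and edge cases

* Boxes are half-open `[x_min, x_max) × [y_min, y_max)`, 0-based,
  x = column, y = row, origin top-left — stated in every output. With
  this convention the continuous box area equals the pixel count for
  integer boxes, so analytic IoU and pixel-counting IoU agree exactly.
* Otsu ties break toward the smallest level (first argmax).
* Sorting ties break (y_min, x_min, label); NMS ties break
  (confidence, area, input index); both make outputs order-independent.
* YOLO-format I/O writes 6-decimal normalized coordinates; round-trips
  are lossless to that precision. Malformed lines report file and line
  number.
* Chain simplification removes only *forward*-collinear vertices
  (cross = 0 and positive dot); spike vertices are kept so the traced
  shape is preserved exactly.

## Problem sizes

The test suite and the acceptance script work at the 1008 × 1344
default canvas with up to 100–200 seeds per image and six replicates
per quantity; oracle-equivalence suites use 12 × 12 masks (200 random
instances) and ≤ 7-prediction AP instances (100 random instances).
These sizes were chosen as the smallest at which every guarantee is
exercised in full.

## Known limitations

* No de-clumping: clustered seeds undercount (flagged, not fixed).
* No lighting normalization, shadow correction or white balance; a
  strong illumination gradient can defeat a single global threshold.
* Species classification and viability are out of scope; the detector
  path post-processes externally produced grids only.
* mm calibration is a single isotropic factor; no automatic reference
  detection.
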