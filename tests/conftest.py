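"""Shared fixtures and independent oracles used across the suite."""

from __future__ import annotations

import numpy as np
import pytest

from phenoseed.simulate import SimConfig, generate_image
from phenoseed.types import BoundingBox


@pytest.fixture(scope="session")
def sample_ten_seeds():
    """A deterministic 10-seed image on white paper, no degradations."""
    return generate_image(SimConfig(n_seeds=10, rng_seed=1234))


def flood_fill_components(mask: np.ndarray, connectivity: int) -> list[set[tuple[int, int]]]:
    """Independent connected-components oracle: explicit-stack flood fill."""
    if connectivity == 4:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        steps = [(dx, dy) for dx in (-1, 0, 1) for dy in (-1, 0, 1) if (dx, dy) != (0, 0)]
    h, w = mask.shape
    seen = np.zeros_like(mask, dtype=bool)
    components = []
    for y in range(h):
        for x in range(w):
            if mask[y, x] and not seen[y, x]:
                comp = set()
                stack = [(x, y)]
                seen[y, x] = True
                while stack:
                    cx, cy = stack.pop()
                    comp.add((cx, cy))
                    for dx, dy in steps:
                        nx, ny = cx + dx, cy + dy
                        if 0 <= nx < w and 0 <= ny < h and mask[ny, nx] and not seen[ny, nx]:
                            seen[ny, nx] = True
                            stack.append((nx, ny))
                components.append(comp)
    return components


def pixel_count_iou(a: BoundingBox, b: BoundingBox, grid: int) -> float:
    """Integer pixel-counting IoU oracle on a grid×grid lattice."""
    ys, xs = np.mgrid[0:grid, 0:grid]

    def inside(box):
        return (xs >= box.x_min) & (xs < box.x_max) & (ys >= box.y_min) & (ys < box.y_max)

    ia, ib = inside(a), inside(b)
    union = (ia | ib).sum()
    return (ia & ib).sum() / union if union else 0.0


def staircase_ap(ranked: list[tuple[float, bool]], n_gt: int) -> float:
    """Brute-force AP oracle: recompute P/R at every rank, integrate the
    upper precision envelope over recall, rank by rank."""
    if n_gt == 0:
        return 1.0 if not ranked else 0.0
    points = []
    tp = fp = 0
    for _, is_tp in ranked:
        tp += is_tp
        fp += not is_tp
        points.append((tp / n_gt, tp / (tp + fp)))
    ap = 0.0
    prev_recall = 0.0
    for k, (r, _) in enumerate(points):
        if r > prev_recall:
            envelope = max(p for rr, p in points[k:] if rr >= r)
            ap += (r - prev_recall) * envelope
            prev_recall = r
    return ap


def scan_simplify(points: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Collinearity-scan simplification oracle: repeatedly delete the
    first vertex that continues a straight run, until none remains."""
    pts = list(points)
    removed = True
    while removed and len(pts) > 2:
        removed = False
        n = len(pts)
        for i in range(n):
            a, b, c = pts[(i - 1) % n], pts[i], pts[(i + 1) % n]
            ab = (b[0] - a[0], b[1] - a[1])
            bc = (c[0] - b[0], c[1] - b[1])
            if ab[0] * bc[1] - ab[1] * bc[0] == 0 and ab[0] * bc[0] + ab[1] * bc[1] > 0:
                del pts[i]
                removed = True
                break
    return pts
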