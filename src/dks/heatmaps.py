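"""Ground-truth heatmap construction and coordinate decoding.

Keypoints are supervised as unnormalized Gaussian response maps with peak 1
(the standard target for hourglass heatmap regression).  Ground truth is
built at several spatial scales — by default 1/8, 1/4 and 1/2 of the input,
plus full resolution for the fusion refiner — with the keypoint coordinate
and the Gaussian width scaled proportionally (sigma floored at 0.5 px so the
peak stays localized on coarse grids).

Anatomical-aware targets encode the co-occurrence of keypoint pairs and
triplets: the pair (triplet) map is the element-wise maximum of the
constituent single-point maps, which keeps values in [0, 1] and is invariant
to permutation within the pair/triple.

Decoding is argmax plus the standard quarter-pixel offset toward the higher
of the two axis neighbours; argmax ties resolve to the smaller (row, col).
A flat (all-equal) channel decodes to the grid centre with a low-confidence
flag instead of raising.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import KeypointSet, SchemaError, ViewId, schema_for

__all__ = [
    "DEFAULT_SCALES",
    "DEFAULT_SIGMA_PX",
    "HeatmapPyramid",
    "AASTargets",
    "gaussian_map",
    "build_stack",
    "build_pyramid",
    "build_aas_targets",
    "decode",
    "decode_points",
]

DEFAULT_SCALES: tuple[float, ...] = (1 / 8, 1 / 4, 1 / 2, 1.0)
DEFAULT_SIGMA_PX = 2.0
MIN_SIGMA_PX = 0.5
LOW_CONFIDENCE = "low_confidence"
OFF_GRID = "off_grid"


def gaussian_map(
    point: Sequence[float], shape: tuple[int, int], sigma_px: float
) -> np.ndarray:
    """Unnormalized Gaussian response centred at ``point`` = (x, y).

    ``grid[r, c] = exp(-((c - x)^2 + (r - y)^2) / (2 sigma^2))``; the peak
    value is 1 when the point lies on a grid cell.  Points outside the grid
    yield a truncated (possibly all-small) map rather than an error.
    """
    if sigma_px <= 0:
        raise ValueError("sigma_px must be > 0")
    h, w = shape
    x, y = float(point[0]), float(point[1])
    cols = np.arange(w, dtype=float)
    rows = np.arange(h, dtype=float)
    gx = np.exp(-((cols - x) ** 2) / (2.0 * sigma_px**2))
    gy = np.exp(-((rows - y) ** 2) / (2.0 * sigma_px**2))
    return np.outer(gy, gx)


def point_off_grid(point: Sequence[float], shape: tuple[int, int]) -> bool:
    h, w = shape
    x, y = point
    return not (0 <= x <= w - 1 and 0 <= y <= h - 1)


@dataclass
class HeatmapPyramid:
    """Per-scale ground-truth (or predicted) keypoint response stacks.

    ``levels[i]`` has shape (K, h_i, w_i) with ``h_i = round(scale_i * H)``,
    one channel per keypoint in schema order.
    """

    view: ViewId
    scales: tuple[float, ...]
    levels: list[np.ndarray]
    input_shape: tuple[int, int]

    def level_for(self, scale: float) -> np.ndarray:
        for s, lv in zip(self.scales, self.levels):
            if abs(s - scale) < 1e-12:
                return lv
        raise KeyError(f"no level at scale {scale}")


@dataclass
class AASTargets:
    """Pairwise / triplet co-occurrence maps for one view.

    ``pair_maps``: (C(K,2), h, w); ``triplet_maps``: (C(K,3), h, w); the
    index order follows ``itertools.combinations`` over schema order.
    """

    view: ViewId
    pair_maps: np.ndarray
    triplet_maps: np.ndarray

    @property
    def pair_index(self) -> list[tuple[int, int]]:
        k = schema_for(self.view).count
        return list(itertools.combinations(range(k), 2))

    @property
    def triplet_index(self) -> list[tuple[int, int, int]]:
        k = schema_for(self.view).count
        return list(itertools.combinations(range(k), 3))


def build_stack(
    points: np.ndarray, shape: tuple[int, int], sigma_px: float
) -> np.ndarray:
    """(K, h, w) stack of single-point Gaussian maps."""
    return np.stack([gaussian_map(p, shape, sigma_px) for p in points])


def build_pyramid(
    kps: KeypointSet,
    input_shape: tuple[int, int],
    scales: Sequence[float] = DEFAULT_SCALES,
    sigma_px: float = DEFAULT_SIGMA_PX,
) -> HeatmapPyramid:
    """Ground-truth pyramid for one view.

    Per scale ``s``: grid = round(s*H) x round(s*W), keypoint coordinates are
    multiplied by ``s`` and drawn with sigma ``max(s * sigma_px, 0.5)``.
    Scales must be ascending and in (0, 1].
    """
    if kps.points.shape[0] == 0:
        raise SchemaError("empty keypoint set")
    scales = tuple(float(s) for s in scales)
    if any(not (0 < s <= 1) for s in scales) or list(scales) != sorted(scales):
        raise ValueError("scales must be ascending and in (0, 1]")
    h, w = input_shape
    levels = []
    for s in scales:
        hs, ws = int(round(s * h)), int(round(s * w))
        sigma_s = max(s * sigma_px, MIN_SIGMA_PX)
        levels.append(build_stack(kps.points * s, (hs, ws), sigma_s))
    return HeatmapPyramid(
        view=kps.view, scales=scales, levels=levels, input_shape=(h, w)
    )


def build_aas_targets(
    kps: KeypointSet,
    shape: tuple[int, int],
    sigma_px: float = DEFAULT_SIGMA_PX,
) -> AASTargets:
    """Pair/triplet co-occurrence targets: element-wise max of single maps."""
    k = kps.points.shape[0]
    if k < 2:
        raise SchemaError("need at least 2 keypoints for pair targets")
    singles = build_stack(kps.points, shape, sigma_px)
    pairs = np.stack(
        [np.maximum(singles[i], singles[j]) for i, j in itertools.combinations(range(k), 2)]
    )
    triplets = np.stack(
        [
            np.maximum(np.maximum(singles[i], singles[j]), singles[l])
            for i, j, l in itertools.combinations(range(k), 3)
        ]
    )
    return AASTargets(view=kps.view, pair_maps=pairs, triplet_maps=triplets)


def _decode_channel(grid: np.ndarray) -> tuple[float, float, bool]:
    """Argmax + quarter-pixel refinement for one channel.

    Returns (x, y, degenerate).  Flat channels fall back to the grid centre.
    """
    h, w = grid.shape
    if grid.max() == grid.min():
        return (w - 1) / 2.0, (h - 1) / 2.0, True
    flat_idx = int(np.argmax(grid))  # row-major: ties go to smaller (row, col)
    r, c = divmod(flat_idx, w)
    x, y = float(c), float(r)
    if 0 < c < w - 1:
        right, left = grid[r, c + 1], grid[r, c - 1]
        if right > left:
            x += 0.25
        elif right < left:
            x -= 0.25
    if 0 < r < h - 1:
        below, above = grid[r + 1, c], grid[r - 1, c]
        if below > above:
            y += 0.25
        elif below < above:
            y -= 0.25
    return x, y, False


def decode_points(grid_stack: np.ndarray) -> tuple[np.ndarray, list[bool]]:
    """Decode a (K, h, w) stack to (K, 2) coordinates plus degeneracy flags."""
    grid_stack = np.asarray(grid_stack, dtype=float)
    coords = np.empty((grid_stack.shape[0], 2), dtype=float)
    degenerate = []
    for i, ch in enumerate(grid_stack):
        x, y, bad = _decode_channel(ch)
        coords[i] = (x, y)
        degenerate.append(bad)
    return coords, degenerate


def decode(grid_stack: np.ndarray, view: ViewId, scale: float = 1.0) -> KeypointSet:
    """Decode a heatmap stack into a KeypointSet at input resolution.

    ``scale`` is the stack's resolution relative to the input; decoded
    coordinates are divided by it.  One channel per schema keypoint.
    """
    schema = schema_for(view)
    if grid_stack.shape[0] != schema.count:
        raise SchemaError(
            f"{view} expects {schema.count} channels, got {grid_stack.shape[0]}"
        )
    coords, degenerate = decode_points(grid_stack)
    flags = tuple(
        f"{LOW_CONFIDENCE}:{schema.names[i]}" for i, bad in enumerate(degenerate) if bad
    )
    return KeypointSet(view=view, points=coords / float(scale), flags=flags)
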