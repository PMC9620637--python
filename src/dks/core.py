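"""Shared domain types for echocardiographic keypoint stadiometry.

Coordinate convention used throughout the package: ``x`` increases rightward
(columns), ``y`` increases downward (rows), the origin is the centre of the
top-left pixel, coordinates are 0-based and may be sub-pixel (continuous).

Three transthoracic-echo views are modelled:

* ``PSSAX`` — parasternal short-axis of the aorta (3 keypoints),
* ``SXLAX`` — subxiphoid long-axis of the two atria (4 keypoints),
* ``A4C``   — apical four-chamber (4 keypoints),

for a total of 11 keypoints per case.  Each view image carries a scale
(millimetres per pixel, equivalently an on-image scale bar) that converts
pixel distances to absolute millimetre measurements.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "ViewId",
    "KeypointSchema",
    "ImageFrame",
    "ScaleInfo",
    "KeypointSet",
    "CaseRecord",
    "SchemaError",
    "schema_for",
    "TOTAL_KEYPOINTS",
]


class SchemaError(ValueError):
    """Raised when a view or keypoint set does not match the fixed schema."""


class ViewId(str, enum.Enum):
    """The three standard TTE views used for ASD assessment."""

    PSSAX = "PSSAX"
    SXLAX = "SXLAX"
    A4C = "A4C"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class KeypointSchema:
    """Fixed, ordered keypoint roles for one view."""

    view: ViewId
    names: tuple[str, ...]

    @property
    def count(self) -> int:
        return len(self.names)

    @property
    def n_pairs(self) -> int:
        k = self.count
        return k * (k - 1) // 2

    @property
    def n_triplets(self) -> int:
        k = self.count
        return k * (k - 1) * (k - 2) // 6


# Keypoint ordering within each view is fixed; a deterministic order is
# required to pair rim landmarks with defect endpoints during measurement.
_SCHEMAS: dict[ViewId, KeypointSchema] = {
    ViewId.PSSAX: KeypointSchema(
        ViewId.PSSAX, ("defect_end_A", "defect_end_B", "wall_point")
    ),
    ViewId.SXLAX: KeypointSchema(
        ViewId.SXLAX,
        ("defect_end_sup", "defect_end_inf", "svc_point", "ivc_point"),
    ),
    ViewId.A4C: KeypointSchema(
        ViewId.A4C,
        ("defect_end_roof", "defect_end_mitral", "roof_point", "mitral_point"),
    ),
}

TOTAL_KEYPOINTS = sum(s.count for s in _SCHEMAS.values())  # 11


def schema_for(view: ViewId | str) -> KeypointSchema:
    """Return the fixed keypoint schema of ``view``.

    Total and deterministic: PSSAX -> 3 points, SXLAX -> 4, A4C -> 4.
    Raises :class:`SchemaError` for an unknown view.
    """
    try:
        view = ViewId(view)
    except ValueError as exc:
        raise SchemaError(f"unknown view: {view!r}") from exc
    return _SCHEMAS[view]


@dataclass
class ScaleInfo:
    """Millimetre calibration of one frame.

    ``mm_per_pixel`` must equal ``scale_bar_length_mm / scale_bar_length_px``;
    the redundant representation mirrors how the on-image measuring scale is
    recorded as metadata alongside each echocardiogram.
    """

    mm_per_pixel: float
    scale_bar_length_px: float
    scale_bar_length_mm: float

    def __post_init__(self) -> None:
        if self.mm_per_pixel <= 0:
            raise ValueError("mm_per_pixel must be > 0")
        if self.scale_bar_length_px <= 0 or self.scale_bar_length_mm <= 0:
            raise ValueError("scale bar lengths must be > 0")
        implied = self.scale_bar_length_mm / self.scale_bar_length_px
        if abs(implied - self.mm_per_pixel) > 1e-9 * max(self.mm_per_pixel, 1.0):
            raise ValueError(
                "inconsistent scale: mm_per_pixel "
                f"{self.mm_per_pixel} vs bar-implied {implied}"
            )

    @classmethod
    def from_mm_per_pixel(
        cls, mm_per_pixel: float, scale_bar_length_mm: float = 40.0
    ) -> "ScaleInfo":
        """Build from a mm/px factor, deriving the scale-bar pixel length."""
        return cls(
            mm_per_pixel=mm_per_pixel,
            scale_bar_length_px=scale_bar_length_mm / mm_per_pixel,
            scale_bar_length_mm=scale_bar_length_mm,
        )

    def to_dict(self) -> dict:
        return {
            "mm_per_pixel": self.mm_per_pixel,
            "scale_bar_length_px": self.scale_bar_length_px,
            "scale_bar_length_mm": self.scale_bar_length_mm,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScaleInfo":
        if "scale_bar_length_px" in d:
            return cls(
                mm_per_pixel=float(d["mm_per_pixel"]),
                scale_bar_length_px=float(d["scale_bar_length_px"]),
                scale_bar_length_mm=float(d["scale_bar_length_mm"]),
            )
        return cls.from_mm_per_pixel(float(d["mm_per_pixel"]))


@dataclass
class ImageFrame:
    """A single grayscale echo frame, intensities normalized to 0-255."""

    pixels: np.ndarray  # (H, W) uint8
    view: ViewId

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("pixels must be a non-empty 2-D grid")
        if px.min() < 0 or px.max() > 255:
            raise ValueError("intensities must lie in [0, 255]")
        self.pixels = px.astype(np.uint8)
        self.view = ViewId(self.view)

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])


@dataclass
class KeypointSet:
    """Ordered sub-pixel keypoint coordinates for one view.

    ``points`` is an (K, 2) array of (x, y) in schema order.  ``flags`` marks
    low-confidence points produced by degenerate heatmap decoding.
    """

    view: ViewId
    points: np.ndarray
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.view = ViewId(self.view)
        pts = np.asarray(self.points, dtype=float)
        schema = schema_for(self.view)
        if pts.shape != (schema.count, 2):
            raise SchemaError(
                f"{self.view.value} expects {schema.count} points, "
                f"got array of shape {pts.shape}"
            )
        self.points = pts

    @property
    def schema(self) -> KeypointSchema:
        return schema_for(self.view)

    def point(self, name: str) -> np.ndarray:
        """Coordinate of the keypoint with role ``name``."""
        try:
            idx = self.schema.names.index(name)
        except ValueError as exc:
            raise SchemaError(f"no keypoint {name!r} in view {self.view.value}") from exc
        return self.points[idx]

    def in_bounds(self, frame: ImageFrame) -> bool:
        x, y = self.points[:, 0], self.points[:, 1]
        return bool(
            (x >= 0).all()
            and (x < frame.width).all()
            and (y >= 0).all()
            and (y < frame.height).all()
        )

    def to_dict(self) -> dict:
        return {
            "view": self.view.value,
            "points": [
                {"name": n, "x": float(x), "y": float(y)}
                for n, (x, y) in zip(self.schema.names, self.points)
            ],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "KeypointSet":
        view = ViewId(d["view"])
        schema = schema_for(view)
        by_name = {p["name"]: (float(p["x"]), float(p["y"])) for p in d["points"]}
        missing = set(schema.names) - set(by_name)
        if missing:
            raise SchemaError(f"missing keypoints for {view.value}: {sorted(missing)}")
        pts = np.array([by_name[n] for n in schema.names], dtype=float)
        return cls(view=view, points=pts)


@dataclass
class CaseRecord:
    """One patient case: three view frames, scales, optional truth."""

    case_id: str
    frames: dict[ViewId, ImageFrame]
    scales: dict[ViewId, ScaleInfo]
    keypoints: Optional[dict[ViewId, KeypointSet]] = None
    label_plan: Optional[str] = None  # "transcatheter" | "surgical"
    label_size_mm: Optional[int] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for coll, what in ((self.frames, "frame"), (self.scales, "scale")):
            missing = set(ViewId) - set(coll)
            if missing:
                raise ValueError(
                    f"case {self.case_id}: missing {what} for "
                    f"{sorted(v.value for v in missing)}"
                )
        if self.label_plan is not None and self.label_plan not in (
            "transcatheter",
            "surgical",
        ):
            raise ValueError(f"invalid plan label {self.label_plan!r}")
        if self.label_size_mm is not None and self.label_plan != "transcatheter":
            raise ValueError("label_size_mm requires label_plan == 'transcatheter'")


def write_annotation(path: str | Path, case_id: str, kps: KeypointSet, scale: ScaleInfo) -> None:
    """Write the per-view keypoint annotation JSON used on disk."""
    payload = {"case_id": case_id, **kps.to_dict(), "scale": scale.to_dict()}
    Path(path).write_text(json.dumps(payload, indent=1))


def read_annotation(path: str | Path) -> tuple[str, KeypointSet, ScaleInfo]:
    d = json.loads(Path(path).read_text())
    return d["case_id"], KeypointSet.from_dict(d), ScaleInfo.from_dict(d["scale"])


def all_views() -> Sequence[ViewId]:
    return (ViewId.PSSAX, ViewId.SXLAX, ViewId.A4C)
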