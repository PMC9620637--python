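"""Convert keypoint coordinates plus the image scale into the named
millimetre measurements used by the closure rules.

Per view:

* PSSAX — defect diameter (between the two defect endpoints) and the rim to
  the atrial/aortic wall, taken from the wall landmark to the *nearer* defect
  endpoint (PSSAX has a single wall landmark for two endpoints).
* SXLAX — defect diameter, rim to the superior vena cava (from the superior
  endpoint) and rim to the inferior vena cava (from the inferior endpoint).
* A4C — defect diameter, rims to the atrial roof and the mitral annulus
  (endpoint-specific), and the atrial septum length, defined here as the
  roof-landmark-to-mitral-landmark distance; for collinear geometry this
  coincides with roof rim + defect + mitral rim.

All distances are Euclidean in pixels, converted by ``mm_per_pixel``.
Measurement names are the stable keys consumed by the rule engine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Mapping

import numpy as np

from .core import KeypointSet, ScaleInfo, SchemaError, ViewId

__all__ = [
    "MeasurementSet",
    "pixel_distance",
    "to_mm",
    "measure_view",
    "assemble",
]


class ScaleError(ValueError):
    pass


def pixel_distance(p, q) -> float:
    """Euclidean distance between two (x, y) points, in pixels."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if not (np.isfinite(p).all() and np.isfinite(q).all()):
        raise ValueError("coordinates must be finite")
    return float(math.hypot(p[0] - q[0], p[1] - q[1]))


def to_mm(d_px: float, scale: ScaleInfo) -> float:
    """Convert a pixel distance to millimetres via the frame's scale."""
    if d_px < 0:
        raise ValueError("distance must be >= 0")
    if scale.mm_per_pixel <= 0:
        raise ScaleError("mm_per_pixel must be > 0")
    return float(d_px) * scale.mm_per_pixel


@dataclass
class MeasurementSet:
    """Named millimetre measurements pooled over the three views."""

    defect_pssax_mm: float
    defect_sxlax_mm: float
    defect_a4c_mm: float
    rim_wall_mm: float
    rim_svc_mm: float
    rim_ivc_mm: float
    rim_roof_mm: float
    rim_mitral_mm: float
    septum_length_mm: float

    def __post_init__(self) -> None:
        for name, value in self.to_dict().items():
            if name == "max_defect_diameter_mm":
                continue
            if value < 0:
                raise ValueError(f"{name} must be >= 0, got {value}")

    @property
    def max_defect_diameter_mm(self) -> float:
        return max(self.defect_pssax_mm, self.defect_sxlax_mm, self.defect_a4c_mm)

    def to_dict(self) -> Dict[str, float]:
        d = {
            "defect_pssax_mm": self.defect_pssax_mm,
            "defect_sxlax_mm": self.defect_sxlax_mm,
            "defect_a4c_mm": self.defect_a4c_mm,
            "rim_wall_mm": self.rim_wall_mm,
            "rim_svc_mm": self.rim_svc_mm,
            "rim_ivc_mm": self.rim_ivc_mm,
            "rim_roof_mm": self.rim_roof_mm,
            "rim_mitral_mm": self.rim_mitral_mm,
            "septum_length_mm": self.septum_length_mm,
        }
        d["max_defect_diameter_mm"] = self.max_defect_diameter_mm
        return d

    @classmethod
    def from_views(cls, per_view: Mapping[ViewId, Mapping[str, float]]) -> "MeasurementSet":
        return assemble(per_view)


def measure_view(kps: KeypointSet, scale: ScaleInfo) -> Dict[str, float]:
    """Measure one view; returns a name -> mm mapping for that view."""
    pts = kps.points
    schema = kps.schema
    if pts.shape[0] != schema.count:  # defensive; KeypointSet enforces this
        raise SchemaError("point count does not match schema")

    def mm(p, q) -> float:
        return to_mm(pixel_distance(p, q), scale)

    if kps.view is ViewId.PSSAX:
        a, b, wall = pts
        return {
            "defect_pssax_mm": mm(a, b),
            "rim_wall_mm": min(mm(wall, a), mm(wall, b)),
        }
    if kps.view is ViewId.SXLAX:
        sup, inf, svc, ivc = pts
        return {
            "defect_sxlax_mm": mm(sup, inf),
            "rim_svc_mm": mm(sup, svc),
            "rim_ivc_mm": mm(inf, ivc),
        }
    if kps.view is ViewId.A4C:
        roof_end, mitral_end, roof, mitral = pts
        return {
            "defect_a4c_mm": mm(roof_end, mitral_end),
            "rim_roof_mm": mm(roof_end, roof),
            "rim_mitral_mm": mm(mitral_end, mitral),
            "septum_length_mm": mm(roof, mitral),
        }
    raise SchemaError(f"unknown view {kps.view!r}")  # pragma: no cover


def assemble(per_view: Mapping[ViewId, Mapping[str, float]]) -> MeasurementSet:
    """Pool the three per-view measurement mappings into a MeasurementSet."""
    missing = set(ViewId) - {ViewId(v) for v in per_view}
    if missing:
        raise ValueError(f"missing views: {sorted(v.value for v in missing)}")
    merged: Dict[str, float] = {}
    for v in per_view:
        merged.update(per_view[v])
    return MeasurementSet(
        defect_pssax_mm=merged["defect_pssax_mm"],
        defect_sxlax_mm=merged["defect_sxlax_mm"],
        defect_a4c_mm=merged["defect_a4c_mm"],
        rim_wall_mm=merged["rim_wall_mm"],
        rim_svc_mm=merged["rim_svc_mm"],
        rim_ivc_mm=merged["rim_ivc_mm"],
        rim_roof_mm=merged["rim_roof_mm"],
        rim_mitral_mm=merged["rim_mitral_mm"],
        septum_length_mm=merged["septum_length_mm"],
    )


def measure_case(
    keypoints: Mapping[ViewId, KeypointSet], scales: Mapping[ViewId, ScaleInfo]
) -> MeasurementSet:
    """Measure all three views and assemble the pooled set."""
    return assemble(
        {v: measure_view(keypoints[v], scales[v]) for v in keypoints}
    )
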