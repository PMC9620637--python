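"""Synthetic echocardiogram-like case generator.

Real TTE studies of atrial septal defects are private clinical data, so this
module fabricates cases with *known* geometry: each of the three views shows
a sector-shaped grayscale frame containing a bright septum band interrupted
by a defect gap, bright landmark blobs at the rim anchor structures,
multiplicative Rayleigh speckle, Gaussian blur, and a randomized
millimetres-per-pixel scale.  Ground-truth keypoints are the analytic pixel
positions of the defect endpoints and rim anchors, and each case's closure
plan / occluder size label is obtained by applying the decision rules to the
ground-truth geometry — so the deterministic back half of the pipeline is
label-consistent by construction.

Geometry layout (identical construction in all views, parameterized per
view): keypoints lie on a straight septum line through the frame centre at a
random angle.  With the defect of diameter ``d`` centred at 0, the endpoints
sit at -d/2 and +d/2 along the line and each rim landmark sits a rim-length
farther out.  The A4C septum length is therefore exactly
roof rim + defect + mitral rim (collinear geometry).

Everything is a pure function of the seeds and parameters: the same seed
reproduces bit-identical images, annotations and labels.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

from .core import (
    CaseRecord,
    ImageFrame,
    KeypointSet,
    ScaleInfo,
    ViewId,
    all_views,
    write_annotation,
)
from .decision import OccluderCatalogue, RuleSet, decide, default_catalogue, default_ruleset
from .stadiometry import measure_case

__all__ = [
    "GeometryParams",
    "NoiseParams",
    "RenderError",
    "sample_geometry",
    "render_case",
    "simulate_cases",
    "generate_dataset",
    "geometry_keypoints",
]

DEFAULT_IMAGE_SIZE = 256
DEFAULT_SCALE_BAR_MM = 40.0
# mm/px sampling range for 256-px frames; rescaled as 256/size for other
# frame sizes (same anatomical field of view).
MM_PER_PIXEL_RANGE_256 = (0.08, 0.30)
# keypoints must stay within this fraction of the frame half-size
FIT_FRACTION = 0.30
BLOB_MARGIN_MM = 4.0

SEPTUM_INTENSITY = 225.0
LANDMARK_INTENSITY = 250.0
ENDPOINT_INTENSITY = 140.0
JET_INTENSITY = 255.0
SEPTUM_HALF_THICKNESS_MM = 1.3
LANDMARK_SIGMA_MM = 1.2
ENDPOINT_SIGMA_MM = 0.9


class RenderError(ValueError):
    """Geometry does not fit inside the image at the given scale."""


@dataclass(frozen=True)
class GeometryParams:
    """Analytic geometry of one synthetic case (all lengths in mm)."""

    defect_diameter_mm: dict[ViewId, float]
    rim_lengths_mm: dict[str, float]  # rim_wall, rim_svc, rim_ivc, rim_roof, rim_mitral
    septum_length_mm: float
    septum_angle_deg: float
    sector_apex: tuple[float, float] = (0.5, -0.05)  # fractions of frame size
    sector_span_deg: float = 80.0

    def __post_init__(self) -> None:
        for v, d in self.defect_diameter_mm.items():
            if not 2.0 <= d <= 35.0:
                raise ValueError(f"defect diameter {d} mm out of [2, 35] for {v}")
        for name, r in self.rim_lengths_mm.items():
            if r < 0:
                raise ValueError(f"rim {name} must be >= 0")
        floor = (
            self.defect_diameter_mm[ViewId.A4C]
            + self.rim_lengths_mm["rim_roof"]
            + self.rim_lengths_mm["rim_mitral"]
        )
        if self.septum_length_mm < floor - 1e-6:
            raise ValueError(
                "septum_length_mm must cover roof rim + defect + mitral rim"
            )


@dataclass(frozen=True)
class NoiseParams:
    """Image-corruption settings; zeros give a deterministic clean image."""

    speckle_strength: float = 0.35
    blur_sigma_px: float = 1.0
    background_level: int = 20
    jet_overlay: bool = False

    def __post_init__(self) -> None:
        if self.speckle_strength < 0 or self.blur_sigma_px < 0:
            raise ValueError("noise magnitudes must be >= 0")
        if not 0 <= self.background_level <= 255:
            raise ValueError("background_level must be in [0, 255]")


def sample_geometry(
    rng_seed: int,
    class_mix: float,
    rules: Optional[RuleSet] = None,
    catalogue: Optional[OccluderCatalogue] = None,
) -> GeometryParams:
    """Draw geometry whose rule-derived plan is transcatheter with
    probability ``class_mix`` (a Bernoulli draw selects the stratum, then the
    geometry is sampled inside it by construction).

    Transcatheter-eligible stratum: all rims in [5.5, 12] mm (clear of the
    5 mm rule threshold), defect base diameter in [5, 24] mm so that the
    suggested size exists and the septum exceeds it.  Ineligible stratum:
    either one deficient rim in [0.5, 4.5] mm or an oversize defect
    (base in [30.5, 33.5] mm) for which no catalogue device fits.
    """
    if not 0.0 <= class_mix <= 1.0:
        raise ValueError("class_mix must be in [0, 1]")
    rng = np.random.default_rng(rng_seed)
    eligible = rng.random() < class_mix

    rim_names = ("rim_wall", "rim_svc", "rim_ivc", "rim_roof", "rim_mitral")
    rims = {n: float(rng.uniform(5.5, 12.0)) for n in rim_names}
    if eligible:
        d_base = rng.uniform(5.0, 24.0)
    else:
        if rng.random() < 0.7:  # deficient-rim failure mode
            bad = rim_names[rng.integers(len(rim_names))]
            rims[bad] = float(rng.uniform(0.5, 4.5))
            d_base = rng.uniform(5.0, 24.0)
        else:  # oversize defect: no catalogue device fits
            d_base = rng.uniform(30.5, 33.5)
    diameters = {
        v: float(np.clip(d_base + rng.uniform(-1.5, 1.5), 2.0, 35.0))
        for v in all_views()
    }
    septum = (
        rims["rim_roof"] + diameters[ViewId.A4C] + rims["rim_mitral"]
    )
    return GeometryParams(
        defect_diameter_mm=diameters,
        rim_lengths_mm=rims,
        septum_length_mm=float(septum),
        septum_angle_deg=float(rng.uniform(-30.0, 30.0)),
    )


def _layout_mm(geom: GeometryParams, view: ViewId) -> tuple[np.ndarray, np.ndarray]:
    """1-D positions (mm) along the septum line, in schema order.

    Returns (keypoint_positions, band_segment_breaks) where the septum band
    covers the two segments outside the defect gap.
    """
    d = geom.defect_diameter_mm[view]
    r = geom.rim_lengths_mm
    if view is ViewId.PSSAX:
        pts = np.array([-d / 2, d / 2, d / 2 + r["rim_wall"]])
    elif view is ViewId.SXLAX:
        pts = np.array(
            [-d / 2, d / 2, -d / 2 - r["rim_svc"], d / 2 + r["rim_ivc"]]
        )
    else:  # A4C
        pts = np.array(
            [-d / 2, d / 2, -d / 2 - r["rim_roof"], d / 2 + r["rim_mitral"]]
        )
    band_lo = pts.min() - BLOB_MARGIN_MM
    band_hi = pts.max() + BLOB_MARGIN_MM
    breaks = np.array([band_lo, -d / 2, d / 2, band_hi])
    return pts, breaks


def geometry_keypoints(
    geom: GeometryParams,
    scale: ScaleInfo,
    image_size: int,
    center_px: Optional[tuple[float, float]] = None,
) -> dict[ViewId, KeypointSet]:
    """Analytic keypoint pixel positions for every view."""
    if center_px is None:
        center_px = ((image_size - 1) / 2.0, (image_size - 1) / 2.0)
    theta = np.deg2rad(geom.septum_angle_deg)
    u = np.array([np.cos(theta), np.sin(theta)])
    out = {}
    for view in all_views():
        t_mm, _ = _layout_mm(geom, view)
        pts = np.asarray(center_px) + (t_mm[:, None] / scale.mm_per_pixel) * u
        out[view] = KeypointSet(view=view, points=pts)
    return out


def _sector_mask(size: int, geom: GeometryParams) -> np.ndarray:
    ax = geom.sector_apex[0] * size
    ay = geom.sector_apex[1] * size
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    dx, dy = xx - ax, yy - ay
    ang = np.degrees(np.arctan2(dx, dy))  # 0 = straight down from apex
    rad = np.hypot(dx, dy)
    return (np.abs(ang) <= geom.sector_span_deg / 2.0) & (rad <= 1.35 * size)


def _render_view(
    geom: GeometryParams,
    noise: NoiseParams,
    scale: ScaleInfo,
    view: ViewId,
    kps: KeypointSet,
    size: int,
    rng: np.random.Generator,
) -> ImageFrame:
    mmpp = scale.mm_per_pixel
    theta = np.deg2rad(geom.septum_angle_deg)
    u = np.array([np.cos(theta), np.sin(theta)])
    center = kps.points[0] - (_layout_mm(geom, view)[0][0] / mmpp) * u

    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    dx, dy = xx - center[0], yy - center[1]
    t = (dx * u[0] + dy * u[1]) * mmpp  # position along the line, mm
    perp = np.abs(-dx * u[1] + dy * u[0]) * mmpp  # distance off the line, mm

    img = np.full((size, size), float(noise.background_level))

    _, breaks = _layout_mm(geom, view)
    in_band = ((t >= breaks[0]) & (t <= breaks[1])) | (
        (t >= breaks[2]) & (t <= breaks[3])
    )
    img = np.where(
        in_band & (perp <= SEPTUM_HALF_THICKNESS_MM), SEPTUM_INTENSITY, img
    )

    def blob(center_pt: np.ndarray, sigma_mm: float, amp: float) -> np.ndarray:
        d2 = (xx - center_pt[0]) ** 2 + (yy - center_pt[1]) ** 2
        return amp * np.exp(-d2 * mmpp**2 / (2.0 * sigma_mm**2))

    schema = kps.schema
    for name, pt in zip(schema.names, kps.points):
        if name.startswith("defect_end"):
            img = np.maximum(img, blob(pt, ENDPOINT_SIGMA_MM, ENDPOINT_INTENSITY))
        else:
            img = np.maximum(img, blob(pt, LANDMARK_SIGMA_MM, LANDMARK_INTENSITY))

    if noise.jet_overlay:
        # saturating Doppler-style flow jet crossing the defect gap
        d = geom.defect_diameter_mm[view]
        sig_par = max(d / 3.0, 1.0)
        jet = JET_INTENSITY * np.exp(
            -(t**2) / (2 * sig_par**2) - (perp**2) / (2 * 1.5**2)
        )
        img = np.maximum(img, jet)

    img *= _sector_mask(size, geom)

    if noise.speckle_strength > 0:
        ray = rng.rayleigh(scale=np.sqrt(2 / np.pi), size=img.shape)  # mean 1
        img = img * (1.0 + noise.speckle_strength * (ray - 1.0))
    if noise.blur_sigma_px > 0:
        img = ndimage.gaussian_filter(img, noise.blur_sigma_px)

    return ImageFrame(pixels=np.clip(np.round(img), 0, 255), view=view)


def render_case(
    geom: GeometryParams,
    noise: NoiseParams,
    scale: ScaleInfo,
    rng_seed: int,
    image_size: int = DEFAULT_IMAGE_SIZE,
    case_id: str = "case",
    rules: Optional[RuleSet] = None,
    catalogue: Optional[OccluderCatalogue] = None,
) -> CaseRecord:
    """Render the three views of one case and derive its labels.

    Raises :class:`RenderError` when a keypoint (plus blob margin) would fall
    outside the frame or the imaging sector at this scale.
    """
    rng = np.random.default_rng(rng_seed)
    keypoints = geometry_keypoints(geom, scale, image_size)

    margin_px = BLOB_MARGIN_MM / scale.mm_per_pixel
    sector = _sector_mask(image_size, geom)
    for view, kset in keypoints.items():
        pts = kset.points
        if (
            (pts < margin_px).any()
            or (pts > image_size - 1 - margin_px).any()
        ):
            raise RenderError(
                f"{view.value}: geometry does not fit the frame at "
                f"{scale.mm_per_pixel:.3f} mm/px"
            )
        rr = np.clip(np.round(pts[:, 1]).astype(int), 0, image_size - 1)
        cc = np.clip(np.round(pts[:, 0]).astype(int), 0, image_size - 1)
        if not sector[rr, cc].all():
            raise RenderError(f"{view.value}: keypoints leave the imaging sector")

    frames = {
        view: _render_view(geom, noise, scale, view, keypoints[view], image_size, rng)
        for view in all_views()
    }
    scales = {view: scale for view in all_views()}

    m = measure_case(keypoints, scales)
    result = decide(m.to_dict(), rules=rules, catalogue=catalogue)
    return CaseRecord(
        case_id=case_id,
        frames=frames,
        scales=scales,
        keypoints=keypoints,
        label_plan=result.plan,
        label_size_mm=result.suggested_size_mm,
        meta={"geometry": _geom_to_dict(geom)},
    )


def _geom_to_dict(geom: GeometryParams) -> dict:
    return {
        "defect_diameter_mm": {v.value: d for v, d in geom.defect_diameter_mm.items()},
        "rim_lengths_mm": dict(geom.rim_lengths_mm),
        "septum_length_mm": geom.septum_length_mm,
        "septum_angle_deg": geom.septum_angle_deg,
        "sector_apex": list(geom.sector_apex),
        "sector_span_deg": geom.sector_span_deg,
    }


def _fit_mm_per_pixel(
    geom: GeometryParams, image_size: int, rng: np.random.Generator
) -> float:
    lo, hi = (r * DEFAULT_IMAGE_SIZE / image_size for r in MM_PER_PIXEL_RANGE_256)
    half_extent = max(
        max(abs(t) for t in _layout_mm(geom, v)[0]) + BLOB_MARGIN_MM
        for v in all_views()
    )
    needed = half_extent / (FIT_FRACTION * image_size)
    return float(max(rng.uniform(lo, hi), needed))


def simulate_cases(
    n_cases: int,
    rng_seed: int,
    class_mix: float = 0.6,
    image_size: int = DEFAULT_IMAGE_SIZE,
    noise: NoiseParams = NoiseParams(),
    rules: Optional[RuleSet] = None,
    catalogue: Optional[OccluderCatalogue] = None,
) -> list[CaseRecord]:
    """Generate ``n_cases`` in-memory CaseRecords, reproducibly from seed."""
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    master = np.random.default_rng(rng_seed)
    cases = []
    for i in range(n_cases):
        geom_seed = int(master.integers(0, 2**31 - 1))
        render_seed = int(master.integers(0, 2**31 - 1))
        geom = sample_geometry(geom_seed, class_mix, rules=rules, catalogue=catalogue)
        scale_rng = np.random.default_rng(int(master.integers(0, 2**31 - 1)))
        mmpp = _fit_mm_per_pixel(geom, image_size, scale_rng)
        scale = ScaleInfo.from_mm_per_pixel(mmpp, DEFAULT_SCALE_BAR_MM)
        cases.append(
            render_case(
                geom,
                noise,
                scale,
                render_seed,
                image_size=image_size,
                case_id=f"syn{i:05d}",
                rules=rules,
                catalogue=catalogue,
            )
        )
    return cases


def generate_dataset(
    n_cases: int,
    rng_seed: int,
    class_mix: float,
    out_dir: str | Path,
    image_size: int = DEFAULT_IMAGE_SIZE,
    noise: NoiseParams = NoiseParams(),
) -> pd.DataFrame:
    """Write a dataset to disk: per-view 8-bit PNGs, per-view annotation
    JSON, and a manifest CSV (one row per case).  Returns the manifest."""
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise IOError(f"output directory {out} is not writable: {exc}") from exc

    cases = simulate_cases(
        n_cases, rng_seed, class_mix, image_size=image_size, noise=noise
    )
    rows = []
    for case in cases:
        row: dict = {
            "case_id": case.case_id,
            "label_plan": case.label_plan,
            "label_size_mm": (
                "" if case.label_size_mm is None else case.label_size_mm
            ),
        }
        for view in all_views():
            img_path = out / f"{case.case_id}_{view.value}.png"
            ann_path = out / f"{case.case_id}_{view.value}.json"
            Image.fromarray(case.frames[view].pixels, mode="L").save(img_path)
            write_annotation(
                ann_path, case.case_id, case.keypoints[view], case.scales[view]
            )
            row[f"image_{view.value}"] = img_path.name
            row[f"annotation_{view.value}"] = ann_path.name
            row[f"mm_per_pixel_{view.value}"] = case.scales[view].mm_per_pixel
        rows.append(row)
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


def load_case(out_dir: str | Path, case_id: str, manifest_row: pd.Series) -> CaseRecord:
    """Re-load one generated case from disk (images + annotations)."""
    from .core import read_annotation

    out = Path(out_dir)
    frames, scales, keypoints = {}, {}, {}
    for view in all_views():
        img = np.asarray(
            Image.open(out / manifest_row[f"image_{view.value}"]).convert("L")
        )
        frames[view] = ImageFrame(pixels=img, view=view)
        _, kps, scale = read_annotation(out / manifest_row[f"annotation_{view.value}"])
        keypoints[view] = kps
        scales[view] = scale
    size_raw = manifest_row.get("label_size_mm", "")
    size = None if size_raw in ("", None) or pd.isna(size_raw) else int(size_raw)
    return CaseRecord(
        case_id=case_id,
        frames=frames,
        scales=scales,
        keypoints=keypoints,
        label_plan=manifest_row["label_plan"],
        label_size_mm=size,
    )
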