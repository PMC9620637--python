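"""End-to-end orchestration: normalize each view, localize keypoints with
the trained networks, convert to millimetre measurements, and apply the
Boolean decision rules — with a file-based clinician-intervention hook.

In ``review`` mode the pipeline writes keypoint overlay images (white
crosses on the frame) and an editable keypoint JSON per view; if an edited
JSON is supplied, the edited coordinates replace the network's before
measurement, mirroring a clinician correcting a landmark in the interaction
window.  Every decision carries its full rule trace for audit.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from PIL import Image

from .core import (
    CaseRecord,
    ImageFrame,
    KeypointSet,
    ViewId,
    all_views,
)
from .decision import (
    DecisionResult,
    OccluderCatalogue,
    RuleSet,
    decide,
    default_catalogue,
    default_ruleset,
)
from .network import BlackboxNet, MSHNet, RegNet, load_checkpoint
from .nnet import autograd as ag
from .stadiometry import MeasurementSet, measure_case
from .training import predict_keypoints

__all__ = [
    "PipelineConfig",
    "normalize_image",
    "run_case",
    "run_blackbox",
    "write_overlay",
    "write_edit_json",
    "read_edit_json",
]

logger = logging.getLogger("dks.pipeline")


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Everything run_case needs: per-view localizer checkpoints, rules,
    catalogue, and the intervention mode."""

    checkpoints: dict[ViewId, tuple[str, str]] = field(default_factory=dict)
    # view -> (mshnet checkpoint path, regnet checkpoint path or "")
    rules: Optional[RuleSet] = None
    catalogue: Optional[OccluderCatalogue] = None
    pck_alpha: float = 0.1
    seed: int = 0
    output_dir: Optional[Path] = None
    intervention: str = "auto"  # "auto" | "review"

    def __post_init__(self) -> None:
        if self.intervention not in ("auto", "review"):
            raise ConfigError(f"intervention must be auto|review, got {self.intervention}")

    def load_models(self) -> dict[ViewId, tuple[MSHNet, Optional[RegNet]]]:
        models = {}
        for view, (msh_path, reg_path) in self.checkpoints.items():
            for p in (msh_path, reg_path):
                if p and not Path(p).exists():
                    raise ConfigError(f"missing checkpoint: {p}")
            msh, _ = load_checkpoint(msh_path)
            reg = load_checkpoint(reg_path)[0] if reg_path else None
            models[ViewId(view)] = (msh, reg)
        return models


def normalize_image(raw: np.ndarray, view: ViewId) -> ImageFrame:
    """Min-max linear rescale of an arbitrary real-valued grid to 0-255.

    Constant images map to all-zero; non-finite pixels are rejected.
    Already-normalized 8-bit input is unchanged up to rounding.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.size == 0:
        raise IOError("empty image")
    if not np.isfinite(raw).all():
        raise IOError("image contains non-finite pixels")
    lo, hi = raw.min(), raw.max()
    if hi == lo:
        return ImageFrame(pixels=np.zeros_like(raw, dtype=np.uint8), view=view)
    scaled = np.round((raw - lo) * (255.0 / (hi - lo)))
    return ImageFrame(pixels=scaled.astype(np.uint8), view=view)


def write_overlay(path: str | Path, frame: ImageFrame, kps: KeypointSet, arm: int = 3) -> None:
    """White-cross keypoint overlay PNG for clinician review."""
    img = frame.pixels.copy()
    h, w = img.shape
    for x, y in kps.points:
        r, c = int(round(y)), int(round(x))
        img[max(0, r - arm) : min(h, r + arm + 1), c : c + 1] = 255
        img[r : r + 1, max(0, c - arm) : min(w, c + arm + 1)] = 255
    Image.fromarray(img, mode="L").save(path)


def write_edit_json(path: str | Path, kps_by_view: dict[ViewId, KeypointSet]) -> None:
    payload = {v.value: kps_by_view[v].to_dict() for v in kps_by_view}
    Path(path).write_text(json.dumps(payload, indent=1))


def read_edit_json(path: str | Path) -> dict[ViewId, KeypointSet]:
    raw = json.loads(Path(path).read_text())
    return {ViewId(v): KeypointSet.from_dict(d) for v, d in raw.items()}


def run_case(
    case: CaseRecord,
    cfg: PipelineConfig,
    models: Optional[dict[ViewId, tuple[MSHNet, Optional[RegNet]]]] = None,
    keypoint_override: Optional[dict[ViewId, KeypointSet]] = None,
    edit_json: Optional[str | Path] = None,
) -> tuple[dict[ViewId, KeypointSet], MeasurementSet, DecisionResult]:
    """Full pipeline on one case.

    ``keypoint_override`` injects keypoints directly (e.g. ground truth, for
    isolating the deterministic back half); otherwise the per-view networks
    are run.  In review mode, overlays and an editable JSON are written to
    ``cfg.output_dir`` and ``edit_json`` (if given) replaces the
    corresponding predictions before measurement.
    """
    missing = set(ViewId) - set(case.frames)
    if missing:
        raise ValueError(f"missing views: {sorted(v.value for v in missing)}")

    if keypoint_override is not None:
        keypoints = dict(keypoint_override)
    else:
        if models is None:
            models = cfg.load_models()
        keypoints = {}
        for view in all_views():
            if view not in models:
                raise ConfigError(f"no checkpoint configured for view {view.value}")
            msh, reg = models[view]
            keypoints[view] = predict_keypoints(
                msh, reg, case.frames[view].pixels, view
            )

    if cfg.intervention == "review" and cfg.output_dir is not None:
        out = Path(cfg.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        for view in all_views():
            write_overlay(
                out / f"{case.case_id}_{view.value}_overlay.png",
                case.frames[view],
                keypoints[view],
            )
        write_edit_json(out / f"{case.case_id}_keypoints.json", keypoints)
    if edit_json is not None:
        edits = read_edit_json(edit_json)
        keypoints.update(edits)
        logger.info("case %s: applied keypoint edits for %s",
                    case.case_id, [v.value for v in edits])

    measurements = measure_case(keypoints, case.scales)
    result = decide(
        measurements.to_dict(),
        rules=cfg.rules if cfg.rules is not None else default_ruleset(),
        catalogue=cfg.catalogue if cfg.catalogue is not None else default_catalogue(),
    )
    logger.info(
        "case %s: plan=%s size=%s trace=%s",
        case.case_id,
        result.plan,
        result.suggested_size_mm,
        [(t["measure"], t["result"]) for t in result.rule_trace],
    )
    return keypoints, measurements, result


def run_blackbox(
    case: CaseRecord, model: BlackboxNet, threshold: float = 0.5
) -> tuple[float, str]:
    """Baseline classifier: P(transcatheter) and the thresholded plan."""
    views = [
        ag.Tensor(case.frames[v].pixels.astype(np.float32)[None, None] / 255.0)
        for v in all_views()
    ]
    scales = np.array(
        [[case.scales[v].mm_per_pixel for v in all_views()]], dtype=np.float32
    )
    prob = float(model(views, scales).data[0, 0])
    plan = "transcatheter" if prob >= threshold else "surgical"
    return prob, plan
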