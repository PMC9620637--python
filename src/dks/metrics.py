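"""Evaluation metrics: PCK for keypoint localization, confusion-matrix
metrics for the closure plan, and MAE / quadratic weighted kappa for the
ordinal occluder-size prediction.

PCK (percentage of correct keypoints) counts a predicted point correct when
its Euclidean pixel error is at most ``alpha`` times the length, in pixels,
of that frame's measuring scale bar — i.e. the error is normalized against a
fraction of the on-image scale.  ``alpha`` defaults to 0.1 and every reported
number should state it.

QWK is Cohen's kappa with quadratic weights w_ij = (i - j)^2 / (K - 1)^2 over
the ordinal size classes, expected agreement from the outer product of the
marginals: kappa = 1 - sum(w * O) / sum(w * E).  It is 1 for a perfect match
and penalizes a 16 mm -> 14 mm confusion less than 16 mm -> 10 mm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .core import KeypointSet, ScaleInfo

__all__ = [
    "PCKConfig",
    "OrdinalLevels",
    "pck",
    "classification_metrics",
    "mae",
    "qwk",
    "pck_table",
    "replicate_summary",
]

POSITIVE_CLASS = "transcatheter"


@dataclass(frozen=True)
class PCKConfig:
    """Correctness radius = alpha x scale_bar_length_px."""

    alpha: float = 0.1

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")


@dataclass(frozen=True)
class OrdinalLevels:
    """Ordered occluder size classes (mm)."""

    levels: tuple[int, ...] = tuple(range(8, 33))

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.levels, self.levels[1:])):
            raise ValueError("levels must be strictly increasing")

    def index(self, size: float) -> int:
        lv = np.asarray(self.levels)
        hit = np.nonzero(lv == size)[0]
        if hit.size == 0:
            raise ValueError(f"size {size} is not an ordinal level")
        return int(hit[0])


def pck(
    pred: Sequence[KeypointSet],
    gt: Sequence[KeypointSet],
    scales: Sequence[ScaleInfo],
    cfg: PCKConfig = PCKConfig(),
) -> float:
    """Fraction of keypoints with error <= alpha x scale-bar length (px).

    ``pred``/``gt`` are aligned case-by-case; comparison is inclusive (a
    point exactly on the radius counts as correct).
    """
    if not (len(pred) == len(gt) == len(scales)) or len(pred) == 0:
        raise ValueError("pred, gt and scales must be non-empty and aligned")
    correct = 0
    total = 0
    for p, g, s in zip(pred, gt, scales):
        if p.view != g.view or p.points.shape != g.points.shape:
            raise ValueError("pred/gt keypoint sets are not aligned")
        radius = cfg.alpha * s.scale_bar_length_px
        err = np.linalg.norm(p.points - g.points, axis=1)
        correct += int(np.sum(err <= radius + 1e-12))
        total += err.size
    return correct / total


def classification_metrics(
    pred_plans: Sequence[str], true_plans: Sequence[str]
) -> dict:
    """Accuracy, F1, sensitivity, specificity for the closure plan.

    Transcatheter is the positive class.  F1 = 2 * precision * recall /
    (precision + recall).  Ratios with a zero denominator are returned as
    NaN with a warning.
    """
    if len(pred_plans) == 0 or len(pred_plans) != len(true_plans):
        raise ValueError("inputs must be non-empty and of equal length")
    p = np.asarray([x == POSITIVE_CLASS for x in pred_plans])
    t = np.asarray([x == POSITIVE_CLASS for x in true_plans])
    tp = int(np.sum(p & t))
    fp = int(np.sum(p & ~t))
    fn = int(np.sum(~p & t))
    tn = int(np.sum(~p & ~t))

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            warnings.warn(f"{name} undefined (zero denominator)", RuntimeWarning)
            return float("nan")
        return num / den

    acc = (tp + tn) / len(p)
    precision = ratio(tp, tp + fp, "precision")
    recall = ratio(tp, tp + fn, "sensitivity")
    specificity = ratio(tn, tn + fp, "specificity")
    if np.isnan(precision) or np.isnan(recall) or (precision + recall) == 0:
        warnings.warn("F1 undefined", RuntimeWarning)
        f1 = float("nan")
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return {
        "acc": acc,
        "f1": f1,
        "sensitivity": recall,
        "specificity": specificity,
        "precision": precision,
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "tn": tn,
    }


def mae(pred_sizes: Sequence[float], true_sizes: Sequence[float]) -> float:
    """Mean absolute error in mm between predicted and true sizes."""
    if len(pred_sizes) == 0 or len(pred_sizes) != len(true_sizes):
        raise ValueError("inputs must be non-empty and of equal length")
    p = np.asarray(pred_sizes, dtype=float)
    t = np.asarray(true_sizes, dtype=float)
    return float(np.mean(np.abs(p - t)))


def qwk(
    pred_sizes: Sequence[float],
    true_sizes: Sequence[float],
    levels: OrdinalLevels = OrdinalLevels(),
) -> float:
    """Quadratic weighted kappa over the ordinal size classes.

    kappa = 1 - sum(w_ij O_ij) / sum(w_ij E_ij), with O the observed
    confusion matrix, E the outer product of its marginals scaled to the same
    total, and w_ij = (i - j)^2 / (K - 1)^2.  Undefined (NaN, with a warning)
    when the weighted expected agreement is zero, e.g. constant vectors.
    """
    if len(pred_sizes) == 0 or len(pred_sizes) != len(true_sizes):
        raise ValueError("inputs must be non-empty and of equal length")
    k = len(levels.levels)
    pi = np.array([levels.index(s) for s in pred_sizes])
    ti = np.array([levels.index(s) for s in true_sizes])
    observed = np.zeros((k, k))
    np.add.at(observed, (ti, pi), 1.0)
    n = observed.sum()
    expected = np.outer(observed.sum(axis=1), observed.sum(axis=0)) / n
    idx = np.arange(k)
    weights = (idx[:, None] - idx[None, :]) ** 2 / (k - 1) ** 2
    denom = float(np.sum(weights * expected))
    if denom == 0.0:
        warnings.warn("QWK undefined (degenerate expected matrix)", RuntimeWarning)
        return float("nan")
    return float(1.0 - np.sum(weights * observed) / denom)


def pck_table(results: dict) -> str:
    """Per-view PCK breakdown: one row per method, columns = views + average.

    ``results`` maps method name -> {view name -> pck}; the average is the
    unweighted mean over the views present.
    """
    views = sorted({v for per_view in results.values() for v in per_view})
    header = f"{'method':<20}" + "".join(f"{v:>10}" for v in views) + f"{'Average':>10}"
    lines = [header]
    for method, per_view in results.items():
        vals = [per_view[v] for v in views if v in per_view]
        cells = "".join(
            f"{per_view[v]:>10.4f}" if v in per_view else f"{'-':>10}" for v in views
        )
        lines.append(f"{method:<20}{cells}{np.mean(vals):>10.4f}")
    return "\n".join(lines)


def replicate_summary(values: Sequence[float]) -> dict:
    """Mean +/- standard deviation over training replicates.

    Matches the reporting format of repeated train/test runs; the standard
    deviation is the sample (ddof=1) one when more than one replicate is
    given.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("no replicate values")
    std = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
    return {
        "mean": float(np.mean(v)),
        "std": std,
        "n": int(v.size),
        "formatted": f"{np.mean(v):.4f} ± {std:.4f}",
    }
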