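"""PCK, classification metrics, MAE and quadratic weighted kappa."""

import itertools
import warnings

import numpy as np
import pytest
from sklearn.metrics import cohen_kappa_score, f1_score

from dks.core import KeypointSet, ScaleInfo, ViewId
from dks.metrics import (
    OrdinalLevels,
    PCKConfig,
    classification_metrics,
    mae,
    pck,
    qwk,
    replicate_summary,
)


def _kps(points):
    return KeypointSet(view=ViewId.PSSAX, points=np.asarray(points, dtype=float))


SCALE = ScaleInfo.from_mm_per_pixel(1.0, scale_bar_length_mm=40.0)  # bar = 40 px


class TestPCK:
    def test_perfect_prediction(self):
        gt = [_kps([[1, 1], [5, 5], [9, 9]])]
        assert pck(gt, gt, [SCALE]) == 1.0

    def test_boundary_error_counts_correct(self):
        radius = 0.1 * SCALE.scale_bar_length_px  # 4 px
        gt = [_kps([[0, 0], [10, 10], [20, 20]])]
        pred = [_kps([[radius, 0], [10, 10], [20, 20]])]
        assert pck(pred, gt, [SCALE]) == 1.0

    def test_counting_fraction(self):
        # 11 points over 3 views' worth of cases, 2 beyond threshold
        gt = [
            _kps([[0, 0], [10, 0], [20, 0]]),
            _kps([[0, 10], [10, 10], [20, 10]]),
            _kps([[0, 20], [10, 20], [20, 20]]),
        ]
        pred = [
            _kps([[0, 0], [10, 0], [20, 0]]),
            _kps([[0, 10], [30, 10], [20, 10]]),  # 20 px off
            _kps([[0, 20], [10, 20], [40, 20]]),  # 20 px off
        ]
        assert pck(pred, gt, [SCALE] * 3) == pytest.approx(7 / 9)

    def test_monotone_in_alpha(self, rng):
        gt = [_kps(rng.uniform(0, 60, (3, 2))) for _ in range(10)]
        pred = [_kps(k.points + rng.normal(0, 3, (3, 2))) for k in gt]
        scales = [SCALE] * 10
        values = [
            pck(pred, gt, scales, PCKConfig(alpha=a))
            for a in (0.02, 0.05, 0.1, 0.2, 0.5)
        ]
        assert all(b >= a for a, b in zip(values, values[1:]))

    def test_misaligned_inputs_rejected(self):
        with pytest.raises(ValueError):
            pck([], [], [])


class TestClassificationMetrics:
    def test_perfect(self):
        plans = ["transcatheter", "surgical", "transcatheter"]
        m = classification_metrics(plans, plans)
        assert m["acc"] == m["f1"] == m["sensitivity"] == m["specificity"] == 1.0

    def test_confusion_example(self):
        # TP=3, FP=1, FN=1, TN=5
        t, s = "transcatheter", "surgical"
        true = [t] * 3 + [s] + [t] + [s] * 5
        pred = [t] * 3 + [t] + [s] + [s] * 5
        m = classification_metrics(pred, true)
        assert m["precision"] == pytest.approx(0.75)
        assert m["sensitivity"] == pytest.approx(0.75)
        assert m["f1"] == pytest.approx(0.75)
        assert m["specificity"] == pytest.approx(5 / 6)

    def test_all_single_case_outcomes_match_formula(self):
        """All 2^4 two-case pred/true combinations against the harmonic-mean
        formula (and sklearn where defined)."""
        t, s = "transcatheter", "surgical"
        lab = lambda b: t if b else s
        for bits in itertools.product([0, 1], repeat=4):
            pred = [lab(bits[0]), lab(bits[1])]
            true = [lab(bits[2]), lab(bits[3])]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m = classification_metrics(pred, true)
            tp = sum(p == t and g == t for p, g in zip(pred, true))
            fp = sum(p == t and g == s for p, g in zip(pred, true))
            fn = sum(p == s and g == t for p, g in zip(pred, true))
            if tp + fp == 0 or tp + fn == 0 or (tp == 0 and (fp or fn)):
                continue  # undefined ratios -> NaN path, checked separately
            precision, recall = tp / (tp + fp), tp / (tp + fn)
            assert m["f1"] == pytest.approx(
                2 * precision * recall / (precision + recall)
            )
            skl = f1_score([x == t for x in true], [x == t for x in pred])
            assert m["f1"] == pytest.approx(skl)

    def test_undefined_ratios_warn_nan(self):
        with pytest.warns(RuntimeWarning):
            m = classification_metrics(["surgical"], ["surgical"])
        assert np.isnan(m["f1"]) and np.isnan(m["sensitivity"])
        assert m["acc"] == 1.0

    def test_swapping_positive_class_swaps_sens_spec(self):
        t, s = "transcatheter", "surgical"
        pred = [t, t, s, s, t]
        true = [t, s, s, t, t]
        m = classification_metrics(pred, true)
        swap = {t: s, s: t}
        m2 = classification_metrics([swap[p] for p in pred], [swap[g] for g in true])
        assert m["sensitivity"] == pytest.approx(m2["specificity"])
        assert m["specificity"] == pytest.approx(m2["sensitivity"])


class TestMAE:
    def test_examples(self):
        assert mae([16], [16]) == 0.0
        assert mae([16], [14]) == 2.0
        assert mae([16, 10], [14, 14]) == pytest.approx(3.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mae([], [])


class TestQWK:
    def test_perfect_match_is_one(self):
        assert qwk([8, 10, 12], [8, 10, 12]) == pytest.approx(1.0)

    def test_near_miss_beats_far_miss(self):
        true = [16, 16, 16, 8, 24]
        near = qwk([14, 14, 14, 8, 24], true)
        far = qwk([10, 10, 10, 8, 24], true)
        assert near > far

    def test_agrees_with_independent_implementation(self, rng):
        levels = OrdinalLevels()
        for _ in range(100):
            n = int(rng.integers(5, 60))
            true = rng.choice(levels.levels, size=n)
            pred = rng.choice(levels.levels, size=n)
            if len(set(true)) < 2 or len(set(pred.tolist() + true.tolist())) < 2:
                continue
            ours = qwk(pred, true, levels)
            ref = cohen_kappa_score(
                true, pred, labels=list(levels.levels), weights="quadratic"
            )
            assert ours == pytest.approx(ref, abs=1e-12)

    def test_degenerate_warns_nan(self):
        with pytest.warns(RuntimeWarning):
            v = qwk([8, 8], [8, 8])
        assert np.isnan(v)

    def test_non_level_size_rejected(self):
        with pytest.raises(ValueError):
            qwk([9.5], [10])

    def test_bounded_above_by_one(self, rng):
        levels = OrdinalLevels()
        true = rng.choice(levels.levels, size=30)
        pred = rng.choice(levels.levels, size=30)
        if len(set(true)) >= 2:
            assert qwk(pred, true, levels) <= 1.0 + 1e-12


def test_pck_table_rows_methods_columns_views():
    from dks.metrics import pck_table

    table = pck_table(
        {
            "DKS": {"PSSAX": 0.98, "SXLAX": 0.95, "A4C": 0.96},
            "vanilla SHN": {"PSSAX": 0.96, "SXLAX": 0.94, "A4C": 0.95},
        }
    )
    lines = table.splitlines()
    assert "Average" in lines[0] and "PSSAX" in lines[0]
    assert lines[1].startswith("DKS") and "0.9633" in lines[1]
    assert lines[2].startswith("vanilla SHN")


def test_replicate_summary_format():
    out = replicate_summary([0.9, 1.0, 0.95])
    assert out["mean"] == pytest.approx(0.95)
    assert out["n"] == 3
    assert "±" in out["formatted"]
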