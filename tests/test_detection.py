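"""Detection/instance metrics: AP tie dialects, legacy formula, FROC, PQ."""

import math

import numpy as np
import pytest

from valimet.core import (
    BoundingBox,
    ConfusionCounts,
    InputError,
    Instance,
    InstanceSet,
    Level,
    MetricParams,
)
from valimet.classification import counting_metric
from valimet.detection import (
    APConfig,
    FROCConfig,
    average_precision,
    detection_counts,
    froc,
    legacy_cellchallenge_precision,
    mean_average_precision,
    panoptic_quality,
)
from valimet.matching import MatchConfig, MatchResult, build_match

from conftest import block_mask


def box_inst(mins, maxs, conf=None):
    return Instance(box=BoundingBox(mins, maxs), confidence=conf)


def envelope_ap_oracle(points):
    """Independent AP from hand-listed PR points: numeric sweep over
    the observed recall levels with a max-precision-at-or-above rule."""
    recalls = sorted({r for r, _ in points})
    ap, prev = 0.0, 0.0
    for r in recalls:
        p_env = max(p for r2, p in points if r2 >= r)
        ap += (r - prev) * p_env
        prev = r
    return ap


class TestDetectionCounts:
    def test_perfect_matching(self):
        m = MatchResult(pairs=((0, 0, 1.0), (1, 1, 1.0), (2, 2, 1.0)),
                        unmatched_preds=(), unmatched_refs=())
        c = detection_counts(m)
        assert (c.tp, c.fp, c.fn) == (3, 0, 0) and c.tn is None

    def test_empty_prediction_makes_ppv_undefined(self):
        m = MatchResult(pairs=(), unmatched_preds=(), unmatched_refs=(0, 1))
        c = detection_counts(m)
        assert (c.tp, c.fp, c.fn) == (0, 0, 2)
        assert math.isnan(counting_metric(c, "ppv").value)

    def test_pixel_sensitivity_hides_missed_lesions(self):
        # three reference lesions, one (large) detected: the
        # pixel-level view is near-perfect, the instance-level
        # view reveals two of three lesions missed
        from valimet.core import pixel_confusion
        shape = (64, 64)
        blocks = [(5, 35, 5, 35), (45, 48, 10, 13), (45, 48, 40, 43)]
        ref_sem = block_mask(shape, blocks)
        pred_sem = block_mask(shape, [blocks[0]])
        pix = counting_metric(pixel_confusion(ref_sem, pred_sem), "sensitivity").value
        refs = InstanceSet("i", [Instance(mask=block_mask(shape, [b])) for b in blocks])
        preds = InstanceSet("i", [Instance(mask=pred_sem, confidence=0.9)])
        c = detection_counts(build_match(preds, refs, MatchConfig("mask_iou", 0.5)))
        inst = counting_metric(c, "sensitivity").value
        assert pix > 0.9
        assert inst == pytest.approx(1 / 3, abs=1e-15)
        assert pix > inst


class TestAveragePrecision:
    REFS = [InstanceSet("img", [box_inst((0, 0), (2, 2)), box_inst((10, 10), (12, 12))])]
    CFG = MatchConfig("box_iou", 0.5)

    def tie_preds(self):
        return [InstanceSet("img", [
            box_inst((0, 0), (2, 2), conf=0.9),
            box_inst((10, 10), (12, 12), conf=0.8),
            box_inst((20, 20), (22, 22), conf=0.8),
        ])]

    def test_single_true_positive(self):
        refs = [InstanceSet("img", [box_inst((0, 0), (2, 2))])]
        preds = [InstanceSet("img", [box_inst((0, 0), (2, 2), conf=0.7)])]
        assert average_precision(preds, refs, self.CFG).value == 1.0

    def test_all_false_positives(self):
        preds = [InstanceSet("img", [box_inst((20, 20), (22, 22), conf=0.7)])]
        assert average_precision(preds, self.REFS, self.CFG).value == 0.0

    def test_tie_dialects_diverge_and_match_enumeration(self):
        preds = self.tie_preds()
        ap_pp = average_precision(preds, self.REFS, self.CFG,
                                  APConfig(tie_dialect="per_prediction")).value
        ap_gs = average_precision(preds, self.REFS, self.CFG,
                                  APConfig(tie_dialect="grouped_by_score")).value
        # hand-enumerated sweeps: per prediction visits (0.5, 1),
        # (1, 1), (1, 2/3); grouped processes the 0.8-block jointly,
        # visiting (0.5, 1), (1, 2/3)
        pp_points = [(0.5, 1.0), (1.0, 1.0), (1.0, 2 / 3)]
        gs_points = [(0.5, 1.0), (1.0, 2 / 3)]
        assert ap_pp == pytest.approx(envelope_ap_oracle(pp_points), abs=1e-15)
        assert ap_gs == pytest.approx(envelope_ap_oracle(gs_points), abs=1e-15)
        assert ap_pp == 1.0
        assert ap_gs == pytest.approx(5 / 6, abs=1e-15)
        assert ap_pp != ap_gs

    def test_invariant_to_monotone_rescoring(self):
        preds = self.tie_preds()
        rescored = [InstanceSet("img", [
            Instance(box=p.box, confidence=p.confidence**3) for p in preds[0]
        ])]
        for dialect in ("per_prediction", "grouped_by_score"):
            a = average_precision(preds, self.REFS, self.CFG, APConfig(dialect)).value
            b = average_precision(rescored, self.REFS, self.CFG, APConfig(dialect)).value
            assert a == pytest.approx(b, abs=1e-15)

    def test_missing_scores_is_an_error(self):
        preds = [InstanceSet("img", [box_inst((0, 0), (2, 2))])]
        with pytest.raises(InputError):
            average_precision(preds, self.REFS, self.CFG)

    def test_no_references_is_nan(self):
        preds = [InstanceSet("img", [box_inst((0, 0), (2, 2), conf=0.5)])]
        refs = [InstanceSet("img", [])]
        assert math.isnan(average_precision(preds, refs, self.CFG).value)


class TestMeanAveragePrecision:
    def test_equal_aps(self):
        assert mean_average_precision([0.7, 0.7, 0.7]).value == pytest.approx(0.7)

    def test_two_class_mean(self):
        assert mean_average_precision([1.0, 0.0]).value == 0.5

    def test_random_values_match_mean(self, rng):
        vals = rng.random(7)
        assert mean_average_precision(vals).value == pytest.approx(float(np.mean(vals)))

    def test_nan_policies(self):
        assert math.isnan(mean_average_precision([0.5, float("nan")]).value)
        assert mean_average_precision([0.5, float("nan")], "omit").value == 0.5
        assert math.isnan(mean_average_precision([float("nan")] * 2).value)


class TestLegacyFormula:
    def C(self, tp, fp, fn):
        return ConfusionCounts(tp=tp, fp=fp, fn=fn, level=Level.OBJECT)

    def test_printed_formula_at_one_each(self):
        assert legacy_cellchallenge_precision(self.C(1, 1, 1)).value == pytest.approx(1 / 3)

    def test_perfect_detection(self):
        assert legacy_cellchallenge_precision(self.C(5, 0, 0)).value == 1.0

    def test_equals_counts_level_iou(self, rng):
        for _ in range(30):
            tp, fp, fn = rng.integers(0, 10, 3)
            if tp + fp + fn == 0:
                continue
            v = legacy_cellchallenge_precision(self.C(tp, fp, fn)).value
            assert v == pytest.approx(tp / (tp + fp + fn), abs=1e-15)

    def test_flagged_as_non_standard(self):
        assert "non-standard" in legacy_cellchallenge_precision(self.C(1, 0, 0)).flags["warning"]

    def test_no_instances_is_nan(self):
        assert math.isnan(legacy_cellchallenge_precision(self.C(0, 0, 0)).value)


class TestFroc:
    CFG = MatchConfig("box_iou", 0.5)

    def three_image_set(self):
        refs = [
            InstanceSet("i1", [box_inst((0, 0), (4, 4)), box_inst((10, 10), (14, 14))]),
            InstanceSet("i2", [box_inst((0, 0), (4, 4))]),
            InstanceSet("i3", []),
        ]
        preds = [
            InstanceSet("i1", [box_inst((0, 0), (4, 4), conf=0.9),
                               box_inst((20, 20), (24, 24), conf=0.6)]),
            InstanceSet("i2", [box_inst((0, 0), (4, 4), conf=0.8)]),
            InstanceSet("i3", [box_inst((5, 5), (9, 9), conf=0.4)]),
        ]
        return preds, refs

    def test_perfect_detector(self):
        refs = [InstanceSet("i", [box_inst((0, 0), (4, 4))])]
        preds = [InstanceSet("i", [box_inst((0, 0), (4, 4), conf=0.9)])]
        (fppi, sens), score = froc(preds, refs, self.CFG)
        assert score.value == 1.0
        assert sens[fppi == 0.0].max() == 1.0

    def test_no_true_positives(self):
        refs = [InstanceSet("i", [box_inst((0, 0), (4, 4))])]
        preds = [InstanceSet("i", [box_inst((10, 10), (14, 14), conf=0.9)])]
        (_, sens), score = froc(preds, refs, self.CFG)
        assert sens.max() == 0.0 and score.value == 0.0

    def test_hand_enumerated_threshold_sweep(self):
        preds, refs = self.three_image_set()
        (fppi, sens), score = froc(preds, refs, self.CFG)
        # thresholds 0.9/0.8/0.6/0.4 give (fppi, sens):
        # (0, 1/3), (0, 2/3), (1/3, 2/3), (2/3, 2/3); dedup keeps
        # (0, 2/3); sensitivity is flat at 2/3 over the curve
        assert list(fppi) == [0.0, 1 / 3, 2 / 3]
        assert list(sens) == [2 / 3, 2 / 3, 2 / 3]
        assert score.value == pytest.approx(2 / 3, abs=1e-15)

    def test_no_references_gives_nan(self):
        refs = [InstanceSet("i", [])]
        preds = [InstanceSet("i", [box_inst((0, 0), (2, 2), conf=0.5)])]
        (_, _), score = froc(preds, refs, self.CFG)
        assert math.isnan(score.value)


class TestPanopticQuality:
    def test_exact_equality(self):
        shape = (10, 10)
        insts = [Instance(mask=block_mask(shape, [(0, 4, 0, 4)])),
                 Instance(mask=block_mask(shape, [(6, 9, 6, 9)]))]
        pq, sq, rq = panoptic_quality(InstanceSet("i", insts), InstanceSet("i", insts))
        assert pq.value == sq.value == rq.value == 1.0

    def test_no_overlap(self):
        shape = (10, 10)
        refs = InstanceSet("i", [Instance(mask=block_mask(shape, [(0, 3, 0, 3)]))])
        preds = InstanceSet("i", [Instance(mask=block_mask(shape, [(6, 9, 6, 9)]))])
        pq, sq, rq = panoptic_quality(refs, preds)
        assert pq.value == 0.0 and rq.value == 0.0 and math.isnan(sq.value)

    def test_worked_value_one_match_one_fp(self):
        shape = (12, 12)
        ref = Instance(mask=block_mask(shape, [(0, 5, 0, 8)]))  # 40 px
        # 30 px inside + 10 px outside: IoU = 30 / 50 = 0.6
        pred = Instance(mask=block_mask(shape, [(0, 5, 2, 8), (8, 10, 0, 5)]))
        fp = Instance(mask=block_mask(shape, [(10, 12, 10, 12)]))
        pq, sq, rq = panoptic_quality(InstanceSet("i", [ref]), InstanceSet("i", [pred, fp]))
        assert pq.value == pytest.approx(0.6 / 1.5, abs=1e-12)
        assert pq.value == pytest.approx(0.4, abs=1e-12)

    def test_pq_factorizes_into_sq_times_rq(self, rng):
        shape = (24, 24)
        for _ in range(20):
            refs, preds = [], []
            for r, c in ((1, 1), (1, 13), (13, 1), (13, 13)):
                refs.append(Instance(mask=block_mask(shape, [(r, r + 6, c, c + 6)])))
                dr, dc = rng.integers(0, 3, 2)
                preds.append(Instance(
                    mask=block_mask(shape, [(r + dr, r + dr + 6, c + dc, c + dc + 6)])))
            if rng.random() < 0.5:
                preds.append(Instance(mask=block_mask(shape, [(22, 24, 0, 2)])))
            pq, sq, rq = panoptic_quality(InstanceSet("i", refs), InstanceSet("i", preds))
            if not math.isnan(sq.value):
                assert pq.value == pytest.approx(sq.value * rq.value, abs=1e-12)

    def test_empty_everything_is_nan(self):
        pq, _, _ = panoptic_quality(InstanceSet("i", []), InstanceSet("i", []))
        assert math.isnan(pq.value)


class TestNanGrid:
    """Per-image TP/FN/FP presence scenarios and the defined/NaN pattern."""

    @pytest.mark.parametrize("tp", [0, 1])
    @pytest.mark.parametrize("fn", [0, 1])
    @pytest.mark.parametrize("fp", [0, 1])
    def test_sensitivity_ppv_f1_definedness(self, tp, fn, fp):
        c = ConfusionCounts(tp=tp, fp=fp, fn=fn, level=Level.OBJECT)
        sens = counting_metric(c, "sensitivity").value
        ppv = counting_metric(c, "ppv").value
        f1 = counting_metric(c, "f_beta", MetricParams(beta=1.0)).value
        assert math.isnan(sens) == (tp + fn == 0)
        assert math.isnan(ppv) == (tp + fp == 0)
        assert math.isnan(f1) == (tp + fn + fp == 0)
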