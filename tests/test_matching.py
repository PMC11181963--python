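"""Localization criteria and one-to-one assignment strategies."""

import itertools
import math

import numpy as np
import pytest

from valimet.core import BoundingBox, InputError, Instance, InstanceSet, PixelMask
from valimet.matching import MatchConfig, build_match, localization_score, mask_iou_gt_zero

from conftest import block_mask


def box_inst(mins, maxs, conf=None):
    return Instance(box=BoundingBox(mins, maxs), confidence=conf)


def mask_inst(shape, blocks, conf=None):
    return Instance(mask=block_mask(shape, blocks), confidence=conf)


class TestLocalizationScore:
    def test_identical_boxes(self):
        a = box_inst((0, 0), (4, 4))
        assert localization_score(a, a, "box_iou") == 1.0

    def test_half_open_box_arithmetic(self):
        a = box_inst((0, 0), (2, 2))
        b = box_inst((0, 1), (2, 3))
        assert localization_score(a, b, "box_iou") == pytest.approx(1 / 3, abs=1e-15)

    def test_ior_of_covered_reference(self):
        pred = mask_inst((8, 8), [(0, 6, 0, 6)])
        ref = mask_inst((8, 8), [(1, 3, 1, 3)])
        assert localization_score(pred, ref, "ior") == 1.0

    def test_ior_empty_reference_is_nan(self):
        pred = mask_inst((8, 8), [(0, 2, 0, 2)])
        ref = mask_inst((8, 8), [])
        assert math.isnan(localization_score(pred, ref, "ior"))

    def test_center_distance_is_spacing_aware(self):
        a = Instance(mask=PixelMask(np.eye(1, 5, 0, dtype=bool).reshape(1, 5) > 0,
                                    spacing=(1.0, 2.0)))
        b = Instance(mask=PixelMask(np.eye(1, 5, 4, dtype=bool).reshape(1, 5) > 0,
                                    spacing=(1.0, 2.0)))
        assert localization_score(a, b, "center_distance") == 8.0

    def test_point_inside_criteria(self):
        ref_mask = mask_inst((6, 6), [(2, 4, 2, 4)])
        assert localization_score(Instance(point=(2.5, 3.5)), ref_mask, "point_inside_mask") == 1.0
        assert localization_score(Instance(point=(0.0, 0.0)), ref_mask, "point_inside_mask") == 0.0
        ref_box = box_inst((2, 2), (4, 4))
        assert localization_score(Instance(point=(3.9, 2.0)), ref_box, "point_inside_box") == 1.0
        assert localization_score(Instance(point=(4.0, 2.0)), ref_box, "point_inside_box") == 0.0

    def test_mask_iou_gt_zero(self, rng):
        touch = mask_inst((6, 6), [(0, 3, 0, 3)])
        other = mask_inst((6, 6), [(2, 5, 2, 5)])
        disjoint = mask_inst((6, 6), [(4, 6, 4, 6)])
        assert mask_iou_gt_zero(touch, other) == 1
        assert mask_iou_gt_zero(touch, disjoint) == 0
        for _ in range(20):
            a = Instance(mask=PixelMask(rng.random((6, 6)) < 0.3))
            b = Instance(mask=PixelMask(rng.random((6, 6)) < 0.3))
            if a.mask.is_empty and b.mask.is_empty:
                continue
            assert mask_iou_gt_zero(a, b) == int(
                localization_score(a, b, "mask_iou") > 0)

    def test_incompatible_locator_raises(self):
        with pytest.raises(InputError):
            localization_score(box_inst((0, 0), (1, 1)),
                               mask_inst((4, 4), [(0, 1, 0, 1)]), "mask_iou")


def enumerate_best_assignment(scores, eligible):
    """Exhaustive search over all one-to-one assignments (oracle)."""
    n, m = scores.shape
    best = (0, -1.0)
    for k in range(min(n, m) + 1):
        for pred_sub in itertools.permutations(range(n), k):
            for ref_sub in itertools.permutations(range(m), k):
                if not all(eligible[i, j] for i, j in zip(pred_sub, ref_sub)):
                    continue
                total = sum(scores[i, j] for i, j in zip(pred_sub, ref_sub))
                best = max(best, (k, total))
    return best


class TestBuildMatch:
    CFG = MatchConfig("box_iou", 0.1)

    def test_single_true_positive(self):
        preds = InstanceSet("img", [box_inst((0, 0), (4, 4), conf=0.9)])
        refs = InstanceSet("img", [box_inst((0, 0), (4, 4))])
        m = build_match(preds, refs, self.CFG)
        assert len(m.pairs) == 1 and not m.unmatched_preds and not m.unmatched_refs

    def test_empty_reference_gives_only_false_positives(self):
        preds = InstanceSet("img", [box_inst((0, 0), (2, 2), conf=0.9),
                                    box_inst((4, 4), (6, 6), conf=0.5)])
        refs = InstanceSet("img", [])
        m = build_match(preds, refs, self.CFG)
        assert len(m.pairs) == 0 and len(m.unmatched_preds) == 2

    def test_greedy_can_lose_a_match_that_optimal_finds(self):
        # the confident prediction overlaps both references and takes
        # the better one, stranding its competitor
        ref_a = box_inst((0, 0), (4, 4))
        ref_b = box_inst((0, 6), (4, 10))
        pred_both = box_inst((0, 3), (4, 9), conf=0.9)  # hits A slightly, B well
        pred_b_only = box_inst((0, 6), (4, 10), conf=0.5)
        preds = InstanceSet("img", [pred_both, pred_b_only])
        refs = InstanceSet("img", [ref_a, ref_b])
        greedy = build_match(preds, refs, MatchConfig("box_iou", 0.1))
        optimal = build_match(preds, refs, MatchConfig("box_iou", 0.1, strategy="optimal"))
        assert len(greedy.pairs) == 1
        assert len(optimal.pairs) == 2

    def test_optimal_matches_exhaustive_enumeration(self, rng):
        for _ in range(25):
            n, m = rng.integers(0, 5, 2)
            preds = InstanceSet("img", [
                box_inst(tuple(p), tuple(p + rng.integers(1, 4, 2)),
                         conf=float(rng.random()))
                for p in rng.integers(0, 6, (n, 2))
            ])
            refs = InstanceSet("img", [
                box_inst(tuple(p), tuple(p + rng.integers(1, 4, 2)))
                for p in rng.integers(0, 6, (m, 2))
            ])
            scores = np.zeros((n, m))
            for i, p in enumerate(preds):
                for j, r in enumerate(refs):
                    scores[i, j] = localization_score(p, r, "box_iou")
            eligible = scores >= 0.1
            best_k, _ = enumerate_best_assignment(scores, eligible)
            cfg = MatchConfig("box_iou", 0.1, strategy="optimal")
            result = build_match(preds, refs, cfg)
            assert len(result.pairs) == best_k
            greedy = build_match(preds, refs, MatchConfig("box_iou", 0.1))
            assert len(greedy.pairs) <= best_k

    def test_partition_invariant(self, rng):
        preds = InstanceSet("img", [
            box_inst(tuple(p), tuple(p + 2), conf=float(rng.random()))
            for p in rng.integers(0, 8, (4, 2))
        ])
        refs = InstanceSet("img", [box_inst(tuple(p), tuple(p + 2))
                                   for p in rng.integers(0, 8, (3, 2))])
        m = build_match(preds, refs, self.CFG)
        assert len(m.pairs) + len(m.unmatched_preds) == 4
        assert len(m.pairs) + len(m.unmatched_refs) == 3

    def test_high_iou_threshold_forces_unique_matching(self, rng):
        # with internally disjoint instance sets and IoU threshold
        # above 0.5, at most one prediction can exceed the threshold
        # per reference, so greedy and optimal must agree; random
        # search for counterexamples
        shape = (18, 18)
        cells = [(r, c) for r in (0, 6, 12) for c in (0, 6, 12)]
        for _ in range(30):
            pred_cells = rng.permutation(len(cells))[:4]
            ref_cells = rng.permutation(len(cells))[:3]
            preds = [mask_inst(shape, [(cells[k][0], cells[k][0] + 4,
                                        cells[k][1], cells[k][1] + 4)],
                               conf=float(rng.random())) for k in pred_cells]
            refs = []
            for k in ref_cells:
                dr, dc = rng.integers(0, 3, 2)
                r0, c0 = cells[k][0] + dr, cells[k][1] + dc
                refs.append(mask_inst(shape, [(r0, r0 + 4, c0, c0 + 4)]))
            preds, refs = InstanceSet("i", preds), InstanceSet("i", refs)
            g = build_match(preds, refs, MatchConfig("mask_iou", 0.55))
            o = build_match(preds, refs, MatchConfig("mask_iou", 0.55, strategy="optimal"))
            assert set(pr[:2] for pr in g.pairs) == set(pr[:2] for pr in o.pairs)

    def test_distance_criterion_matches_below_threshold(self):
        preds = InstanceSet("img", [Instance(point=(0.0, 0.0), confidence=0.9)])
        refs = InstanceSet("img", [Instance(point=(0.0, 3.0))])
        near = build_match(preds, refs, MatchConfig("center_distance", 5.0))
        far = build_match(preds, refs, MatchConfig("center_distance", 2.0))
        assert len(near.pairs) == 1 and len(far.pairs) == 0

    def test_greedy_without_confidence_raises(self):
        preds = InstanceSet("img", [box_inst((0, 0), (2, 2))])
        refs = InstanceSet("img", [box_inst((0, 0), (2, 2))])
        with pytest.raises(InputError):
            build_match(preds, refs, self.CFG)
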