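"""Localization criteria and one-to-one prediction/reference assignment.

Object-level TP/FP/FN counts only exist *after* a matching step: a
localization criterion decides whether a prediction "hits" a
reference, and an assignment strategy resolves competition between
predictions.  Both choices change the counts, so both are explicit
and recorded.

Criterion directions differ: IoU-type criteria match when the score
is >= the threshold, distance criteria when the value is <= the
threshold.  The direction is stored with the criterion so it cannot
be silently misused.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .core import InputError, Instance, InstanceSet

__all__ = [
    "CRITERIA",
    "MatchConfig",
    "MatchResult",
    "localization_score",
    "mask_iou_gt_zero",
    "build_match",
]

# criterion -> comparison direction ("higher" matches when score >= threshold)
CRITERIA = {
    "box_iou": "higher",
    "approx_iou": "higher",
    "mask_iou": "higher",
    "mask_iou_gt_zero": "higher",
    "center_distance": "lower",
    "point_inside_mask": "higher",
    "point_inside_box": "higher",
    "ior": "higher",
}


@dataclass(frozen=True)
class MatchConfig:
    """Localization criterion, decision threshold and assignment strategy.

    No default threshold is shipped: the threshold is itself a known
    pitfall source and must be chosen consciously.
    """

    criterion: str
    threshold: float
    strategy: str = "greedy_by_confidence"

    def __post_init__(self):
        if self.criterion not in CRITERIA:
            raise InputError(f"unknown localization criterion {self.criterion!r}")
        if self.strategy not in ("greedy_by_confidence", "optimal"):
            raise InputError(f"unknown matching strategy {self.strategy!r}")
        if CRITERIA[self.criterion] == "higher" and not 0.0 <= self.threshold <= 1.0:
            raise InputError("IoU-type thresholds must lie in [0, 1]")
        if CRITERIA[self.criterion] == "lower" and self.threshold < 0:
            raise InputError("distance thresholds must be non-negative")

    @property
    def direction(self) -> str:
        return CRITERIA[self.criterion]


@dataclass(frozen=True)
class MatchResult:
    """One-to-one assignment plus the unmatched leftovers."""

    pairs: tuple  # (pred_index, ref_index, criterion_value)
    unmatched_preds: tuple
    unmatched_refs: tuple
    flags: dict = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "pairs", tuple(tuple(p) for p in self.pairs))
        object.__setattr__(self, "unmatched_preds", tuple(self.unmatched_preds))
        object.__setattr__(self, "unmatched_refs", tuple(self.unmatched_refs))
        preds = [p for p, _, _ in self.pairs]
        refs = [r for _, r, _ in self.pairs]
        if len(set(preds)) != len(preds) or len(set(refs)) != len(refs):
            raise InputError("double assignment: each instance may appear at most once")


def _mask_pair(pred: Instance, ref: Instance, criterion: str):
    if pred.mask is None or ref.mask is None:
        raise InputError(f"{criterion} requires mask locators on both instances")
    if pred.mask.grid.shape != ref.mask.grid.shape:
        raise InputError("mask shape mismatch")
    return pred.mask.grid, ref.mask.grid


def _center(inst: Instance) -> np.ndarray:
    if inst.mask is not None:
        if inst.mask.is_empty:
            raise InputError("centroid of an empty mask is undefined")
        coords = np.argwhere(inst.mask.grid).astype(float)
        return coords.mean(axis=0) * np.asarray(inst.mask.spacing)
    if inst.box is not None:
        return np.asarray(inst.box.center(), dtype=float)
    return np.asarray(inst.point, dtype=float)


def localization_score(pred: Instance, ref: Instance, criterion: str) -> float:
    """Evaluate one localization criterion for one candidate pair."""
    if criterion not in CRITERIA:
        raise InputError(f"unknown localization criterion {criterion!r}")

    if criterion == "box_iou":
        if pred.box is None or ref.box is None:
            raise InputError("box_iou requires box locators")
        inter = pred.box.intersection_volume(ref.box)
        union = pred.box.volume + ref.box.volume - inter
        return inter / union

    if criterion in ("mask_iou", "approx_iou"):
        # "approx" locators are coarse user-supplied masks routed
        # through the same pathway, but tagged separately.
        p, r = _mask_pair(pred, ref, criterion)
        inter = int(np.sum(p & r))
        union = int(np.sum(p | r))
        if union == 0:
            raise InputError("both masks empty")
        return inter / union

    if criterion == "mask_iou_gt_zero":
        p, r = _mask_pair(pred, ref, criterion)
        return 1.0 if np.any(p & r) else 0.0

    if criterion == "ior":
        p, r = _mask_pair(pred, ref, criterion)
        denom = int(np.sum(r))
        if denom == 0:
            return float("nan")
        return int(np.sum(p & r)) / denom

    if criterion == "center_distance":
        a, b = _center(pred), _center(ref)
        if a.shape != b.shape:
            raise InputError("center dimensionality mismatch")
        return float(np.linalg.norm(a - b))

    if criterion == "point_inside_mask":
        if pred.point is None or ref.mask is None:
            raise InputError("point_inside_mask requires a point prediction and mask reference")
        idx = tuple(int(np.floor(c)) for c in pred.point)
        grid = ref.mask.grid
        inside = all(0 <= i < s for i, s in zip(idx, grid.shape)) and bool(grid[idx])
        return 1.0 if inside else 0.0

    # point_inside_box
    if pred.point is None or ref.box is None:
        raise InputError("point_inside_box requires a point prediction and box reference")
    inside = all(lo <= c < hi for c, lo, hi in zip(pred.point, ref.box.mins, ref.box.maxs))
    return 1.0 if inside else 0.0


def mask_iou_gt_zero(pred: Instance, ref: Instance) -> int:
    """1 iff the two instance masks overlap at all."""
    return int(localization_score(pred, ref, "mask_iou_gt_zero"))


def _score_matrix(preds: InstanceSet, refs: InstanceSet, cfg: MatchConfig):
    scores = np.full((len(preds), len(refs)), np.nan)
    for i, p in enumerate(preds):
        for j, r in enumerate(refs):
            scores[i, j] = localization_score(p, r, cfg.criterion)
    if cfg.direction == "higher":
        eligible = scores >= cfg.threshold
    else:
        eligible = scores <= cfg.threshold
    eligible &= ~np.isnan(scores)
    return scores, eligible


def build_match(preds: InstanceSet, refs: InstanceSet, cfg: MatchConfig) -> MatchResult:
    """Assign predictions to references one-to-one under the criterion.

    ``greedy_by_confidence``: predictions in descending confidence
    order (ties broken by input order) each take the best
    still-unmatched reference satisfying the threshold.  ``optimal``:
    the assignment maximizing the number of matched pairs, breaking
    remaining freedom by total criterion quality.  Both are
    deterministic.
    """
    if preds.image_id != refs.image_id:
        raise InputError("prediction and reference sets belong to different images")
    flags = {"criterion": cfg.criterion, "threshold": cfg.threshold,
             "direction": cfg.direction, "strategy": cfg.strategy}
    n, m = len(preds), len(refs)
    if n == 0 or m == 0:
        return MatchResult(pairs=(), unmatched_preds=tuple(range(n)),
                           unmatched_refs=tuple(range(m)), flags=flags)
    scores, eligible = _score_matrix(preds, refs, cfg)

    if cfg.strategy == "greedy_by_confidence":
        if any(p.confidence is None for p in preds):
            raise InputError("greedy matching requires a confidence on every prediction")
        order = sorted(range(n), key=lambda i: (-preds.instances[i].confidence, i))
        taken = set()
        pairs = []
        for i in order:
            best_j, best_val = None, None
            for j in range(m):
                if j in taken or not eligible[i, j]:
                    continue
                v = scores[i, j]
                better = (
                    best_val is None
                    or (cfg.direction == "higher" and v > best_val)
                    or (cfg.direction == "lower" and v < best_val)
                )
                if better:
                    best_j, best_val = j, v
            if best_j is not None:
                taken.add(best_j)
                pairs.append((i, best_j, float(best_val)))
        pairs.sort()
    else:
        # benefit = BIG per matched pair (count dominates), plus a
        # quality term in [0, 1) to break remaining freedom
        big = float(n + m + 1)
        with np.errstate(invalid="ignore"):
            quality = np.where(
                np.isnan(scores), 0.0,
                scores if cfg.direction == "higher" else 1.0 / (1.0 + scores),
            )
        benefit = np.where(eligible, big + np.clip(quality, 0.0, 1.0), 0.0)
        rows, cols = linear_sum_assignment(benefit, maximize=True)
        pairs = [
            (int(i), int(j), float(scores[i, j]))
            for i, j in zip(rows, cols)
            if eligible[i, j]
        ]
        pairs.sort()

    matched_p = {p for p, _, _ in pairs}
    matched_r = {r for _, r, _ in pairs}
    return MatchResult(
        pairs=tuple(pairs),
        unmatched_preds=tuple(i for i in range(n) if i not in matched_p),
        unmatched_refs=tuple(j for j in range(m) if j not in matched_r),
        flags=flags,
    )
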