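"""Dataset-level detection and instance-segmentation metrics.

Covers per-image counting with honest NaN semantics, average
precision with explicitly selectable score-tie dialects, the
mis-named legacy "Mean Average Precision" of the cell-segmentation
community (which is really TP/(TP+FP+FN), i.e. a counts-level IoU),
FROC, and panoptic quality.

Score-tie dialects
------------------
Evaluation codebases disagree on how predictions with *identical*
confidence scores enter the precision-recall sweep: one school
processes each prediction individually in input order
(``per_prediction``), another processes all equal-score predictions
as one joint block (``grouped_by_score``).  The two dialects can give
different AP values on the same detections, so the dialect is a
mandatory, logged parameter rather than a hidden default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import ConfusionCounts, InputError, InstanceSet, Level, MetricResult, nan_result
from .matching import MatchConfig, MatchResult, build_match, localization_score

logger = logging.getLogger("valimet")

__all__ = [
    "APConfig",
    "FROCConfig",
    "detection_counts",
    "average_precision",
    "mean_average_precision",
    "legacy_cellchallenge_precision",
    "froc",
    "panoptic_quality",
]


@dataclass(frozen=True)
class APConfig:
    """Tie dialect and interpolation for the PR sweep."""

    tie_dialect: str = "per_prediction"
    interpolation: str = "precision_envelope_all_points"

    def __post_init__(self):
        if self.tie_dialect not in ("per_prediction", "grouped_by_score"):
            raise InputError(f"unknown tie dialect {self.tie_dialect!r}")
        if self.interpolation != "precision_envelope_all_points":
            raise InputError(f"unknown interpolation {self.interpolation!r}")


@dataclass(frozen=True)
class FROCConfig:
    """FP-per-image operating points; the score averages sensitivity there."""

    operating_points: tuple = (0.125, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0)

    def __post_init__(self):
        pts = tuple(float(p) for p in self.operating_points)
        if not pts or any(p <= 0 for p in pts):
            raise InputError("operating points must be positive")
        if any(b <= a for a, b in zip(pts, pts[1:])):
            raise InputError("operating points must be strictly increasing")
        object.__setattr__(self, "operating_points", pts)


def detection_counts(match: MatchResult) -> ConfusionCounts:
    """Object-level TP/FP/FN from a matching; TNs do not exist here."""
    return ConfusionCounts(
        tp=len(match.pairs),
        fp=len(match.unmatched_preds),
        fn=len(match.unmatched_refs),
        tn=None,
        level=Level.OBJECT,
    )


# ---------------------------------------------------------------------------
# average precision


def _sweep_events(preds: Sequence[InstanceSet], refs: Sequence[InstanceSet],
                  match_cfg: MatchConfig, dialect: str):
    """Yield cumulative (tp, fp) after each sweep event.

    An event is one prediction (``per_prediction``) or one block of
    equal-score predictions (``grouped_by_score``).  Within the
    sweep, a prediction matches the best still-unmatched reference of
    its image satisfying the criterion.
    """
    ref_by_image = {rs.image_id: rs for rs in refs}
    flat = []  # (confidence, global_order, image_id, pred_index)
    for ps in preds:
        for k, p in enumerate(ps):
            if p.confidence is None:
                raise InputError(
                    "average precision requires a confidence score on every prediction"
                )
            flat.append((p.confidence, len(flat), ps.image_id, p))
    flat.sort(key=lambda t: (-t[0], t[1]))

    taken = {img: set() for img in ref_by_image}
    tp = fp = 0
    i = 0
    while i < len(flat):
        if dialect == "per_prediction":
            block = [flat[i]]
            i += 1
        else:
            j = i
            while j < len(flat) and flat[j][0] == flat[i][0]:
                j += 1
            block = flat[i:j]
            i = j
        for conf, _, image_id, p in block:
            rs = ref_by_image.get(image_id)
            best_j, best_val = None, -1.0
            if rs is not None:
                used = taken[image_id]
                for j2, r in enumerate(rs):
                    if j2 in used:
                        continue
                    v = localization_score(p, r, match_cfg.criterion)
                    ok = (v >= match_cfg.threshold if match_cfg.direction == "higher"
                          else v <= match_cfg.threshold)
                    if not ok or np.isnan(v):
                        continue
                    key = v if match_cfg.direction == "higher" else -v
                    if best_j is None or key > best_val:
                        best_j, best_val = j2, key
            if best_j is not None:
                taken[image_id].add(best_j)
                tp += 1
            else:
                fp += 1
        yield tp, fp


def _envelope_area(points) -> float:
    """Area under the PR step curve with the monotone precision envelope.

    AP = sum over distinct recall steps of (r_k - r_{k-1}) times the
    maximum precision attained at recall >= r_k.
    """
    if not points:
        return 0.0
    pts = sorted(points)
    area = 0.0
    prev_r = 0.0
    best_after = {}
    running = 0.0
    for r, p in sorted(pts, reverse=True):
        running = max(running, p)
        best_after[r] = running
    for r in sorted({r for r, _ in pts}):
        if r > prev_r:
            area += (r - prev_r) * best_after[r]
            prev_r = r
    return area


def average_precision(preds: Sequence[InstanceSet], refs: Sequence[InstanceSet],
                      match_cfg: MatchConfig, ap_cfg: APConfig = APConfig()) -> MetricResult:
    """AP over a dataset: area under the confidence-sweep PR curve."""
    n_ref = sum(len(rs) for rs in refs)
    flags = {"tie_dialect": ap_cfg.tie_dialect, "criterion": match_cfg.criterion,
             "threshold": match_cfg.threshold}
    if n_ref == 0:
        return nan_result("average_precision", "no reference instances in dataset",
                          level=Level.OBJECT, flags=flags)
    points = []
    for tp, fp in _sweep_events(preds, refs, match_cfg, ap_cfg.tie_dialect):
        recall = tp / n_ref
        precision = tp / (tp + fp)
        points.append((recall, precision))
    value = _envelope_area(points)
    return MetricResult(metric="average_precision", value=float(value),
                        level=Level.OBJECT, flags=flags)


def mean_average_precision(per_class_ap: Sequence[float],
                           nan_policy: str = "propagate") -> MetricResult:
    """Arithmetic mean of per-class APs (the standard mAP)."""
    values = np.asarray(list(per_class_ap), dtype=float)
    if values.size == 0:
        raise InputError("need at least one class AP")
    flags = {"nan_policy": nan_policy, "n_classes": int(values.size)}
    if np.all(np.isnan(values)):
        return nan_result("mean_average_precision", "all class APs undefined", flags=flags)
    if nan_policy == "propagate":
        value = float(np.mean(values))
    elif nan_policy == "omit":
        flags["omitted_nan"] = int(np.isnan(values).sum())
        value = float(np.nanmean(values))
    else:
        raise InputError(f"unknown nan policy {nan_policy!r}")
    return MetricResult(metric="mean_average_precision", value=value, flags=flags)


def legacy_cellchallenge_precision(counts: ConfusionCounts) -> MetricResult:
    """The mis-named cell-challenge "precision" TP/(TP+FP+FN).

    Despite circulating under "Mean Average Precision", this formula
    is a counts-level IoU, not a precision.  It is provided because
    the dialect is widespread, but results are flagged as
    non-standard naming.
    """
    if counts.level is not Level.OBJECT:
        raise InputError("legacy formula is defined on object-level counts")
    den = counts.tp + counts.fp + counts.fn
    flags = {"warning": "non-standard naming: formula equals counts-level IoU"}
    if den == 0:
        return nan_result("legacy_cellchallenge_precision", "no instances counted",
                          level=Level.OBJECT, flags=flags)
    return MetricResult(metric="legacy_cellchallenge_precision",
                        value=counts.tp / den, level=Level.OBJECT, flags=flags)


def froc(preds: Sequence[InstanceSet], refs: Sequence[InstanceSet],
         match_cfg: MatchConfig, froc_cfg: FROCConfig = FROCConfig()):
    """Free-response ROC: lesion sensitivity vs mean FPs per image.

    Sweeps the confidence threshold over all observed scores; at each
    threshold predictions at or above it are matched per image.
    Returns the curve as (fp_per_image, sensitivity) arrays plus the
    score: mean sensitivity at the configured operating points, with
    linear interpolation between achieved FP rates and clamping at
    the extremes.
    """
    n_ref = sum(len(rs) for rs in refs)
    n_img = len(list(refs))
    if n_img == 0:
        raise InputError("need at least one image")
    flags = {"operating_points": froc_cfg.operating_points,
             "criterion": match_cfg.criterion, "threshold": match_cfg.threshold}
    if n_ref == 0:
        curve = (np.asarray([0.0]), np.asarray([float("nan")]))
        return curve, nan_result("froc_score", "no reference instances in dataset",
                                 level=Level.OBJECT, flags=flags)
    all_scores = sorted(
        {p.confidence for ps in preds for p in ps}, reverse=True
    )
    if any(p.confidence is None for ps in preds for p in ps):
        raise InputError("FROC requires a confidence score on every prediction")
    ref_by_image = {rs.image_id: rs for rs in refs}
    fppi_list, sens_list = [0.0], [0.0]
    for t in all_scores:
        tp = fp = 0
        for ps in preds:
            kept = InstanceSet(ps.image_id,
                               [p for p in ps if p.confidence >= t])
            rs = ref_by_image.get(ps.image_id, InstanceSet(ps.image_id, []))
            m = build_match(kept, rs, match_cfg)
            tp += len(m.pairs)
            fp += len(m.unmatched_preds)
        fppi_list.append(fp / n_img)
        sens_list.append(tp / n_ref)
    fppi = np.asarray(fppi_list)
    sens = np.asarray(sens_list)
    order = np.argsort(fppi, kind="stable")
    fppi, sens = fppi[order], sens[order]
    # keep the best sensitivity per achieved FP rate
    uniq_f, best_s = [], []
    for f, s in zip(fppi, sens):
        if uniq_f and f == uniq_f[-1]:
            best_s[-1] = max(best_s[-1], s)
        else:
            uniq_f.append(f)
            best_s.append(s)
    value = float(np.mean(np.interp(froc_cfg.operating_points, uniq_f, best_s)))
    result = MetricResult(metric="froc_score", value=value, level=Level.OBJECT, flags=flags)
    return (np.asarray(uniq_f), np.asarray(best_s)), result


def panoptic_quality(refs: InstanceSet, preds: InstanceSet):
    """Panoptic quality with matching fixed at mask IoU > 0.5.

    PQ = (sum of matched IoUs) / (|TP| + |FP|/2 + |FN|/2); it factors
    into SQ (mean matched IoU) times RQ (detection F1).  An IoU
    threshold above 0.5 makes the matching unambiguous: no reference
    can overlap two predictions above 0.5.

    Returns ``(pq, sq, rq)`` as MetricResults.
    """
    flags = {"criterion": "mask_iou", "threshold": "> 0.5"}
    if len(refs) == 0 and len(preds) == 0:
        nan = nan_result("panoptic_quality", "no instances on either side",
                         level=Level.OBJECT, flags=flags)
        return nan, nan_result("segmentation_quality", "no instances", flags=flags), \
            nan_result("recognition_quality", "no instances", flags=flags)
    pairs = []
    taken = set()
    for j, r in enumerate(refs):
        for i, p in enumerate(preds):
            if i in taken:
                continue
            v = localization_score(p, r, "mask_iou")
            if v > 0.5:
                pairs.append((i, j, v))
                taken.add(i)
                break  # IoU > 0.5 is unique per reference
    tp = len(pairs)
    fp = len(preds) - tp
    fn = len(refs) - tp
    den = tp + 0.5 * fp + 0.5 * fn
    iou_sum = sum(v for _, _, v in pairs)
    pq = MetricResult(metric="panoptic_quality", value=float(iou_sum / den),
                      level=Level.OBJECT, flags=flags)
    if tp == 0:
        sq = nan_result("segmentation_quality", "no matched pairs", flags=flags)
    else:
        sq = MetricResult(metric="segmentation_quality", value=float(iou_sum / tp),
                          level=Level.OBJECT, flags=flags)
    rq = MetricResult(metric="recognition_quality", value=float(tp / den),
                      level=Level.OBJECT, flags=flags)
    return pq, sq, rq
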