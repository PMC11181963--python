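"""Metric aggregation across classes, images, patients and cohorts.

Aggregation is where validation results are most easily distorted
without anyone noticing: a flat mean over all images hides that one
patient contributed most of them, pooling pixel counts over the data
set lets one huge well-segmented structure drown the errors on small
ones, and silently dropped NaNs make undefined cases disappear.

The defaults here are deliberately the loudest ones: mean per image,
macro over classes, NaN propagation.  Every aggregate comes with an
audit record stating exactly how many values went in, how many were
NaN, and what happened to them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import InputError, Level, MetricResult, PixelMask, pixel_confusion
from .overlap import OverlapConfig

__all__ = ["CohortTable", "AggregationSpec", "aggregate", "pooled_pixel_metric"]

_LEVEL_COLUMNS = {"image": "image_id", "patient": "patient_id", "cohort": "cohort_id",
                  "hospital": "cohort_id"}


@dataclass(frozen=True)
class CohortTable:
    """Long-format per-case metric records with hierarchy columns.

    Required columns: metric, value, image_id.  Optional: class_label,
    patient_id, cohort_id.  (metric, class_label, image_id) keys must
    be unique and an image must belong to exactly one patient.
    """

    records: pd.DataFrame

    def __post_init__(self):
        df = self.records.copy()
        for col in ("metric", "value", "image_id"):
            if col not in df.columns:
                raise InputError(f"cohort table requires column {col!r}")
        for col in ("class_label", "patient_id", "cohort_id"):
            if col not in df.columns:
                df[col] = None
        keys = df[["metric", "class_label", "image_id"]]
        if keys.duplicated().any():
            raise InputError("(metric, class, image) keys must be unique")
        per_image = df.groupby("image_id")["patient_id"].nunique(dropna=False)
        if (per_image > 1).any():
            raise InputError("an image must belong to exactly one patient")
        object.__setattr__(self, "records", df)

    @classmethod
    def from_results(cls, results: Sequence[MetricResult], patients=None, cohorts=None):
        rows = []
        patients = patients or {}
        cohorts = cohorts or {}
        for r in results:
            rows.append({
                "metric": r.metric, "value": r.value, "class_label": r.class_label,
                "image_id": r.image_id, "patient_id": patients.get(r.image_id),
                "cohort_id": cohorts.get(r.image_id),
            })
        return cls(pd.DataFrame(rows))


@dataclass(frozen=True)
class AggregationSpec:
    """How to turn per-case values into one number — and how loudly.

    ``substitute_worst`` replaces NaN by ``worst_value`` (0 for
    [0,1]-scores; for distances pass a finite cap such as the image
    diagonal), logging every substitution in the audit.
    """

    scheme: str = "mean_per_image"
    hierarchy: tuple = ("patient", "image")
    class_handling: str = "macro"
    nan_policy: str = "propagate"
    worst_value: float = 0.0

    def __post_init__(self):
        if self.scheme not in ("mean_per_image", "hierarchical", "pool_then_compute"):
            raise InputError(f"unknown aggregation scheme {self.scheme!r}")
        if self.scheme == "hierarchical" and len(self.hierarchy) < 1:
            raise InputError("hierarchical scheme requires at least one level")
        for level in self.hierarchy:
            if level not in _LEVEL_COLUMNS:
                raise InputError(f"unknown hierarchy level {level!r}")
        if self.class_handling not in ("macro", "micro"):
            raise InputError(f"unknown class handling {self.class_handling!r}")
        if self.nan_policy not in ("propagate", "omit_with_count", "substitute_worst"):
            raise InputError(f"unknown NaN policy {self.nan_policy!r}")
        object.__setattr__(self, "hierarchy", tuple(self.hierarchy))
        if not math.isfinite(self.worst_value):
            raise InputError("worst_value must be finite (cap distances explicitly)")


def _apply_nan_policy(values: np.ndarray, spec: AggregationSpec, audit: dict) -> np.ndarray:
    nan_mask = np.isnan(values)
    audit["nan_seen"] = audit.get("nan_seen", 0) + int(nan_mask.sum())
    if spec.nan_policy == "propagate" or not nan_mask.any():
        return values
    if spec.nan_policy == "omit_with_count":
        audit["nan_omitted"] = audit.get("nan_omitted", 0) + int(nan_mask.sum())
        return values[~nan_mask]
    audit["nan_substituted"] = audit.get("nan_substituted", 0) + int(nan_mask.sum())
    out = values.copy()
    out[nan_mask] = spec.worst_value
    return out


def _mean(values: np.ndarray, spec: AggregationSpec, audit: dict) -> float:
    values = _apply_nan_policy(np.asarray(values, dtype=float), spec, audit)
    if values.size == 0:
        return float("nan")
    return float(np.mean(values))


def _aggregate_one_metric(df: pd.DataFrame, spec: AggregationSpec, audit: dict) -> float:
    if spec.scheme == "mean_per_image":
        return _mean(df["value"].to_numpy(), spec, audit)
    # hierarchical: average bottom-up, innermost level first
    levels = [_LEVEL_COLUMNS[name] for name in spec.hierarchy]
    work = df[levels + ["value"]].copy()
    audit.setdefault("per_level_counts", {})
    # innermost level is the record grain; average it within each
    # outer grouping, then walk outwards
    for depth in range(len(levels) - 1, 0, -1):
        group_cols = levels[:depth]
        audit["per_level_counts"][spec.hierarchy[depth]] = int(len(work))
        work = (
            work.groupby(group_cols, dropna=False)["value"]
            .apply(lambda v: _mean(v.to_numpy(), spec, audit))
            .reset_index()
        )
    audit["per_level_counts"][spec.hierarchy[0]] = int(len(work))
    return _mean(work["value"].to_numpy(), spec, audit)


def aggregate(table: CohortTable, spec: AggregationSpec = AggregationSpec()):
    """Aggregate a cohort table into one value per metric.

    Returns ``(results, audit)``: a dict metric -> MetricResult and an
    audit record with record counts and the fate of every NaN.
    """
    df = table.records
    if df.empty:
        raise InputError("empty cohort table")
    if spec.scheme == "pool_then_compute":
        raise InputError(
            "pool_then_compute operates on masks, not on a value table; "
            "use pooled_pixel_metric"
        )
    results = {}
    audit = {"scheme": spec.scheme, "nan_policy": spec.nan_policy,
             "records_total": int(len(df)), "per_metric": {}}
    for metric, sub in df.groupby("metric", sort=True):
        m_audit: dict = {"records": int(len(sub))}
        classes = [c for c in sub["class_label"].unique()]
        if spec.class_handling == "macro" and len(classes) > 1:
            per_class = {}
            for c, csub in sub.groupby("class_label", dropna=False, sort=True):
                per_class[c] = _aggregate_one_metric(csub, spec, m_audit)
            value = _mean(np.asarray(list(per_class.values())), spec, m_audit)
            m_audit["per_class"] = {str(k): v for k, v in per_class.items()}
        else:
            value = _aggregate_one_metric(sub, spec, m_audit)
        audit["per_metric"][metric] = m_audit
        results[metric] = MetricResult(
            metric=metric, value=value,
            flags={"scheme": spec.scheme, "class_handling": spec.class_handling,
                   "nan_policy": spec.nan_policy},
        )
    return results, audit


def pooled_pixel_metric(mask_pairs, metric_id: str, beta: float = 1.0,
                        cfg: OverlapConfig = OverlapConfig()) -> MetricResult:
    """Dataset-pooled overlap metric: sum counts first, apply formula once.

    ``mask_pairs`` is an iterable of (reference, prediction)
    PixelMask pairs.  Pooling suppresses per-image information —
    errors on small structures vanish behind large correct ones — so
    the result is explicitly flagged ``scheme=pool_then_compute``.
    """
    if metric_id not in ("dice", "iou", "pixel_f_beta"):
        raise InputError(f"unknown pooled pixel metric {metric_id!r}")
    tp = fp = fn = 0
    n_pairs = 0
    for ref, pred in mask_pairs:
        c = pixel_confusion(ref, pred)
        tp, fp, fn = tp + c.tp, fp + c.fp, fn + c.fn
        n_pairs += 1
    if n_pairs == 0:
        raise InputError("no mask pairs supplied")
    flags = {"scheme": "pool_then_compute", "n_images": n_pairs,
             "empty_both_policy": cfg.empty_both_policy}
    if tp + fp + fn == 0:
        if cfg.empty_both_policy == "one":
            value = 1.0
        else:
            return MetricResult(metric=metric_id, value=float("nan"),
                                level=Level.PIXEL, flags=flags)
    elif metric_id == "dice":
        value = 2.0 * tp / (2.0 * tp + fp + fn)
    elif metric_id == "iou":
        value = tp / (tp + fp + fn)
    else:
        b2 = beta * beta
        flags["beta"] = beta
        value = (1 + b2) * tp / ((1 + b2) * tp + b2 * fn + fp)
    return MetricResult(metric=metric_id, value=float(value), level=Level.PIXEL, flags=flags)
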