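"""Algorithm ranking, ranking stability, and metric-redundancy warnings.

Challenge leaderboards are produced by a pipeline of choices —
aggregate with mean or median, aggregate before or after ranking —
and each choice can change who "wins".  The schemes are therefore
named and selectable, and a seeded case-resampling bootstrap
quantifies how stable the resulting ranking actually is (Kendall's
tau-b between each replicate ranking and the full-data ranking).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import kendalltau, rankdata

from .core import InputError

__all__ = [
    "RankingTask",
    "StabilityConfig",
    "rank",
    "bootstrap_stability",
    "redundancy_check",
    "KNOWN_METRIC_IDS",
]


@dataclass(frozen=True)
class RankingTask:
    """Algorithms x cases value matrix plus orientation and scheme."""

    values: pd.DataFrame  # rows = algorithms, columns = cases
    orientation: str = "higher"
    scheme: str = "aggregate_then_rank_mean"

    def __post_init__(self):
        df = pd.DataFrame(self.values).astype(float)
        if df.shape[0] < 2 or df.shape[1] < 1:
            raise InputError("need at least 2 algorithms and 1 case")
        if self.orientation not in ("higher", "lower"):
            raise InputError("orientation must be 'higher' or 'lower'")
        if self.scheme not in (
            "aggregate_then_rank_mean",
            "aggregate_then_rank_median",
            "rank_then_aggregate",
        ):
            raise InputError(f"unknown ranking scheme {self.scheme!r}")
        object.__setattr__(self, "values", df)


@dataclass(frozen=True)
class StabilityConfig:
    """Bootstrap replicate count and the mandatory seed."""

    replicates: int = 1000
    seed: int = 0

    def __post_init__(self):
        if int(self.replicates) < 1:
            raise InputError("replicate count must be >= 1")
        if self.seed is None:
            raise InputError("a seed is mandatory for reproducible resampling")


def _aggregate_rows(task: RankingTask, values: pd.DataFrame) -> pd.Series:
    """Per-algorithm score whose *ascending* order is the ranking order."""
    with np.errstate(invalid="ignore"):
        if task.scheme == "rank_then_aggregate":
            # per-case midranks (rank 1 = best), mean over cases
            arr = values.to_numpy()
            oriented = -arr if task.orientation == "higher" else arr
            # NaN values rank worst within their case
            worst = np.nanmax(oriented) if np.isfinite(oriented).any() else 0.0
            oriented = np.where(np.isnan(oriented), worst + 1.0, oriented)
            case_ranks = np.apply_along_axis(
                lambda col: rankdata(col, method="average"), 0, oriented
            )
            return pd.Series(case_ranks.mean(axis=1), index=values.index)
        agg = np.nanmean if task.scheme == "aggregate_then_rank_mean" else np.nanmedian

        def row_agg(row):
            arr = row.to_numpy()
            if np.all(np.isnan(arr)):
                return np.nan
            return agg(arr)

        scores = values.apply(row_agg, axis=1)
    # all-NaN rows aggregate to NaN; they must rank last
    key = scores if task.orientation == "lower" else -scores
    key = key.fillna(np.inf)
    return key


def rank(task: RankingTask) -> pd.DataFrame:
    """Rank algorithms under the task's scheme.

    Returns a DataFrame indexed by algorithm with columns ``score``
    (the aggregate or mean rank the ordering is based on) and
    ``rank`` (competition ranking: ties share the best rank).  Rows
    are ordered by rank, ties broken for display by algorithm id.
    """
    key = _aggregate_rows(task, task.values)
    if np.isinf(key).any():
        import logging
        logging.getLogger("valimet").warning(
            "algorithm(s) with all-NaN values ranked last: %s",
            list(key.index[np.isinf(key)]),
        )
    ranks = rankdata(key.to_numpy(), method="min")
    out = pd.DataFrame({"score": key.to_numpy(), "rank": ranks.astype(int)},
                       index=key.index)
    out = out.loc[sorted(out.index)]  # display tie-break by algorithm id
    return out.sort_values("rank", kind="stable")


def bootstrap_stability(task: RankingTask, cfg: StabilityConfig):
    """Case-resampling bootstrap of the ranking.

    Resamples the case columns with replacement ``replicates`` times
    (seeded, bit-reproducible), ranks each replicate under the task
    scheme, and compares it to the full-data ranking via Kendall's
    tau-b (tie-adjusted).  Returns ``(taus, rank_frequency)`` where
    ``rank_frequency`` counts, per algorithm, how often each rank was
    attained across replicates.
    """
    n_cases = task.values.shape[1]
    if n_cases < 2:
        raise InputError("bootstrap needs at least 2 cases to resample")
    rng = np.random.default_rng(cfg.seed)
    full = rank(task)["rank"]
    algorithms = list(task.values.index)
    n_algo = len(algorithms)
    taus = np.empty(cfg.replicates)
    freq = pd.DataFrame(0, index=algorithms, columns=range(1, n_algo + 1))
    for b in range(cfg.replicates):
        cols = rng.integers(0, n_cases, size=n_cases)
        sample = task.values.iloc[:, cols]
        sample.columns = range(n_cases)  # duplicated labels are fine as positions
        rep = rank(RankingTask(sample, task.orientation, task.scheme))["rank"]
        rep = rep.reindex(algorithms)
        tau, _ = kendalltau(full.reindex(algorithms), rep)
        taus[b] = tau
        for a in algorithms:
            freq.loc[a, int(rep[a])] += 1
    return taus, freq


# ---------------------------------------------------------------------------
# metric-redundancy warnings

# every metric id the toolkit can produce, plus common synonyms
_SYNONYM_GROUPS = (
    frozenset({"sensitivity", "recall", "true_positive_rate", "tpr", "hit_rate"}),
    frozenset({"ppv", "precision"}),
    frozenset({"iou", "jaccard"}),
    frozenset({"dice", "dsc", "f1"}),
)

_RELATED_PAIRS = (
    (frozenset({"dice", "dsc"}), frozenset({"iou", "jaccard"}),
     "IoU = DSC / (2 - DSC): the two are functionally determined"),
    (frozenset({"legacy_cellchallenge_precision"}), frozenset({"iou", "jaccard"}),
     "TP/(TP+FP+FN) is the counts-level IoU under a misleading name"),
)

KNOWN_METRIC_IDS = frozenset(
    {
        "accuracy", "balanced_accuracy", "sensitivity", "specificity", "ppv", "npv",
        "lr_plus", "f_beta", "mcc", "expected_cost", "weighted_cohens_kappa",
        "net_benefit", "auroc", "ece", "dice", "iou", "pixel_f_beta", "cl_dice",
        "hausdorff", "hausdorff_95", "assd", "average_precision",
        "mean_average_precision", "legacy_cellchallenge_precision", "froc_score",
        "panoptic_quality", "segmentation_quality", "recognition_quality",
    }
    | frozenset().union(*_SYNONYM_GROUPS)
)


def redundancy_check(metric_ids: Sequence[str]):
    """Warn when a metric set contains synonyms or related pairs.

    Two metrics that are synonyms (sensitivity/recall) or functional
    transforms of each other (DSC and IoU) measure the same thing;
    ranking on both adds no information and silently double-weights
    it.
    """
    ids = [m.lower() for m in metric_ids]
    for m in ids:
        if m not in KNOWN_METRIC_IDS:
            raise InputError(f"unknown metric id {m!r}")
    warnings = []
    present = set(ids)
    for group in _SYNONYM_GROUPS:
        hit = sorted(present & group)
        if len(hit) > 1:
            warnings.append({
                "kind": "synonym",
                "metrics": hit,
                "message": f"{' and '.join(hit)} refer to the same mathematical formula",
            })
    for a, b, why in _RELATED_PAIRS:
        ha, hb = sorted(present & a), sorted(present & b)
        if ha and hb:
            warnings.append({
                "kind": "related",
                "metrics": ha + hb,
                "message": why,
            })
    return warnings
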