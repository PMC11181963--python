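"""Image-level classification metrics: counting, multi-threshold, calibration.

All counting metrics share one edge-case policy: a zero denominator
makes the value *undefined* and the function returns NaN (logged with
the reason).  No smoothing constant is ever added silently; callers
who want a fallback value substitute it explicitly downstream (see
:mod:`valimet.aggregation`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.stats import rankdata

from .core import (
    ConfusionCounts,
    ConfusionMatrix,
    InputError,
    Level,
    MetricParams,
    MetricResult,
    nan_result,
)

__all__ = [
    "COUNTING_METRICS",
    "CostMatrix",
    "CalibrationSet",
    "KappaWeights",
    "counting_metric",
    "macro_counting_metric",
    "one_vs_rest_counts",
    "expected_cost",
    "weighted_cohens_kappa",
    "net_benefit",
    "auroc",
    "expected_calibration_error",
]


@dataclass(frozen=True)
class CostMatrix:
    """Per-confusion costs, indexed (true, predicted); diagonal usually 0."""

    classes: tuple
    costs: np.ndarray

    def __post_init__(self):
        classes = tuple(self.classes)
        costs = np.asarray(self.costs, dtype=float)
        if costs.shape != (len(classes), len(classes)):
            raise InputError("costs must be K x K matching the class order")
        if np.any(costs < 0):
            raise InputError("costs must be non-negative")
        costs = costs.copy()
        costs.setflags(write=False)
        object.__setattr__(self, "classes", classes)
        object.__setattr__(self, "costs", costs)

    @classmethod
    def zero_one(cls, classes) -> "CostMatrix":
        k = len(tuple(classes))
        return cls(tuple(classes), np.ones((k, k)) - np.eye(k))


@dataclass(frozen=True)
class CalibrationSet:
    """Per-sample confidences and binary outcomes plus the binning config.

    The binning is part of the value: different bin counts or schemes
    give different ECEs, so both are carried and echoed into the
    result flags.
    """

    confidences: np.ndarray
    outcomes: np.ndarray
    bins: int = 10
    scheme: str = "equal_width"

    def __post_init__(self):
        conf = np.asarray(self.confidences, dtype=float)
        out = np.asarray(self.outcomes)
        if conf.ndim != 1 or out.shape != conf.shape:
            raise InputError("confidences and outcomes must be equal-length 1D")
        if conf.size and (conf.min() < 0.0 or conf.max() > 1.0):
            raise InputError("confidences must lie in [0, 1]")
        if not np.all(np.isin(out, [0, 1])):
            raise InputError("outcomes must be binary")
        if int(self.bins) < 1:
            raise InputError("bin count must be >= 1")
        if self.scheme not in ("equal_width", "equal_count"):
            raise InputError(f"unknown binning scheme {self.scheme!r}")
        conf = conf.copy()
        conf.setflags(write=False)
        out = out.astype(np.int64)
        out.setflags(write=False)
        object.__setattr__(self, "confidences", conf)
        object.__setattr__(self, "outcomes", out)
        object.__setattr__(self, "bins", int(self.bins))


@dataclass(frozen=True)
class KappaWeights:
    """Disagreement weights for weighted Cohen's kappa."""

    scheme: str = "quadratic"
    custom: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.scheme not in ("linear", "quadratic", "custom"):
            raise InputError(f"unknown kappa weight scheme {self.scheme!r}")
        if (self.scheme == "custom") != (self.custom is not None):
            raise InputError("custom weights required iff scheme == 'custom'")
        if self.custom is not None:
            w = np.asarray(self.custom, dtype=float)
            if w.ndim != 2 or w.shape[0] != w.shape[1]:
                raise InputError("custom weights must be square")
            if np.any(w < 0) or np.any(np.diag(w) != 0):
                raise InputError("custom weights must be non-negative with zero diagonal")
            w = w.copy()
            w.setflags(write=False)
            object.__setattr__(self, "custom", w)

    def matrix(self, k: int) -> np.ndarray:
        if self.scheme == "custom":
            if self.custom.shape != (k, k):
                raise InputError("custom weight matrix size mismatch")
            return self.custom
        i, j = np.indices((k, k))
        d = np.abs(i - j).astype(float)
        return d if self.scheme == "linear" else d**2


# ---------------------------------------------------------------------------
# counting metrics

COUNTING_METRICS = (
    "accuracy",
    "balanced_accuracy",
    "sensitivity",
    "specificity",
    "ppv",
    "npv",
    "lr_plus",
    "f_beta",
    "mcc",
)

_NEEDS_TN = {"accuracy", "balanced_accuracy", "specificity", "npv", "lr_plus", "mcc"}


def _ratio(num: float, den: float) -> float:
    return num / den if den != 0 else float("nan")


def counting_metric(
    counts: ConfusionCounts,
    metric_id: str,
    params: Optional[MetricParams] = None,
) -> MetricResult:
    """Evaluate one confusion-count metric with uniform NaN semantics."""
    params = params or MetricParams()
    if metric_id not in COUNTING_METRICS:
        raise InputError(f"unknown counting metric {metric_id!r}")
    if metric_id in _NEEDS_TN and counts.tn is None:
        raise InputError(f"{metric_id} requires true negatives; object-level counts have none")
    tp, fp, fn = float(counts.tp), float(counts.fp), float(counts.fn)
    tn = float(counts.tn) if counts.tn is not None else float("nan")
    flags: dict = {}

    if metric_id == "accuracy":
        value = _ratio(tp + tn, tp + tn + fp + fn)
    elif metric_id == "sensitivity":
        value = _ratio(tp, tp + fn)
    elif metric_id == "specificity":
        value = _ratio(tn, tn + fp)
    elif metric_id == "ppv":
        value = _ratio(tp, tp + fp)
    elif metric_id == "npv":
        value = _ratio(tn, tn + fn)
    elif metric_id == "balanced_accuracy":
        sens = _ratio(tp, tp + fn)
        spec = _ratio(tn, tn + fp)
        value = (sens + spec) / 2.0
    elif metric_id == "lr_plus":
        sens = _ratio(tp, tp + fn)
        fpr = _ratio(fp, fp + tn)
        value = _ratio(sens, fpr) if not math.isnan(sens) and not math.isnan(fpr) else float("nan")
    elif metric_id == "f_beta":
        b2 = params.beta**2
        value = _ratio((1 + b2) * tp, (1 + b2) * tp + b2 * fn + fp)
        flags["beta"] = params.beta
    else:  # mcc
        den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
        value = _ratio(tp * tn - fp * fn, den)

    if math.isnan(value):
        return nan_result(metric_id, "zero denominator", level=counts.level, flags=flags)
    return MetricResult(metric=metric_id, value=float(value), level=counts.level, flags=flags)


def one_vs_rest_counts(cm: ConfusionMatrix, class_label) -> ConfusionCounts:
    """Collapse a multi-class table to binary counts for one class."""
    if class_label not in cm.classes:
        raise InputError(f"class {class_label!r} not in matrix")
    i = cm.classes.index(class_label)
    tp = int(cm.counts[i, i])
    fn = int(cm.counts[i, :].sum() - tp)
    fp = int(cm.counts[:, i].sum() - tp)
    tn = int(cm.total - tp - fn - fp)
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn, level=Level.IMAGE)


def macro_counting_metric(
    cm: ConfusionMatrix, metric_id: str, params: Optional[MetricParams] = None
) -> MetricResult:
    """One-vs-rest macro average; per-class NaNs propagate visibly."""
    values = [
        counting_metric(one_vs_rest_counts(cm, c), metric_id, params).value
        for c in cm.classes
    ]
    value = float(np.mean(values))  # NaN if any class undefined
    return MetricResult(
        metric=metric_id,
        value=value,
        level=Level.IMAGE,
        flags={"averaging": "macro_one_vs_rest", "per_class": values},
    )


# ---------------------------------------------------------------------------
# cost- and agreement-based metrics


def expected_cost(
    cm: ConfusionMatrix, costs: CostMatrix, priors: Optional[Sequence[float]] = None
) -> MetricResult:
    """Prior-weighted expected misclassification cost.

    EC = sum_i pi_i sum_j c(i, j) P(pred = j | true = i).  With no
    explicit priors the empirical class frequencies are used.  A class
    with zero support but nonzero prior makes the conditional
    probabilities - and hence EC - undefined.
    """
    if costs.classes != cm.classes:
        raise InputError("cost matrix classes must match confusion matrix classes")
    support = cm.row_marginals().astype(float)
    total = support.sum()
    if priors is None:
        if total == 0:
            return nan_result("expected_cost", "empty confusion matrix")
        pi = support / total
        prior_kind = "empirical"
    else:
        pi = np.asarray(priors, dtype=float)
        if pi.shape != (len(cm.classes),):
            raise InputError("priors length must match class count")
        if abs(pi.sum() - 1.0) > 1e-9:
            raise InputError("priors must sum to 1")
        prior_kind = "explicit"
    flags = {"priors": prior_kind}
    if np.any((support == 0) & (pi > 0)):
        return nan_result(
            "expected_cost", "class with zero support but nonzero prior", flags=flags
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        cond = np.divide(
            cm.counts, support[:, None], out=np.zeros_like(cm.counts, dtype=float),
            where=support[:, None] != 0,
        )
    value = float(np.sum(pi[:, None] * costs.costs * cond))
    return MetricResult(metric="expected_cost", value=value, flags=flags)


def weighted_cohens_kappa(cm: ConfusionMatrix, weights: KappaWeights) -> MetricResult:
    """Chance-corrected agreement with confusion-severity weights.

    kappa_w = 1 - (sum w O) / (sum w E), with E the outer product of
    the margins scaled to the total.
    """
    total = cm.total
    if total == 0:
        raise InputError("all-zero confusion matrix")
    k = len(cm.classes)
    w = weights.matrix(k)
    observed = cm.counts / total
    expected = np.outer(cm.row_marginals(), cm.col_marginals()) / (total * total)
    exp_dis = float(np.sum(w * expected))
    flags = {"weights": weights.scheme}
    if exp_dis == 0:
        return nan_result("weighted_cohens_kappa", "expected disagreement is zero", flags=flags)
    value = 1.0 - float(np.sum(w * observed)) / exp_dis
    return MetricResult(metric="weighted_cohens_kappa", value=value, flags=flags)


def net_benefit(counts: ConfusionCounts, threshold_prob: float, n: int) -> MetricResult:
    """Decision-analytic net benefit at threshold probability p_t.

    NB = TP/n - (FP/n) * p_t / (1 - p_t).  The threshold probability
    encodes the harm:benefit odds of acting on a positive prediction.
    """
    if not 0.0 < threshold_prob < 1.0:
        raise InputError("threshold_prob must lie in (0, 1)")
    if n == 0:
        raise InputError("n must be positive")
    if n < counts.total:
        raise InputError("n smaller than the number of counted samples")
    value = counts.tp / n - (counts.fp / n) * (threshold_prob / (1.0 - threshold_prob))
    return MetricResult(
        metric="net_benefit", value=float(value), flags={"threshold_prob": threshold_prob}
    )


# ---------------------------------------------------------------------------
# multi-threshold and calibration metrics


def auroc(scores, labels) -> MetricResult:
    """Area under the ROC curve via the rank-sum identity.

    Equals the probability that a uniformly drawn positive outranks a
    uniformly drawn negative, counting ties as half.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if s.ndim != 1 or y.shape != s.shape:
        raise InputError("scores and labels must be equal-length 1D")
    if not np.all(np.isin(y, [0, 1])):
        raise InputError("labels must be binary")
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        return nan_result("auroc", "only one class present")
    ranks = rankdata(s)  # midranks: ties counted half
    value = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    return MetricResult(metric="auroc", value=float(value))


def _bin_edges(cal: CalibrationSet) -> np.ndarray:
    if cal.scheme == "equal_width":
        return np.linspace(0.0, 1.0, cal.bins + 1)
    # equal_count: quantile edges over the observed confidences
    qs = np.linspace(0.0, 1.0, cal.bins + 1)
    edges = np.quantile(cal.confidences, qs)
    edges[0], edges[-1] = 0.0, 1.0
    return edges


def expected_calibration_error(cal: CalibrationSet) -> MetricResult:
    """Binned expected calibration error.

    ECE = sum_b (n_b / N) |acc_b - conf_b| over non-empty bins.  Bins
    are right-closed at 1.0 so confidence 1.0 falls in the last bin.
    Note the estimator is biased upward for small samples even for a
    perfectly calibrated model.
    """
    n = cal.confidences.size
    if n == 0:
        raise InputError("empty calibration set")
    edges = _bin_edges(cal)
    # right-open bins except the last, which is right-closed at 1.0
    idx = np.clip(np.searchsorted(edges, cal.confidences, side="right") - 1, 0, cal.bins - 1)
    ece = 0.0
    for b in range(cal.bins):
        sel = idx == b
        nb = int(sel.sum())
        if nb == 0:
            continue
        acc = cal.outcomes[sel].mean()
        conf = cal.confidences[sel].mean()
        ece += (nb / n) * abs(acc - conf)
    return MetricResult(
        metric="ece",
        value=float(ece),
        flags={"bins": cal.bins, "scheme": cal.scheme},
    )
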