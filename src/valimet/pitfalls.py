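"""Machine-readable pitfall taxonomy and seeded toy-scenario generators.

The taxonomy has three top-level categories — (P1) inadequate choice
of the problem category, (P2) poor metric selection, (P3) poor metric
application — with four subcategories under P2 and five under P3,
and 37 distinct pitfall sources in total.  Each source carries the
set of metrics it can affect (the warning matrix) and, where the
pitfall is computational rather than a matter of reporting style, a
deterministic toy-scenario generator whose expected behaviour is
assertable.

Sources whose pitfall lives in prose, plots or study design
(visualization, variability reporting, interpretation margins) are
*registry-only*: they appear in the taxonomy and applicability matrix
but honestly carry no numeric demonstration.

The exact allocation of a few sources between neighbouring
subcategories is not uniquely determined by the published category
overview; the registry metadata records this ambiguity
(``assignment_note``) instead of hiding it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import overlap
from .aggregation import AggregationSpec, CohortTable, aggregate, pooled_pixel_metric
from .boundary import BoundaryConfig, SurfacePointSet, hausdorff, hausdorff_percentile, mask_distance
from .classification import (
    CalibrationSet,
    CostMatrix,
    counting_metric,
    expected_cost,
    expected_calibration_error,
)
from .core import (
    BoundingBox,
    ConfusionCounts,
    InputError,
    Instance,
    InstanceSet,
    Level,
    MetricParams,
    PixelMask,
    multiclass_confusion,
)
from .detection import APConfig, average_precision, detection_counts
from .matching import MatchConfig, build_match
from .ranking import KNOWN_METRIC_IDS, RankingTask, StabilityConfig, bootstrap_stability, redundancy_check

__all__ = [
    "PitfallSource",
    "TaxonomyRegistry",
    "ScenarioBundle",
    "DemoReport",
    "registry",
    "pitfall_applicability",
    "generate",
    "demonstrate",
    "SCENARIO_IDS",
]

ALL = frozenset({"*"})  # source applies to any metric being aggregated/reported

_COUNTING = frozenset({
    "accuracy", "balanced_accuracy", "expected_cost", "f_beta", "lr_plus", "mcc",
    "net_benefit", "ppv", "npv", "sensitivity", "specificity", "weighted_cohens_kappa",
})
_OVERLAP = frozenset({"dice", "iou", "pixel_f_beta", "cl_dice"})
_BOUNDARY = frozenset({"hausdorff", "hausdorff_95", "assd"})
_DETECTION = frozenset({"f_beta", "ppv", "sensitivity", "average_precision",
                        "froc_score", "panoptic_quality"})


@dataclass(frozen=True)
class PitfallSource:
    """One pitfall source: category code, warning row, scenario links."""

    id: str
    category: str
    name: str
    affected_metrics: frozenset
    figure_anchor: Optional[str] = None
    scenarios: tuple = ()
    footnotes: dict = field(default_factory=dict)

    @property
    def registry_only(self) -> bool:
        return not self.scenarios


_SOURCES = (
    # ----- P1: inadequate choice of the problem category
    PitfallSource(
        "wrong_problem_category", "P1", "Wrong choice of problem category",
        frozenset({"dice", "iou", "pixel_f_beta", "sensitivity"}),
        "F1/F3", ("F1A", "F3"),
    ),
    PitfallSource(
        "no_matching_problem_category", "P1", "Lack of matching problem category",
        frozenset({"dice", "iou", "pixel_f_beta", "sensitivity"}),
    ),
    # ----- P2.1: disregard of the domain interest
    PitfallSource(
        "structure_boundaries", "P2.1", "Importance of structure boundaries",
        _OVERLAP, "F4a", ("F4a",),
    ),
    PitfallSource(
        "structure_centerline", "P2.1", "Importance of structure center(line)",
        frozenset({"dice", "iou", "pixel_f_beta"}), "F7b", ("F7b",),
    ),
    PitfallSource(
        "structure_volume", "P2.1", "Importance of structure volume",
        frozenset({"dice", "iou", "pixel_f_beta"}),
    ),
    PitfallSource(
        "unequal_confusion_severity", "P2.1", "Unequal severity of class confusions",
        (_COUNTING - {"expected_cost", "weighted_cohens_kappa", "net_benefit"})
        | frozenset({"cl_dice", "dice", "iou"}) | _DETECTION,
        "F4b", ("F4b",),
        footnotes={"f_beta": "the beta hyperparameter can penalize one confusion "
                             "direction in the binary case"},
    ),
    PitfallSource(
        "confidence_awareness", "P2.1", "Importance of confidence awareness",
        _COUNTING,
        footnotes={"*": "discrimination metrics ignore predicted class scores; "
                        "pair them with a calibration metric"},
    ),
    PitfallSource(
        "cross_dataset_comparability", "P2.1", "Importance of comparability across data sets",
        frozenset({"accuracy", "expected_cost", "f_beta", "mcc", "net_benefit",
                   "ppv", "npv", "weighted_cohens_kappa"}),
        footnotes={"expected_cost": "the weights in EC can be adjusted to avoid this pitfall"},
    ),
    PitfallSource(
        "cost_benefit", "P2.1", "Importance of cost-benefit analysis",
        _COUNTING - {"expected_cost", "weighted_cohens_kappa", "net_benefit"},
    ),
    # ----- P2.2: disregard of the properties of the target structures
    PitfallSource(
        "small_structures", "P2.2", "Small structure sizes",
        _OVERLAP, "F7a", ("F7a",),
    ),
    PitfallSource(
        "size_variability", "P2.2", "High variability of structure sizes",
        _OVERLAP,
    ),
    PitfallSource(
        "complex_shapes", "P2.2", "Complex structure shapes",
        frozenset({"dice", "iou", "pixel_f_beta"}), "F7b", ("F7b",),
    ),
    PitfallSource(
        "box_disconnectedness", "P2.2", "Bounding boxes hide disconnected structures",
        frozenset({"average_precision", "froc_score"}),
    ),
    PitfallSource(
        "overlapping_touching_structures", "P2.2", "Overlapping or touching structures",
        _OVERLAP,
    ),
    # ----- P2.3: disregard of the properties of the data set
    PitfallSource(
        "class_imbalance", "P2.3", "High class imbalance",
        frozenset({"accuracy", "balanced_accuracy", "expected_cost", "lr_plus",
                   "net_benefit", "npv", "sensitivity", "specificity",
                   "weighted_cohens_kappa", "auroc"}),
        "F5a", ("F5a",),
        footnotes={"expected_cost": "the weights in EC can be adjusted to avoid this pitfall"},
    ),
    PitfallSource(
        "small_test_set", "P2.3", "Small test set size",
        _COUNTING | frozenset({"ece"}) | _DETECTION, "F5b", ("F5b",),
    ),
    PitfallSource(
        "imperfect_reference", "P2.3", "Imperfect reference standard",
        frozenset({"dice", "iou", "pixel_f_beta"}) | _BOUNDARY, "F5c", ("F5c",),
        footnotes={"hausdorff": "can be mitigated by the choice of the percentile"},
    ),
    PitfallSource(
        "empty_reference", "P2.3", "Occurrence of cases with an empty reference",
        _OVERLAP | _BOUNDARY | _DETECTION, "F8b", ("F8b",),
    ),
    # ----- P2.4: disregard of the properties of the algorithm output
    PitfallSource(
        "overlapping_predictions", "P2.4", "Possibility of overlapping predictions",
        _OVERLAP | _BOUNDARY, "F8a", ("F8a",),
    ),
    PitfallSource(
        "empty_prediction", "P2.4", "Possibility of empty prediction",
        _OVERLAP | _BOUNDARY | _DETECTION, "F8b", ("F8b",),
    ),
    PitfallSource(
        "missing_scores", "P2.4", "Lack of predicted class scores",
        frozenset({"average_precision", "froc_score"}),
    ),
    # ----- P3.1: inadequate metric implementation
    PitfallSource(
        "score_tie_handling", "P3.1", "Handling of identical confidence scores",
        frozenset({"average_precision", "auroc", "froc_score"}), "F6a", ("F6a",),
    ),
    PitfallSource(
        "discretization", "P3.1", "Discretization of continuous variables",
        frozenset({"ece", "auroc"}),
    ),
    PitfallSource(
        "boundary_extraction_dialect", "P3.1", "Non-standardized boundary extraction",
        _BOUNDARY, None, ("Ddialect",),
    ),
    PitfallSource(
        "hyperparameter_choice", "P3.1",
        "Suboptimal hyperparameter choice (beta, localization threshold)",
        frozenset({"f_beta", "pixel_f_beta", "average_precision", "froc_score"}),
    ),
    # ----- P3.2: inadequate metric aggregation
    PitfallSource(
        "hierarchical_data", "P3.2", "Ignoring the hierarchical data structure",
        ALL, "F6b", ("F6b",),
    ),
    PitfallSource(
        "dataset_pooling", "P3.2", "Global pooling over the data set",
        frozenset({"dice", "iou", "pixel_f_beta"}), None, ("Dpool",),
    ),
    PitfallSource("class_hierarchy", "P3.2", "Hierarchical class structure", ALL),
    PitfallSource("missing_values", "P3.2", "Missing values and biased aggregates", ALL),
    # ----- P3.3: inadequate ranking scheme
    PitfallSource(
        "related_metrics", "P3.3", "Mathematically related metrics",
        frozenset({"dice", "iou", "legacy_cellchallenge_precision"}),
        None, ("Dredundancy",),
    ),
    PitfallSource(
        "metric_synonyms", "P3.3", "Unawareness of metric synonyms",
        frozenset({"sensitivity", "ppv"}), None, ("Dredundancy",),
    ),
    PitfallSource(
        "ranking_instability", "P3.3", "Ranking instability",
        ALL, None, ("Dranking",),
    ),
    # ----- P3.4: inadequate metric reporting
    PitfallSource("uninformative_visualization", "P3.4",
                  "Uninformative visualization of metric distributions", ALL, "F6c"),
    PitfallSource("nondeterminism", "P3.4",
                  "Non-determinism of algorithms across runs", ALL),
    PitfallSource("incomplete_variability_reporting", "P3.4",
                  "Reporting without variability (best run only, no SD/CI)", ALL),
    # ----- P3.5: inadequate interpretation of metric values
    PitfallSource("irrelevant_rank_differences", "P3.5",
                  "Minor metric differences driving rank differences", ALL),
    PitfallSource("unbounded_metric_values", "P3.5",
                  "Unbounded or practically unachievable metric values",
                  frozenset({"lr_plus", "expected_cost"}) | _BOUNDARY),
)


@dataclass(frozen=True)
class TaxonomyRegistry:
    """The packaged taxonomy: 3 categories, 4+5 subcategories, 37 sources."""

    sources: tuple
    assignment_note: str = (
        "the subcategory allocation of a few sources is not uniquely fixed by "
        "the published category overview; this registry follows the per-category "
        "body-text lists, and 'missing_values' absorbs aggregation biases"
    )

    def __len__(self) -> int:
        return len(self.sources)

    @property
    def categories(self) -> tuple:
        return ("P1", "P2", "P3")

    def subcategories(self, category: str) -> tuple:
        subs = sorted({s.category for s in self.sources
                       if s.category.startswith(category + ".")})
        return tuple(subs)

    def source(self, source_id: str) -> PitfallSource:
        for s in self.sources:
            if s.id == source_id:
                return s
        raise InputError(f"unknown pitfall source {source_id!r}")

    def ids(self) -> tuple:
        return tuple(s.id for s in self.sources)

    def affected(self, metric_id: str) -> tuple:
        """All sources whose warning row covers the given metric."""
        return tuple(s for s in self.sources
                     if s.affected_metrics is ALL or metric_id in s.affected_metrics)

    def to_records(self) -> list:
        return [
            {
                "id": s.id, "category": s.category, "name": s.name,
                "affected_metrics": sorted(s.affected_metrics),
                "figure_anchor": s.figure_anchor,
                "scenarios": list(s.scenarios),
                "registry_only": s.registry_only,
            }
            for s in self.sources
        ]


_REGISTRY = TaxonomyRegistry(sources=_SOURCES)


def registry() -> TaxonomyRegistry:
    """Return the packaged taxonomy registry."""
    return _REGISTRY


def pitfall_applicability(metric_id: str, fingerprint: set) -> list:
    """Warnings for one metric given the problem's pitfall fingerprint.

    ``fingerprint`` is a set of pitfall-source ids describing the
    problem at hand (e.g. ``{"small_structures", "empty_reference"}``);
    the warnings are the registry rows that intersect it.
    """
    if metric_id.lower() not in KNOWN_METRIC_IDS:
        raise InputError(f"unknown metric id {metric_id!r}")
    warnings = []
    for flag in sorted(fingerprint):
        source = _REGISTRY.source(flag)  # raises on unknown flag
        if source.affected_metrics is not ALL and metric_id not in source.affected_metrics:
            continue
        note = source.footnotes.get(metric_id, source.footnotes.get("*"))
        warnings.append({
            "source": source.id,
            "category": source.category,
            "name": source.name,
            "figure_anchor": source.figure_anchor,
            "mitigation": note,
        })
    return warnings


# ---------------------------------------------------------------------------
# scenario generators


@dataclass(frozen=True)
class ScenarioBundle:
    """Deterministically generated inputs plus an assertable expectation."""

    scenario_id: str
    pitfall_id: str
    seed: int
    inputs: dict
    expectation: str


@dataclass(frozen=True)
class DemoReport:
    """Outcome of running a scenario through the toolkit."""

    scenario_id: str
    pitfall_id: str
    seed: int
    passed: bool
    values: dict
    expectation: str

    def to_dict(self) -> dict:
        def clean(v):
            if isinstance(v, float) and np.isnan(v):
                return None
            return v
        return {
            "scenario_id": self.scenario_id,
            "pitfall_id": self.pitfall_id,
            "seed": self.seed,
            "passed": self.passed,
            "expectation": self.expectation,
            "values": {k: clean(v) for k, v in self.values.items()},
        }


def _mask(shape, blocks, spacing=None) -> PixelMask:
    grid = np.zeros(shape, dtype=bool)
    for (r0, r1, c0, c1) in blocks:
        grid[r0:r1, c0:c1] = True
    return PixelMask(grid, spacing)


def _gen_f1a(seed, params):
    shape = (64, 64)
    large = (5, 35, 5, 35)       # 30x30 = 900 px
    small_a = (45, 48, 10, 13)   # 3x3
    small_b = (45, 48, 40, 43)   # 3x3
    ref_sem = _mask(shape, [large, small_a, small_b])
    pred_sem = _mask(shape, [large])
    refs = InstanceSet("img", [Instance(mask=_mask(shape, [b]))
                               for b in (large, small_a, small_b)])
    preds = InstanceSet("img", [Instance(mask=_mask(shape, [large]), confidence=0.9)])
    return {"ref_mask": ref_sem, "pred_mask": pred_sem, "refs": refs, "preds": preds,
            "match": MatchConfig("mask_iou", 0.5)}


def _demo_f1a(bundle):
    inp = bundle.inputs
    from .core import pixel_confusion
    c = pixel_confusion(inp["ref_mask"], inp["pred_mask"])
    pixel_sens = counting_metric(c, "sensitivity").value
    m = build_match(inp["preds"], inp["refs"], inp["match"])
    dc = detection_counts(m)
    inst_sens = counting_metric(dc, "sensitivity").value
    values = {"pixel_sensitivity": pixel_sens, "instance_sensitivity": inst_sens}
    passed = pixel_sens > 0.9 and abs(inst_sens - 1.0 / 3.0) < 1e-12
    return values, passed


def _gen_f3(seed, params):
    shape = (12, 41)
    squares = [(1, 11, 3, 13), (1, 11, 16, 26), (1, 11, 29, 39)]
    ref_sem = _mask(shape, squares)
    refs = InstanceSet("img", [Instance(mask=_mask(shape, [s])) for s in squares])
    # prediction 1: one structure, segmented perfectly
    p1_sem = _mask(shape, [squares[0]])
    p1 = InstanceSet("img", [Instance(mask=p1_sem, confidence=0.9)])
    # prediction 2: every structure found, but coarsely (partial + spill-over)
    p2_blocks = [(1, 11, 0, 6), (1, 11, 13, 19), (1, 11, 26, 32)]
    p2_sem = _mask(shape, p2_blocks)
    p2 = InstanceSet("img", [Instance(mask=_mask(shape, [b]), confidence=0.9)
                             for b in p2_blocks])
    return {"ref_mask": ref_sem, "refs": refs,
            "pred1_mask": p1_sem, "pred1": p1,
            "pred2_mask": p2_sem, "pred2": p2,
            "match": MatchConfig("mask_iou", 0.2)}


def _demo_f3(bundle):
    inp = bundle.inputs
    d1 = overlap.dice(inp["ref_mask"], inp["pred1_mask"]).value
    d2 = overlap.dice(inp["ref_mask"], inp["pred2_mask"]).value
    f1 = {}
    for name in ("pred1", "pred2"):
        m = build_match(inp[name], inp["refs"], inp["match"])
        f1[name] = counting_metric(detection_counts(m), "f_beta", MetricParams(beta=1.0)).value
    values = {"dice_pred1": d1, "dice_pred2": d2,
              "object_f1_pred1": f1["pred1"], "object_f1_pred2": f1["pred2"]}
    passed = d1 > d2 and f1["pred2"] > f1["pred1"]
    return values, passed


def _gen_f4a(seed, params):
    shape = (16, 16)
    ref = _mask(shape, [(4, 12, 4, 12)])
    pred1 = _mask(shape, [(4, 12, 5, 13)])                 # shifted by one column
    pred2 = _mask(shape, [(4, 12, 5, 12), (4, 12, 14, 15)])  # clipped + detached strip
    return {"ref": ref, "pred1": pred1, "pred2": pred2}


def _demo_f4a(bundle):
    inp = bundle.inputs
    d1 = overlap.dice(inp["ref"], inp["pred1"]).value
    d2 = overlap.dice(inp["ref"], inp["pred2"]).value
    a1 = mask_distance(inp["ref"], inp["pred1"], "assd").value
    a2 = mask_distance(inp["ref"], inp["pred2"], "assd").value
    values = {"dice_pred1": d1, "dice_pred2": d2, "assd_pred1": a1, "assd_pred2": a2}
    passed = d1 == d2 and abs(a1 - a2) > 1e-9
    return values, passed


def _gen_f4b(seed, params):
    classes = ("mild", "moderate", "severe")
    ref = ["mild", "moderate", "severe"]
    pred_a = ["mild", "moderate", "mild"]      # severe graded as mild: dangerous
    pred_b = ["severe", "moderate", "severe"]  # mild graded as severe: cautious
    costs = np.zeros((3, 3))
    costs[2, 0] = 10.0  # severe -> mild
    costs[0, 2] = 1.0   # mild -> severe
    return {"classes": classes, "ref": ref, "pred_a": pred_a, "pred_b": pred_b,
            "costs": CostMatrix(classes, costs)}


def _demo_f4b(bundle):
    inp = bundle.inputs
    cm_a = multiclass_confusion(inp["ref"], inp["pred_a"], inp["classes"])
    cm_b = multiclass_confusion(inp["ref"], inp["pred_b"], inp["classes"])
    ec_a = expected_cost(cm_a, inp["costs"]).value
    ec_b = expected_cost(cm_b, inp["costs"]).value
    acc = [np.trace(cm.counts) / cm.total for cm in (cm_a, cm_b)]
    values = {"ec_dangerous": ec_a, "ec_cautious": ec_b,
              "accuracy_dangerous": acc[0], "accuracy_cautious": acc[1]}
    passed = acc[0] == acc[1] and abs(ec_a - 10.0 * ec_b) < 1e-12
    return values, passed


def _gen_f5a(seed, params):
    # 5 positives all found, but 20 of 95 negatives called positive
    return {"counts": ConfusionCounts(tp=5, fp=20, fn=0, tn=75, level=Level.IMAGE)}


def _demo_f5a(bundle):
    c = bundle.inputs["counts"]
    acc = counting_metric(c, "accuracy").value
    ba = counting_metric(c, "balanced_accuracy").value
    mcc = counting_metric(c, "mcc").value
    values = {"accuracy": acc, "balanced_accuracy": ba, "mcc": mcc}
    passed = acc >= 0.8 and ba >= 0.85 and mcc < 0.5
    return values, passed


def _gen_f5b(seed, params):
    return {"replicates": int(params.get("replicates", 200)),
            "n_small": int(params.get("n_small", 10)),
            "n_large": int(params.get("n_large", 10_000)),
            "bins": int(params.get("bins", 10))}


def _demo_f5b(bundle):
    inp = bundle.inputs
    rng = np.random.default_rng(bundle.seed)

    def mean_ece(n: int) -> float:
        vals = []
        for _ in range(inp["replicates"]):
            conf = rng.uniform(0.0, 1.0, size=n)
            out = (rng.uniform(0.0, 1.0, size=n) < conf).astype(int)
            cal = CalibrationSet(conf, out, bins=inp["bins"])
            vals.append(expected_calibration_error(cal).value)
        return float(np.mean(vals))

    small = mean_ece(inp["n_small"])
    large = mean_ece(inp["n_large"])
    values = {"mean_ece_small_n": small, "mean_ece_large_n": large}
    passed = small > large and large < 0.02
    return values, passed


def _gen_f5c(seed, params):
    # 40 boundary points on the rim of an 11x11 square (spacing 1)
    side = 10
    pts = []
    for k in range(side):
        pts.append((0.0, float(k)))
        pts.append((float(side), float(k + 1)))
        pts.append((float(k + 1), 0.0))
        pts.append((float(k), float(side)))
    ref = np.asarray(sorted(pts))
    pred = ref.copy()
    # displace one mid-edge annotation outward by 20 units
    idx = int(np.where((ref[:, 0] == 0.0) & (ref[:, 1] == 5.0))[0][0])
    pred[idx] = (-20.0, 5.0)
    return {"ref": SurfacePointSet(ref, dialect="point_list"),
            "pred_clean": SurfacePointSet(ref.copy(), dialect="point_list"),
            "pred_outlier": SurfacePointSet(pred, dialect="point_list"),
            "cfg": BoundaryConfig(percentile=95.0)}


def _demo_f5c(bundle):
    inp = bundle.inputs
    hd_clean = hausdorff(inp["ref"], inp["pred_clean"]).value
    hd_out = hausdorff(inp["ref"], inp["pred_outlier"]).value
    hd95_clean = hausdorff_percentile(inp["ref"], inp["pred_clean"], inp["cfg"]).value
    hd95_out = hausdorff_percentile(inp["ref"], inp["pred_outlier"], inp["cfg"]).value
    values = {"hd_clean": hd_clean, "hd_outlier": hd_out,
              "hd95_clean": hd95_clean, "hd95_outlier": hd95_out}
    passed = (hd_out - hd_clean) >= 20.0 and hd95_out == hd95_clean
    return values, passed


def _gen_f6a(seed, params):
    refs = [InstanceSet("img", [
        Instance(box=BoundingBox((0, 0), (2, 2))),
        Instance(box=BoundingBox((10, 10), (12, 12))),
    ])]
    preds = [InstanceSet("img", [
        Instance(box=BoundingBox((0, 0), (2, 2)), confidence=0.9),    # TP
        Instance(box=BoundingBox((10, 10), (12, 12)), confidence=0.8),  # TP, tied score
        Instance(box=BoundingBox((20, 20), (22, 22)), confidence=0.8),  # FP, tied score
    ])]
    return {"refs": refs, "preds": preds, "match": MatchConfig("box_iou", 0.5)}


def _demo_f6a(bundle):
    inp = bundle.inputs
    ap_pp = average_precision(inp["preds"], inp["refs"], inp["match"],
                              APConfig(tie_dialect="per_prediction")).value
    ap_gs = average_precision(inp["preds"], inp["refs"], inp["match"],
                              APConfig(tie_dialect="grouped_by_score")).value
    values = {"ap_per_prediction": ap_pp, "ap_grouped_by_score": ap_gs}
    passed = abs(ap_pp - ap_gs) > 1e-12
    return values, passed


def _gen_f6b(seed, params):
    rows = []
    for i in range(10):
        rows.append({"metric": "dice", "value": 0.9, "image_id": f"p1_img{i}",
                     "patient_id": "patient1"})
    for p in range(2, 6):
        rows.append({"metric": "dice", "value": 0.5, "image_id": f"p{p}_img0",
                     "patient_id": f"patient{p}"})
    return {"table": CohortTable(pd.DataFrame(rows))}


def _demo_f6b(bundle):
    table = bundle.inputs["table"]
    flat, _ = aggregate(table, AggregationSpec(scheme="mean_per_image"))
    hier, _ = aggregate(table, AggregationSpec(scheme="hierarchical",
                                               hierarchy=("patient", "image")))
    values = {"flat_mean": flat["dice"].value, "per_patient_mean": hier["dice"].value}
    passed = (abs(values["flat_mean"] - 11.0 / 14.0) < 1e-12
              and abs(values["per_patient_mean"] - 0.58) < 1e-12
              and values["flat_mean"] > values["per_patient_mean"])
    return values, passed


def _gen_f7a(seed, params):
    shape = (32, 32)
    ref_large = _mask(shape, [(2, 22, 2, 22)])   # 400 px
    ref_small = _mask(shape, [(26, 28, 26, 28)])  # 4 px
    def drop_one(mask):
        grid = mask.grid.copy()
        r, c = np.argwhere(grid)[0]
        grid[r, c] = False
        return PixelMask(grid, mask.spacing)
    return {"ref_large": ref_large, "pred_large": drop_one(ref_large),
            "ref_small": ref_small, "pred_small": drop_one(ref_small)}


def _demo_f7a(bundle):
    inp = bundle.inputs
    d_large = overlap.dice(inp["ref_large"], inp["pred_large"]).value
    d_small = overlap.dice(inp["ref_small"], inp["pred_small"]).value
    values = {"dice_large_after_flip": d_large, "dice_small_after_flip": d_small,
              "delta_large": 1.0 - d_large, "delta_small": 1.0 - d_small}
    passed = (1.0 - d_small) > (1.0 - d_large)
    return values, passed


def _gen_f7b(seed, params):
    shape = (20, 30)
    bar = (10, 15, 4, 26)
    branches = [(3, 10, c, c + 1) for c in (6, 11, 16, 21)]
    ref = _mask(shape, [bar] + branches)
    pred_bulky = _mask(shape, [bar])                       # misses every branch
    pred_centered = _mask(shape, [(11, 14, 4, 26)] + branches)  # thinner, keeps lines
    return {"ref": ref, "pred_bulky": pred_bulky, "pred_centered": pred_centered}


def _demo_f7b(bundle):
    inp = bundle.inputs
    d_bulk = overlap.dice(inp["ref"], inp["pred_bulky"]).value
    d_cent = overlap.dice(inp["ref"], inp["pred_centered"]).value
    cl_bulk = overlap.cl_dice(inp["ref"], inp["pred_bulky"]).value
    cl_cent = overlap.cl_dice(inp["ref"], inp["pred_centered"]).value
    values = {"dice_bulky": d_bulk, "dice_centered": d_cent,
              "cl_dice_bulky": cl_bulk, "cl_dice_centered": cl_cent}
    passed = d_bulk >= d_cent and cl_cent > cl_bulk
    return values, passed


def _gen_f8a(seed, params):
    shape = (12, 18)
    r1 = _mask(shape, [(1, 11, 1, 11)])
    r2 = _mask(shape, [(1, 11, 7, 17)])
    union = PixelMask(r1.grid | r2.grid)
    pred = _mask(shape, [(1, 11, 3, 17)])  # R2, overextended into R1
    refs = InstanceSet("img", [Instance(mask=r1), Instance(mask=r2)])
    preds = InstanceSet("img", [Instance(mask=pred, confidence=0.9)])
    return {"r1": r1, "r2": r2, "union": union, "pred": pred,
            "refs": refs, "preds": preds, "match": MatchConfig("mask_iou", 0.5)}


def _demo_f8a(bundle):
    inp = bundle.inputs
    assd_sem = mask_distance(inp["union"], inp["pred"], "assd").value
    m = build_match(inp["preds"], inp["refs"], inp["match"])
    matched_ref = inp["refs"].instances[m.pairs[0][1]]
    assd_inst = mask_distance(matched_ref.mask, inp["pred"], "assd").value
    values = {"assd_semantic": assd_sem, "assd_instance": assd_inst,
              "matched_reference_index": m.pairs[0][1]}
    passed = assd_inst > assd_sem and m.pairs[0][1] == 1
    return values, passed


def _gen_f8b(seed, params):
    shape = (30, 30)
    tp_box = BoundingBox((2, 2), (6, 6))
    fn_box = BoundingBox((10, 10), (14, 14))
    fp_box = BoundingBox((20, 20), (24, 24))
    cases = {}
    for has_tp in (0, 1):
        for has_fn in (0, 1):
            for has_fp in (0, 1):
                refs, preds = [], []
                if has_tp:
                    refs.append(Instance(box=tp_box))
                    preds.append(Instance(box=tp_box, confidence=0.9))
                if has_fn:
                    refs.append(Instance(box=fn_box))
                if has_fp:
                    preds.append(Instance(box=fp_box, confidence=0.8))
                cases[(has_tp, has_fn, has_fp)] = (
                    InstanceSet("img", preds), InstanceSet("img", refs))
    return {"cases": cases, "match": MatchConfig("box_iou", 0.5), "shape": shape}


def _demo_f8b(bundle):
    inp = bundle.inputs
    values = {}
    passed = True
    for key, (preds, refs) in sorted(inp["cases"].items()):
        m = build_match(preds, refs, inp["match"])
        c = detection_counts(m)
        sens = counting_metric(c, "sensitivity").value
        ppv = counting_metric(c, "ppv").value
        f1 = counting_metric(c, "f_beta", MetricParams(beta=1.0)).value
        tp, fn, fp = key
        expect_sens_nan = (tp + fn) == 0
        expect_ppv_nan = (tp + fp) == 0
        expect_f1_nan = (tp + fn + fp) == 0
        ok = (np.isnan(sens) == expect_sens_nan
              and np.isnan(ppv) == expect_ppv_nan
              and np.isnan(f1) == expect_f1_nan
              and (c.tp, c.fn, c.fp) == (tp, fn, fp))
        passed = passed and ok
        values[f"tp{tp}_fn{fn}_fp{fp}"] = {"sensitivity": sens, "ppv": ppv, "f1": f1}
    return values, passed


def _gen_ddialect(seed, params):
    shape = (9, 13)
    plus = np.zeros(shape, dtype=bool)
    plus[4, 3:6] = True
    plus[3:6, 4] = True
    ref = PixelMask(plus)
    pred = PixelMask(np.roll(plus, 4, axis=1))
    return {"ref": ref, "pred": pred}


def _demo_ddialect(bundle):
    inp = bundle.inputs
    a4 = mask_distance(inp["ref"], inp["pred"], "assd",
                       BoundaryConfig(dialect="inner_erosion_4")).value
    a8 = mask_distance(inp["ref"], inp["pred"], "assd",
                       BoundaryConfig(dialect="inner_erosion_8")).value
    values = {"assd_erosion4": a4, "assd_erosion8": a8}
    passed = abs(a4 - a8) > 1e-12
    return values, passed


def _gen_dpool(seed, params):
    shape = (64, 64)
    ref_small = _mask(shape, [(2, 4, 2, 4)])
    pred_small = _mask(shape, [])                 # small structure fully missed
    ref_big = _mask(shape, [(5, 55, 5, 55)])
    pred_big = _mask(shape, [(5, 55, 5, 55)])     # big structure perfect
    return {"pairs": [(ref_small, pred_small), (ref_big, pred_big)]}


def _demo_dpool(bundle):
    pairs = bundle.inputs["pairs"]
    pooled = pooled_pixel_metric(pairs, "dice").value
    per_image = [overlap.dice(r, p).value for r, p in pairs]
    mean = float(np.mean(per_image))
    values = {"pooled_dice": pooled, "mean_per_image_dice": mean}
    passed = pooled > 0.99 and abs(mean - 0.5) < 1e-12
    return values, passed


def _gen_dredundancy(seed, params):
    return {"sets": {"related": ["dice", "iou"],
                     "synonym": ["sensitivity", "recall"],
                     "clean": ["dice", "hausdorff"]}}


def _demo_dredundancy(bundle):
    sets = bundle.inputs["sets"]
    w_rel = redundancy_check(sets["related"])
    w_syn = redundancy_check(sets["synonym"])
    w_clean = redundancy_check(sets["clean"])
    values = {"related_warnings": len(w_rel), "synonym_warnings": len(w_syn),
              "clean_warnings": len(w_clean)}
    passed = (len(w_rel) == 1 and w_rel[0]["kind"] == "related"
              and len(w_syn) == 1 and w_syn[0]["kind"] == "synonym"
              and len(w_clean) == 0)
    return values, passed


def _gen_dranking(seed, params):
    rng = np.random.default_rng(seed)
    n_cases = int(params.get("n_cases", 8))
    # dominated: algorithm A beats B beats C on every case
    base = rng.uniform(0.3, 0.6, size=n_cases)
    dominated = pd.DataFrame(
        {f"case{i}": [base[i] + 0.3, base[i] + 0.15, base[i]] for i in range(n_cases)},
        index=["A", "B", "C"],
    )
    near_tied = pd.DataFrame(
        rng.normal(0.7, 0.05, size=(3, n_cases)),
        index=["A", "B", "C"], columns=[f"case{i}" for i in range(n_cases)],
    ).clip(0, 1)
    return {"dominated": RankingTask(dominated),
            "near_tied": RankingTask(near_tied),
            "replicates": int(params.get("replicates", 100))}


def _demo_dranking(bundle):
    inp = bundle.inputs
    cfg = StabilityConfig(replicates=inp["replicates"], seed=bundle.seed)
    taus_dom, _ = bootstrap_stability(inp["dominated"], cfg)
    taus_tie, _ = bootstrap_stability(inp["near_tied"], cfg)
    values = {"dominated_min_tau": float(np.min(taus_dom)),
              "near_tied_tau_std": float(np.nanstd(taus_tie))}
    passed = values["dominated_min_tau"] == 1.0 and values["near_tied_tau_std"] > 0.0
    return values, passed


_SCENARIOS = {
    "F1A": (_gen_f1a, _demo_f1a, "wrong_problem_category",
            "pixel sensitivity > 0.9 while instance sensitivity = 1/3"),
    "F3": (_gen_f3, _demo_f3, "wrong_problem_category",
           "pixel DSC prefers the prediction that misses two of three structures; "
           "object-level F1 prefers the one that finds all three"),
    "F4a": (_gen_f4a, _demo_f4a, "structure_boundaries",
            "identical DSC for both predictions, different ASSD"),
    "F4b": (_gen_f4b, _demo_f4b, "unequal_confusion_severity",
            "equal accuracy; expected cost penalizes the dangerous error 10x"),
    "F5a": (_gen_f5a, _demo_f5a, "class_imbalance",
            "accuracy and balanced accuracy high despite many FPs; MCC low"),
    "F5b": (_gen_f5b, _demo_f5b, "small_test_set",
            "mean ECE of a perfectly calibrated model larger at small n than at "
            "large n, the latter near 0"),
    "F5c": (_gen_f5c, _demo_f5c, "imperfect_reference",
            "one displaced annotation raises HD by >= 20 units; HD95 unchanged"),
    "F6a": (_gen_f6a, _demo_f6a, "score_tie_handling",
            "AP differs between per-prediction and grouped-by-score tie dialects"),
    "F6b": (_gen_f6b, _demo_f6b, "hierarchical_data",
            "flat mean 11/14 vs per-patient mean 0.58 on the 14-image cohort"),
    "F7a": (_gen_f7a, _demo_f7a, "small_structures",
            "a single flipped pixel changes DSC far more on the small structure"),
    "F7b": (_gen_f7b, _demo_f7b, "complex_shapes",
            "DSC ties or prefers the branch-missing prediction; clDice prefers the "
            "center-line-covering one"),
    "F8a": (_gen_f8a, _demo_f8a, "overlapping_predictions",
            "semantic-segmentation ASSD understates the boundary error of the "
            "matched instance"),
    "F8b": (_gen_f8b, _demo_f8b, "empty_prediction",
            "sensitivity/PPV/F1 defined-vs-NaN pattern matches the 8 TP/FN/FP "
            "presence scenarios"),
    "Ddialect": (_gen_ddialect, _demo_ddialect, "boundary_extraction_dialect",
                 "4- and 8-connectivity boundary extraction give different ASSD"),
    "Dpool": (_gen_dpool, _demo_dpool, "dataset_pooling",
              "dataset-pooled DSC near 1 while mean-per-image DSC is 0.5"),
    "Dredundancy": (_gen_dredundancy, _demo_dredundancy, "related_metrics",
                    "DSC+IoU flagged as related, sensitivity+recall as synonyms"),
    "Dranking": (_gen_dranking, _demo_dranking, "ranking_instability",
                 "dominated task has tau = 1 in every bootstrap replicate; "
                 "near-tied task has tau variance > 0"),
}

SCENARIO_IDS = tuple(sorted(_SCENARIOS))


def generate(scenario_id: str, seed: int = 0, **params) -> ScenarioBundle:
    """Build the deterministic toy-scenario bundle for one pitfall."""
    if scenario_id not in _SCENARIOS:
        source_ids = {s.id for s in _SOURCES}
        if scenario_id in source_ids:
            src = _REGISTRY.source(scenario_id)
            if src.scenarios:
                scenario_id = src.scenarios[0]
            else:
                raise InputError(
                    f"pitfall source {src.id!r} is registry-only: no generator exists"
                )
        else:
            raise InputError(f"unknown scenario {scenario_id!r}")
    gen, _, pitfall_id, expectation = _SCENARIOS[scenario_id]
    return ScenarioBundle(
        scenario_id=scenario_id, pitfall_id=pitfall_id, seed=int(seed),
        inputs=gen(int(seed), params), expectation=expectation,
    )


def demonstrate(scenario_id: str, seed: int = 0, **params) -> DemoReport:
    """Run a scenario through the toolkit and evaluate its expectation.

    A failed expectation is reported as ``passed=False`` — never a
    silent pass.
    """
    bundle = generate(scenario_id, seed, **params)
    _, demo, _, _ = _SCENARIOS[bundle.scenario_id]
    values, passed = demo(bundle)
    return DemoReport(
        scenario_id=bundle.scenario_id, pitfall_id=bundle.pitfall_id,
        seed=bundle.seed, passed=bool(passed), values=values,
        expectation=bundle.expectation,
    )
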