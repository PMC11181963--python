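# valimet

Pitfall-aware validation metrics for biomedical image analysis.

Validation metrics decide which image-analysis algorithms are called
state of the art, yet they are routinely chosen and applied in ways
that quietly distort the result: a Dice score that cannot see that two
of three lesions were missed, an "Average Precision" that changes with
how a codebase breaks score ties, a cohort mean dominated by the one
patient who contributed most of the images, an Expected Calibration
Error that is biased upward on small test sets. `valimet` is a toolkit
for researchers and challenge organizers who validate classification,
semantic segmentation, object detection and instance segmentation
models and want these failure modes to be *explicit*: every
pitfall-prone choice (boundary-extraction dialect, tie handling,
binning, F-beta, localization threshold, NaN policy, aggregation
scheme) is a named, logged parameter, undefined values are honest
`NaN`s with recorded reasons, and a machine-readable taxonomy of 37
pitfall sources ships with runnable toy scenarios that demonstrate
each computational pitfall.

## What it computes

* **Counting metrics** on TP/FP/TN/FN at image, object or pixel level:
  accuracy, balanced accuracy, sensitivity/specificity, PPV/NPV, LR+,
  F<sub>β</sub> = (1+β²)TP / ((1+β²)TP + β²FN + FP), MCC, expected cost
  EC = Σᵢ πᵢ Σⱼ c(i,j) P(ĵ|i), weighted Cohen's kappa, net benefit,
  AUROC, expected calibration error.
* **Overlap metrics**: DSC = 2TP/(2TP+FP+FN), IoU = TP/(TP+FP+FN)
  (and the identity IoU = DSC/(2−DSC)), pixel-level F<sub>β</sub>, and
  centerline Dice (harmonic mean of skeleton precision/sensitivity).
* **Boundary metrics** in physical units with selectable extraction
  dialects: Hausdorff distance, percentile Hausdorff (HD95), average
  symmetric surface distance.
* **Detection / instance segmentation**: localization criteria
  (box/mask IoU, IoR, center distance, point-inside), greedy and
  optimal one-to-one matching, average precision with both score-tie
  dialects, mAP, FROC, panoptic quality PQ = SQ·RQ, and the
  widely-propagated but mis-named cell-challenge "precision"
  TP/(TP+FP+FN) — flagged for what it is, a counts-level IoU.
* **Aggregation** across classes, images, patients and cohorts with
  explicit schemes (mean per image, hierarchical, pool-then-compute)
  and NaN policies, each run producing an audit record.
* **Ranking**: aggregate-then-rank (mean/median) and
  rank-then-aggregate, seeded bootstrap ranking stability (Kendall's
  τ-b), and redundancy warnings for synonym or functionally related
  metric pairs.
* **Pitfall taxonomy**: 37 sources in 3 categories (problem-category
  choice, metric selection with 4 subcategories, metric application
  with 5), an affected-metric warning matrix, and deterministic
  scenario generators with assertable expectations.

## A worked example

```python
from valimet import APConfig, BoundingBox, Instance, InstanceSet, MatchConfig, average_precision

refs = [InstanceSet("img", [Instance(box=BoundingBox((0, 0), (2, 2))),
                            Instance(box=BoundingBox((10, 10), (12, 12)))])]
preds = [InstanceSet("img", [
    Instance(box=BoundingBox((0, 0), (2, 2)), confidence=0.9),      # hit
    Instance(box=BoundingBox((10, 10), (12, 12)), confidence=0.8),  # hit, tied score
    Instance(box=BoundingBox((20, 20), (22, 22)), confidence=0.8),  # miss, tied score
])]
match = MatchConfig(criterion="box_iou", threshold=0.5)
for dialect in ("per_prediction", "grouped_by_score"):
    print(dialect, average_precision(preds, refs, match, APConfig(dialect)).value)
```

prints

```
per_prediction 1.0
grouped_by_score 0.8333333333333333
```

Same three detections, same matching criterion — the AP differs by
0.17 solely because the two conventions disagree on how the two
predictions with confidence 0.80 enter the precision–recall sweep.
The dialect is recorded in the result's flags, so the number can never
circulate without its convention.

More narrative examples live in `examples/` (segmentation overlap vs
boundary metrics, hierarchical aggregation, a tour of the taxonomy);
each prints its numbers with a short explanation. The `valimet` CLI
exposes the same operations (`valimet pitfall list`,
`valimet pitfall demo F6a`, `valimet evaluate-seg ...`,
`valimet check-metrics dice iou --fingerprint small_structures`).

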