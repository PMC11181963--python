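# Methods

This note records the models, conventions and design choices behind
`valimet`, the way they are actually implemented, including the
places where the field has no single convention and a choice had to
be made.

## Scope and levels

The toolkit treats four problem categories — image-level
classification, semantic segmentation, object detection, instance
segmentation — as classification at three levels: image, object,
pixel. Every count and metric result carries its level, because the
central failure mode the toolkit guards against is reading a value at
the wrong level (a pixel-level sensitivity of 0.98 on an image where
two of three lesions are entirely missed). Object-level confusion
counts never carry a TN entry: the set of correctly-absent objects is
unbounded, so any metric needing TN raises an error rather than
silently receiving a 0.

Coordinates are 0-based with axis order (row, col[, slice]); bounding
boxes are half-open (`min` inclusive, `max` exclusive), which makes
discrete IoU arithmetic exact. Masks are binary lattices obtained by
explicit class selection from label images; float-valued images are
refused at the reader, because thresholding a continuous map is a
discretization choice that must be made consciously upstream. Masks
are 2D or 3D everywhere; skeletonization (and hence clDice) is
restricted to 2D, where the thinning algorithm is well established —
a 3D thinning choice would be arbitrary and is out of scope.

## Undefined values

A zero denominator makes a metric *undefined*, and the toolkit
returns `NaN`, never a smoothed or substituted number. Each NaN is
logged with its reason and the reason is stored in the result flags.
The defined/undefined pattern is part of the contract: with
object-level counts, sensitivity is NaN iff TP+FN = 0 (no reference
instances), PPV iff TP+FP = 0 (no predictions), F1 iff all three are
zero, and the test suite checks all 8 presence/absence combinations.
For overlap metrics the one genuinely ambiguous case — both masks
empty — is a policy (`empty_both_policy`: `nan` by default, `1`
on request); an empty reference with a non-empty prediction is
well-defined (score 0) and needs no policy. Boundary metrics on an
empty mask return NaN at the `mask_distance` layer (no boundary
exists) rather than crashing. What ultimately happens to NaNs is
decided only at aggregation time by one of three explicit policies
(below).

## Counting and calibration metrics

Counting metrics use the standard formulas over TP/FP/TN/FN.
Multi-class inputs are reduced one-vs-rest with macro averaging, and
per-class values are kept in the flags so an undefined class stays
visible. Expected cost is the prior-weighted sum
EC = Σᵢ πᵢ Σⱼ c(i,j)·P(pred=j|true=i), unnormalized, with empirical
priors by default; a class with zero support but nonzero prior makes
EC undefined. Weighted Cohen's kappa is 1 − ΣwO/ΣwE with E the
margin outer product and linear, quadratic or custom non-negative
weights (zero diagonal). Net benefit is TP/n − (FP/n)·p_t/(1−p_t),
where the threshold probability p_t encodes the harm:benefit odds of
acting on a positive call. AUROC is computed by the rank-sum
(Mann–Whitney) identity with midranks, so ties count half.

ECE uses B = 10 equal-width bins by default (equal-count available),
right-closed at 1.0 so a confidence of exactly 1 lands in the last
bin; bin count and scheme are echoed in the flags because the
binning is itself a discretization pitfall. The estimator is biased
upward for small n even under perfect calibration — the toolkit
demonstrates rather than corrects this (scenario F5b: mean ECE ≈ 0.25
at n=10 versus < 0.02 at n=10,000 over 200 replicates).

## Overlap and boundary metrics

DSC, IoU and pixel-level F_β are counting metrics over pixel
confusion counts; F_β's β is the explicit lever for unequal over- vs
undersegmentation severity (β > 1 forgives false positives relative
to misses). clDice composes skeleton precision and sensitivity:
Tprec = |skel(pred)∩ref|/|skel(pred)|, Tsens = |skel(ref)∩pred|/|skel(ref)|,
clDice = their harmonic mean; an empty skeleton leaves it undefined.
Skeletonization uses Lee's medial-axis thinning, which is
deterministic, idempotent on its own output, and reduces a solid
rectangular bar to its clean center row (classic two-pass thinning
leaves a corner spur there); the method tag travels in the flags.

Boundary extraction is deliberately pluralistic, because published
evaluation pipelines genuinely disagree: two inner-boundary dialects
are shipped (foreground sites removed by one binary erosion with
face-connectivity or full-connectivity), every distance result
carries its dialect tag, and a packaged scenario exhibits masks where
the two dialects give different ASSD. These dialects are the
toolkit's own constructions illustrating the divergence, not
reproductions of any specific challenge codebase. All distances are
taken after scaling lattice coordinates by the per-axis spacing, so
anisotropic voxels are measured in physical units. HD is the max of
the two directed max–min distances; HD_q takes the nearest-rank
percentile (no interpolation — exact and testable) of each directed
nearest-distance list and combines per the configured rule
(per-direction-then-max by default, pooled available); ASSD sums all
nearest-neighbor distances in both directions over the total point
count. Nearest neighbors come from a k-d tree and are verified in the
tests against a full O(n·m) pairwise oracle.

## Matching and detection metrics

Object-level counts exist only after matching. A `MatchConfig` binds
a localization criterion, its threshold, and its comparison direction
(IoU-type criteria match at ≥ threshold, distance criteria at ≤);
the direction is stored with the criterion so it cannot be silently
inverted. No default threshold is shipped — the threshold is itself a
pitfall source and must be chosen consciously. Matching is strictly
one-to-one; duplicate hits become FPs. Greedy matching processes
predictions by descending confidence (ties by input order), each
taking the best still-unmatched eligible reference; optimal matching
maximizes matched-pair count and then total criterion quality via a
linear assignment with a count-dominant benefit offset. Both are
deterministic; the tests compare the optimal strategy against
exhaustive enumeration of all assignments on small instances. "Approx"
locators are treated as user-supplied coarse masks routed through the
mask pathway under their own tag.

Average precision sweeps predictions by descending score and
integrates the precision–recall curve with the monotone precision
envelope over all operating points (no 11-point subsampling). The
score-tie dialect is mandatory and logged: `per_prediction` records a
PR point after every single prediction (equal scores broken by input
order), `grouped_by_score` processes an equal-score block jointly and
records one point. The packaged tie scenario uses two predictions at
confidence 0.80 with the hit listed before the miss, where the
dialects demonstrably diverge (AP 1.0 vs 5/6). FROC sweeps the same
thresholds and reports sensitivity versus mean FPs per image, scored
as the mean sensitivity at configurable operating points (default
0.125–8 FPs/image, a common grid, logged) with linear interpolation
clamped at the achieved extremes. Panoptic quality fixes matching at
mask IoU > 0.5 — above one half, matching is provably unique for
internally disjoint instance sets — and reports
PQ = ΣIoU/(TP+½FP+½FN) together with SQ (mean matched IoU) and RQ;
the identity PQ = SQ·RQ is property-tested. The legacy
cell-challenge formula TP/(TP+FP+FN) is provided because it
circulates widely under the name "Mean Average Precision", and is
flagged in its results as non-standard naming (it is a counts-level
IoU).

## Aggregation and ranking

Aggregation defaults are the loudest available: mean per image, macro
over classes, NaN propagation. Hierarchical aggregation averages
bottom-up (images within patient, then patients, arbitrary depth);
with a balanced hierarchy and no NaNs it equals the flat mean
exactly, and with an unbalanced one it does not — the packaged
14-image cohort (ten images at 0.9 from one patient, four patients at
0.5) gives flat 11/14 ≈ 0.786 versus per-patient 0.58. The NaN
policies are propagate, omit-with-count, and substitute-worst
(substituting the metric's worst achievable value, with distances
requiring an explicit finite cap such as the image diagonal); every
omission or substitution is counted in the audit record that
accompanies each aggregate. Pool-then-compute sums pixel confusion
counts over the dataset before applying the formula; it is supported
because it is common, flagged because it suppresses per-image
information (a missed 4-pixel structure vanishes behind a perfect
2500-pixel one: pooled DSC 0.999 vs mean-per-image 0.5).

Ranking supports aggregate-then-rank with mean or median and
rank-then-aggregate (per-case midranks, then mean rank); ties share
ranks competition-style, display ties break by algorithm id, and an
all-NaN algorithm ranks last with a warning. Stability is assessed by
a seeded case-resampling bootstrap: each replicate is re-ranked under
the task's scheme and compared to the full-data ranking by Kendall's
τ-b (tie-adjusted, appropriate for leaderboards with shared ranks);
the run is bit-reproducible for a fixed seed. No equivalence margin
for "practically equal" scores is applied by default (none has an
agreed value); redundancy checking instead warns when a metric set
contains synonyms (sensitivity/recall, PPV/precision, DSC/F1) or
functionally determined pairs (IoU = DSC/(2−DSC); the legacy formula
vs IoU).

## The scenario generators

Every computational pitfall source links to a deterministic generator
whose output satisfies a stated, assertable relation; regeneration
with the same seed is bit-identical. The geometries are toy
constructions chosen to make the relations hold cleanly (e.g. a
30×30-pixel lesion plus two 3×3 lesions for the pixel-vs-instance
sensitivity inversion; a 40-point square rim with one annotation
displaced 20 units for HD vs HD95), emulating the *structure* of real
failures, not real data: they contain no noise, no annotation
ambiguity, no class imbalance beyond what the scenario needs, and no
realistic anatomy. Passing scenarios therefore show that the metrics
and procedures behave as documented on inputs designed to trigger
each pitfall — not that any particular real dataset is affected to
any particular degree. Purely presentational pitfalls (visualization,
variability reporting, interpretation margins) are registry-only:
they appear in the taxonomy and warning matrix with no fabricated
numeric assertion. The exact allocation of a few sources between
neighbouring subcategories is not uniquely fixed by the published
category overview; the registry states this in its
`assignment_note` rather than hiding it.

## Problem sizes and numerics

The identity and oracle checks use sizes chosen for exactness and
speed: 1,000 random 16×16 mask pairs for the DSC↔IoU identity
(tolerance 1e−12; observed deviation ~1e−16), 100 random point sets
of up to 30 points for the boundary-metric oracles (exact equality),
200 replicates at n = 10 and n = 10,000 for the calibration-bias
simulation, and 1,000 bootstrap replicates for ranking stability.
Floating-point ties in matching and ranking are broken
deterministically (input order / algorithm id), percentiles use
nearest-rank, and all stochastic procedures take an explicit seed.

## Known limitations

Fuzzy/probabilistic masks, crowd/ignore regions, tracking, surface
Dice at tolerance, normalized surface distance, proper scoring rules
beyond ECE, significance-based (test-then-rank) ranking,
mixed-effects modeling of hierarchies, and 3D skeletonization are out
of scope. COCO import covers boxes and scores; mask locators are
built programmatically or from label images rather than RLE.
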