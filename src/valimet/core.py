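"""Shared domain types and confusion-count computations.

Validation of image analysis algorithms reduces, for the problem
categories covered here, to classification at one of three levels:
whole images (image-level classification), objects (detection /
instance segmentation) and pixels (semantic segmentation).  The types
in this module carry the level explicitly, because mixing levels is
one of the classic ways validation goes wrong: a pixel-level
sensitivity near 1 can coexist with two of three lesions missed.

Conventions
-----------
* Coordinates are 0-based with axis order ``(row, col[, slice])``.
* Bounding boxes are half-open: ``min`` inclusive, ``max`` exclusive.
* ``NaN`` is a first-class metric value.  Undefined computations
  (zero denominators) return NaN and log the triggering denominator;
  they are never silently coerced to 0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np

logger = logging.getLogger("valimet")

__all__ = [
    "InputError",
    "Level",
    "ConfusionCounts",
    "ConfusionMatrix",
    "PixelMask",
    "MultiClassMask",
    "BoundingBox",
    "Instance",
    "InstanceSet",
    "MetricResult",
    "MetricParams",
    "confusion_from_labels",
    "multiclass_confusion",
    "pixel_confusion",
    "nan_result",
]


class InputError(ValueError):
    """Raised when an operation receives inputs violating its contract."""


class Level(str, Enum):
    """Classification level at which counts were obtained."""

    PIXEL = "pixel"
    OBJECT = "object"
    IMAGE = "image"


def _check_count(name: str, value) -> int:
    if value is None or int(value) != value or value < 0:
        raise InputError(f"{name} must be a non-negative integer, got {value!r}")
    return int(value)


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/TN/FN cardinalities of a binary confusion matrix.

    ``tn`` must be ``None`` exactly when ``level`` is ``object``: in
    detection there is no meaningful count of true negatives (the set
    of "objects that are correctly not there" is unbounded).
    """

    tp: int
    fp: int
    fn: int
    tn: Optional[int] = None
    level: Level = Level.IMAGE

    def __post_init__(self):
        object.__setattr__(self, "tp", _check_count("tp", self.tp))
        object.__setattr__(self, "fp", _check_count("fp", self.fp))
        object.__setattr__(self, "fn", _check_count("fn", self.fn))
        level = Level(self.level)
        object.__setattr__(self, "level", level)
        if level is Level.OBJECT:
            if self.tn is not None:
                raise InputError("object-level counts must not carry tn")
        else:
            if self.tn is None:
                raise InputError(f"{level.value}-level counts require tn")
            object.__setattr__(self, "tn", _check_count("tn", self.tn))

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + (self.tn or 0)


@dataclass(frozen=True)
class ConfusionMatrix:
    """K x K class-confusion table indexed ``(true, predicted)``."""

    classes: tuple
    counts: np.ndarray

    def __post_init__(self):
        classes = tuple(self.classes)
        if len(classes) < 2:
            raise InputError("need at least two classes")
        if len(set(classes)) != len(classes):
            raise InputError("duplicate class labels")
        counts = np.asarray(self.counts)
        if counts.shape != (len(classes), len(classes)):
            raise InputError(
                f"counts shape {counts.shape} does not match {len(classes)} classes"
            )
        if np.any(counts < 0) or not np.issubdtype(counts.dtype, np.integer):
            if not np.all(counts == np.floor(counts)) or np.any(counts < 0):
                raise InputError("counts must be non-negative integers")
        counts = counts.astype(np.int64)
        counts.setflags(write=False)
        object.__setattr__(self, "classes", classes)
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def row_marginals(self) -> np.ndarray:
        """Per-true-class sample counts."""
        return self.counts.sum(axis=1)

    def col_marginals(self) -> np.ndarray:
        """Per-predicted-class sample counts."""
        return self.counts.sum(axis=0)


@dataclass(frozen=True)
class PixelMask:
    """Binary lattice with physical spacing, 2D or 3D.

    ``spacing`` is the physical extent of one lattice step per axis
    (e.g. mm), strictly positive.  Axis order is (row, col[, slice]).
    """

    grid: np.ndarray
    spacing: tuple = None

    def __post_init__(self):
        grid = np.asarray(self.grid)
        if grid.ndim not in (2, 3):
            raise InputError(f"mask must be 2D or 3D, got ndim={grid.ndim}")
        if grid.dtype != bool:
            values = np.unique(grid)
            if not np.all(np.isin(values, [0, 1])):
                raise InputError(
                    "mask grid must be binary; derive masks from label images "
                    "by explicit class selection, never by thresholding"
                )
            grid = grid.astype(bool)
        spacing = self.spacing
        if spacing is None:
            spacing = (1.0,) * grid.ndim
        spacing = tuple(float(s) for s in spacing)
        if len(spacing) != grid.ndim:
            raise InputError("spacing length must match mask dimensionality")
        if any(s <= 0 for s in spacing):
            raise InputError("spacing must be strictly positive on every axis")
        grid = grid.copy()
        grid.setflags(write=False)
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "spacing", spacing)

    @property
    def foreground_count(self) -> int:
        return int(self.grid.sum())

    @property
    def is_empty(self) -> bool:
        return self.foreground_count == 0

    def same_geometry(self, other: "PixelMask") -> bool:
        return self.grid.shape == other.grid.shape and self.spacing == other.spacing


@dataclass(frozen=True)
class MultiClassMask:
    """Label lattice for semantic segmentation; label 0 is background."""

    grid: np.ndarray
    labels: frozenset

    def __post_init__(self):
        grid = np.asarray(self.grid)
        labels = frozenset(int(v) for v in self.labels) | {0}
        if any(v < 0 for v in labels):
            raise InputError("labels must be non-negative integers")
        present = set(int(v) for v in np.unique(grid))
        if not present <= labels:
            raise InputError(f"grid contains undeclared labels {sorted(present - labels)}")
        grid = grid.copy()
        grid.setflags(write=False)
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "labels", labels)

    def binary(self, label: int, spacing: Optional[Sequence[float]] = None) -> PixelMask:
        """Explicit class selection: the binary mask of one label."""
        if int(label) not in self.labels:
            raise InputError(f"label {label} not declared")
        return PixelMask(self.grid == int(label), spacing)


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned integer box, half-open on every axis."""

    mins: tuple
    maxs: tuple

    def __post_init__(self):
        mins = tuple(int(v) for v in self.mins)
        maxs = tuple(int(v) for v in self.maxs)
        if len(mins) != len(maxs):
            raise InputError("mins/maxs dimensionality mismatch")
        if any(lo >= hi for lo, hi in zip(mins, maxs)):
            raise InputError("box must satisfy min < max on every axis")
        object.__setattr__(self, "mins", mins)
        object.__setattr__(self, "maxs", maxs)

    @property
    def volume(self) -> int:
        v = 1
        for lo, hi in zip(self.mins, self.maxs):
            v *= hi - lo
        return v

    def center(self) -> tuple:
        return tuple((lo + hi) / 2.0 for lo, hi in zip(self.mins, self.maxs))

    def intersection_volume(self, other: "BoundingBox") -> int:
        v = 1
        for (alo, ahi), (blo, bhi) in zip(
            zip(self.mins, self.maxs), zip(other.mins, other.maxs)
        ):
            w = min(ahi, bhi) - max(alo, blo)
            if w <= 0:
                return 0
            v *= w
        return v


@dataclass(frozen=True)
class Instance:
    """One predicted or reference object with exactly one locator."""

    mask: Optional[PixelMask] = None
    box: Optional[BoundingBox] = None
    point: Optional[tuple] = None
    label: int = 1
    confidence: Optional[float] = None

    def __post_init__(self):
        locators = [x is not None for x in (self.mask, self.box, self.point)]
        if sum(locators) != 1:
            raise InputError("instance must carry exactly one locator (mask, box or point)")
        if self.point is not None:
            object.__setattr__(self, "point", tuple(float(v) for v in self.point))
        if self.confidence is not None:
            c = float(self.confidence)
            if not 0.0 <= c <= 1.0:
                raise InputError("confidence must lie in [0, 1]")
            object.__setattr__(self, "confidence", c)

    @property
    def locator_kind(self) -> str:
        if self.mask is not None:
            return "mask"
        if self.box is not None:
            return "box"
        return "point"


@dataclass(frozen=True)
class InstanceSet:
    """All instances of one image; spatial overlap between instances is legal."""

    image_id: str
    instances: tuple = ()

    def __post_init__(self):
        object.__setattr__(self, "instances", tuple(self.instances))

    def __len__(self) -> int:
        return len(self.instances)

    def __iter__(self):
        return iter(self.instances)


@dataclass(frozen=True)
class MetricResult:
    """One metric value with full provenance.

    ``flags`` records every dialect/default that shaped the value
    (boundary-extraction dialect, tie handling, binning, beta, NaN
    policy ...) so that any number can be audited after the fact.
    """

    metric: str
    value: float
    level: Level = Level.IMAGE
    class_label: Optional[int] = None
    image_id: Optional[str] = None
    flags: dict = field(default_factory=dict)

    @property
    def is_nan(self) -> bool:
        return isinstance(self.value, float) and math.isnan(self.value)


@dataclass(frozen=True)
class MetricParams:
    """Hyperparameters that materially change counting-metric values."""

    beta: float = 1.0
    threshold_prob: Optional[float] = None
    priors: Optional[tuple] = None
    positive_label: object = 1

    def __post_init__(self):
        if self.beta <= 0:
            raise InputError("beta must be > 0")
        if self.threshold_prob is not None and not 0.0 < self.threshold_prob < 1.0:
            raise InputError("threshold_prob must lie in (0, 1)")
        if self.priors is not None:
            priors = tuple(float(p) for p in self.priors)
            if abs(sum(priors) - 1.0) > 1e-9:
                raise InputError("priors must sum to 1 (tolerance 1e-9)")
            if any(p < 0 for p in priors):
                raise InputError("priors must be non-negative")
            object.__setattr__(self, "priors", priors)


def nan_result(metric: str, reason: str, **kwargs) -> MetricResult:
    """Build a NaN MetricResult and log why the value is undefined."""
    logger.warning("%s undefined: %s", metric, reason)
    flags = dict(kwargs.pop("flags", {}))
    flags["nan_reason"] = reason
    return MetricResult(metric=metric, value=float("nan"), flags=flags, **kwargs)


# ---------------------------------------------------------------------------
# confusion-count computations


def confusion_from_labels(ref, pred, positive_label) -> ConfusionCounts:
    """Binary image-level confusion counts from two label sequences.

    Any label not equal to ``positive_label`` counts as negative.
    """
    ref = list(ref)
    pred = list(pred)
    if len(ref) != len(pred):
        raise InputError(f"length mismatch: {len(ref)} vs {len(pred)}")
    if not ref:
        raise InputError("empty label lists")
    if positive_label not in set(ref) | set(pred):
        raise InputError(f"positive label {positive_label!r} absent from label set")
    r = np.asarray([x == positive_label for x in ref])
    p = np.asarray([x == positive_label for x in pred])
    return ConfusionCounts(
        tp=int(np.sum(r & p)),
        fp=int(np.sum(~r & p)),
        fn=int(np.sum(r & ~p)),
        tn=int(np.sum(~r & ~p)),
        level=Level.IMAGE,
    )


def multiclass_confusion(ref, pred, class_order) -> ConfusionMatrix:
    """K x K confusion table; cell (i, j) counts true class i predicted j."""
    ref = list(ref)
    pred = list(pred)
    if len(ref) != len(pred):
        raise InputError(f"length mismatch: {len(ref)} vs {len(pred)}")
    if not ref:
        raise InputError("empty label lists")
    classes = tuple(class_order)
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for r, p in zip(ref, pred):
        if r not in index or p not in index:
            raise InputError(f"label outside declared class order: {r!r}/{p!r}")
        counts[index[r], index[p]] += 1
    return ConfusionMatrix(classes=classes, counts=counts)


def pixel_confusion(ref: PixelMask, pred: PixelMask) -> ConfusionCounts:
    """Pixel-level confusion counts of two masks on the same lattice."""
    if not ref.same_geometry(pred):
        raise InputError(
            f"geometry mismatch: {ref.grid.shape}/{ref.spacing} vs "
            f"{pred.grid.shape}/{pred.spacing}"
        )
    r, p = ref.grid, pred.grid
    return ConfusionCounts(
        tp=int(np.sum(r & p)),
        fp=int(np.sum(~r & p)),
        fn=int(np.sum(r & ~p)),
        tn=int(np.sum(~r & ~p)),
        level=Level.PIXEL,
    )
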