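"""Readers/writers for label images, COCO-style detections, CSV tables, reports.

Two reporting rules are enforced structurally rather than by
convention: every report carries the per-case raw values (aggregates
alone are never written), and every report echoes the full
configuration including dialect flags and seed, so a run can be
reproduced from its own output.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml
from PIL import Image

from .core import (
    BoundingBox,
    InputError,
    Instance,
    InstanceSet,
    MetricResult,
    MultiClassMask,
    PixelMask,
)

logger = logging.getLogger("valimet")

__all__ = [
    "RunConfig",
    "read_label_image",
    "write_label_image",
    "read_detections",
    "write_detections",
    "read_classification_csv",
    "read_calibration_csv",
    "read_cohort_csv",
    "write_report",
]


@dataclass(frozen=True)
class RunConfig:
    """Fully serializable evaluation configuration, echoed into reports."""

    task: str = "semantic_seg"
    metrics: tuple = ("dice",)
    metric_params: dict = field(default_factory=dict)
    match: Optional[dict] = None
    aggregation: dict = field(default_factory=dict)
    dialect_flags: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.task not in ("classification", "semantic_seg", "object_detection",
                             "instance_seg"):
            raise InputError(f"unknown task category {self.task!r}")
        object.__setattr__(self, "metrics", tuple(self.metrics))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


# ---------------------------------------------------------------------------
# label images


def _load_spacing(path: Path, ndim: int):
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        with open(sidecar) as fh:
            spacing = json.load(fh).get("spacing")
        return tuple(float(s) for s in spacing)
    logger.warning("no spacing sidecar for %s: assuming unit spacing", path.name)
    return (1.0,) * ndim


def read_label_image(path, class_selector=None, labels=None):
    """Read a single-channel integer PNG/TIFF as a mask.

    With ``class_selector`` set, returns the binary :class:`PixelMask`
    of that label; otherwise a :class:`MultiClassMask` over ``labels``
    (defaults to the labels present).  Float-valued images are refused
    outright: thresholding a continuous map is a hidden discretization
    choice that must be made explicitly upstream.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(Image.open(path))
    if arr.ndim not in (2, 3):
        raise InputError(f"expected single-channel 2D/3D image, got shape {arr.shape}")
    if np.issubdtype(arr.dtype, np.floating):
        raise InputError(
            "float-valued image: refusing to threshold implicitly; "
            "map continuous values to labels explicitly first"
        )
    spacing = _load_spacing(path, arr.ndim)
    if labels is None:
        labels = {int(v) for v in np.unique(arr)}
    mcm = MultiClassMask(arr.astype(np.int64), frozenset(labels))
    if class_selector is None:
        return mcm
    return mcm.binary(int(class_selector), spacing)


def write_label_image(path, grid, spacing=None):
    """Write an integer label lattice as PNG (2D) or TIFF (2D/3D stack)."""
    path = Path(path)
    arr = np.asarray(grid)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr.astype(np.uint16), photometric="minisblack")
    else:
        if arr.ndim != 2:
            raise InputError("PNG supports 2D only; use TIFF for stacks")
        Image.fromarray(arr.astype(np.uint8), mode="L").save(path)
    if spacing is not None:
        sidecar = path.with_suffix(path.suffix + ".json")
        with open(sidecar, "w") as fh:
            json.dump({"spacing": list(spacing)}, fh)


# ---------------------------------------------------------------------------
# COCO-style detections


def read_detections(path):
    """Read COCO-style detection JSON into per-image instance sets.

    COCO boxes are ``[x, y, width, height]`` with x = column; they are
    converted to half-open (row, col) boxes.  Missing scores are
    preserved as ``confidence=None`` so that score-requiring metrics
    can surface the problem as an error instead of guessing.
    """
    with open(path) as fh:
        data = json.load(fh)
    images = {img["id"]: str(img.get("file_name", img["id"])) for img in data.get("images", [])}
    per_image: dict = {img_id: [] for img_id in images}
    for ann in data.get("annotations", []):
        x, y, w, h = ann["bbox"]
        if w <= 0 or h <= 0:
            raise InputError(f"non-positive box extent in annotation {ann.get('id')}")
        box = BoundingBox((int(y), int(x)), (int(y + h), int(x + w)))
        conf = ann.get("score")
        inst = Instance(box=box, label=int(ann.get("category_id", 1)),
                        confidence=float(conf) if conf is not None else None)
        per_image.setdefault(ann["image_id"], []).append(inst)
    return [InstanceSet(str(images.get(img_id, img_id)), instances)
            for img_id, instances in sorted(per_image.items(), key=lambda kv: str(kv[0]))]


def write_detections(path, sets: Sequence[InstanceSet]):
    """Write box instance sets back to COCO-style JSON."""
    images, annotations = [], []
    ann_id = 1
    for img_idx, s in enumerate(sets, start=1):
        images.append({"id": img_idx, "file_name": s.image_id})
        for inst in s:
            if inst.box is None:
                raise InputError("COCO export currently supports box locators only")
            (r0, c0), (r1, c1) = inst.box.mins, inst.box.maxs
            ann = {"id": ann_id, "image_id": img_idx, "category_id": inst.label,
                   "bbox": [c0, r0, c1 - c0, r1 - r0]}
            if inst.confidence is not None:
                ann["score"] = inst.confidence
            annotations.append(ann)
            ann_id += 1
    with open(path, "w") as fh:
        json.dump({"images": images, "annotations": annotations,
                   "categories": [{"id": 1}]}, fh, indent=1)


# ---------------------------------------------------------------------------
# CSV tables


def read_classification_csv(path):
    """Classification records: case_id, ref_label, pred_label[, score_*]."""
    df = pd.read_csv(path)
    for col in ("case_id", "ref_label", "pred_label"):
        if col not in df.columns:
            raise InputError(f"classification CSV requires column {col!r}")
    return df


def read_calibration_csv(path):
    """Calibration records: case_id, confidence, outcome."""
    df = pd.read_csv(path)
    for col in ("case_id", "confidence", "outcome"):
        if col not in df.columns:
            raise InputError(f"calibration CSV requires column {col!r}")
    return df


def read_cohort_csv(path):
    """Long-format per-case metric values with hierarchy columns."""
    from .aggregation import CohortTable

    df = pd.read_csv(path)
    return CohortTable(df)


# ---------------------------------------------------------------------------
# reports


def _result_record(r: MetricResult) -> dict:
    value = r.value
    rec = {
        "metric": r.metric,
        "value": None if (isinstance(value, float) and math.isnan(value)) else value,
        "level": r.level.value,
        "class_label": r.class_label,
        "image_id": r.image_id,
        "flags": r.flags,
    }
    if rec["value"] is None:
        rec["nan_reason"] = r.flags.get("nan_reason", "undefined")
    return rec


def write_report(path, per_case: Sequence[MetricResult], aggregates=None,
                 audit=None, config: Optional[RunConfig] = None):
    """Write a JSON report plus a long-format CSV of the raw values.

    The per-case raw values are mandatory: an aggregate without its
    raw-value distribution hides exactly the information (outliers,
    clusters, NaN cases) that summary numbers conceal.  NaN is
    serialized as null with an explicit reason field.
    """
    path = Path(path)
    records = [_result_record(r) for r in per_case]
    if not records:
        raise InputError("reports must contain per-case raw values")
    report = {
        "config": config.to_dict() if config is not None else None,
        "n_cases": len(records),
        "nan_count": sum(1 for r in records if r["value"] is None),
        "per_case_raw_values": records,
        "aggregates": {
            k: _result_record(v) for k, v in (aggregates or {}).items()
        },
        "audit": audit,
        "raw_values_csv": str(path.with_suffix(".csv").name),
    }
    with open(path, "w") as fh:
        json.dump(report, fh, indent=1, default=str)
    pd.DataFrame(
        [{k: v for k, v in r.items() if k != "flags"} for r in records]
    ).to_csv(path.with_suffix(".csv"), index=False)
    return report
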