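"""Segmentation evaluation: overlap metrics and surface distances.

Overlap metrics (mIoU, Dice, Jaccard) are computed from exact per-class
confusion counts.  Surface metrics (ASD, HD, 95HD) operate on the sets of
boundary pixels/voxels of binary masks: a foreground element is a surface
element iff it has a face-adjacent background neighbour (4-connectivity in
2D, 6-connectivity in 3D) or lies on the raster border.  Distances are
Euclidean with optional anisotropic physical spacing, computed with a k-d
tree.

Conventions fixed here once: percentiles use linear interpolation between
order statistics; 95HD is the maximum over the two directions of the
directed 95th-percentile distance (a pooled-percentile variant is exposed
via ``method="pooled"``); classes absent from both rasters are excluded
from mIoU.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

__all__ = [
    "ConfusionCounts",
    "SurfaceSet",
    "MetricsReport",
    "EmptySurfaceError",
    "confusion_counts",
    "per_class_iou",
    "miou",
    "dice",
    "jaccard",
    "extract_surface",
    "asd",
    "hd",
    "hd95",
    "evaluate_segmentation",
]


class EmptySurfaceError(ValueError):
    """Raised when a surface-distance operand has no boundary elements."""


@dataclass(frozen=True)
class ConfusionCounts:
    """Per-class true-positive / false-positive / false-negative pixel counts."""

    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    total_pixels: int

    @property
    def num_classes(self) -> int:
        return len(self.tp)

    def union(self) -> np.ndarray:
        return self.tp + self.fp + self.fn


@dataclass(frozen=True)
class SurfaceSet:
    """Boundary elements of a binary mask, as integer grid coordinates."""

    coordinates: np.ndarray  # (n, ndim) integer coordinates
    spacing: np.ndarray  # (ndim,) physical spacing per axis

    def __len__(self) -> int:
        return len(self.coordinates)

    def physical(self) -> np.ndarray:
        return self.coordinates * self.spacing


def confusion_counts(pred: np.ndarray, gt: np.ndarray, num_classes: int) -> ConfusionCounts:
    """Exact per-class confusion counts between two label rasters."""
    pred = np.asarray(pred)
    gt = np.asarray(gt)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs gt {gt.shape}")
    for name, arr in (("pred", pred), ("gt", gt)):
        if not np.issubdtype(arr.dtype, np.integer):
            raise ValueError(f"{name} must be an integer label raster")
        if arr.size and (arr.min() < 0 or arr.max() >= num_classes):
            raise ValueError(f"{name} labels must lie in 0..{num_classes - 1}")
    cm = np.bincount(
        (gt.reshape(-1).astype(np.int64) * num_classes + pred.reshape(-1)),
        minlength=num_classes * num_classes,
    ).reshape(num_classes, num_classes)  # cm[i, j] = #(gt == i and pred == j)
    tp = np.diag(cm).copy()
    fn = cm.sum(axis=1) - tp
    fp = cm.sum(axis=0) - tp
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, total_pixels=int(pred.size))


def per_class_iou(counts: ConfusionCounts) -> np.ndarray:
    """IoU per class; NaN for classes absent from both rasters."""
    union = counts.union().astype(np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(union > 0, counts.tp / union, np.nan)


def miou(counts: ConfusionCounts) -> float:
    """Mean of TP/(TP+FP+FN) over classes present in at least one raster."""
    iou = per_class_iou(counts)
    valid = ~np.isnan(iou)
    if not valid.any():
        raise ValueError("no class with nonzero union; mIoU undefined")
    return float(iou[valid].mean())


def _class_counts(counts: ConfusionCounts, class_index: int):
    if not 0 <= class_index < counts.num_classes:
        raise ValueError(f"class_index {class_index} out of range")
    tp = counts.tp[class_index]
    union = counts.union()[class_index]
    if union == 0:
        raise ValueError(f"class {class_index} absent from both rasters; metric undefined")
    return float(tp), float(union)


def dice(counts: ConfusionCounts, class_index: int) -> float:
    """2TP / (2TP + FP + FN) for one class."""
    tp, union = _class_counts(counts, class_index)
    return 2.0 * tp / (union + tp)


def jaccard(counts: ConfusionCounts, class_index: int) -> float:
    """TP / (TP + FP + FN) for one class."""
    tp, union = _class_counts(counts, class_index)
    return tp / union


def extract_surface(mask: np.ndarray, spacing=None) -> SurfaceSet:
    """Boundary elements of a binary mask (2D or 3D).

    Face-connectivity erosion with background outside the raster implements
    the convention that border foreground elements are surface elements.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.ndim not in (2, 3):
        raise ValueError("mask must be 2D or 3D")
    spacing = np.ones(mask.ndim) if spacing is None else np.asarray(spacing, dtype=np.float64)
    if spacing.shape != (mask.ndim,) or np.any(spacing <= 0):
        raise ValueError("spacing must be one positive value per axis")
    structure = ndimage.generate_binary_structure(mask.ndim, 1)
    interior = ndimage.binary_erosion(mask, structure=structure, border_value=0)
    return SurfaceSet(coordinates=np.argwhere(mask & ~interior), spacing=spacing)


def _directed_distances(a: SurfaceSet, b: SurfaceSet) -> tuple[np.ndarray, np.ndarray]:
    for name, s in (("first", a), ("second", b)):
        if len(s) == 0:
            raise EmptySurfaceError(f"the {name} surface set is empty")
    tree_a, tree_b = cKDTree(a.physical()), cKDTree(b.physical())
    return tree_b.query(a.physical())[0], tree_a.query(b.physical())[0]


def asd(a: SurfaceSet, b: SurfaceSet) -> float:
    """Average symmetric surface distance."""
    d_ab, d_ba = _directed_distances(a, b)
    return float((d_ab.sum() + d_ba.sum()) / (len(a) + len(b)))


def hd(a: SurfaceSet, b: SurfaceSet) -> float:
    """Hausdorff distance: max over both directed maximum distances."""
    d_ab, d_ba = _directed_distances(a, b)
    return float(max(d_ab.max(), d_ba.max()))


def hd95(a: SurfaceSet, b: SurfaceSet, method: str = "directed") -> float:
    """95th-percentile Hausdorff distance.

    ``directed`` (default): max over the two directions of the directed
    95th percentile.  ``pooled``: 95th percentile of the pooled distances.
    """
    d_ab, d_ba = _directed_distances(a, b)
    if method == "directed":
        return float(max(np.percentile(d_ab, 95), np.percentile(d_ba, 95)))
    if method == "pooled":
        return float(np.percentile(np.concatenate([d_ab, d_ba]), 95))
    raise ValueError(f"unknown hd95 method {method!r}")


_SURFACE_METRICS = {"asd": asd, "hd": hd, "hd95": hd95}
_OVERLAP_METRICS = ("miou", "dice", "jaccard")


@dataclass
class MetricsReport:
    """Per-class and aggregate metric values, JSON-serialisable."""

    num_classes: int
    spacing: list
    per_class: dict = field(default_factory=dict)  # metric -> {class_index: value}
    aggregate: dict = field(default_factory=dict)  # metric -> value
    excluded_classes: list = field(default_factory=list)

    def to_json(self, indent: int | None = None) -> str:
        return json.dumps(
            {
                "num_classes": self.num_classes,
                "spacing": self.spacing,
                "per_class": {m: {str(c): v for c, v in d.items()} for m, d in self.per_class.items()},
                "aggregate": self.aggregate,
                "excluded_classes": self.excluded_classes,
            },
            indent=indent,
        )


def evaluate_segmentation(
    pred: np.ndarray,
    gt: np.ndarray,
    num_classes: int,
    metrics: tuple = ("miou", "dice", "jaccard"),
    spacing=None,
) -> MetricsReport:
    """Evaluate a predicted label raster against ground truth.

    Overlap metrics come from confusion counts; surface metrics are computed
    per foreground class on the binarised masks and averaged over classes
    present in both rasters.  Requesting a surface metric for a class whose
    prediction or ground truth has empty foreground raises
    :class:`EmptySurfaceError`.
    """
    counts = confusion_counts(pred, gt, num_classes)
    iou = per_class_iou(counts)
    report = MetricsReport(
        num_classes=num_classes,
        spacing=list(np.ones(np.asarray(gt).ndim) if spacing is None else np.asarray(spacing)),
        excluded_classes=[int(c) for c in np.flatnonzero(np.isnan(iou))],
    )
    evaluated = [c for c in range(num_classes) if not np.isnan(iou[c])]

    for metric in metrics:
        if metric == "miou":
            report.per_class["iou"] = {c: float(iou[c]) for c in evaluated}
            report.aggregate["miou"] = miou(counts)
        elif metric in ("dice", "jaccard"):
            fn = dice if metric == "dice" else jaccard
            vals = {c: fn(counts, c) for c in evaluated}
            report.per_class[metric] = vals
            report.aggregate[f"mean_{metric}"] = float(np.mean(list(vals.values())))
        elif metric in _SURFACE_METRICS:
            fn = _SURFACE_METRICS[metric]
            vals = {}
            for c in evaluated:
                if c == 0:
                    continue  # background boundary is not a clinical surface
                try:
                    vals[c] = fn(
                        extract_surface(pred == c, spacing), extract_surface(gt == c, spacing)
                    )
                except EmptySurfaceError as err:
                    raise EmptySurfaceError(f"class {c}: {err}") from err
            if vals:
                report.per_class[metric] = vals
                report.aggregate[f"mean_{metric}"] = float(np.mean(list(vals.values())))
        else:
            raise ValueError(f"unknown metric {metric!r}")
    return report
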