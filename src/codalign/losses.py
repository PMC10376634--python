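"""Supervised, cross-pseudo-supervision and over-expectation losses.

The supervised loss is the mean pixel-wise cross-entropy of both networks
against the ground truth.  On unlabeled data each network is supervised by
the other network's hard pseudo-labels; the over-expectation (O-E) variant
additionally discards pixels whose confidence does not exceed the
pseudo-class's own expected confidence ``t(i) = Mu[i, i]`` — the diagonal
of the unlabeled distribution matrix — so that only above-expectation
pseudo-labels contribute gradient.  Setting every threshold to zero
recovers the plain cross-pseudo-supervision loss exactly.

Losses here are reported as scalars; the gradient forms live in the
training engine (they are all softmax cross-entropy gradients because the
pseudo-labels, accept masks and alignment weights are detached).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .distributions import ClassDistributionMatrix, ProbabilityMap

__all__ = [
    "PseudoLabelMap",
    "LossReport",
    "supervised_loss",
    "compute_oe_threshold",
    "build_pseudo_labels",
    "oe_loss",
    "cross_pseudo_loss",
]

_LOG_FLOOR = 1e-12  # keeps -log finite; far below any probability a softmax head emits


@dataclass(frozen=True)
class PseudoLabelMap:
    """Hard pseudo-labels with confidences and the O-E acceptance mask.

    ``thresholds`` records the per-class acceptance thresholds the mask was
    built with, so the mask is reproducible from the stored fields alone.
    """

    labels: np.ndarray  # integer class indices, raster-shaped
    confidences: np.ndarray  # probability of the chosen class, in [0, 1]
    accept_mask: np.ndarray  # boolean, True where confidence > threshold(label)
    thresholds: np.ndarray  # per-class thresholds used, shape (K,)
    source: str = ""  # identifier of the generating model

    def __post_init__(self) -> None:
        if self.labels.shape != self.confidences.shape or self.labels.shape != self.accept_mask.shape:
            raise ValueError("labels, confidences and accept_mask must share a shape")

    @property
    def accepted_fraction(self) -> float:
        return float(self.accept_mask.mean()) if self.accept_mask.size else 0.0


@dataclass(frozen=True)
class LossReport:
    """Per-iteration loss summary for the training log."""

    supervised: float
    unsupervised: float
    lambda_u: float
    accepted_fraction_1: float
    accepted_fraction_2: float

    @property
    def total(self) -> float:
        return self.supervised + self.lambda_u * self.unsupervised

    def to_json(self) -> str:
        return json.dumps(
            {
                "supervised": self.supervised,
                "unsupervised": self.unsupervised,
                "lambda_u": self.lambda_u,
                "total": self.total,
                "accepted_fraction_1": self.accepted_fraction_1,
                "accepted_fraction_2": self.accepted_fraction_2,
            }
        )


def _gather_label_probs(probs: ProbabilityMap, labels: np.ndarray) -> np.ndarray:
    values = probs.values
    if labels.shape != values.shape[:-1]:
        raise ValueError(
            f"labels shape {labels.shape} does not match raster shape {values.shape[:-1]}"
        )
    if labels.size and (labels.min() < 0 or labels.max() >= values.shape[-1]):
        raise ValueError(f"labels must lie in 0..{values.shape[-1] - 1}")
    return np.take_along_axis(values, labels[..., None], axis=-1)[..., 0]


def supervised_loss(
    probs1: ProbabilityMap, probs2: ProbabilityMap, labels: np.ndarray
) -> float:
    """Mean over labeled pixels of ``-(log F1(x)_y + log F2(x)_y)``.

    Zero only when both networks put probability one on the true class at
    every pixel; symmetric in the two networks.
    """
    if probs1.values.shape != probs2.values.shape:
        raise ValueError("the two probability maps must share a shape")
    labels = np.asarray(labels)
    if not np.issubdtype(labels.dtype, np.integer):
        raise ValueError("labels must be integer class indices")
    p1 = np.clip(_gather_label_probs(probs1, labels), _LOG_FLOOR, None)
    p2 = np.clip(_gather_label_probs(probs2, labels), _LOG_FLOOR, None)
    return float(-(np.log(p1) + np.log(p2)).mean())


def compute_oe_threshold(Mu: ClassDistributionMatrix, class_index: int) -> float:
    """Dynamic per-class threshold ``t(i) = Mu[i, i]``.

    The diagonal of the unlabeled matrix is the running mean confidence the
    network assigns to class *i* on pixels it pseudo-labels *i*; a pixel is
    kept only if it beats that expectation.
    """
    if not 0 <= class_index < Mu.num_classes:
        raise ValueError(f"class_index {class_index} out of range for K={Mu.num_classes}")
    return float(Mu.entries[class_index, class_index])


def build_pseudo_labels(
    aligned: ProbabilityMap,
    Mu: ClassDistributionMatrix,
    static_threshold: float | None = None,
    source: str = "",
) -> PseudoLabelMap:
    """Argmax pseudo-labels plus the strict over-expectation filter.

    Pseudo-labels are always derived from an aligned probability map (raw
    maps are rejected).  ``static_threshold`` replaces the dynamic per-class
    thresholds with a single scalar — used for threshold-ablation runs.
    """
    if not aligned.aligned:
        raise ValueError("pseudo-labels must be built from an aligned probability map")
    if Mu.num_classes != aligned.num_classes:
        raise ValueError("matrix and probability map disagree on num_classes")
    values = aligned.values
    labels = np.argmax(values, axis=-1)
    confidences = np.max(values, axis=-1)
    if static_threshold is None:
        thresholds = np.diag(Mu.entries).copy()
    else:
        if not 0.0 <= static_threshold <= 1.0:
            raise ValueError("static_threshold must lie in [0, 1]")
        thresholds = np.full(Mu.num_classes, float(static_threshold))
    accept_mask = confidences > thresholds[labels]
    return PseudoLabelMap(
        labels=labels,
        confidences=confidences,
        accept_mask=accept_mask,
        thresholds=thresholds,
        source=source,
    )


def oe_loss(probs_self: ProbabilityMap, pseudo_other: PseudoLabelMap) -> float:
    """One direction of the over-expectation cross-entropy loss.

    Mean over ALL unlabeled pixels of ``accept * -log p_self[label]``:
    rejected pixels contribute zero but stay in the denominator, so raising
    thresholds can only shrink the loss.  The engine sums both directions.
    """
    if pseudo_other.labels.shape != probs_self.values.shape[:-1]:
        raise ValueError("pseudo-label map and probability map must share a raster shape")
    p = np.clip(_gather_label_probs(probs_self, pseudo_other.labels), _LOG_FLOOR, None)
    contrib = np.where(pseudo_other.accept_mask, -np.log(p), 0.0)
    return float(contrib.mean()) if contrib.size else 0.0


def cross_pseudo_loss(probs_self: ProbabilityMap, labels_other: np.ndarray) -> float:
    """Plain cross-pseudo-supervision loss (the zero-threshold special case)."""
    p = np.clip(_gather_label_probs(probs_self, np.asarray(labels_other)), _LOG_FLOOR, None)
    return float(-np.log(p).mean())
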