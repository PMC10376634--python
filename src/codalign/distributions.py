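"""Class-wise marginal prediction distributions and distribution alignment.

A segmentation network's output statistics are summarised by two K x K
matrices: row *i* of the *labeled* matrix is the running mean of the
network's probability vectors over pixels whose ground-truth class is *i*;
row *i* of the *unlabeled* matrix is the same conditional mean over pixels
whose *pseudo* class (argmax) is *i*.  Both are maintained with an
exponential moving average so they track the network as it trains.

Alignment rescales every unlabeled prediction by the ratio of the labeled
to the unlabeled row of its argmax class, with the labeled row flattened by
an adaptive per-class temperature ``tau_i = 1 - Ml[i, i]`` before the
ratio is taken.  The net effect is to pull the class statistics of the
unlabeled predictions toward the class statistics observed on labeled
data, which protects minority classes from being drowned out by the
majority during pseudo-labeling.

All functions are pure: inputs are never mutated and repeated calls return
identical results.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "ClassDistributionMatrix",
    "ProbabilityMap",
    "EMAConfig",
    "init_distributions",
    "update_labeled_distribution",
    "update_unlabeled_distribution",
    "compute_temperature",
    "align_prediction",
]

_ROW_SUM_TOL = 1e-6


@dataclass(frozen=True)
class EMAConfig:
    """Numerical configuration for distribution maintenance and alignment.

    alpha
        EMA momentum in [0, 1]; the estimate averages roughly the last
        1/(1 - alpha) batches.  Default 0.99 (~100 batches), stable at the
        small batch sizes typical of segmentation training.
    epsilon
        Additive guard for divisions and for the base of fractional powers.
    tau_min
        Lower clamp of the adaptive temperature; tau -> 0 together with a
        zero entry in a labeled row is ill-conditioned.
    """

    alpha: float = 0.99
    epsilon: float = 1e-8
    tau_min: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.epsilon <= 0.0:
            raise ValueError(f"epsilon must be positive, got {self.epsilon}")
        if not 0.0 < self.tau_min <= 1.0:
            raise ValueError(f"tau_min must be in (0, 1], got {self.tau_min}")


@dataclass(frozen=True)
class ClassDistributionMatrix:
    """K x K matrix of per-class marginal prediction distributions.

    ``entries[i]`` is the estimated mean probability vector over pixels of
    class *i* (ground-truth class for ``role='labeled'``, argmax pseudo-class
    for ``role='unlabeled'``).  Every row lies on the probability simplex.
    """

    entries: np.ndarray
    role: str  # "labeled" | "unlabeled"

    def __post_init__(self) -> None:
        entries = np.asarray(self.entries, dtype=np.float64)
        object.__setattr__(self, "entries", entries)
        if self.role not in ("labeled", "unlabeled"):
            raise ValueError(f"role must be 'labeled' or 'unlabeled', got {self.role!r}")
        if entries.ndim != 2 or entries.shape[0] != entries.shape[1]:
            raise ValueError(f"entries must be square, got shape {entries.shape}")
        if entries.shape[0] < 2:
            raise ValueError("num_classes must be >= 2")
        if np.any(entries < -_ROW_SUM_TOL) or np.any(entries > 1.0 + _ROW_SUM_TOL):
            raise ValueError("entries must lie in [0, 1]")
        if not np.allclose(entries.sum(axis=1), 1.0, atol=_ROW_SUM_TOL):
            raise ValueError("every row must sum to 1")

    @property
    def num_classes(self) -> int:
        return self.entries.shape[0]

    def to_json(self) -> str:
        return json.dumps(
            {
                "num_classes": self.num_classes,
                "role": self.role,
                "entries": self.entries.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "ClassDistributionMatrix":
        doc = json.loads(text)
        entries = np.asarray(doc["entries"], dtype=np.float64)
        if entries.shape != (doc["num_classes"], doc["num_classes"]):
            raise ValueError("entries shape disagrees with num_classes")
        return cls(entries=entries, role=doc["role"])


@dataclass(frozen=True)
class ProbabilityMap:
    """Per-pixel class-probability vectors with classes on the last axis.

    ``values`` has shape ``(..., K)``; any leading raster/batch shape is
    accepted.  ``aligned`` distinguishes raw network output from the
    post-alignment output that pseudo-labels must be built from.
    """

    values: np.ndarray
    aligned: bool = False

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", values)
        if values.ndim < 1 or values.shape[-1] < 2:
            raise ValueError("values must have >= 2 classes on the last axis")
        if np.any(values < -_ROW_SUM_TOL):
            raise ValueError("probabilities must be nonnegative")
        if not np.allclose(values.sum(axis=-1), 1.0, atol=_ROW_SUM_TOL):
            raise ValueError("pixel probability vectors must sum to 1")

    @property
    def num_classes(self) -> int:
        return self.values.shape[-1]

    def mark_aligned(self) -> "ProbabilityMap":
        return replace(self, aligned=True)


def init_distributions(num_classes: int, role: str = "labeled") -> ClassDistributionMatrix:
    """Uniform K x K initialisation (every entry 1/K).

    Uniform rows make alignment an exact no-op at step 0, avoiding any bias
    before statistics have been observed.
    """
    if int(num_classes) != num_classes or num_classes < 2:
        raise ValueError(f"num_classes must be an integer >= 2, got {num_classes}")
    num_classes = int(num_classes)
    entries = np.full((num_classes, num_classes), 1.0 / num_classes, dtype=np.float64)
    return ClassDistributionMatrix(entries=entries, role=role)


def _check_probs_labels(probs: ProbabilityMap, labels: np.ndarray, num_classes: int) -> np.ndarray:
    labels = np.asarray(labels)
    if not np.issubdtype(labels.dtype, np.integer):
        raise ValueError("labels must be integer class indices")
    if labels.shape != probs.values.shape[:-1]:
        raise ValueError(
            f"labels shape {labels.shape} does not match raster shape {probs.values.shape[:-1]}"
        )
    if labels.size and (labels.min() < 0 or labels.max() >= num_classes):
        raise ValueError(f"labels must lie in 0..{num_classes - 1}")
    if probs.num_classes != num_classes:
        raise ValueError("probability map and matrix disagree on num_classes")
    return labels


def _ema_by_group(
    entries: np.ndarray, probs_flat: np.ndarray, groups: np.ndarray, alpha: float
) -> np.ndarray:
    """EMA-update each row whose group appears; leave absent rows untouched."""
    out = entries.copy()
    for i in np.unique(groups):
        cond_mean = probs_flat[groups == i].mean(axis=0)
        out[i] = alpha * out[i] + (1.0 - alpha) * cond_mean
    return out


def update_labeled_distribution(
    M: ClassDistributionMatrix,
    probs: ProbabilityMap,
    labels: np.ndarray,
    cfg: EMAConfig,
) -> ClassDistributionMatrix:
    """EMA update of the labeled matrix grouped by ground-truth class.

    Row *i* moves toward the conditional mean probability vector of the
    pixels labeled *i* in this batch; rows of classes absent from the batch
    are left unchanged.
    """
    if M.role != "labeled":
        raise ValueError("update_labeled_distribution requires a labeled matrix")
    if probs.aligned:
        raise ValueError("distribution updates consume raw (unaligned) probabilities")
    labels = _check_probs_labels(probs, labels, M.num_classes)
    flat = probs.values.reshape(-1, M.num_classes)
    entries = _ema_by_group(M.entries, flat, labels.reshape(-1), cfg.alpha)
    return ClassDistributionMatrix(entries=entries, role="labeled")


def update_unlabeled_distribution(
    Mu: ClassDistributionMatrix,
    Ml: ClassDistributionMatrix,
    probs: ProbabilityMap,
    cfg: EMAConfig,
) -> ClassDistributionMatrix:
    """EMA update of the unlabeled matrix grouped by argmax pseudo-class.

    Classes with at least one pseudo-labeled pixel are updated exactly like
    the labeled rows.  A class absent from the batch (typically a minority
    class) is instead refreshed through the average labeled-to-unlabeled
    transformation: its labeled row is multiplied entrywise by the mean over
    all K classes of the ratio ``Mu_prev_row_j / Ml_row_j`` and renormalised.
    """
    if Mu.role != "unlabeled":
        raise ValueError("update_unlabeled_distribution requires an unlabeled matrix")
    if Ml.role != "labeled":
        raise ValueError("Ml must be the labeled matrix")
    if probs.aligned:
        raise ValueError("distribution updates consume raw (unaligned) probabilities")
    K = Mu.num_classes
    if Ml.num_classes != K or probs.num_classes != K:
        raise ValueError("Ml, Mu and probs must share num_classes")

    flat = probs.values.reshape(-1, K)
    pseudo = np.argmax(flat, axis=1)
    entries = _ema_by_group(Mu.entries, flat, pseudo, cfg.alpha)

    present = np.zeros(K, dtype=bool)
    present[np.unique(pseudo)] = True
    if not present.all():
        mean_ratio = (Mu.entries / (Ml.entries + cfg.epsilon)).mean(axis=0)
        for i in np.flatnonzero(~present):
            row = Ml.entries[i] * mean_ratio
            total = row.sum()
            entries[i] = row / total if total > 0 else np.full(K, 1.0 / K)
    return ClassDistributionMatrix(entries=entries, role="unlabeled")


def compute_temperature(Ml: ClassDistributionMatrix, class_index: int, cfg: EMAConfig) -> float:
    """Adaptive temperature ``tau_i = 1 - Ml[i, i]``, clamped to [tau_min, 1].

    A confidently learned class (large diagonal) gets a small temperature,
    flattening its labeled row toward uniform before alignment so the
    transformation does not over-amplify already dominant classes.
    """
    if not 0 <= class_index < Ml.num_classes:
        raise ValueError(f"class_index {class_index} out of range for K={Ml.num_classes}")
    return float(np.clip(1.0 - Ml.entries[class_index, class_index], cfg.tau_min, 1.0))


def _alignment_weights(
    Ml: ClassDistributionMatrix, Mu: ClassDistributionMatrix, cfg: EMAConfig
) -> np.ndarray:
    """Per-class weight rows ``Ml_i^tau_i / (Mu_i + eps)``, max-rescaled.

    Each row is divided by its maximum: the final per-pixel normalisation is
    invariant to row scale, and the rescaling keeps the uniform-matrices case
    an exact identity (all-ones weight row) while improving conditioning.
    """
    K = Ml.num_classes
    taus = np.clip(1.0 - np.diag(Ml.entries), cfg.tau_min, 1.0)
    base = np.maximum(Ml.entries, cfg.epsilon)
    weights = base ** taus[:, None] / (Mu.entries + cfg.epsilon)
    weights /= weights.max(axis=1, keepdims=True)
    return weights


def align_prediction(
    probs: ProbabilityMap,
    Ml: ClassDistributionMatrix,
    Mu: ClassDistributionMatrix,
    cfg: EMAConfig,
) -> ProbabilityMap:
    """Coefficient transformation of unlabeled predictions.

    For each pixel with argmax class *i* the probability vector is
    multiplied entrywise by ``Ml_i^tau_i / (Mu_i + eps)`` and renormalised.
    The returned map carries ``aligned=True``.
    """
    if probs.aligned:
        raise ValueError("input probabilities are already aligned")
    K = probs.num_classes
    if Ml.num_classes != K or Mu.num_classes != K:
        raise ValueError("matrices and probabilities must share num_classes")
    values = probs.values
    idx = np.argmax(values, axis=-1)
    weighted = values * _alignment_weights(Ml, Mu, cfg)[idx]
    out = weighted / weighted.sum(axis=-1, keepdims=True)
    return ProbabilityMap(values=out, aligned=True)
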