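"""Synthetic imbalanced multi-class segmentation tasks.

Each image starts as background (class 0); foreground classes 1..K-1 are
painted as randomly placed shapes whose expected total area decays
geometrically with the class index (ratio ``imbalance_ratio``), painted in
increasing class order so later (rarer) classes overwrite earlier ones.
Shape counts are Poisson-distributed, so minority classes are genuinely
absent from some images — the regime the absent-class distribution update
is designed for.  Pixel intensities are the class mean plus Gaussian noise,
quantised to 8 bits.

The generator emulates the two properties that make sparsely labeled
biomedical segmentation hard — strong class imbalance and labeled/unlabeled
distribution mismatch from tiny labeled subsets — not the appearance of any
real modality.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace

import imageio.v3 as iio
import numpy as np
import pandas as pd

__all__ = ["SyntheticDatasetSpec", "DatasetBundle", "generate", "split_labeled"]


class SpecInfeasibleError(ValueError):
    """Raised when requested shapes cannot fit the raster."""


@dataclass(frozen=True)
class SyntheticDatasetSpec:
    """Parameters of a synthetic imbalanced segmentation task.

    Defaults define the reference task used throughout the package: 4
    classes with geometric area decay (ratio 0.4), 64 images of 32x32, 12%
    labeled, and noise chosen so that the labeled subset alone visibly
    under-fits (single-pixel intensity is an unreliable classifier) while
    local context still makes the task learnable.
    """

    num_classes: int = 4
    image_size: tuple = (32, 32)
    num_images: int = 64
    labeled_fraction: float = 0.12
    imbalance_ratio: float = 0.4
    intensity_means: tuple | None = None  # default: even spread over [0.15, 0.9]
    noise_sigma: float = 0.30
    shape_family: str = "ellipse"  # ellipse | rectangle | blob
    seed: int = 0
    test_fraction: float = 0.2
    base_shape_rate: float = 2.0  # expected shape count for class 1
    base_area_fraction: float = 0.2  # expected total area of class 1, fraction of raster

    def __post_init__(self) -> None:
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2")
        if not 0.0 < self.labeled_fraction <= 1.0:
            raise ValueError("labeled_fraction must lie in (0, 1]")
        if not 0.0 < self.imbalance_ratio < 1.0:
            raise ValueError("imbalance_ratio must lie in (0, 1)")
        if self.shape_family not in ("ellipse", "rectangle", "blob"):
            raise ValueError(f"unknown shape_family {self.shape_family!r}")
        if self.num_images * self.labeled_fraction < 1:
            raise ValueError("labeled_fraction * num_images must be >= 1")
        if self.intensity_means is not None and len(self.intensity_means) != self.num_classes:
            raise ValueError("intensity_means must have one entry per class")

    def means(self) -> np.ndarray:
        if self.intensity_means is not None:
            return np.asarray(self.intensity_means, dtype=np.float64)
        return np.linspace(0.15, 0.9, self.num_classes)


@dataclass
class DatasetBundle:
    """Images, masks and a labeled/unlabeled/test partition.

    ``images`` are uint8 grayscale (N, H, W); ``masks`` are uint8 class
    indices.  Unlabeled masks are retained for evaluation only — the
    training engine never sees them.  ``manifest`` has one row per item
    with columns ``image_path, mask_path, split``.
    """

    images: np.ndarray
    masks: np.ndarray
    manifest: pd.DataFrame
    num_classes: int

    def _indices(self, split: str) -> np.ndarray:
        return self.manifest.index[self.manifest["split"] == split].to_numpy()

    def labeled_arrays(self):
        idx = self._indices("labeled")
        return self.images[idx], self.masks[idx]

    def unlabeled_images(self) -> np.ndarray:
        return self.images[self._indices("unlabeled")]

    def unlabeled_masks(self) -> np.ndarray:
        """Held-out masks of the unlabeled split, for evaluation only."""
        return self.masks[self._indices("unlabeled")]

    def test_arrays(self):
        idx = self._indices("test")
        return self.images[idx], self.masks[idx]

    def save(self, out_dir: str) -> None:
        os.makedirs(os.path.join(out_dir, "images"), exist_ok=True)
        os.makedirs(os.path.join(out_dir, "masks"), exist_ok=True)
        rows = []
        for i, split in enumerate(self.manifest["split"]):
            image_path = os.path.join("images", f"{i:05d}.png")
            mask_path = os.path.join("masks", f"{i:05d}.png")
            iio.imwrite(os.path.join(out_dir, image_path), self.images[i])
            iio.imwrite(os.path.join(out_dir, mask_path), self.masks[i])
            rows.append(
                {
                    "image_path": image_path,
                    "mask_path": "" if split == "unlabeled" else mask_path,
                    "split": split,
                }
            )
        pd.DataFrame(rows).to_csv(os.path.join(out_dir, "manifest.csv"), index=False)

    @classmethod
    def load(cls, in_dir: str, num_classes: int | None = None) -> "DatasetBundle":
        manifest = pd.read_csv(os.path.join(in_dir, "manifest.csv"), keep_default_na=False)
        images, masks = [], []
        for _, row in manifest.iterrows():
            images.append(iio.imread(os.path.join(in_dir, row["image_path"])))
            # unlabeled rows omit the mask from the manifest; read the sibling
            # file when present so held-out evaluation still works, else zeros
            mask_path = row["mask_path"] or row["image_path"].replace("images", "masks")
            full = os.path.join(in_dir, mask_path)
            masks.append(iio.imread(full) if os.path.exists(full) else np.zeros_like(images[-1]))
        images = np.stack(images)
        masks = np.stack(masks).astype(np.uint8)
        k = int(masks.max()) + 1 if num_classes is None else num_classes
        return cls(images=images, masks=masks, manifest=manifest[["image_path", "mask_path", "split"]].copy(), num_classes=k)


def _paint_ellipse(mask, cls, center, area, aspect, angle):
    h, w = mask.shape
    b = np.sqrt(area / (np.pi * aspect))  # semi-minor; semi-major a = aspect*b
    a = aspect * b
    rr, cc = np.mgrid[0:h, 0:w]
    ca, sa = np.cos(angle), np.sin(angle)
    x = (rr - center[0]) * ca + (cc - center[1]) * sa
    y = -(rr - center[0]) * sa + (cc - center[1]) * ca
    mask[(x / a) ** 2 + (y / b) ** 2 <= 1.0] = cls


def _paint_rectangle(mask, cls, center, area, aspect, angle):
    h, w = mask.shape
    side_b = np.sqrt(area / aspect)
    side_a = aspect * side_b
    rr, cc = np.mgrid[0:h, 0:w]
    ca, sa = np.cos(angle), np.sin(angle)
    x = (rr - center[0]) * ca + (cc - center[1]) * sa
    y = -(rr - center[0]) * sa + (cc - center[1]) * ca
    mask[(np.abs(x) <= side_a / 2) & (np.abs(y) <= side_b / 2)] = cls


def _paint_blob(mask, cls, center, area, aspect, angle, rng):
    # union of three jittered ellipse lobes approximating an irregular blob
    for _ in range(3):
        jitter = rng.normal(0, np.sqrt(area) / 4, size=2)
        _paint_ellipse(mask, cls, center + jitter, area / 2.2, aspect, rng.uniform(0, np.pi))


def generate(spec: SyntheticDatasetSpec) -> DatasetBundle:
    """Generate a deterministic imbalanced dataset bundle from a spec."""
    h, w = spec.image_size
    rng = np.random.default_rng(spec.seed)
    means = spec.means()
    if np.any(means < 0) or np.any(means > 1):
        raise ValueError("intensity means must lie in [0, 1]")

    area1 = spec.base_area_fraction * h * w  # expected total area, class 1
    mean_shape_area = area1 / spec.base_shape_rate
    if 2.0 * np.sqrt(mean_shape_area / np.pi) > min(h, w):
        raise SpecInfeasibleError("expected shape diameter exceeds the raster")

    images = np.empty((spec.num_images, h, w), dtype=np.uint8)
    masks = np.empty((spec.num_images, h, w), dtype=np.uint8)
    for n in range(spec.num_images):
        mask = np.zeros((h, w), dtype=np.uint8)
        for cls in range(1, spec.num_classes):
            rate = spec.base_shape_rate * spec.imbalance_ratio ** (cls - 1)
            for _ in range(rng.poisson(rate)):
                center = rng.uniform([0, 0], [h, w])
                area = mean_shape_area * rng.uniform(0.5, 1.5)
                aspect = rng.uniform(1.0, 2.0)
                angle = rng.uniform(0, np.pi)
                if spec.shape_family == "ellipse":
                    _paint_ellipse(mask, cls, center, area, aspect, angle)
                elif spec.shape_family == "rectangle":
                    _paint_rectangle(mask, cls, center, area, aspect, angle)
                else:
                    _paint_blob(mask, cls, center, area, aspect, angle, rng)
        intensity = means[mask] + rng.normal(0.0, spec.noise_sigma, size=mask.shape)
        images[n] = np.round(np.clip(intensity, 0.0, 1.0) * 255).astype(np.uint8)
        masks[n] = mask

    n_test = int(round(spec.test_fraction * spec.num_images))
    n_labeled = max(1, int(round(spec.labeled_fraction * spec.num_images)))
    if n_labeled + n_test > spec.num_images:
        raise ValueError("labeled_fraction and test_fraction exceed the dataset")
    perm = rng.permutation(spec.num_images)
    split = np.full(spec.num_images, "unlabeled", dtype=object)
    split[perm[:n_test]] = "test"
    split[perm[n_test : n_test + n_labeled]] = "labeled"
    manifest = pd.DataFrame(
        {
            "image_path": [f"images/{i:05d}.png" for i in range(spec.num_images)],
            "mask_path": [
                "" if s == "unlabeled" else f"masks/{i:05d}.png" for i, s in enumerate(split)
            ],
            "split": split,
        }
    )
    return DatasetBundle(images=images, masks=masks, manifest=manifest, num_classes=spec.num_classes)


def split_labeled(bundle: DatasetBundle, labeled_fraction: float, seed: int) -> DatasetBundle:
    """Re-draw the labeled subset among non-test images.

    The labeled count is ``max(1, round(labeled_fraction * num_images))``;
    remaining non-test images become unlabeled.  Deterministic given seed.
    """
    if not 0.0 < labeled_fraction <= 1.0:
        raise ValueError("labeled_fraction must lie in (0, 1]")
    n = len(bundle.manifest)
    n_labeled = max(1, int(round(labeled_fraction * n)))
    train_idx = bundle.manifest.index[bundle.manifest["split"] != "test"].to_numpy()
    if n_labeled > len(train_idx):
        n_labeled = len(train_idx)
    rng = np.random.default_rng(seed)
    chosen = set(rng.choice(train_idx, size=n_labeled, replace=False).tolist())
    manifest = bundle.manifest.copy()
    for i in train_idx:
        manifest.loc[i, "split"] = "labeled" if i in chosen else "unlabeled"
        manifest.loc[i, "mask_path"] = f"masks/{i:05d}.png" if i in chosen else ""
    return replace(bundle, manifest=manifest)
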