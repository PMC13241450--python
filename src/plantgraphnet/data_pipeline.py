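"""Patch dataset handling: directory loading, stratified splitting and
training-time augmentation.

The on-disk layout is one subdirectory per class containing PNG/JPEG patches.
Classes are ordered alphabetically, giving dense, deterministic class
indices. The default split is 60/20/20 train/validation/test, stratified per
class with largest-remainder rounding, and augmentation (random rotation,
horizontal/vertical flips, zoom) is applied on the fly to training images
only, after splitting, so no augmented copy of a test image can leak into
training.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from skimage.transform import rescale, rotate

logger = logging.getLogger(__name__)

__all__ = [
    "PatchDataset",
    "SplitSpec",
    "load_patch_dataset",
    "split_dataset",
    "augment",
]

_IMAGE_SUFFIXES = (".png", ".jpg", ".jpeg")


@dataclass
class PatchDataset:
    """File-backed patch collection with dense class indices."""

    samples: list[tuple[Path, int]]
    class_names: list[str]
    patch_size: int = 150

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def labels(self) -> np.ndarray:
        return np.array([label for _, label in self.samples], dtype=np.int64)

    def load_image(self, index: int) -> np.ndarray:
        """Read one patch as an H x W x 3 uint8 array, resizing if needed."""
        path, _ = self.samples[index]
        with Image.open(path) as im:
            arr = np.asarray(im.convert("RGB"))
        if arr.shape[:2] != (self.patch_size, self.patch_size):
            logger.warning(
                "patch %s has size %s, resizing to %d x %d",
                path.name,
                arr.shape[:2],
                self.patch_size,
                self.patch_size,
            )
            with Image.open(path) as im:
                arr = np.asarray(
                    im.convert("RGB").resize((self.patch_size, self.patch_size), Image.BILINEAR)
                )
        return arr


@dataclass
class SplitSpec:
    """Train/validation/test fractions plus stratification and seed."""

    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        self.fractions = tuple(float(f) for f in self.fractions)
        if len(self.fractions) != 3 or any(f <= 0 for f in self.fractions):
            raise ValueError("three positive split fractions are required")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


def load_patch_dataset(root, patch_size: int = 150) -> PatchDataset:
    """Scan ``root`` (one subdirectory per class) into a PatchDataset."""
    root = Path(root)
    if not root.is_dir():
        raise ValueError(f"dataset root {root} is not a directory")
    class_dirs = sorted(p for p in root.iterdir() if p.is_dir())
    if not class_dirs:
        raise ValueError(f"dataset root {root} contains no class directories")
    samples: list[tuple[Path, int]] = []
    class_names = []
    for index, cdir in enumerate(class_dirs):
        class_names.append(cdir.name)
        files = sorted(
            p for p in cdir.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES
        )
        if not files:
            logger.warning("class directory %s contains no images", cdir.name)
        samples.extend((p, index) for p in files)
    return PatchDataset(samples=samples, class_names=class_names, patch_size=patch_size)


def _largest_remainder(n: int, fractions: tuple[float, ...]) -> list[int]:
    """Split ``n`` items into integer quotas honouring ``fractions``."""
    quotas = [n * f for f in fractions]
    counts = [int(np.floor(q)) for q in quotas]
    remainders = [q - c for q, c in zip(quotas, counts)]
    short = n - sum(counts)
    for i in sorted(range(len(fractions)), key=lambda i: -remainders[i])[:short]:
        counts[i] += 1
    return counts


def split_dataset(dataset: PatchDataset, spec: SplitSpec):
    """Disjoint, covering train/val/test index arrays.

    Stratified mode shuffles each class independently and applies
    largest-remainder rounding to its size, so per-class proportions track
    the requested fractions to within one sample.
    """
    n = len(dataset)
    if n == 0:
        raise ValueError("cannot split an empty dataset")
    rng = np.random.default_rng(spec.seed)
    groups: list[np.ndarray]
    if spec.stratified:
        labels = dataset.labels
        groups = [np.flatnonzero(labels == c) for c in range(len(dataset.class_names))]
    else:
        groups = [np.arange(n)]
    parts: list[list[np.ndarray]] = [[], [], []]
    for group in groups:
        if group.size == 0:
            continue
        perm = group[rng.permutation(group.size)]
        counts = _largest_remainder(group.size, spec.fractions)
        start = 0
        for slot, count in enumerate(counts):
            parts[slot].append(perm[start : start + count])
            start += count
    train, val, test = (
        np.sort(np.concatenate(p)) if p else np.array([], dtype=np.int64) for p in parts
    )
    if min(train.size, val.size, test.size) == 0:
        raise ValueError("a split is empty; dataset too small for the requested fractions")
    return train, val, test


def augment(image: np.ndarray, seed: int, training: bool = True) -> np.ndarray:
    """Random rotation (±30°), horizontal/vertical flips (p = 0.5 each) and
    zoom (factor 0.8–1.2), preserving image size; identity when not training.

    Deterministic for a fixed seed: the same seed reproduces the same
    augmented image bit for bit.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an H x W x 3 RGB image")
    if not training:
        return image.copy()
    rng = np.random.default_rng(seed)
    h, w = image.shape[:2]
    out = image.astype(np.float64) / 255.0
    angle = rng.uniform(-30.0, 30.0)
    out = rotate(out, angle, mode="reflect", preserve_range=True)
    if rng.random() < 0.5:
        out = out[:, ::-1]
    if rng.random() < 0.5:
        out = out[::-1, :]
    zoom = rng.uniform(0.8, 1.2)
    scaled = rescale(out, zoom, channel_axis=2, mode="reflect", anti_aliasing=zoom < 1.0)
    sh, sw = scaled.shape[:2]
    if sh >= h and sw >= w:  # zoom in: centre crop back
        top, left = (sh - h) // 2, (sw - w) // 2
        out = scaled[top : top + h, left : left + w]
    else:  # zoom out: reflect-pad back
        pad_h, pad_w = h - sh, w - sw
        out = np.pad(
            scaled,
            ((pad_h // 2, pad_h - pad_h // 2), (pad_w // 2, pad_w - pad_w // 2), (0, 0)),
            mode="reflect",
        )
    return np.clip(np.round(out * 255.0), 0, 255).astype(np.uint8)
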