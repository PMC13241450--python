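"""Procedural, class-separable vegetation-like patches.

Real heathland patch corpora are not redistributable, so the test and
benchmark data are generated: each class renders Poisson-placed high-contrast
blobs (keypoint attractors — the *structural* signal read by the graph
branch) over a coloured, sinusoidally textured background (the *appearance*
signal read by the image branch), plus pixel noise. The default class
parameters deliberately include pairs that differ only in structure and
pairs that differ only in appearance, so the graph-only and image-only
variants have distinct failure modes and the gain from fusing the two
branches is testable rather than assumed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .data_pipeline import PatchDataset, load_patch_dataset

__all__ = [
    "ClassParams",
    "SyntheticSpec",
    "default_class_params",
    "generate_class_image",
    "generate_dataset_arrays",
    "generate_synthetic_dataset",
]

# grayscale weights of the luminance the keypoint detector operates on
_GRAY_W = (0.2125, 0.7154, 0.0721)


def _isoluminant(reference: tuple[int, int, int], r: int, b: int) -> tuple[int, int, int]:
    """Solve the green channel so (r, g, b) has the reference's luminance."""
    target = sum(w * c for w, c in zip(_GRAY_W, reference))
    g = (target - _GRAY_W[0] * r - _GRAY_W[2] * b) / _GRAY_W[1]
    return (r, int(round(g)), b)


# vegetation-like base colours with matched luminance: appearance differences
# live in chroma only, so the grey-level keypoint detector cannot see them
_GREEN = (70, 110, 60)
_PALETTE = (_GREEN, _isoluminant(_GREEN, 150, 60))


@dataclass
class ClassParams:
    blob_density: float  # expected blob (keypoint attractor) count per patch
    blob_scale: float  # blob radius, pixels
    base_colour: tuple[int, int, int]
    texture_freq: float  # sinusoidal stripes per image


@dataclass
class SyntheticSpec:
    num_classes: int = 3
    samples_per_class: int = 30
    image_size: int = 150
    seed: int = 0
    class_params: list[ClassParams] | None = None

    def __post_init__(self) -> None:
        if self.num_classes < 2:
            raise ValueError("at least two classes are required")
        if self.class_params is None:
            self.class_params = default_class_params(self.num_classes)
        if len(self.class_params) != self.num_classes:
            raise ValueError("one ClassParams entry per class is required")
        seen = set()
        for p in self.class_params:
            if p.blob_density <= 0:
                raise ValueError("blob densities must be positive")
            key = (p.blob_density, p.base_colour)
            if key in seen:
                raise ValueError("classes must differ in (blob_density, base_colour)")
            seen.add(key)


def default_class_params(num_classes: int) -> list[ClassParams]:
    """Structure/appearance grid: colour alternates with class parity while
    density steps up every two classes, so consecutive classes share density
    (appearance-only contrast) and alternate classes share colour
    (structure-only contrast)."""
    params = []
    for i in range(num_classes):
        params.append(
            ClassParams(
                blob_density=8.0 + 16.0 * (i // 2),
                blob_scale=4.0,
                base_colour=_PALETTE[i % 2],
                texture_freq=3.0 + 2.0 * (i % 2),
            )
        )
    return params


def generate_class_image(spec: SyntheticSpec, class_index: int, instance_seed: int) -> np.ndarray:
    """Render one patch; deterministic per (spec.seed, class_index, instance_seed)."""
    if not 0 <= class_index < spec.num_classes:
        raise ValueError(f"class_index {class_index} out of range")
    params = spec.class_params[class_index]
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, class_index, instance_seed]))
    s = spec.image_size
    yy, xx = np.mgrid[0:s, 0:s].astype(np.float64)
    img = np.tile(np.array(params.base_colour, dtype=np.float64), (s, s, 1))
    # appearance signal: isoluminant chroma texture — the red/blue modulations
    # cancel in the grayscale projection, so keypoint detection cannot use it
    phase = rng.uniform(0, 2 * np.pi)
    tex = np.sin(2 * np.pi * params.texture_freq * xx / s + phase)
    img[:, :, 0] += 8.0 * tex
    img[:, :, 2] -= 8.0 * (_GRAY_W[0] / _GRAY_W[2]) * tex
    # structural signal: zero-integral centre-surround luminance blobs — strong
    # local contrast for the keypoint detector, no global-statistics footprint
    n_blobs = int(rng.poisson(params.blob_density))
    margin = max(3, int(params.blob_scale))
    sigma = params.blob_scale
    for _ in range(n_blobs):
        cy = rng.uniform(margin, s - margin)
        cx = rng.uniform(margin, s - margin)
        amp = rng.uniform(60.0, 90.0)
        r2 = (yy - cy) ** 2 + (xx - cx) ** 2
        bump = amp * (np.exp(-r2 / (2.0 * sigma**2)) - 0.25 * np.exp(-r2 / (8.0 * sigma**2)))
        img += bump[:, :, None]
    img += rng.normal(0.0, 5.0, size=img.shape)
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def generate_dataset_arrays(spec: SyntheticSpec):
    """All patches in memory: (images list, labels array), balanced classes."""
    images, labels = [], []
    for c in range(spec.num_classes):
        for j in range(spec.samples_per_class):
            images.append(generate_class_image(spec, c, j))
            labels.append(c)
    return images, np.array(labels, dtype=np.int64)


def generate_synthetic_dataset(spec: SyntheticSpec, output_dir) -> PatchDataset:
    """Write the patches to ``output_dir`` in the class-directory layout.

    Produces ``class_<i>/img_<j>.png`` plus a ``manifest.csv`` recording the
    per-image seeds; regeneration with the same spec is byte-identical.
    """
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for c in range(spec.num_classes):
        cdir = output_dir / f"class_{c:02d}"
        cdir.mkdir(exist_ok=True)
        for j in range(spec.samples_per_class):
            img = generate_class_image(spec, c, j)
            path = cdir / f"img_{j:04d}.png"
            Image.fromarray(img).save(path)
            rows.append((str(path.relative_to(output_dir)), c, spec.seed, j))
    with (output_dir / "manifest.csv").open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["path", "class", "dataset_seed", "instance_seed"])
        writer.writerows(rows)
    return load_patch_dataset(output_dir, patch_size=spec.image_size)
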