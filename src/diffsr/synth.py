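"""Anatomy-like phantom generation and the resolution-degradation pipeline.

The framework is exercised end-to-end on synthetic phantoms: piecewise-smooth
images built from overlapping ellipses at tissue-like intensity plateaus,
with slightly blurred boundaries and a low-frequency intra-structure texture.
These reproduce the statistical features the super-resolution task actually
depends on — sharp edges between smooth regions, a bounded intensity range,
and optional additive Gaussian noise — without attempting MR physics (no
k-space sampling, no bias field, no Rician noise floor).

The degradation pipeline mirrors the acquisition protocol being emulated:
high-resolution 256x256 targets are anti-alias down-sampled to 86x128
(a ~6x pixel-count reduction, anisotropic because the phase-encoding
direction is degraded more), and under-sized sources can be zero-padded onto
the working grid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.transform import resize

from .image import ImageGrid

__all__ = ["PhantomSpec", "make_phantom", "degrade", "zero_pad", "make_dataset"]

HR_SHAPE = (256, 256)
LR_SHAPE = (86, 128)


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for one synthetic phantom; deterministic given ``seed``."""

    shape: tuple[int, int] = HR_SHAPE
    n_structures: int = 6
    intensity_levels: tuple[float, ...] = (60.0, 110.0, 160.0, 210.0)
    background: float = 20.0
    edge_sharpness: float = 1.0  # Gaussian blur std (px) applied at boundaries
    texture_amp: float = 8.0  # amplitude of smooth intra-structure texture
    noise_std: float = 0.0  # additive Gaussian noise, storage units
    value_range: tuple[float, float] = (0.0, 255.0)
    seed: int = 0


def make_phantom(spec: PhantomSpec) -> ImageGrid:
    """Render a piecewise-smooth ellipse phantom from its spec.

    Structures are painted back-to-front (later ellipses overwrite earlier
    ones), edges are softened by a small blur, a smooth texture field is
    added inside structures, and optional i.i.d. Gaussian noise is applied
    last.  The composite is clipped to the storage range.
    """
    h, w = spec.shape
    if h < 4 or w < 4:
        raise ValueError(f"degenerate phantom shape {spec.shape}")
    rng = np.random.default_rng(spec.seed)
    img = np.full((h, w), spec.background)
    yy, xx = np.mgrid[0:h, 0:w]
    mask_any = np.zeros((h, w), dtype=bool)
    for _ in range(spec.n_structures):
        cy = rng.uniform(0.2 * h, 0.8 * h)
        cx = rng.uniform(0.2 * w, 0.8 * w)
        ry = rng.uniform(0.08, 0.3) * h
        rx = rng.uniform(0.08, 0.3) * w
        theta = rng.uniform(0, np.pi)
        level = float(rng.choice(spec.intensity_levels))
        dy, dx = yy - cy, xx - cx
        u = dy * np.cos(theta) + dx * np.sin(theta)
        v = -dy * np.sin(theta) + dx * np.cos(theta)
        mask = (u / ry) ** 2 + (v / rx) ** 2 <= 1.0
        img[mask] = level
        mask_any |= mask
    if spec.edge_sharpness > 0:
        img = gaussian_filter(img, spec.edge_sharpness, mode="nearest")
    if spec.texture_amp > 0 and mask_any.any():
        texture = gaussian_filter(rng.standard_normal((h, w)), min(h, w) / 24.0)
        std = texture.std()
        if std > 0:
            img = img + spec.texture_amp * (texture / std) * mask_any
    if spec.noise_std > 0:
        img = img + rng.normal(0.0, spec.noise_std, size=(h, w))
    lo, hi = spec.value_range
    return ImageGrid(np.clip(img, lo, hi), value_range=spec.value_range)


def degrade(hr: ImageGrid, target_shape: tuple[int, int] = LR_SHAPE, method: str = "bicubic") -> ImageGrid:
    """Anti-aliased down-sampling of a high-resolution image.

    ``method`` selects the interpolation kernel: ``bicubic`` (default,
    matching the interpolation family used for the upsampling baseline),
    ``bilinear`` or ``nearest``.
    """
    h, w = hr.shape
    th, tw = target_shape
    if th >= h or tw >= w:
        raise ValueError(f"target {target_shape} not smaller than source {hr.shape}")
    order = {"bicubic": 3, "bilinear": 1, "nearest": 0}.get(method)
    if order is None:
        raise ValueError(f"unknown down-sampling method {method!r}")
    px = resize(
        hr.pixels,
        target_shape,
        order=order,
        mode="edge",
        anti_aliasing=(order > 0),
    )
    return hr.with_pixels(px)


def zero_pad(img: ImageGrid, target_shape: tuple[int, int]) -> ImageGrid:
    """Center the image in a zero background of ``target_shape``.

    When a margin is odd the extra pixel goes to the bottom/right (floor
    offsets), so padding is invertible from the recorded shapes alone.
    """
    h, w = img.shape
    th, tw = target_shape
    if th < h or tw < w:
        raise ValueError(f"target {target_shape} smaller than image {img.shape}")
    top, left = (th - h) // 2, (tw - w) // 2
    out = np.zeros(target_shape)
    out[top : top + h, left : left + w] = img.pixels
    return img.with_pixels(out)


def make_dataset(
    n_train: int,
    n_test: int,
    spec_template: PhantomSpec = PhantomSpec(),
    *,
    lr_shape: tuple[int, int] = LR_SHAPE,
    degrade_method: str = "bicubic",
    seed: int = 0,
    out_dir=None,
):
    """Generate a disjoint train/test set of (LR, HR) phantom pairs.

    Each phantom gets its own child seed drawn from the master ``seed``, so
    the whole dataset is reproducible.  Returns
    ``(train_pairs, test_pairs, manifest)`` where pairs are
    ``(lr: ImageGrid, hr: ImageGrid)``.  When ``out_dir`` is given, images
    are also written as PNGs with a JSON manifest (ids, seeds, split).
    """
    if n_train < 1 or n_test < 1:
        raise ValueError("n_train and n_test must both be >= 1")
    master = np.random.default_rng(seed)
    child_seeds = master.integers(0, 2**31 - 1, size=n_train + n_test)
    splits = ["train"] * n_train + ["test"] * n_test

    pairs = {"train": [], "test": []}
    manifest = {"seed": seed, "lr_shape": list(lr_shape), "degrade": degrade_method, "items": []}
    writer = None
    if out_dir is not None:
        from .io import write_image  # local import: io also imports nothing from here

        out_dir = Path(out_dir)
        (out_dir / "hr").mkdir(parents=True, exist_ok=True)
        (out_dir / "lr").mkdir(parents=True, exist_ok=True)
        writer = write_image

    for i, (child, split) in enumerate(zip(child_seeds, splits)):
        image_id = f"{split}_{i:04d}"
        hr = make_phantom(replace(spec_template, seed=int(child)))
        lr = degrade(hr, lr_shape, method=degrade_method)
        pairs[split].append((lr, hr))
        item = {"id": image_id, "seed": int(child), "split": split}
        if writer is not None:
            hr_path = out_dir / "hr" / f"{image_id}.png"
            lr_path = out_dir / "lr" / f"{image_id}.png"
            writer(hr, hr_path)
            writer(lr, lr_path)
            item["hr"] = str(hr_path.relative_to(out_dir))
            item["lr"] = str(lr_path.relative_to(out_dir))
        manifest["items"].append(item)

    if out_dir is not None:
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
    return pairs["train"], pairs["test"], manifest
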