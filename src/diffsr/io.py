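"""Image readers/writers (PNG and NIfTI) and the run configuration.

Conventions pinned here so every module agrees:

* arrays are row-major, 0-based, indexed ``(row, column) = (y, x)``;
* NIfTI volumes are processed slice-wise along the third axis;
* PNGs are written clip-then-round at the declared bit depth;
* a run configuration is a flat YAML document with explicit keys — unknown
  keys are rejected rather than silently ignored, because a typo in a
  hyper-parameter name must fail loudly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import yaml

from .image import ImageGrid

__all__ = ["read_image", "write_image", "RunConfig"]

logger = logging.getLogger("diffsr")


def read_image(path, *, slice_index: "int | None" = None, to_gray: bool = False) -> ImageGrid:
    """Read a grayscale image from PNG (8/16-bit) or NIfTI.

    NIfTI volumes require ``slice_index`` (third axis); 2-D NIfTI files do
    not.  RGB PNGs are rejected unless ``to_gray`` requests a luminance
    conversion.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image file: {path}")
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        vol = np.asanyarray(nib.load(path).dataobj).astype(np.float64)
        if vol.ndim == 2:
            data = vol
        elif vol.ndim == 3:
            if slice_index is None:
                raise ValueError(
                    f"{path} is a {vol.shape} volume; a slice index is required"
                )
            if not 0 <= slice_index < vol.shape[2]:
                raise IndexError(
                    f"slice {slice_index} out of range for {vol.shape[2]} slices"
                )
            data = vol[:, :, slice_index]
        else:
            raise ValueError(f"unsupported NIfTI dimensionality {vol.ndim}")
        vmax = float(data.max())
        rng_hi = max(vmax, 1.0)
        return ImageGrid(data, value_range=(0.0, rng_hi))
    if name.endswith(".png"):
        data = iio.imread(path)
        if data.ndim == 3:
            if not to_gray:
                raise ValueError(f"{path} is RGB; pass to_gray=True to convert")
            data = data[..., :3].mean(axis=2)
        peak = 65535.0 if data.dtype == np.uint16 else 255.0
        return ImageGrid(data.astype(np.float64), value_range=(0.0, peak))
    raise ValueError(f"unknown image format: {path}")


def write_image(img: ImageGrid, path, *, bit_depth: int = 8) -> None:
    """Write an image as PNG (clip-then-round quantization) or NIfTI slice."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = img.to_storage()
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        nib.save(nib.Nifti1Image(img.pixels, affine=np.eye(4)), path)
        return
    if not name.endswith(".png"):
        raise ValueError(f"unknown image format: {path}")
    if bit_depth == 8:
        peak, dtype = 255.0, np.uint8
    elif bit_depth == 16:
        peak, dtype = 65535.0, np.uint16
    else:
        raise ValueError(f"bit_depth must be 8 or 16, got {bit_depth}")
    lo, hi = img.value_range
    scaled = (img.pixels - lo) / (hi - lo) * peak
    if scaled.min() < -0.5 or scaled.max() > peak + 0.5:
        logger.warning("out-of-range intensities in %s clipped on write", path)
    iio.imwrite(path, np.clip(np.round(scaled), 0, peak).astype(dtype))


_RUNCONFIG_DEFAULTS = dict(
    # schedule
    timesteps=5000,
    schedule_kind="linear-beta",
    gamma_start=1.0 - 1e-4,
    gamma_end=5e-3,
    # denoiser
    base_channels=64,
    depth_multipliers=[1, 2, 4, 8, 16],
    hr_shape=[256, 256],
    lr_shape=[86, 128],
    # training
    epochs=10,
    batch_size=16,
    learning_rate=1e-4,
    # gate
    patch_size=7,
    stride=3,
    max_attempts=10,
    # bookkeeping
    seed=0,
    out_dir="runs/default",
)


@dataclass
class RunConfig:
    """Flat, explicitly-typed run configuration with YAML round-tripping."""

    values: dict = field(default_factory=lambda: dict(_RUNCONFIG_DEFAULTS))

    def __getattr__(self, key):
        values = object.__getattribute__(self, "values")
        if key in values:
            return values[key]
        raise AttributeError(key)

    @classmethod
    def from_dict(cls, overrides: dict) -> "RunConfig":
        unknown = set(overrides) - set(_RUNCONFIG_DEFAULTS)
        if unknown:
            raise KeyError(
                f"unknown config keys {sorted(unknown)}; valid keys: "
                f"{sorted(_RUNCONFIG_DEFAULTS)}"
            )
        return cls(values={**_RUNCONFIG_DEFAULTS, **overrides})

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config {path} is not a mapping")
        return cls.from_dict(data)

    def save(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            yaml.safe_dump(self.values, fh, sort_keys=True)
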