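"""2-D grayscale image container shared by every stage of the pipeline.

Images live on one of two intensity scales:

* **storage scale** — the interval the pixels occupy on disk, e.g. ``[0, 255]``
  for 8-bit PNG.  Noise estimation and all quality metrics operate here.
* **model scale** — the symmetric interval ``[-1, 1]`` the diffusion model
  works on, so that the standard-normal noise it adds and predicts is on unit
  scale.

``ImageGrid`` records which scale its pixels are on and converts between the
two; conversion back to storage scale clips, because a generative sampler can
momentarily step outside the representable range.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["ImageGrid"]


@dataclass(frozen=True)
class ImageGrid:
    """A 2-D real-valued grayscale image with an explicit intensity range.

    Parameters
    ----------
    pixels
        ``(height, width)`` float array.  Always copied defensively on
        construction? No — treated as immutable by convention; callers must
        not mutate it in place.
    value_range
        The storage-scale intensity interval ``(low, high)``.
    model_scale
        ``True`` when ``pixels`` are on the model's ``[-1, 1]`` interval.
    """

    pixels: np.ndarray
    value_range: tuple[float, float] = (0.0, 255.0)
    model_scale: bool = False

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2:
            raise ValueError(f"expected a 2-D image, got shape {px.shape}")
        if not np.all(np.isfinite(px)):
            raise ValueError("image contains non-finite pixel values")
        lo, hi = self.value_range
        if not hi > lo:
            raise ValueError(f"degenerate value_range {self.value_range}")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def to_model(self) -> "ImageGrid":
        """Map storage-scale intensities affinely onto ``[-1, 1]``."""
        if self.model_scale:
            return self
        lo, hi = self.value_range
        px = 2.0 * (self.pixels - lo) / (hi - lo) - 1.0
        return replace(self, pixels=px, model_scale=True)

    def to_storage(self, clip: bool = True) -> "ImageGrid":
        """Map model-scale intensities back to storage scale.

        Values outside ``[-1, 1]`` are clipped by default: bounded storage
        formats cannot represent them and the sampler can overshoot.
        """
        if not self.model_scale:
            return self
        lo, hi = self.value_range
        px = (self.pixels + 1.0) * (hi - lo) / 2.0 + lo
        if clip:
            px = np.clip(px, lo, hi)
        return replace(self, pixels=px, model_scale=False)

    def with_pixels(self, pixels: np.ndarray) -> "ImageGrid":
        """Same scale/range metadata, new pixel array."""
        return replace(self, pixels=pixels)
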