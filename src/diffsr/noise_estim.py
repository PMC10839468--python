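"""Single-image noise-level estimation from patch-covariance eigenvalues.

The estimated noise level (ENL) of an image is obtained by sliding a small
window (7x7 by default) over the image, forming the covariance matrix of the
flattened patches, and taking its minimum eigenvalue: for an image that is
locally low-rank plus i.i.d. additive noise of variance ``sigma^2``, every
eigenvalue of the patch covariance is inflated by ``sigma^2``, and the
smallest one — the direction the clean signal does not occupy — estimates it.

    sigma^2 = lambda_min( Sigma_y ),
    Sigma_y = (1/M) sum_i z_i z_i^T     (z_i mean-centered patch vectors)

Patches are mean-centered before the outer-product average.  The raw second
moment would fold the mean patch (overall brightness and large-scale
structure) into every eigenvalue; centering leaves the noise floor unchanged
while making the estimator exactly zero on constant images.

The estimate carries a known slight negative bias (the smallest sample
eigenvalue of a noise covariance sits below ``sigma^2`` at finite patch
count, the Marchenko–Pastur edge effect) and a positive bias on images so
textured that no patch direction is signal-free.  Both matter when comparing
two images, which is why the acceptance gate always compares ENLs computed
with identical patch parameters on the same grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
from numpy.lib.stride_tricks import sliding_window_view

from .image import ImageGrid

__all__ = ["PatchSet", "EnlReport", "extract_patches", "patch_covariance", "estimate_noise"]

DEFAULT_PATCH_SIZE = 7
DEFAULT_STRIDE = 3


@dataclass(frozen=True)
class PatchSet:
    """Flattened image patches as columns of a ``(p*p, M)`` matrix."""

    patches: np.ndarray
    patch_size: int
    stride: int

    @property
    def M(self) -> int:
        return self.patches.shape[1]


@dataclass(frozen=True)
class EnlReport:
    """Estimated noise level of one image, with the parameters used."""

    sigma: float
    sigma2: float
    patch_size: int
    stride: int
    M: int


def extract_patches(
    img: ImageGrid,
    patch_size: int = DEFAULT_PATCH_SIZE,
    stride: int = 1,
    *,
    min_patches: "int | None" = None,
) -> PatchSet:
    """All fully-contained ``patch_size``-square patches on the stride grid.

    Patches are flattened row-major into columns.  Raises if the image is
    smaller than the patch, or — when ``min_patches`` is given — if the
    stride leaves fewer patches than required (the noise estimator needs at
    least ``p^2`` so the covariance can be full rank).
    """
    if stride < 1:
        raise ValueError(f"stride must be >= 1, got {stride}")
    h, w = img.shape
    p = patch_size
    if h < p or w < p:
        raise ValueError(f"image {h}x{w} smaller than patch size {p}")
    windows = sliding_window_view(img.pixels, (p, p))[::stride, ::stride]
    m = windows.shape[0] * windows.shape[1]
    if min_patches is not None and m < min_patches:
        raise ValueError(
            f"only {m} patches < required {min_patches}; use a smaller stride"
        )
    cols = windows.reshape(m, p * p).T
    return PatchSet(patches=np.ascontiguousarray(cols), patch_size=p, stride=stride)


def patch_covariance(patches: PatchSet) -> np.ndarray:
    """Mean outer product of the mean-centered patch vectors.

    Returns a symmetric PSD ``(p^2, p^2)`` matrix (symmetrized against
    floating-point asymmetry).
    """
    z = patches.patches
    zc = z - z.mean(axis=1, keepdims=True)
    sigma = (zc @ zc.T) / patches.M
    return 0.5 * (sigma + sigma.T)


def estimate_noise(
    img: ImageGrid,
    patch_size: int = DEFAULT_PATCH_SIZE,
    stride: int = DEFAULT_STRIDE,
) -> EnlReport:
    """ENL of a single image: ``sigma = sqrt(lambda_min(Sigma_y))``.

    ``lambda_min`` is computed with a symmetric eigensolver and clamped at
    zero against negative round-off.  Estimation is intended to run on the
    storage intensity scale, and ``sigma`` is reported in those units.
    """
    ps = extract_patches(
        img, patch_size=patch_size, stride=stride, min_patches=patch_size**2
    )
    sigma_y = patch_covariance(ps)
    # smallest eigenvalue only, via the subset symmetric solver
    lam_min = float(scipy.linalg.eigh(sigma_y, eigvals_only=True, subset_by_index=[0, 0])[0])
    if lam_min < 0.0:
        lam_min = 0.0
    return EnlReport(
        sigma=float(np.sqrt(lam_min)),
        sigma2=lam_min,
        patch_size=patch_size,
        stride=ps.stride,
        M=ps.M,
    )
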