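"""Reverse ancestral sampling and the noise-level acceptance gate.

A super-resolved image is generated by starting from pure Gaussian noise
``y_T`` and walking the learned reverse chain down to ``y_0``, conditioning
every step on the bicubic-upsampled low-resolution input.  Each step applies

    y_{t-1} = sqrt(1 - alpha_t) * eps_t
              + (1/sqrt(alpha_t)) * [ y_t - (1 - alpha_t)/sqrt(1 - gamma_t)
                                            * f_theta(x_up, y_t, gamma_t) ]

with a fresh standard-normal draw ``eps_t`` for every step except the last,
where ``eps_t = 0`` so the final step is deterministic.

Because the chain is stochastic, individual outputs vary; two quality-control
strategies are provided.  ``average_samples`` reduces noise by averaging
independent runs.  ``gated_sample`` implements the acceptance rule: the
estimated noise level (ENL) of a synthetic image must not exceed that of the
input — candidates are regenerated until one passes, so accepted outputs
never add noise relative to what the scanner actually recorded.  Both ENLs
are computed on the storage intensity scale on the common high-resolution
grid (the input is upsampled first), making the comparison scale- and
resolution-consistent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from .image import ImageGrid
from .noise_estim import DEFAULT_PATCH_SIZE, DEFAULT_STRIDE, estimate_noise
from .schedule import NoiseSchedule

__all__ = [
    "SRResult",
    "upsample_condition",
    "reverse_step",
    "sample_sr",
    "gated_sample",
    "average_samples",
]

logger = logging.getLogger("diffsr")


@dataclass(frozen=True)
class SRResult:
    """Outcome of a gated inference run.

    ``enl_history`` holds one estimated noise level per full reverse chain
    attempted; ``accepted`` is False only when ``max_attempts`` chains all
    exceeded the input's noise level, in which case ``image`` is the
    lowest-ENL candidate seen.
    """

    image: ImageGrid
    attempts: int
    enl_history: tuple[float, ...]
    accepted: bool
    sigma_x: float
    seed_state: dict


def upsample_condition(lr: ImageGrid, target_shape: tuple[int, int]) -> ImageGrid:
    """Bicubic interpolation of the low-resolution image to the HR grid."""
    h, w = lr.shape
    th, tw = target_shape
    if th < h or tw < w:
        raise ValueError(f"target {target_shape} smaller than input {lr.shape}")
    if (th, tw) == (h, w):
        return lr
    px = resize(lr.pixels, target_shape, order=3, mode="edge", anti_aliasing=False)
    return lr.with_pixels(px)


def reverse_step(
    denoiser,
    x_up: ImageGrid,
    yt: ImageGrid,
    t: int,
    schedule: NoiseSchedule,
    rng: np.random.Generator,
    *,
    eps_t: "np.ndarray | None" = None,
) -> ImageGrid:
    """One ancestral denoising step y_t -> y_{t-1} (model scale).

    Noise is injected for ``t > 1``; the final step (``t = 1``) is
    deterministic.  ``eps_t`` may be forced for tests.
    """
    schedule._check_t(t)
    a_t = schedule.alpha_at(t)
    g_t = schedule.gamma_at(t)
    eps_hat = denoiser.predict(x_up, yt, g_t)
    if not np.all(np.isfinite(eps_hat.pixels)):
        raise FloatingPointError(f"non-finite denoiser output at t={t}")
    mu = (yt.pixels - (1.0 - a_t) / np.sqrt(1.0 - g_t) * eps_hat.pixels) / np.sqrt(a_t)
    if t > 1:
        if eps_t is None:
            eps_t = rng.standard_normal(yt.shape)
        prev = np.sqrt(1.0 - a_t) * eps_t + mu
    else:
        prev = mu
    return yt.with_pixels(prev)


def sample_sr(
    denoiser,
    lr: ImageGrid,
    schedule: NoiseSchedule,
    rng: np.random.Generator,
    *,
    target_shape: "tuple[int, int] | None" = None,
) -> ImageGrid:
    """One full reverse chain: Gaussian noise -> super-resolved image.

    Returns the result on the storage scale (clipped).  Deterministic given
    the rng state; distinct rng states give distinct samples.
    """
    if target_shape is None:
        target_shape = getattr(denoiser.config, "image_shape", None)
        if target_shape is None:
            raise ValueError(
                "target_shape not given and denoiser config carries no image_shape"
            )
    x_up = upsample_condition(lr, target_shape).to_model()
    yt = x_up.with_pixels(rng.standard_normal(target_shape))
    for t in range(schedule.T, 0, -1):
        yt = reverse_step(denoiser, x_up, yt, t, schedule, rng)
    return yt.to_storage()


def gated_sample(
    denoiser,
    lr: ImageGrid,
    schedule: NoiseSchedule,
    rng: np.random.Generator,
    max_attempts: int = 10,
    *,
    target_shape: "tuple[int, int] | None" = None,
    patch_size: int = DEFAULT_PATCH_SIZE,
    stride: int = DEFAULT_STRIDE,
    sigma_x_grid: str = "upsampled",
    sample_fn=None,
) -> SRResult:
    """ENL-gated inference: regenerate until the sample is no noisier than
    the input.

    The input's noise level ``sigma_x`` is estimated once, by default on the
    bicubic-upsampled storage-scale image so both estimates share a grid
    (``sigma_x_grid="native"`` estimates on the as-acquired low-resolution
    grid instead, which preserves the whiteness of acquisition noise that
    interpolation smooths away — the estimator is resolution-sensitive, so
    the choice is explicit).  Fresh reverse chains are run until a
    candidate's ENL is ``<= sigma_x`` (equality accepted).  If
    ``max_attempts`` chains all fail the test, the lowest-ENL candidate is
    returned with ``accepted=False`` and a warning is logged — the loop must
    terminate even on a model whose samples never pass.

    ``sample_fn(denoiser, lr, schedule, rng)`` may replace the chain sampler
    (used by tests to exercise the gate in isolation).
    """
    if max_attempts < 1:
        raise ValueError(f"max_attempts must be >= 1, got {max_attempts}")
    if sample_fn is None:
        sample_fn = lambda d, l, s, r: sample_sr(d, l, s, r, target_shape=target_shape)
    if target_shape is None:
        target_shape = getattr(denoiser.config, "image_shape", None) or lr.shape
    if sigma_x_grid == "native":
        sigma_src = lr
    elif sigma_x_grid == "upsampled":
        sigma_src = upsample_condition(lr, target_shape)
    else:
        raise ValueError(f"sigma_x_grid must be 'upsampled' or 'native', got {sigma_x_grid!r}")
    sigma_x = estimate_noise(sigma_src, patch_size=patch_size, stride=stride).sigma

    seed_state = rng.bit_generator.state
    history: list[float] = []
    best_img, best_enl = None, np.inf
    for attempt in range(1, max_attempts + 1):
        candidate = sample_fn(denoiser, lr, schedule, rng)
        enl = estimate_noise(candidate, patch_size=patch_size, stride=stride).sigma
        history.append(enl)
        if enl < best_enl:
            best_img, best_enl = candidate, enl
        if enl <= sigma_x:
            return SRResult(
                image=candidate,
                attempts=attempt,
                enl_history=tuple(history),
                accepted=True,
                sigma_x=sigma_x,
                seed_state=seed_state,
            )
    logger.warning(
        "noise gate exhausted %d attempts (best ENL %.4g > sigma_x %.4g); "
        "returning best-so-far candidate",
        max_attempts,
        best_enl,
        sigma_x,
    )
    return SRResult(
        image=best_img,
        attempts=max_attempts,
        enl_history=tuple(history),
        accepted=False,
        sigma_x=sigma_x,
        seed_state=seed_state,
    )


def average_samples(samples) -> ImageGrid:
    """Pixel-wise mean of independently generated samples.

    Averaging S independent runs shrinks the stochastic component of each
    sample by ~1/sqrt(S), the mechanism by which multi-run averaging lowers
    the estimated noise level.
    """
    samples = list(samples)
    if not samples:
        raise ValueError("average_samples requires at least one sample")
    shape = samples[0].shape
    for s in samples[1:]:
        if s.shape != shape:
            raise ValueError(f"shape mismatch: {s.shape} vs {shape}")
    mean = np.mean([s.pixels for s in samples], axis=0)
    return samples[0].with_pixels(mean)
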