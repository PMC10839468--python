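"""Diffusion noise schedule and the forward Gaussian noising process.

The forward process is a Markov chain that mixes a clean image ``y0`` with
Gaussian noise over ``T`` steps.  Each step retains a fraction ``alpha_t`` in
``(0, 1)`` of the signal; the cumulative signal fraction is
``gamma_t = prod_{i<=t} alpha_i``.  The chain admits a closed-form marginal

    y_t = sqrt(gamma_t) * y0 + sqrt(1 - gamma_t) * eps,   eps ~ N(0, I)

and, given both endpoints ``(y0, y_t)``, a Gaussian posterior over ``y_{t-1}``
whose mean and variance are computed by :func:`posterior_params`.  The
convention ``gamma_0 = 1`` makes the posterior well defined at ``t = 1``
(where it degenerates to a point mass on ``y0``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image import ImageGrid

__all__ = [
    "NoiseSchedule",
    "PosteriorParams",
    "build_schedule",
    "forward_sample",
    "posterior_params",
]


class ScheduleError(ValueError):
    """Raised when schedule construction parameters are invalid."""


@dataclass(frozen=True)
class NoiseSchedule:
    """Per-step retention ``alpha`` and cumulative signal fraction ``gamma``.

    ``alpha[t-1]`` and ``gamma[t-1]`` hold the step-``t`` values (steps are
    1-based as in the sampling recursion); ``gamma0 == 1.0`` by convention.
    """

    T: int
    alpha: np.ndarray
    gamma: np.ndarray
    kind: str = "explicit"
    gamma0: float = 1.0

    def __post_init__(self) -> None:
        a = np.asarray(self.alpha, dtype=np.float64)
        g = np.asarray(self.gamma, dtype=np.float64)
        if self.T < 1:
            raise ScheduleError(f"T must be >= 1, got {self.T}")
        if a.shape != (self.T,) or g.shape != (self.T,):
            raise ScheduleError("alpha/gamma length must equal T")
        bad = np.where((a <= 0.0) | (a >= 1.0))[0]
        if bad.size:
            t = int(bad[0]) + 1
            raise ScheduleError(
                f"alpha_t must lie in (0, 1); offending step t={t}, "
                f"alpha={a[bad[0]]!r}"
            )
        object.__setattr__(self, "alpha", a)
        object.__setattr__(self, "gamma", g)

    def gamma_at(self, t: int) -> float:
        """``gamma_t`` with the ``gamma_0 = 1`` boundary convention."""
        if t == 0:
            return self.gamma0
        self._check_t(t)
        return float(self.gamma[t - 1])

    def alpha_at(self, t: int) -> float:
        self._check_t(t)
        return float(self.alpha[t - 1])

    def _check_t(self, t: int) -> None:
        if not 1 <= t <= self.T:
            raise ValueError(f"timestep t={t} outside [1, {self.T}]")

    def spec(self) -> dict:
        """Serializable description; explicit alphas make it exact."""
        return {"kind": self.kind, "T": self.T, "alpha": self.alpha.tolist()}


@dataclass(frozen=True)
class PosteriorParams:
    """Mean image and scalar variance of ``q(y_{t-1} | y0, y_t)``."""

    mu: np.ndarray
    sigma2: float


def build_schedule(
    T: int = 5000,
    kind: str = "linear-beta",
    *,
    gamma_start: float = 1.0 - 1e-4,
    gamma_end: float = 5e-3,
    beta_start: "float | None" = None,
    beta_end: "float | None" = None,
    alpha: "np.ndarray | list | tuple | None" = None,
) -> NoiseSchedule:
    """Construct a noise schedule.

    Kinds
    -----
    ``"linear-beta"`` (default)
        ``alpha_t = 1 - beta_t`` with ``beta_t`` linear from ``beta_start``
        to ``beta_end``; defaults scale with the chain length
        (``0.1/T`` to ``20/T``), keeping the total noise budget — and hence
        ``gamma_T ~ e^-10`` — the same at any ``T``.  This family has
        ``alpha_t -> 1`` at the clean end of the chain, which the reverse
        sampler's constant per-step variance ``1 - alpha_t`` requires: there
        the true denoising posterior variance shrinks like
        ``1 - gamma_{t-1}``, and a schedule whose ``1 - alpha_t`` stays
        large would inject far more noise than the final steps can remove.
    ``"geometric-gamma"``
        ``gamma_t`` interpolated geometrically from ``gamma_start`` to
        ``gamma_end``, ``alpha_t = gamma_t / gamma_{t-1}`` (constant); kept
        for experimentation, not recommended with the constant-variance
        sampler for the reason above.
    ``"explicit"``
        ``alpha`` given directly.

    The default number of steps is ``T = 5000``; any ``T >= 1`` is accepted
    so scaled-down runs can use short chains.
    """
    if T < 1:
        raise ScheduleError(f"T must be a positive integer, got {T}")
    if beta_start is None:
        beta_start = 0.1 / T
    if beta_end is None:
        beta_end = min(20.0 / T, 0.5)  # capped so very short chains stay valid

    if kind == "explicit":
        if alpha is None:
            raise ScheduleError("kind='explicit' requires alpha")
        a = np.asarray(alpha, dtype=np.float64)
        if a.shape != (T,):
            raise ScheduleError(f"alpha must have length T={T}, got {a.shape}")
    elif kind == "geometric-gamma":
        if not (0.0 < gamma_end < gamma_start < 1.0):
            raise ScheduleError(
                f"need 0 < gamma_end < gamma_start < 1, got "
                f"({gamma_start}, {gamma_end})"
            )
        if T == 1:
            g = np.array([gamma_end])
        else:
            g = np.exp(np.linspace(np.log(gamma_start), np.log(gamma_end), T))
        prev = np.concatenate(([1.0], g[:-1]))
        a = g / prev
    elif kind == "linear-beta":
        beta = np.linspace(beta_start, beta_end, T)
        a = 1.0 - beta
    else:
        raise ScheduleError(f"unknown schedule kind {kind!r}")

    gamma = np.cumprod(a)
    return NoiseSchedule(T=T, alpha=a, gamma=gamma, kind=kind)


def forward_sample(
    y0: ImageGrid,
    t: int,
    schedule: NoiseSchedule,
    rng: np.random.Generator,
    *,
    eps: "np.ndarray | None" = None,
) -> tuple[ImageGrid, np.ndarray]:
    """Draw ``y_t`` from the closed-form forward marginal.

    Returns both the noisy image and the standard-normal field ``eps`` that
    produced it — the latter is the regression target for training the
    denoiser.  ``eps`` may be supplied explicitly for deterministic tests.
    """
    if not y0.model_scale:
        raise ValueError("forward_sample expects y0 on model scale")
    schedule._check_t(t)
    if eps is None:
        eps = rng.standard_normal(y0.shape)
    else:
        eps = np.asarray(eps, dtype=np.float64)
        if eps.shape != y0.shape:
            raise ValueError("eps shape does not match y0")
    g = schedule.gamma_at(t)
    yt = np.sqrt(1.0 - g) * eps + np.sqrt(g) * y0.pixels
    return y0.with_pixels(yt), eps


def posterior_params(
    y0: ImageGrid, yt: ImageGrid, t: int, schedule: NoiseSchedule
) -> PosteriorParams:
    """Mean/variance of the forward-process posterior ``q(y_{t-1}|y0, y_t)``.

    mu     = (1-gamma_t)^-1 [ sqrt(gamma_{t-1}) (1-alpha_t) y0
                              + sqrt(alpha_t) (1-gamma_{t-1}) y_t ]
    sigma2 = (1-gamma_t)^-1 (1-gamma_{t-1}) (1-alpha_t)

    At ``t = 1`` the ``gamma_0 = 1`` convention collapses this to
    ``(y0, 0)`` exactly.
    """
    schedule._check_t(t)
    if y0.shape != yt.shape:
        raise ValueError(f"shape mismatch: y0 {y0.shape} vs yt {yt.shape}")
    a_t = schedule.alpha_at(t)
    g_t = schedule.gamma_at(t)
    g_prev = schedule.gamma_at(t - 1)
    # scalar coefficients first: at t=1 (gamma_0 = 1, gamma_1 = alpha_1) the
    # y0 coefficient is exactly 1 and the posterior collapses to (y0, 0)
    c0 = np.sqrt(g_prev) * (1.0 - a_t) / (1.0 - g_t)
    c1 = np.sqrt(a_t) * (1.0 - g_prev) / (1.0 - g_t)
    mu = c0 * y0.pixels + c1 * yt.pixels
    sigma2 = (1.0 - g_prev) * (1.0 - a_t) / (1.0 - g_t)
    return PosteriorParams(mu=mu, sigma2=float(sigma2))
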