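"""Conditional noise-predicting U-Net and its training loop.

The reverse diffusion process needs a function ``f_theta(x_up, y_t, gamma_t)``
that looks at the bicubic-upsampled low-resolution condition ``x_up`` and the
noisy state ``y_t`` and predicts the standard-normal noise component ``eps``
of ``y_t``.  The architecture is a U-Net: the two inputs are concatenated as
channels, pushed through residual convolution blocks at progressively halved
resolutions (channel widths = ``base_channels`` times the depth multipliers),
then decoded back up with skip connections.  The noise level is injected at
every residual block through a learned embedding of the scalar ``gamma_t``.

Training minimizes the mean-squared error between the predicted and true
noise, the stochastic (uniformly drawn ``t``) version of averaging the
per-step objective over all timesteps.  The squared error is averaged over
pixels and batch so loss magnitudes are size-invariant; a denoiser that
outputs zeros scores ~1.0 (the variance of the standard-normal target).

The network, its backpropagation and the Adam optimizer are implemented
directly on numpy arrays; gradients are verified against finite differences
in the test suite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .image import ImageGrid
from .schedule import NoiseSchedule

__all__ = [
    "DenoiserConfig",
    "Denoiser",
    "TrainState",
    "build_denoiser",
    "training_step",
    "train",
    "save_checkpoint",
    "load_checkpoint",
]


# ---------------------------------------------------------------------------
# parameters and primitive layers
# ---------------------------------------------------------------------------


class Param:
    """A trainable array with its gradient and Adam moment buffers."""

    __slots__ = ("value", "grad", "m", "v")

    def __init__(self, value: np.ndarray, dtype=np.float64):
        self.value = np.asarray(value, dtype=dtype)
        self.grad = np.zeros_like(self.value)
        self.m = np.zeros_like(self.value)
        self.v = np.zeros_like(self.value)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    # tanh form avoids exp overflow in single precision
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def _silu(x: np.ndarray) -> np.ndarray:
    return x * _sigmoid(x)


def _silu_grad(x: np.ndarray) -> np.ndarray:
    s = _sigmoid(x)
    return s * (1.0 + x * (1.0 - s))


class Conv2d:
    """Same-padded k x k convolution on (N, C, H, W) arrays.

    Implemented as a sum of k^2 shifted channel contractions, which maps the
    whole operation onto BLAS matrix products.
    """

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator, zero_init: bool = False, dtype=np.float64):
        fan_in = cin * k * k
        w = rng.standard_normal((cout, cin, k, k)) * np.sqrt(2.0 / fan_in)
        if zero_init:
            w[:] = 0.0
        self.W = Param(w, dtype)
        self.b = Param(np.zeros(cout), dtype)
        self.k = k

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        k, p = self.k, self.k // 2
        n, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        self._xp, self._xshape = xp, x.shape
        cout = self.W.value.shape[0]
        z = np.zeros((n, h, w, cout), dtype=self.W.value.dtype)
        for di in range(k):
            for dj in range(k):
                xs = xp[:, :, di : di + h, dj : dj + w]
                z += np.tensordot(xs, self.W.value[:, :, di, dj], axes=([1], [1]))
        z += self.b.value
        return z.transpose(0, 3, 1, 2)

    def backward(self, g: np.ndarray) -> np.ndarray:
        k, p = self.k, self.k // 2
        n, c, h, w = self._xshape
        gt = np.ascontiguousarray(g.transpose(0, 2, 3, 1))  # N, H, W, Cout
        self.b.grad += gt.sum(axis=(0, 1, 2))
        gxp = np.zeros_like(self._xp)
        for di in range(k):
            for dj in range(k):
                xs = self._xp[:, :, di : di + h, dj : dj + w]
                self.W.grad[:, :, di, dj] += np.tensordot(
                    gt, xs, axes=([0, 1, 2], [0, 2, 3])
                )
                gxp[:, :, di : di + h, dj : dj + w] += np.tensordot(
                    gt, self.W.value[:, :, di, dj], axes=([3], [0])
                ).transpose(0, 3, 1, 2)
        return gxp[:, :, p:-p, p:-p] if p else gxp


class Linear:
    def __init__(self, cin: int, cout: int, rng: np.random.Generator, dtype=np.float64):
        self.W = Param(rng.standard_normal((cin, cout)) * np.sqrt(1.0 / cin), dtype)
        self.b = Param(np.zeros(cout), dtype)

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.W.grad += self._x.T @ g
        self.b.grad += g.sum(axis=0)
        return g @ self.W.value.T


def _avgpool(x: np.ndarray) -> np.ndarray:
    n, c, h, w = x.shape
    return x.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))


def _avgpool_grad(g: np.ndarray) -> np.ndarray:
    n, c, h, w = g.shape
    return np.repeat(np.repeat(g, 2, axis=2), 2, axis=3) * 0.25


def _upsample(x: np.ndarray) -> np.ndarray:
    return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)


def _upsample_grad(g: np.ndarray) -> np.ndarray:
    n, c, h, w = g.shape
    return g.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class ResBlock:
    """conv -> +gamma-embedding bias -> SiLU -> conv, plus a shortcut."""

    def __init__(self, cin: int, cout: int, emb_dim: int, rng: np.random.Generator, dtype=np.float64):
        self.conv1 = Conv2d(cin, cout, 3, rng, dtype=dtype)
        self.emb_proj = Linear(emb_dim, cout, rng, dtype=dtype)
        self.conv2 = Conv2d(cout, cout, 3, rng, dtype=dtype)
        self.short = Conv2d(cin, cout, 1, rng, dtype=dtype) if cin != cout else None

    def params(self):
        ps = self.conv1.params() + self.emb_proj.params() + self.conv2.params()
        if self.short is not None:
            ps += self.short.params()
        return ps

    def forward(self, x: np.ndarray, temb: np.ndarray) -> np.ndarray:
        a = self.conv1.forward(x) + self.emb_proj.forward(temb)[:, :, None, None]
        self._a = a
        h = self.conv2.forward(_silu(a))
        s = x if self.short is None else self.short.forward(x)
        return h + s

    def backward(self, g: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        ga = self.conv2.backward(g) * _silu_grad(self._a)
        gtemb = self.emb_proj.backward(ga.sum(axis=(2, 3)))
        gx = self.conv1.backward(ga)
        gx += g if self.short is None else self.short.backward(g)
        return gx, gtemb


# ---------------------------------------------------------------------------
# the network
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DenoiserConfig:
    """Architecture of the noise-predicting U-Net.

    ``base_channels`` is the first-layer width (64 at full scale);
    ``depth_multipliers`` widen it at each halved resolution (1, 2, 4, 8, 16
    at full scale).  Inputs are 2 channels: the upsampled condition
    concatenated with the noisy image.  ``image_shape`` records the
    high-resolution geometry the model is trained for; each side must be
    divisible by ``2 ** (len(depth_multipliers) - 1)``.
    """

    base_channels: int = 64
    depth_multipliers: tuple[int, ...] = (1, 2, 4, 8, 16)
    emb_dim: int = 32
    input_channels: int = 2
    image_shape: "tuple[int, int] | None" = None

    def __post_init__(self) -> None:
        if not self.depth_multipliers or any(m <= 0 for m in self.depth_multipliers):
            raise ValueError("depth_multipliers must be non-empty and positive")
        if self.image_shape is not None:
            self.check_shape(self.image_shape)

    @property
    def divisor(self) -> int:
        return 2 ** (len(self.depth_multipliers) - 1)

    def check_shape(self, shape: tuple[int, int]) -> None:
        d = self.divisor
        if shape[0] % d or shape[1] % d:
            raise ValueError(
                f"image sides {shape} must be divisible by {d} "
                f"(2^(levels-1) for {len(self.depth_multipliers)} resolution levels)"
            )


def _gamma_features(gamma: np.ndarray, dim: int) -> np.ndarray:
    """Sinusoidal features of log(gamma), gamma in (0, 1)."""
    u = np.log(np.asarray(gamma, dtype=np.float64))
    half = dim // 2
    freqs = np.exp(np.linspace(0.0, np.log(50.0), half))
    ang = u[:, None] * freqs[None, :]
    return np.concatenate([np.sin(ang), np.cos(ang)], axis=1)


class Denoiser:
    """The trainable conditional noise predictor f_theta.

    ``predict`` is deterministic: the same inputs and parameters always give
    the same output.  Use :func:`build_denoiser` to construct one.
    """

    def __init__(self, config: DenoiserConfig, seed: int, dtype=np.float32):
        self.config = config
        self.seed = seed
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        chans = [config.base_channels * m for m in config.depth_multipliers]
        emb = config.emb_dim
        self._emb_mlp1 = Linear(emb, emb, rng, dtype=dtype)
        self._emb_mlp2 = Linear(emb, emb, rng, dtype=dtype)
        self.stem = Conv2d(config.input_channels, chans[0], 3, rng, dtype=dtype)
        self.enc = [
            ResBlock(chans[max(i - 1, 0)], chans[i], emb, rng, dtype=dtype)
            for i in range(len(chans))
        ]
        self.mid = ResBlock(chans[-1], chans[-1], emb, rng, dtype=dtype)
        self.dec = []
        for i in range(len(chans)):
            cin = (chans[i + 1] if i + 1 < len(chans) else chans[-1]) + chans[i]
            self.dec.append(ResBlock(cin, chans[i], emb, rng, dtype=dtype))
        self.final = Conv2d(chans[0], 1, 1, rng, zero_init=True, dtype=dtype)
        self._chans = chans

    # -- parameter plumbing -------------------------------------------------

    def params(self) -> list[Param]:
        ps = self._emb_mlp1.params() + self._emb_mlp2.params() + self.stem.params()
        for b in self.enc:
            ps += b.params()
        ps += self.mid.params()
        for b in self.dec:
            ps += b.params()
        ps += self.final.params()
        return ps

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[:] = 0.0

    # -- forward / backward -------------------------------------------------

    def forward_batch(self, x_up: np.ndarray, yt: np.ndarray, gamma: np.ndarray) -> np.ndarray:
        """Batched prediction: (N,H,W) condition and state -> (N,H,W) eps-hat."""
        n, h, w = yt.shape
        self.config.check_shape((h, w))
        feats = _gamma_features(gamma, self.config.emb_dim).astype(self.dtype)
        self._e1 = self._emb_mlp1.forward(feats)
        temb = self._emb_mlp2.forward(_silu(self._e1))
        self._temb = temb

        x = np.stack([x_up, yt], axis=1).astype(self.dtype)
        h0 = self.stem.forward(x)
        levels = len(self._chans)
        skips = []
        hcur = h0
        for i in range(levels):
            if i > 0:
                hcur = _avgpool(hcur)
            hcur = self.enc[i].forward(hcur, temb)
            skips.append(hcur)
        hcur = self.mid.forward(hcur, temb)
        for i in reversed(range(levels)):
            hcur = self.dec[i].forward(np.concatenate([hcur, skips[i]], axis=1), temb)
            if i > 0:
                hcur = _upsample(hcur)
        out = self.final.forward(hcur)
        self._skip_channels = [s.shape[1] for s in skips]
        return out[:, 0]

    def backward_batch(self, g_out: np.ndarray) -> None:
        """Accumulate parameter gradients for a loss gradient w.r.t. eps-hat."""
        levels = len(self._chans)
        gtemb = np.zeros_like(self._temb)
        g = self.final.backward(np.asarray(g_out, dtype=self.dtype)[:, None])
        gskips: list[np.ndarray | None] = [None] * levels
        for i in range(levels):
            if i > 0:
                g = _upsample_grad(g)
            g, gt = self.dec[i].backward(g)
            gtemb += gt
            nskip = self._skip_channels[i]
            gskips[i] = g[:, -nskip:]
            g = g[:, :-nskip]
        g, gt = self.mid.backward(g)
        gtemb += gt
        g = g + gskips[levels - 1]
        for i in reversed(range(levels)):
            g, gt = self.enc[i].backward(g)
            gtemb += gt
            if i > 0:
                g = _avgpool_grad(g)
                g = g + gskips[i - 1]
        self.stem.backward(g)
        ge = self._emb_mlp2.backward(gtemb) * _silu_grad(self._e1)
        self._emb_mlp1.backward(ge)

    # -- public inference contract ------------------------------------------

    def predict(self, x_up: ImageGrid, yt: ImageGrid, gamma_t: float) -> ImageGrid:
        """eps-hat for a single model-scale image pair at noise level gamma_t."""
        if x_up.shape != yt.shape:
            raise ValueError(f"condition {x_up.shape} and state {yt.shape} differ")
        if not (0.0 < gamma_t < 1.0):
            raise ValueError(f"gamma_t must lie in (0,1), got {gamma_t}")
        out = self.forward_batch(
            x_up.pixels[None], yt.pixels[None], np.array([gamma_t])
        )[0]
        if not np.all(np.isfinite(out)):
            raise FloatingPointError("denoiser produced non-finite output")
        return yt.with_pixels(out)


def build_denoiser(config: DenoiserConfig, seed: int, dtype=np.float32) -> Denoiser:
    """Initialize a denoiser with reproducible random parameters.

    ``dtype`` selects the arithmetic precision; single precision is the
    training default, double is used where exactness matters (e.g. gradient
    verification).
    """
    return Denoiser(config, seed, dtype=dtype)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


@dataclass
class TrainState:
    """Optimizer hyper-parameters and progress counters."""

    lr: float = 1e-4
    beta1: float = 0.9
    beta2: float = 0.999
    adam_eps: float = 1e-8
    clip_norm: float = 1.0
    step: int = 0
    loss: float = float("nan")
    history: list = field(default_factory=list)


def _adam_update(params: list[Param], state: TrainState) -> None:
    if state.clip_norm is not None:
        total = np.sqrt(sum(float(np.sum(p.grad**2)) for p in params))
        if total > state.clip_norm:
            scale = state.clip_norm / total
            for p in params:
                p.grad *= scale
    state.step += 1
    b1, b2 = state.beta1, state.beta2
    bias1 = 1.0 - b1**state.step
    bias2 = 1.0 - b2**state.step
    for p in params:
        p.m = b1 * p.m + (1.0 - b1) * p.grad
        p.v = b2 * p.v + (1.0 - b2) * p.grad**2
        p.value -= state.lr * (p.m / bias1) / (np.sqrt(p.v / bias2) + state.adam_eps)


def training_step(
    denoiser,
    batch: tuple[np.ndarray, np.ndarray],
    schedule: NoiseSchedule,
    rng: np.random.Generator,
    state: TrainState,
    *,
    t: "np.ndarray | None" = None,
    eps: "np.ndarray | None" = None,
) -> float:
    """One stochastic objective evaluation and (if trainable) Adam update.

    ``batch`` is a pair of model-scale arrays ``(x_up, y0)`` of shape
    ``(N, H, W)``.  A timestep is drawn uniformly per element, the noisy state
    is formed from the closed-form marginal, and the loss is the pixel- and
    batch-averaged squared error between the predicted and true noise.
    ``t``/``eps`` may be forced for deterministic tests.  Objects without
    trainable parameters (stub denoisers) are evaluated but not updated.
    """
    x_up, y0 = batch
    x_up = np.asarray(x_up, dtype=np.float64)
    y0 = np.asarray(y0, dtype=np.float64)
    n = y0.shape[0]
    if t is None:
        t = rng.integers(1, schedule.T + 1, size=n)
    else:
        t = np.asarray(t)
    if eps is None:
        eps = rng.standard_normal(y0.shape)
    g = schedule.gamma[t - 1]
    yt = np.sqrt(g)[:, None, None] * y0 + np.sqrt(1.0 - g)[:, None, None] * eps

    eps_hat = denoiser.forward_batch(x_up, yt, g)
    diff = eps_hat - eps
    loss = float(np.mean(diff**2))
    if not np.isfinite(loss):
        raise FloatingPointError(
            f"non-finite training loss at step {state.step} "
            f"(t drawn: {t.tolist()}, y_t std: {float(yt.std()):.3g})"
        )
    state.loss = loss

    if hasattr(denoiser, "backward_batch") and hasattr(denoiser, "params"):
        denoiser.zero_grad()
        denoiser.backward_batch(2.0 * diff / diff.size)
        _adam_update(denoiser.params(), state)
    return loss


def train(
    dataset,
    config: DenoiserConfig,
    schedule: NoiseSchedule,
    *,
    epochs: int,
    batch_size: int = 16,
    lr: float = 1e-4,
    lr_decay: str = "none",
    ema_decay: "float | None" = 0.995,
    seed: int = 0,
    checkpoint_path=None,
    checkpoint_every: "int | None" = None,
) -> tuple[Denoiser, list[dict]]:
    """Train a denoiser on paired (low-res, high-res) ``ImageGrid`` data.

    Low-resolution images are bicubic-upsampled to the high-resolution grid,
    both are mapped to model scale, and minibatches are drawn in a shuffled
    order re-seeded per epoch.  Returns the denoiser and a per-epoch log of
    mean losses; the whole run is reproducible from ``seed``.

    ``lr_decay="cosine"`` anneals the learning rate to zero over the run;
    ``ema_decay`` maintains an exponential moving average of the parameters
    that is swapped in at the end (both standard practice for diffusion
    models, where the sampling chain compounds small parameter noise; pass
    ``ema_decay=None`` to keep the last raw iterate).
    """
    from .sampler import upsample_condition  # deferred: no import cycle at load

    if len(dataset) == 0:
        raise ValueError("training dataset is empty")
    hr_shape = dataset[0][1].shape
    xs, ys = [], []
    for lr_img, hr_img in dataset:
        if hr_img.shape != hr_shape:
            raise ValueError(
                f"inconsistent HR shapes in dataset: {hr_img.shape} vs {hr_shape}"
            )
        xs.append(upsample_condition(lr_img, hr_shape).to_model().pixels)
        ys.append(hr_img.to_model().pixels)
    x_all = np.stack(xs)
    y_all = np.stack(ys)

    if config.image_shape is None:
        config = DenoiserConfig(**{**asdict(config), "image_shape": hr_shape})
    config.check_shape(hr_shape)

    denoiser = build_denoiser(config, seed)
    state = TrainState(lr=lr)
    rng = np.random.default_rng(seed + 1)
    log: list[dict] = []
    n = len(dataset)
    steps_total = max(1, epochs * ((n + batch_size - 1) // batch_size))
    ema = (
        [p.value.copy() for p in denoiser.params()] if ema_decay is not None else None
    )
    for epoch in range(epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            if lr_decay == "cosine":
                state.lr = lr * 0.5 * (1.0 + np.cos(np.pi * state.step / steps_total))
            losses.append(
                training_step(denoiser, (x_all[idx], y_all[idx]), schedule, rng, state)
            )
            if ema is not None:
                for e, p in zip(ema, denoiser.params()):
                    e *= ema_decay
                    e += (1.0 - ema_decay) * p.value
        log.append({"epoch": epoch, "mean_loss": float(np.mean(losses)), "step": state.step})
        if (
            checkpoint_path is not None
            and checkpoint_every
            and (epoch + 1) % checkpoint_every == 0
        ):
            save_checkpoint(denoiser, checkpoint_path, schedule=schedule, extra={"epoch": epoch})
    if ema is not None:
        for e, p in zip(ema, denoiser.params()):
            p.value = e
    if checkpoint_path is not None:
        save_checkpoint(denoiser, checkpoint_path, schedule=schedule, extra={"epoch": epochs - 1})
    return denoiser, log


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------


def save_checkpoint(denoiser: Denoiser, path, *, schedule: "NoiseSchedule | None" = None, extra: "dict | None" = None) -> None:
    """Write parameters + config (+ schedule spec) to a ``.npz`` file."""
    arrays = {f"p{i}": p.value for i, p in enumerate(denoiser.params())}
    meta = {
        "config": asdict(denoiser.config),
        "seed": denoiser.seed,
        "schedule": schedule.spec() if schedule is not None else None,
        "extra": extra or {},
    }
    arrays["meta_json"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path) -> tuple[Denoiser, "NoiseSchedule | None"]:
    """Rebuild a denoiser (and its schedule, if stored) from a checkpoint."""
    from .schedule import build_schedule

    with np.load(path) as data:
        meta = json.loads(bytes(data["meta_json"]).decode())
        cfg = meta["config"]
        cfg["depth_multipliers"] = tuple(cfg["depth_multipliers"])
        if cfg.get("image_shape") is not None:
            cfg["image_shape"] = tuple(cfg["image_shape"])
        denoiser = build_denoiser(DenoiserConfig(**cfg), meta["seed"])
        for i, p in enumerate(denoiser.params()):
            stored = data[f"p{i}"]
            if stored.shape != p.value.shape:
                raise ValueError(f"checkpoint parameter {i} has shape {stored.shape}")
            p.value = stored.astype(denoiser.dtype)
    sched = None
    if meta["schedule"] is not None:
        s = meta["schedule"]
        sched = build_schedule(T=s["T"], kind="explicit", alpha=np.asarray(s["alpha"]))
    return denoiser, sched
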