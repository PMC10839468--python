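"""Noise-predicting network: contracts, gradients, training behavior."""

import numpy as np
import pytest

from diffsr import (
    DenoiserConfig,
    ImageGrid,
    TrainState,
    build_denoiser,
    build_schedule,
    load_checkpoint,
    save_checkpoint,
    train,
    training_step,
)

TINY_CFG = DenoiserConfig(base_channels=4, depth_multipliers=(1, 2), emb_dim=8)


class StubDenoiser:
    """Returns a fixed offset from the true noise; no trainable state."""

    def __init__(self, offset=0.0, eps=None):
        self.offset = offset
        self.eps = eps

    def forward_batch(self, x_up, yt, gamma):
        base = self.eps if self.eps is not None else np.zeros_like(yt)
        return base + self.offset


class TestNetworkContracts:
    def test_output_shape_matches_input(self, rng):
        den = build_denoiser(TINY_CFG, seed=0)
        out = den.forward_batch(
            rng.standard_normal((3, 32, 32)), rng.standard_normal((3, 32, 32)),
            np.full(3, 0.5),
        )
        assert out.shape == (3, 32, 32)
        assert np.all(np.isfinite(out))

    def test_same_seed_same_predictions(self, rng):
        x = rng.standard_normal((2, 16, 16))
        y = rng.standard_normal((2, 16, 16))
        g = np.array([0.3, 0.7])
        a = build_denoiser(TINY_CFG, seed=9).forward_batch(x, y, g)
        b = build_denoiser(TINY_CFG, seed=9).forward_batch(x, y, g)
        np.testing.assert_array_equal(a, b)

    def test_default_config_is_full_scale(self):
        cfg = DenoiserConfig()
        assert cfg.base_channels == 64
        assert cfg.depth_multipliers == (1, 2, 4, 8, 16)
        den = build_denoiser(cfg, seed=0)
        # first convolution: 64 output channels over the 2 stacked inputs
        assert den.stem.W.value.shape == (64, 2, 3, 3)
        assert len(den.enc) == 5

    def test_incompatible_geometry_reported(self, rng):
        den = build_denoiser(TINY_CFG, seed=0)  # two levels -> sides % 2 == 0
        with pytest.raises(ValueError, match="divisible by 2"):
            den.forward_batch(
                rng.standard_normal((1, 15, 15)), rng.standard_normal((1, 15, 15)),
                np.array([0.5]),
            )

    def test_predict_single_image_contract(self, rng):
        den = build_denoiser(TINY_CFG, seed=0)
        x = ImageGrid(rng.standard_normal((16, 16)), model_scale=True)
        y = x.with_pixels(rng.standard_normal((16, 16)))
        out = den.predict(x, y, 0.4)
        assert out.shape == (16, 16)
        with pytest.raises(ValueError, match="gamma"):
            den.predict(x, y, 1.5)


class TestGradients:
    def test_backprop_matches_finite_differences(self, rng):
        den = build_denoiser(TINY_CFG, seed=0, dtype=np.float64)
        sched = build_schedule(T=10)
        x = rng.standard_normal((2, 8, 8))
        y0 = rng.standard_normal((2, 8, 8))
        eps = rng.standard_normal((2, 8, 8))
        t = np.array([3, 8])
        g = sched.gamma[t - 1]
        yt = np.sqrt(g)[:, None, None] * y0 + np.sqrt(1 - g)[:, None, None] * eps

        def loss():
            d = den.forward_batch(x, yt, g) - eps
            return float(np.mean(d**2))

        diff = den.forward_batch(x, yt, g) - eps
        den.zero_grad()
        den.backward_batch(2.0 * diff / diff.size)
        params = den.params()
        check = np.random.default_rng(5)
        for _ in range(15):
            p = params[check.integers(len(params))]
            idx = tuple(check.integers(s) for s in p.value.shape)
            h, orig = 1e-6, p.value[idx]
            p.value[idx] = orig + h
            lp = loss()
            p.value[idx] = orig - h
            lm = loss()
            p.value[idx] = orig
            num = (lp - lm) / (2 * h)
            assert abs(num - p.grad[idx]) < 1e-6 * max(1.0, abs(num))


class TestTrainingStep:
    def _batch(self, rng, n=4, side=16):
        return rng.standard_normal((n, side, side)), rng.standard_normal((n, side, side))

    def test_true_noise_stub_has_zero_loss(self, rng):
        sched = build_schedule(T=10)
        x, y0 = self._batch(rng)
        eps = rng.standard_normal(y0.shape)
        loss = training_step(
            StubDenoiser(eps=eps), (x, y0), sched, rng, TrainState(), eps=eps
        )
        assert loss == 0.0

    def test_constant_offset_stub_loss_is_offset_squared(self, rng):
        sched = build_schedule(T=10)
        x, y0 = self._batch(rng)
        eps = rng.standard_normal(y0.shape)
        loss = training_step(
            StubDenoiser(offset=0.25, eps=eps), (x, y0), sched, rng, TrainState(), eps=eps
        )
        assert loss == pytest.approx(0.25**2, abs=1e-12)

    def test_zero_stub_loss_near_one(self, rng):
        # E||eps||^2 per pixel is 1 for standard-normal noise
        sched = build_schedule(T=10)
        x, y0 = self._batch(rng, n=4, side=50)  # 10^4 pixels
        loss = training_step(StubDenoiser(), (x, y0), sched, rng, TrainState())
        assert loss == pytest.approx(1.0, abs=0.05)

    def test_single_step_does_not_increase_batch_loss(self, rng):
        # in expectation over repeats, a small-lr update helps the same batch
        sched = build_schedule(T=20)
        deltas = []
        for rep in range(10):
            den = build_denoiser(TINY_CFG, seed=rep)
            r1 = np.random.default_rng(100 + rep)
            x, y0 = self._batch(r1, n=8)
            t = r1.integers(1, 21, size=8)
            eps = r1.standard_normal(y0.shape)
            state = TrainState(lr=1e-3)
            before = training_step(den, (x, y0), sched, r1, state, t=t, eps=eps)
            g = sched.gamma[t - 1]
            yt = np.sqrt(g)[:, None, None] * y0 + np.sqrt(1 - g)[:, None, None] * eps
            after = float(np.mean((den.forward_batch(x, yt, g) - eps) ** 2))
            deltas.append(before - after)
        assert np.mean(deltas) > 0


def _phantom_pairs(n, side=16, seed=0):
    from diffsr import PhantomSpec, degrade, make_phantom

    pairs = []
    for i in range(n):
        hr = make_phantom(
            PhantomSpec(shape=(side, side), n_structures=3, edge_sharpness=0.3, seed=seed + i)
        )
        pairs.append((degrade(hr, (side // 2, side // 2)), hr))
    return pairs


@pytest.fixture(scope="module")
def quick_run():
    """A small-but-real training run shared by the behavioral tests."""
    pairs = _phantom_pairs(24)
    sched = build_schedule(T=50)
    den, log = train(pairs, TINY_CFG, sched, epochs=60, batch_size=8, lr=3e-3,
                     lr_decay="cosine", seed=0)
    return pairs, sched, den, log


class TestTrainLoop:
    def _phantom_pairs(self, n, side=16, seed=0):
        return _phantom_pairs(n, side, seed)

    def test_zero_learning_rate_is_noop(self):
        pairs = self._phantom_pairs(2)
        sched = build_schedule(T=10)
        den, _ = train(pairs, TINY_CFG, sched, epochs=1, lr=0.0, ema_decay=None, seed=3)
        ref = build_denoiser(
            DenoiserConfig(**{**TINY_CFG.__dict__, "image_shape": (16, 16)}), seed=3
        )
        for p, q in zip(den.params(), ref.params()):
            np.testing.assert_array_equal(p.value, q.value)

    def test_loss_decreases_on_small_run(self, quick_run):
        _, _, _, log = quick_run
        assert log[-1]["mean_loss"] < log[0]["mean_loss"]

    def test_same_seed_reproduces_loss_log(self):
        pairs = self._phantom_pairs(8)
        sched = build_schedule(T=20)
        _, log1 = train(pairs, TINY_CFG, sched, epochs=2, lr=1e-3, seed=11)
        _, log2 = train(pairs, TINY_CFG, sched, epochs=2, lr=1e-3, seed=11)
        assert log1 == log2

    def test_trained_model_uses_the_condition(self, quick_run):
        # permuting the condition across the batch must hurt the loss
        pairs, sched, den, _ = quick_run

        from diffsr.sampler import upsample_condition

        x = np.stack([upsample_condition(l, (16, 16)).to_model().pixels for l, h in pairs])
        y = np.stack([h.to_model().pixels for l, h in pairs])
        r = np.random.default_rng(0)
        t = r.integers(1, 51, size=len(pairs))
        eps = r.standard_normal(y.shape)
        g = sched.gamma[t - 1]
        yt = np.sqrt(g)[:, None, None] * y + np.sqrt(1 - g)[:, None, None] * eps
        aligned = float(np.mean((den.forward_batch(x, yt, g) - eps) ** 2))
        perm = np.roll(np.arange(len(pairs)), 1)
        shuffled = float(np.mean((den.forward_batch(x[perm], yt, g) - eps) ** 2))
        assert shuffled > aligned

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            train([], TINY_CFG, build_schedule(T=5), epochs=1)

    def test_checkpoint_round_trip(self, tmp_path, rng):
        pairs = self._phantom_pairs(4)
        sched = build_schedule(T=10)
        path = tmp_path / "ckpt.npz"
        den, _ = train(pairs, TINY_CFG, sched, epochs=1, lr=1e-3, seed=2, checkpoint_path=path)
        loaded, loaded_sched = load_checkpoint(path)
        x = rng.standard_normal((1, 16, 16))
        yt = rng.standard_normal((1, 16, 16))
        g = np.array([0.5])
        np.testing.assert_array_equal(
            den.forward_batch(x, yt, g), loaded.forward_batch(x, yt, g)
        )
        np.testing.assert_allclose(loaded_sched.gamma, sched.gamma, rtol=1e-12)
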