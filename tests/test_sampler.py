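"""Reverse chain, acceptance gate and sample averaging."""

import numpy as np
import pytest

from diffsr import (
    ImageGrid,
    average_samples,
    build_schedule,
    estimate_noise,
    gated_sample,
    reverse_step,
    sample_sr,
    upsample_condition,
)
from diffsr.synth import PhantomSpec, degrade, make_phantom


class FixedEpsDenoiser:
    """Predicts a fixed noise field regardless of inputs."""

    def __init__(self, eps):
        self.eps = np.asarray(eps, dtype=np.float64)

    def predict(self, x_up, yt, gamma_t):
        return yt.with_pixels(self.eps if self.eps.shape else np.full(yt.shape, float(self.eps)))


class TestUpsampleCondition:
    def test_constant_image_stays_constant(self):
        lr = ImageGrid(np.full((10, 12), 37.0))
        up = upsample_condition(lr, (40, 48))
        np.testing.assert_allclose(up.pixels, 37.0, atol=1e-9)

    def test_full_scale_geometry(self):
        lr = ImageGrid(np.random.default_rng(0).uniform(0, 255, (86, 128)))
        assert upsample_condition(lr, (256, 256)).shape == (256, 256)

    def test_round_trip_small_on_smooth_phantom(self):
        hr = make_phantom(PhantomSpec(shape=(64, 64), n_structures=3, edge_sharpness=3.0,
                                      texture_amp=0.0, seed=4))
        lr = degrade(hr, (32, 32))
        back = upsample_condition(lr, (64, 64))
        rel = np.mean(np.abs(back.pixels - hr.pixels)) / np.ptp(hr.pixels)
        assert rel < 0.02

    def test_target_smaller_than_input_rejected(self):
        with pytest.raises(ValueError, match="smaller"):
            upsample_condition(ImageGrid(np.zeros((10, 10))), (5, 20))


class TestReverseStep:
    def test_true_noise_oracle_recovers_y0_at_t1(self, rng):
        sched = build_schedule(T=3)
        y0 = ImageGrid(rng.uniform(-1, 1, (8, 8)), model_scale=True)
        eps = rng.standard_normal((8, 8))
        g1 = sched.gamma_at(1)
        y1 = y0.with_pixels(np.sqrt(g1) * y0.pixels + np.sqrt(1 - g1) * eps)
        den = FixedEpsDenoiser(eps)
        out = reverse_step(den, y0, y1, 1, sched, rng)
        np.testing.assert_allclose(out.pixels, y0.pixels, atol=1e-10)

    def test_zero_prediction_zero_noise_rescales(self, rng):
        sched = build_schedule(T=2, kind="explicit", alpha=(0.99, 0.99))
        yt = ImageGrid(rng.standard_normal((6, 6)), model_scale=True)
        out = reverse_step(
            FixedEpsDenoiser(np.zeros((6, 6))), yt, yt, 2, sched, rng,
            eps_t=np.zeros((6, 6)),
        )
        np.testing.assert_allclose(out.pixels, yt.pixels / np.sqrt(0.99), rtol=1e-12)

    def test_update_is_affine(self, rng):
        sched = build_schedule(T=5)
        yt = ImageGrid(rng.standard_normal((6, 6)), model_scale=True)
        eps_hat = rng.standard_normal((6, 6))
        eps_t = rng.standard_normal((6, 6))
        base = reverse_step(FixedEpsDenoiser(eps_hat), yt, yt, 3, sched, rng, eps_t=eps_t)
        c = 1.7
        scaled = reverse_step(
            FixedEpsDenoiser(c * eps_hat), yt, yt.with_pixels(c * yt.pixels), 3,
            sched, rng, eps_t=c * eps_t,
        )
        np.testing.assert_allclose(scaled.pixels, c * base.pixels, rtol=1e-12)

    def test_final_step_injects_no_noise(self, rng):
        sched = build_schedule(T=3)
        yt = ImageGrid(rng.standard_normal((6, 6)), model_scale=True)
        den = FixedEpsDenoiser(rng.standard_normal((6, 6)))
        a = reverse_step(den, yt, yt, 1, sched, np.random.default_rng(1))
        b = reverse_step(den, yt, yt, 1, sched, np.random.default_rng(2))
        np.testing.assert_array_equal(a.pixels, b.pixels)


class TestSampleSR:
    class _Cfg:
        image_shape = (8, 8)

    def _stub(self):
        den = FixedEpsDenoiser(np.zeros((8, 8)))
        den.config = self._Cfg()
        return den

    def test_single_step_chain_is_rescaled_noise(self):
        sched = build_schedule(T=1, kind="explicit", alpha=(0.99,))
        lr = ImageGrid(np.full((4, 4), 128.0))
        rng1 = np.random.default_rng(3)
        out = sample_sr(self._stub(), lr, sched, rng1)
        y_T = np.random.default_rng(3).standard_normal((8, 8))
        expected = ImageGrid(
            np.clip(y_T / np.sqrt(0.99), -1, 1), value_range=lr.value_range, model_scale=True
        ).to_storage()
        np.testing.assert_allclose(out.pixels, expected.pixels, rtol=1e-12)

    def test_seed_determinism_and_variation(self):
        sched = build_schedule(T=4)
        lr = ImageGrid(np.full((4, 4), 100.0))
        a = sample_sr(self._stub(), lr, sched, np.random.default_rng(7))
        b = sample_sr(self._stub(), lr, sched, np.random.default_rng(7))
        c = sample_sr(self._stub(), lr, sched, np.random.default_rng(8))
        np.testing.assert_array_equal(a.pixels, b.pixels)
        assert not np.array_equal(a.pixels, c.pixels)


def _noisy_image(base, std, seed):
    r = np.random.default_rng(seed)
    return base.with_pixels(base.pixels + r.normal(0, std, base.shape))


class TestGate:
    """Acceptance-loop semantics, exercised with scripted sample streams."""

    def setup_method(self):
        # the "input": a smooth phantom with genuine acquisition noise, kept
        # at its own resolution so sigma_x is meaningful
        clean = make_phantom(PhantomSpec(shape=(64, 64), n_structures=4,
                                         edge_sharpness=3.0, texture_amp=0.0, seed=1))
        self.lr = _noisy_image(clean, 8.0, seed=2)
        self.clean = clean
        self.sched = build_schedule(T=2)

    def _scripted(self, images):
        stream = iter(images)
        return lambda d, l, s, r: next(stream)

    def test_accepts_first_candidate_at_or_below_sigma_x(self):
        # a candidate above the gate, then one below: second accepted
        res = gated_sample(
            None, self.lr, self.sched, np.random.default_rng(0), max_attempts=5,
            target_shape=(64, 64), stride=2,
            sample_fn=self._scripted([_noisy_image(self.clean, 30.0, 3), self.clean]),
        )
        assert res.attempts == 2
        assert res.accepted
        assert len(res.enl_history) == 2
        assert res.enl_history[-1] <= res.sigma_x

    def test_equality_is_accepted_on_first_attempt(self):
        # the input itself has ENL exactly sigma_x (<= comparison)
        res = gated_sample(
            None, self.lr, self.sched, np.random.default_rng(0), max_attempts=5,
            target_shape=(64, 64), stride=2,
            sample_fn=self._scripted([self.lr]),
        )
        assert res.attempts == 1 and res.accepted

    def test_exhaustion_returns_lowest_enl_candidate(self):
        noisy = [_noisy_image(self.clean, s, seed=10 + i) for i, s in enumerate([40, 25, 33])]
        res = gated_sample(
            None, self.lr, self.sched, np.random.default_rng(0), max_attempts=3,
            target_shape=(64, 64), stride=2,
            sample_fn=self._scripted(noisy),
        )
        assert res.attempts == 3
        assert not res.accepted
        np.testing.assert_array_equal(res.image.pixels, noisy[1].pixels)
        assert res.enl_history[1] == min(res.enl_history)

    def test_accepted_result_reverifies(self):
        res = gated_sample(
            None, self.lr, self.sched, np.random.default_rng(0), max_attempts=5,
            target_shape=(64, 64), stride=2,
            sample_fn=self._scripted([_noisy_image(self.clean, 30.0, 3), self.clean]),
        )
        assert res.accepted
        recomputed = estimate_noise(res.image, stride=2).sigma
        sigma_x = estimate_noise(upsample_condition(self.lr, (64, 64)), stride=2).sigma
        assert recomputed <= sigma_x

    def test_invalid_max_attempts(self):
        with pytest.raises(ValueError):
            gated_sample(None, self.lr, self.sched, np.random.default_rng(0), max_attempts=0)


class TestAverageSamples:
    def test_mean_of_identical_images_is_identity(self):
        img = ImageGrid(np.random.default_rng(0).uniform(0, 255, (16, 16)))
        out = average_samples([img] * 5)
        np.testing.assert_allclose(out.pixels, img.pixels, rtol=1e-15)

    def test_noise_shrinks_like_sqrt_s(self):
        clean = ImageGrid(np.full((200, 200), 100.0))
        sigma = 12.0
        samples = [_noisy_image(clean, sigma, seed=i) for i in range(4)]
        resid = average_samples(samples).pixels - clean.pixels
        assert abs(resid.std() - sigma / 2) < 0.1 * (sigma / 2)

    def test_enl_of_average_non_increasing_in_s(self):
        clean = make_phantom(PhantomSpec(shape=(96, 96), n_structures=4,
                                         edge_sharpness=3.0, texture_amp=0.0, seed=5))
        samples = [_noisy_image(clean, 10.0, seed=100 + i) for i in range(20)]
        enls = [
            estimate_noise(average_samples(samples[:s]), stride=2).sigma
            for s in (3, 5, 10, 20)
        ]
        assert all(a >= b for a, b in zip(enls, enls[1:]))

    def test_empty_and_mismatched_inputs_rejected(self):
        with pytest.raises(ValueError):
            average_samples([])
        with pytest.raises(ValueError, match="mismatch"):
            average_samples([ImageGrid(np.zeros((4, 4))), ImageGrid(np.zeros((4, 5)))])
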