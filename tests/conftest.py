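import numpy as np
import pytest

from diffsr import ImageGrid, PhantomSpec, make_phantom
from diffsr.study import run_tiny_study


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def smooth_noisy_phantom(shape=(256, 256), noise_std=0.0, seed=0):
    """A smooth (locally low-rank) phantom plus optional i.i.d. noise.

    Heavy boundary smoothing keeps 7x7 patches far from full rank, so the
    minimum covariance eigenvalue isolates the injected noise.
    """
    clean = make_phantom(
        PhantomSpec(shape=shape, n_structures=5, edge_sharpness=4.0, texture_amp=0.0, seed=seed)
    )
    if noise_std == 0:
        return clean, clean
    noise_rng = np.random.default_rng(seed + 10_000)
    noisy = clean.with_pixels(clean.pixels + noise_rng.normal(0.0, noise_std, shape))
    return clean, noisy


@pytest.fixture(scope="session")
def tiny_study():
    """The desk-scale end-to-end experiment, run once per session.

    Training plus gated inference on held-out phantoms; shared by the
    end-to-end ordering tests.
    """
    return run_tiny_study(seed=7)
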