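import numpy as np
import pytest

from mscnnseg import PhantomConfig, generate_phantom, normalize


@pytest.fixture(scope="session")
def small_phantom():
    """A small, centered, moderately noisy phantom with all five classes."""
    cfg = PhantomConfig(volume_shape=(64, 64, 64), brain_radius=28,
                        core_radius=6, enh_rim_width=3, nonenh_width=3,
                        edema_width=6, tumor_center=(32, 32, 32),
                        noise_sd=3.0, seed=7)
    vol, labels = generate_phantom(cfg)
    return cfg, vol, labels


@pytest.fixture(scope="session")
def small_case(small_phantom):
    """Normalized (volume, labels) pair ready for sampling/training."""
    _, vol, labels = small_phantom
    return normalize(vol), labels


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
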