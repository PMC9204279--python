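import numpy as np
import pytest

from msfaseg.model import ModelConfig, build_model
from msfaseg.phantom import PhantomConfig, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_phantom():
    """One 64x64 phantom with default (noisy, vesselled) settings."""
    return generate_phantom(PhantomConfig(image_size=64, seed=3), 0)


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free, vessel-free 64x64 phantom (exact-threshold oracle holds)."""
    cfg = PhantomConfig(image_size=64, vessel_count=0, noise_sd=0.0, seed=3)
    return generate_phantom(cfg, 0)


@pytest.fixture(scope="session")
def tiny_model():
    """Smallest valid model: 2 levels, 4 base channels."""
    return build_model(ModelConfig(num_levels=2, base_channels=4, seed=0))


def random_mask(rng, shape, p=0.3):
    return (rng.random(shape) < p).astype(np.uint8)
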