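import numpy as np
import pytest

from valveoptics import PhantomConfig, generate_phantom


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free phantom section with uniform calcium (no deposits): every
    channel value follows the mixing product exactly."""
    cfg = PhantomConfig(
        image_size=(64, 64),
        noise_gaussian_sd=0.0,
        ars_area_fraction=0.0,
        seed=123,
    )
    return generate_phantom(cfg)


@pytest.fixture(scope="session")
def noisy_phantom():
    """Default-noise phantom section (2% Gaussian) with deposits."""
    return generate_phantom(PhantomConfig(image_size=(64, 64), seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
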