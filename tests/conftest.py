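import numpy as np
import pytest
from hypothesis import settings

from dks.core import ViewId
from dks.synthgen import NoiseParams, simulate_cases

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cases():
    """20 noisy synthetic cases at 64 px, shared across tests."""
    return simulate_cases(20, 2024, class_mix=0.6, image_size=64)


@pytest.fixture(scope="session")
def clean_cases():
    """Noise-free cases: deterministic images, analytic keypoints."""
    return simulate_cases(
        10,
        77,
        class_mix=0.5,
        image_size=64,
        noise=NoiseParams(speckle_strength=0.0, blur_sigma_px=0.0),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def all_view_ids():
    return list(ViewId)
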