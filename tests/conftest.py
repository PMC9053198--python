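import numpy as np
import pytest

from threecb import SimConfig, default_attenuation_model, generate_phantom


@pytest.fixture(scope="session")
def atten_model():
    return default_attenuation_model()


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale phantom config for fast unit tests."""
    return SimConfig(shape=(160, 160), pixel_spacing_mm=0.25,
                     lesion_radius_mm_range=(2.0, 3.5))


@pytest.fixture(scope="session")
def small_phantom(small_config):
    return generate_phantom(small_config, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
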