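import numpy as np
import pytest

from alrls.config import RunConfig
from alrls.phantom import clean_spec, generate_phantom, stalling_spec


@pytest.fixture(scope="session")
def clean_phantom():
    """One lesion-free phantom used across tests."""
    return generate_phantom(clean_spec(seed=11))


@pytest.fixture(scope="session")
def lesioned_phantom():
    """One stalling-regime phantom (wall-attached lesions)."""
    return generate_phantom(stalling_spec(seed=21))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def small_cfg():
    """A small-ball configuration for 16x16 unit-test instances."""
    return RunConfig(ball_radius=4, band_width=4)
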