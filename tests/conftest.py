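import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import bnmic
from bnmic.workflows import spiral_validation, surrogate_study

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_conn():
    """20-region bilateral synthetic connectome, spectrally normalized."""
    return bnmic.normalize_spectral(bnmic.synth_connectome(20, 0.3, seed=1))


@pytest.fixture(scope="session")
def study():
    """The full parameter-recovery experiment at its default conditions."""
    return surrogate_study(epochs=200, seed=0, stride=2)


@pytest.fixture(scope="session")
def spiral_report():
    """The spiral system-identification experiment at its default conditions."""
    return spiral_validation(seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
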