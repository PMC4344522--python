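import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20150208)


@pytest.fixture
def wt_kinetics():
    """Wild-type-like chromatin-binding kinetics (slow linker-histone class)."""
    from chromodyn.simkit import KineticParams

    return KineticParams(tau_half=14.1, immobile_fraction=0.128,
                         bleach_depth=0.3, noise_sd=0.02)
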