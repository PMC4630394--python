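import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import woodftir as wf

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def noiseless_config() -> wf.GeneratorConfig:
    """Default band structure, no noise, no baseline drift."""
    return wf.GeneratorConfig(seed=7, noise_sd=0.0, baseline=(0.0, 0.0))


@pytest.fixture(scope="session")
def noiseless_dataset(noiseless_config):
    return wf.generate_dataset(noiseless_config)


@pytest.fixture(scope="session")
def default_dataset():
    return wf.generate_dataset(wf.GeneratorConfig(seed=1))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
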