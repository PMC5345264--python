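import numpy as np
import pytest

from shoremeth.config import SimulationConfig
from shoremeth.simulate import default_reference


@pytest.fixture(scope="session")
def reference():
    return default_reference()


@pytest.fixture()
def config():
    """Default study-structure configuration with a fixed seed."""
    return SimulationConfig(seed=7)


@pytest.fixture()
def clean_config():
    """Noise-free configuration for exact round-trip checks."""
    cfg = SimulationConfig(seed=7)
    cfg.qpcr_params.ct_noise_sd = 0.0
    cfg.clone_params.conversion_failure_rate = 0.0
    cfg.clone_params.sequencing_error_rate = 0.0
    return cfg


@pytest.fixture()
def small_config():
    """Scaled-down cohort for fast pipeline-level tests."""
    cfg = SimulationConfig(seed=11)
    cfg.n_per_genotype = {"GG": 12, "GA": 8, "AA": 6}
    return cfg


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
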