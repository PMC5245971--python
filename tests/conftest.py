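import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")

from fmricode import ExperimentConfig, generate_distortions, generate_prototype, init_network


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def stimulus_set():
    proto = generate_prototype(dim=100, seed=7)
    return generate_distortions(proto, seed=8)


@pytest.fixture
def small_network():
    return init_network(dim=20, depth=8, seed=11)


@pytest.fixture
def tiny_config():
    """Scaled-down protocol for fast unit-level pipeline checks."""
    return ExperimentConfig(dim=30, n_networks=5, seed=3)
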