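import numpy as np
import pytest
from hypothesis import settings

from neurophen import simulate

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def control_samples():
    """Small control-like cluster set shared across tests."""
    return simulate.generate_cluster_set(4, "control_like", seed=101)


@pytest.fixture(scope="session")
def mutant_samples():
    """Small mutant-like cluster set shared across tests."""
    return simulate.generate_cluster_set(4, "mutant_like", seed=202)


@pytest.fixture(scope="session")
def benchmark_set():
    """Constructed 35-cluster set with exactly 21 fully synchronous clusters."""
    return simulate.generate_full_sync_benchmark(35, 21, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
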