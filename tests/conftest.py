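import numpy as np
import pytest

from causalblend import SimConfig, simulate_study
from causalblend.graph import ground_truth_dag


@pytest.fixture(scope="session")
def study5000():
    """The reference study conditions: n=5000 units at seed 42."""
    return simulate_study(SimConfig(n=5000, seed=42))


@pytest.fixture(scope="session")
def tiny_study():
    return simulate_study(SimConfig(n=400, seed=7))


@pytest.fixture(scope="session")
def truth_dag():
    return ground_truth_dag()


@pytest.fixture
def rng():
    return np.random.default_rng(0)
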