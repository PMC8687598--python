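import numpy as np
import pytest

from deepcme import (
    build_example_network,
    default_outputs,
    simulate_batch,
)


@pytest.fixture(scope="session")
def bd1():
    """Single-species birth-death network (k=10, gamma=1, x0=0)."""
    return build_example_network("birth_death", 1)


@pytest.fixture(scope="session")
def outs1():
    return default_outputs(1)


@pytest.fixture(scope="session")
def bd1_batch(bd1, outs1):
    """Moderate training-sized batch reused by several tests."""
    return simulate_batch(bd1, 1.0, 50, 200, 42, outs1)


@pytest.fixture(scope="session")
def bd1_batch_2000(bd1, outs1):
    """Larger batch for statistical assertions."""
    return simulate_batch(bd1, 1.0, 50, 2000, 7, outs1)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
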