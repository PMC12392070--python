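import numpy as np
import pytest

from decayrl.tasks import make_task


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def fig1_task():
    """Deterministic unit-reward task: 5 states, 200 trials, gamma = 1."""
    return make_task(5, [(1.0, 1.0)], 200, 1.0)


@pytest.fixture
def probabilistic_task():
    """Two-point reward {1, 3} with equal probabilities."""
    return make_task(5, [(1.0, 0.5), (3.0, 0.5)], 200, 1.0)
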