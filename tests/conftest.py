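import numpy as np
import pytest

from perturbreach.simulate import (
    BehaviorParams,
    BlockDesign,
    generate_block,
    generate_session,
    simulate_trajectory,
)


@pytest.fixture(scope="session")
def default_block():
    """One deterministic block (design + 240 trials)."""
    return generate_block(12345)


@pytest.fixture(scope="session")
def trials(default_block):
    return default_block[1]


@pytest.fixture(scope="session")
def behavior():
    return BehaviorParams()


@pytest.fixture(scope="session")
def noiseless_behavior():
    return BehaviorParams(trajectory_noise_sd=0.0)


@pytest.fixture(scope="session")
def small_session():
    """A mixed-class session shared by read-only tests (8 neurons)."""
    return generate_session(7, n_neurons=8, with_trajectories=True)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
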