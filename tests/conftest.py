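import numpy as np
import pytest

from ploopmsm.synthetic import (build_toy_ploop, default_truth,
                                generate_ensemble)


@pytest.fixture(scope="session")
def truth():
    return default_truth(seed=0)


@pytest.fixture(scope="session")
def small_ensemble(truth):
    """10 trajectories x 1000 frames — enough transitions for stable MSMs."""
    return generate_ensemble(truth, n_trajectories=10, n_steps=1000, seed=11)


@pytest.fixture(scope="session")
def toy_a():
    return build_toy_ploop("A")


@pytest.fixture(scope="session")
def toy_b():
    return build_toy_ploop("B")


@pytest.fixture(scope="session")
def toy_far():
    return build_toy_ploop("far")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
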