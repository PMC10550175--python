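import numpy as np
import pytest

from drillscore.synthesis import PhantomConfig, build_tooth_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """Quarter-resolution phantom shared across fast tests."""
    return build_tooth_phantom(PhantomConfig.small(seed=1))


@pytest.fixture(scope="session")
def default_phantom():
    """Full 90x135x90 phantom for the end-to-end checks."""
    return build_tooth_phantom(PhantomConfig(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_mask_triple(rng, shape=(12, 12, 12), p_initial=0.6):
    """Random (initial, ideal, actual) boolean masks satisfying the subset
    preconditions of outcome classification."""
    initial = rng.random(shape) < p_initial
    ideal = initial & (rng.random(shape) < 0.7)
    actual = initial & (rng.random(shape) < 0.7)
    return initial, ideal, actual
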