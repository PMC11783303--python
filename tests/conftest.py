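import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def uniform_pi():
    return np.full(61, 1.0 / 61)


@pytest.fixture(scope="session")
def small_tree():
    """12-taxon two-clade tree used by the mid-size simulation tests."""
    import immusel as im

    return im.simulate_tree(6, 0.5, seed=7)


@pytest.fixture(scope="session")
def tiny_tree():
    """4-taxon tree for fast per-gene checks."""
    import immusel as im

    return im.simulate_tree(2, 0.8, seed=2)
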