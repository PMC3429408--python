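import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from knng import ExpressionMatrix, generate_fixture

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def line_matrix():
    """Four points on a line at 0, 1, 3, 7 — the worked k=1 example."""
    return ExpressionMatrix(
        np.array([[0.0], [1.0], [3.0], [7.0]]),
        ["a", "b", "c", "d"],
        ["x"],
    )


@pytest.fixture
def small_fixture():
    """150 x 12 block-structured matrix used across engine tests."""
    return generate_fixture(150, 12, n_blocks=4, noise_sd=0.3, seed=5)


@pytest.fixture
def rng():
    return np.random.default_rng(11)
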