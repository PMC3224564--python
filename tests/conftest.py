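import numpy as np
import pytest

from ecbs import build_model

TEST_SEED = 20260928


@pytest.fixture(scope="session")
def tiny_model():
    """Small lookup model around normal noise, for unit tests that need a
    model object but not calibration accuracy."""
    return build_model(
        grid=(
            np.array([100, 150, 250]),
            np.array([-0.1, 0.0, 0.1]),
            np.array([2.8, 3.0, 3.2]),
        ),
        replicates=400,
        seed=TEST_SEED,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(TEST_SEED)
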