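import numpy as np
import pytest

from delaysync.synthetic_data import (
    SWEEP_4S_SCHEDULE,
    TriangularSchedule,
    default_cameras,
    example_responder_2p1z,
    example_responder_3p3z,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def model_3p3z():
    """3-pole/3-zero tracking model with a 15 ms pure transport delay."""
    return example_responder_3p3z()


@pytest.fixture
def model_2p1z():
    """2-pole/1-zero tracking model with a 40 ms pure transport delay."""
    return example_responder_2p1z()


@pytest.fixture
def sweep_4s():
    return SWEEP_4S_SCHEDULE


@pytest.fixture
def cameras():
    return default_cameras()
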