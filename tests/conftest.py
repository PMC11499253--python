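import numpy as np
import pandas as pd
import pytest

from linedyn import SimConfig, simulate_session
from linedyn.behavior import BoutTable


@pytest.fixture(scope="session")
def receptive_session():
    """One default receptive synthetic session (10 min, 100 neurons)."""
    return simulate_session(SimConfig(seed=11))


@pytest.fixture(scope="session")
def small_session():
    """A short, small receptive session for fast fitting tests."""
    return simulate_session(SimConfig(seed=5, n_neurons=30,
                                      duration_frames=3000))


@pytest.fixture(scope="session")
def unreceptive_session():
    return simulate_session(SimConfig(seed=11, regime="unreceptive"))


def make_bouts(rows, frame_rate=10.0):
    df = pd.DataFrame(rows, columns=["actor", "behavior", "start", "stop"])
    return BoutTable(df, frame_rate=frame_rate)


@pytest.fixture
def simple_bouts():
    return make_bouts([
        ("male", "sniff", 10, 30),
        ("male", "mount", 50, 80),
        ("male", "intromission", 120, 180),
        ("female", "lordose", 125, 175),
        ("female", "dart", 55, 70),
    ])


@pytest.fixture
def rng():
    return np.random.default_rng(0)
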