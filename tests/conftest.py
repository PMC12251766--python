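import datetime as dt

import numpy as np
import pytest

from fishcurtain import BeamStream, SensorConfig

START = dt.datetime(2025, 7, 1, 10, 0, 0, tzinfo=dt.timezone.utc)


@pytest.fixture
def full_config():
    return SensorConfig.full_scale()


@pytest.fixture
def mini_config():
    return SensorConfig.mini()


@pytest.fixture
def start_time():
    return START


def make_stream(config, interrupted_a=None, interrupted_b=None, n_frames=None,
                start_time=START):
    """Build a stream from boolean interruption masks (frames x beams)."""
    if interrupted_a is None and interrupted_b is None:
        assert n_frames is not None
        interrupted_a = np.zeros((n_frames, config.n_beams), dtype=bool)
    if interrupted_a is None:
        interrupted_a = np.zeros_like(interrupted_b)
    if interrupted_b is None:
        interrupted_b = np.zeros_like(interrupted_a)
    states_a = np.where(interrupted_a, 0, 1).astype(np.uint8)
    states_b = np.where(interrupted_b, 0, 1).astype(np.uint8)
    return BeamStream(config, start_time, states_a, states_b)
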