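import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracle module

from breathkin.core import TimeSeries
from breathkin.synthetic import generate_session, speech_session


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_ts(values, rate_hz=100.0, start_s=0.0, label="sig", units="au"):
    return TimeSeries(np.asarray(values, dtype=float), rate_hz, start_s, label, units)


@pytest.fixture
def small_session():
    """Two speech cycles plus a trailing recovery cycle, light noise, at
    reduced device rates (fast; the analysis happens at 100 Hz anyway)."""
    spec = speech_session(
        n_cycles=3, rip_noise_sd=0.02, sensor_noise_sd=0.12,
        sync_offset_s=0.35, rip_rate_hz=4410.0, ema_rate_hz=625.0, seed=7,
    )
    return generate_session(spec)


@pytest.fixture
def noiseless_session():
    spec = speech_session(
        n_cycles=3, rip_noise_sd=0.0, sensor_noise_sd=0.0,
        sync_offset_s=0.35, rip_rate_hz=4410.0, ema_rate_hz=625.0, seed=1,
    )
    return generate_session(spec)
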