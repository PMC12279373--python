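import numpy as np
import pytest

from steerlab.core import KinematicsTrace, TimeSeries
from steerlab.synthetic import SimConfig, simulate_steering_session


@pytest.fixture(scope="session")
def short_session():
    """A 60 s synthetic session with voltage, shared across tests."""
    cfg = SimConfig(duration_s=60.0, seed=11, make_voltage=True)
    return simulate_steering_session(cfg)


@pytest.fixture(scope="session")
def quiet_session():
    """A noise-free, always-active session for exact identities."""
    cfg = SimConfig(duration_s=120.0, seed=7, make_voltage=False,
                    noise_sd={"v_r": 0.0, "v_s": 0.0, "v_f": 0.0},
                    immobility_bout_rate_per_min=0.0)
    return simulate_steering_session(cfg)


def make_ts(values, rate=100.0, **kw):
    return TimeSeries(np.asarray(values, dtype=float), rate, **kw)


def make_kin(v_r, v_s, v_f, rate=100.0):
    return KinematicsTrace(v_r=make_ts(v_r, rate), v_s=make_ts(v_s, rate),
                          v_f=make_ts(v_f, rate))
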