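import numpy as np
import pytest

from actotrap.params import Conditions, variant
from actotrap import synthetics as sy
from actotrap.detection import detect_events


@pytest.fixture(scope="session")
def s267e():
    return variant("S267E")


@pytest.fixture(scope="session")
def wt():
    return variant("WT")


@pytest.fixture(scope="session")
def cond_100um():
    return Conditions(atp=0.1)


@pytest.fixture(scope="session")
def langevin_trace(s267e, cond_100um):
    """~50-event Langevin trace at 100 uM ATP, no forcing (shared)."""
    dur = 120.0
    traj = sy.simulate_state_sequence(s267e.rates, cond_100um, dur, 31,
                                      mech=s267e.mech)
    cfg = sy.SimConfig(duration=dur, seed=32, forcing_amp=0.0)
    return sy.simulate_trap_trace(traj, s267e.mech, cfg, rates=s267e.rates,
                                  cond=cond_100um)


@pytest.fixture(scope="session")
def forcing_trace(s267e, cond_100um):
    """~50-event Langevin trace at 100 uM ATP with 100-Hz forcing."""
    dur = 130.0
    traj = sy.simulate_state_sequence(s267e.rates, cond_100um, dur, 61,
                                      mech=s267e.mech)
    cfg = sy.SimConfig(duration=dur, seed=62, forcing_amp=100.0)
    return sy.simulate_trap_trace(traj, s267e.mech, cfg, rates=s267e.rates,
                                  cond=cond_100um)


@pytest.fixture(scope="session")
def langevin_events(langevin_trace):
    return detect_events(langevin_trace)


@pytest.fixture(scope="session")
def forcing_events(forcing_trace):
    return detect_events(forcing_trace)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
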