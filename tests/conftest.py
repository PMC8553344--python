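import numpy as np
import pytest

from obsync.core_events import EventTrain, PairRecording, ProtocolConfig, TrialSet
from obsync.synth import SyncPairSpec, synchronous_pair


@pytest.fixture(scope="session")
def protocol():
    return ProtocolConfig()


@pytest.fixture(scope="session")
def periodic_train():
    """Perfectly periodic 50 Hz train over 1 s."""
    times = np.arange(0.02, 1.0, 0.02)
    return EventTrain(times, 1.0, label="periodic50")


@pytest.fixture(scope="session")
def poisson_train():
    rng = np.random.default_rng(12345)
    t = np.cumsum(rng.exponential(1 / 20.0, 100))
    t = t[t < 2.0]
    return EventTrain(t, 2.0, label="poisson20")


@pytest.fixture(scope="session")
def sync_pair():
    """Gamma-synchronized pair at 50 Hz, dense participation."""
    return synchronous_pair(SyncPairSpec(seed=42, f_start=50.0, f_end=50.0,
                                         phase_jitter=0.001,
                                         participation=0.8, n_trials=8))


def make_trialset(list_of_times, duration, protocol=None):
    protocol = protocol or ProtocolConfig()
    trains = tuple(EventTrain(np.asarray(t, dtype=float), duration)
                   for t in list_of_times)
    return TrialSet(trains, protocol)


def make_pair(times_a, times_b, duration, protocol=None):
    return PairRecording(make_trialset(times_a, duration, protocol),
                         make_trialset(times_b, duration, protocol),
                         pair_id="fixture")
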