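import numpy as np
import pytest

from socalim.core import BehaviorSession, Epoch
from socalim.synthetic import SimulationConfig, simulate_behavior, simulate_dff


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        n_neurons=16,
        class_counts={"SAN": 3, "SIN": 3, "NewPN": 2, "OldPN": 2},
        response_gain=1.0,
        baseline_noise_sd=0.2,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_session(small_config):
    return simulate_behavior(small_config)


@pytest.fixture(scope="session")
def small_dff(small_config, small_session):
    dff, truth = simulate_dff(small_config, small_session)
    return dff, truth


def make_manual_session(rate=10.0, n_frames=400, epoch_spec=None):
    """Hand-built session: epoch_spec is a list of (event, start, end) frames."""
    t = np.arange(n_frames) / rate
    from socalim.core import EVENT_TYPES

    vectors = {ev: np.zeros(n_frames, dtype=np.uint8) for ev in EVENT_TYPES}
    epochs = []
    for ev, s, e in (epoch_spec or []):
        vectors[ev][s:e] = 1
        epochs.append(Epoch(event=ev, start=s, end=e, start_t=s / rate, end_t=e / rate))
    third = n_frames // 3
    stage_slices = {
        "habituation": slice(0, third),
        "sociability": slice(third, 2 * third),
        "novelty": slice(2 * third, n_frames),
    }
    return BehaviorSession(imaging_t=t, vectors=vectors, stage_slices=stage_slices,
                           epochs=epochs, imaging_rate=rate)
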