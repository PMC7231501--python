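import numpy as np
import pytest

from fissionfusion import ArenaSpec, TrackTable, WalkConfig, simulate


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture(scope="session")
def small_sim_track():
    """A short simulated 6-agent recording (30 s at 5 Hz)."""
    config = WalkConfig(
        n_agents=6, step=0.5, heading_change_prob=0.05, duration=30.0, seed=42
    )
    return simulate(config)


@pytest.fixture()
def static_track():
    """Six stationary individuals at fixed, hand-chosen positions."""
    positions = np.array(
        [
            [5.0, 5.0],
            [9.0, 5.0],
            [30.0, 30.0],
            [30.1, 30.0],
            [55.0, 55.0],
            [55.0, 50.0],
        ]
    )
    n_frames = 50
    return TrackTable(
        arena=ArenaSpec(),
        ids=[f"F{i}" for i in range(1, 7)],
        times=np.arange(n_frames) / 5.0,
        positions=np.broadcast_to(positions, (n_frames, 6, 2)).copy(),
        sample_rate=5.0,
    )


def make_track(positions, sample_rate=5.0, arena=None, ids=None):
    """TrackTable from a raw (T, N, 2) array of positions."""
    positions = np.asarray(positions, float)
    t, n, _ = positions.shape
    return TrackTable(
        arena=arena or ArenaSpec(),
        ids=ids or [f"F{i + 1}" for i in range(n)],
        times=np.arange(t) / sample_rate,
        positions=positions,
        sample_rate=sample_rate,
    )
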