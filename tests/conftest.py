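import numpy as np
import pytest

from dcdmotion.io import TrackSet, Trajectory, trackset_from_arrays

TAU = 1.5


@pytest.fixture
def straight_track() -> TrackSet:
    """Noiseless constant-velocity track: 120 frames, 0.05 um per frame in x."""
    pos = np.column_stack([0.05 * np.arange(120), np.zeros(120)])
    return trackset_from_arrays([pos], TAU)


@pytest.fixture
def stationary_track() -> TrackSet:
    pos = np.zeros((10, 2))
    return trackset_from_arrays([pos], TAU)


@pytest.fixture
def zigzag_track() -> TrackSet:
    """Pure reversal: positions alternate between (0,0) and (1,0)."""
    pos = np.column_stack([np.arange(12) % 2.0, np.zeros(12)])
    return trackset_from_arrays([pos], TAU)


def make_random_tracks(
    n_tracks: int, n_frames: int, seed: int, step: float = 0.05
) -> TrackSet:
    rng = np.random.default_rng(seed)
    walks = [
        np.cumsum(rng.normal(0, step, size=(n_frames, 2)), axis=0)
        for _ in range(n_tracks)
    ]
    return trackset_from_arrays(walks, TAU)


@pytest.fixture
def diffusive_tracks() -> TrackSet:
    return make_random_tracks(5, 60, seed=123)
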