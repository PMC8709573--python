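import numpy as np
import pytest

from togsense.synthetic import SimulationConfig, simulate_organ_truth
from togsense.traces import StimulusSchedule


@pytest.fixture
def schedule():
    """The standard acquisition layout: 60 frames, stimulus on frames 30-44."""
    return StimulusSchedule()


@pytest.fixture
def small_config():
    """A small, fast simulation geometry used by most imaging tests."""
    return SimulationConfig(n_cells=6, n_landmarks=0, volume_shape=(15, 64, 64),
                            n_frames=12, stim_onset_frame=5, stim_offset_frame=8,
                            seed=1)


@pytest.fixture
def organ_truth():
    """A full default organ (30 taste cells + 4 landmarks)."""
    cfg = SimulationConfig(seed=2)
    return simulate_organ_truth(cfg, ["sucrose"], rng=np.random.default_rng(2))


def make_dff(values, f0=100.0):
    from togsense.traces import DffTrace
    return DffTrace(values=np.asarray(values, dtype=float), f0=f0)
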