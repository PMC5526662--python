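import numpy as np
import pandas as pd
import pytest

from stopgamma.core_io import Recording
from stopgamma.synthetic import SimConfig, simulate_behavior, simulate_dataset


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    """Scaled-down cohort for fast end-to-end tests (structure preserved)."""
    return SimConfig(n_subjects=3, n_stop_trials=8, sample_rate=400.0, seed=123)


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    return simulate_dataset(small_cfg)


@pytest.fixture(scope="session")
def behavior_draw():
    cfg = SimConfig(n_stop_trials=40, seed=5)
    return cfg, *simulate_behavior(cfg)


@pytest.fixture()
def tiny_recording() -> Recording:
    rng = np.random.default_rng(0)
    return Recording(
        subject_id="T1",
        channel_names=["C3", "Cz", "EOG"],
        channel_kinds=["eeg", "eeg", "eog"],
        sample_rate=100.0,
        data=rng.standard_normal((3, 1000)),
    )


@pytest.fixture()
def tiny_events() -> pd.DataFrame:
    rows = [
        ("metronome", 1.0, 0, 1),
        ("tap_onset", 0.97, 0, 1),
        ("metronome", 1.9, 0, 2),
        ("tap_onset", 1.88, 0, 2),
        ("stop_cue", 2.587, 0, 0),
    ]
    return pd.DataFrame(rows, columns=["event_type", "time", "trial_idx", "tap_idx"])
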