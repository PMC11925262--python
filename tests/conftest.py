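import numpy as np
import pytest

from wearbci.signal_core import Recording
from wearbci.synth import (
    Montage,
    SessionPlan,
    default_state_specs,
    default_uhd_montage,
    generate_recording,
    generate_task_battery,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20_250_306)


@pytest.fixture(scope="session")
def small_montage() -> Montage:
    """Scaled-down grid montage: 8 grids x 4 channels, every region present."""
    return default_uhd_montage(
        region_counts={"frontal": 2, "occipital": 2, "precentral": 1,
                       "postcentral": 1, "other": 2},
        channels_per_grid=4,
    )


@pytest.fixture(scope="session")
def small_battery(small_montage):
    """Short three-state battery: 2 x 30 s trials per state on the small montage."""
    rec, intervals = generate_task_battery(
        n_trials_per_state=2, trial_seconds=30.0, seed=11, montage=small_montage
    )
    return rec, intervals


@pytest.fixture(scope="session")
def idle_baseline(small_montage) -> Recording:
    plan = SessionPlan((("idle", 60.0),), small_montage)
    rec, _ = generate_recording(plan, default_state_specs(), seed=5)
    return rec


def sinusoid_recording(freq: float, fs: float, seconds: float = 8.0, amp: float = 1.0,
                       n_channels: int = 1) -> Recording:
    t = np.arange(int(seconds * fs)) / fs
    x = amp * np.sin(2 * np.pi * freq * t)
    return Recording(data=np.tile(x, (n_channels, 1)), fs=fs)


def steady_amplitude(rec: Recording, freq: float, skip_seconds: float = 3.0) -> float:
    """Amplitude of the `freq` component after the filter transient."""
    x = rec.data[0, int(skip_seconds * rec.fs):]
    t = np.arange(len(x)) / rec.fs
    c = np.exp(-2j * np.pi * freq * t)
    return 2 * abs((x * c).mean())
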