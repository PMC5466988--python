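import numpy as np
import pytest

from ecogmap.preproc import Recording, TrialSet
from ecogmap.simulate import MrcpParams, SimulationConfig, simulate_recording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_trialset(
    epochs: np.ndarray,
    fs: float = 100.0,
    pre_ms: float = 2000.0,
    post_ms: float = 4000.0,
    channel_ids=None,
) -> TrialSet:
    epochs = np.asarray(epochs, dtype=float)
    if channel_ids is None:
        channel_ids = [f"chan_{i + 1}" for i in range(epochs.shape[1])]
    return TrialSet(
        epochs=epochs, fs=fs, channel_ids=channel_ids, pre_ms=pre_ms, post_ms=post_ms
    )


@pytest.fixture
def small_cfg():
    """Fast simulator config: low rate, few trials, small grid."""
    return SimulationConfig(
        n_rows=2,
        n_cols=4,
        fs=500.0,
        n_trials=14,
        iti_range_s=(5.0, 7.0),
        mrcp_channels=("chan_3",),
        erd_channels=("chan_3", "chan_4"),
        ers_channels=("chan_4",),
        mrcp=MrcpParams(amplitude_uv=120.0),
        delta_background_uv=40.0,
        seed=7,
    )


@pytest.fixture
def small_recording(small_cfg):
    rec, gt = simulate_recording(small_cfg)
    return rec, gt


@pytest.fixture
def noise_recording(rng):
    """Plain white-noise recording with an EMG burst train."""
    fs = 500.0
    n = int(40 * fs)
    data = rng.standard_normal((4, n))
    emg = 0.01 * rng.standard_normal(n)
    for onset in (int(8 * fs), int(16 * fs), int(24 * fs), int(32 * fs)):
        emg[onset : onset + int(fs)] += rng.standard_normal(int(fs))
    return Recording(
        data=data, fs=fs, channel_ids=["a", "b", "c", "d"], emg=emg
    )
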