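import numpy as np
import pytest

import freqtag as ft
from freqtag.validation import SMALL_GRID_16


@pytest.fixture(scope="session")
def montage60():
    return ft.make_montage(60)


@pytest.fixture(scope="session")
def montage64():
    return ft.make_montage(64)


@pytest.fixture(scope="session")
def montage16(montage60):
    return montage60.subset(list(SMALL_GRID_16))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def sine_evoked(amp=1.0, freq=1.0, fs=100.0, n=500, n_channels=1, phase=0.0):
    t = np.arange(n) / fs
    row = amp * np.sin(2 * np.pi * freq * t + phase)
    data = np.tile(row, (n_channels, 1))
    labels = [f"ch{i}" for i in range(n_channels)]
    return ft.Evoked(data=data, fs=fs, labels=labels, t0=1.0, n_trials_averaged=1)
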