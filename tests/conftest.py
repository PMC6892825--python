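import numpy as np
import pytest

from mslab.io import Recording
from mslab.montage import CHANNELS_1020, standard_1020_positions
from mslab.synthetic import SimulationSpec, make_templates


@pytest.fixture(scope="session")
def montage():
    return standard_1020_positions()


@pytest.fixture(scope="session")
def templates():
    return make_templates(4, seed=7)


@pytest.fixture()
def small_spec():
    """A light cohort spec for fast end-to-end tests."""
    return SimulationSpec(
        n_subjects_per_group={"DS": 3, "DS-AD": 3},
        epochs_per_subject=(30, 40),
        seed=11,
    )


def make_recording(data, fs=1000.0, reference="raw"):
    data = np.atleast_2d(np.asarray(data, dtype=float))
    n_ch = data.shape[0]
    return Recording(
        data=data, fs=fs, ch_names=list(CHANNELS_1020[:n_ch]),
        montage=standard_1020_positions()[:n_ch], reference=reference,
    )


@pytest.fixture()
def sine_recording():
    """19-channel recording carrying a pure sine, for filter tests."""
    def _make(freq, fs=1000.0, seconds=5.0):
        t = np.arange(int(seconds * fs)) / fs
        wave = np.sin(2 * np.pi * freq * t)
        data = np.tile(wave, (19, 1)) * np.linspace(0.5, 1.5, 19)[:, None]
        return make_recording(data, fs=fs)
    return _make
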