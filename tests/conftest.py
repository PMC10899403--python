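"""Shared fixtures: tiny simulated recordings and cohorts.

Everything is generated at test time from fixed seeds; no data files.
"""

import numpy as np
import pytest

from eegmdd import montage, simulate
from eegmdd.preprocess import Recording


@pytest.fixture(scope="session")
def tiny_spec():
    """Desk-scale spec shrunk further for unit tests: 6 subjects, 40 s."""
    return simulate.SimulationSpec(n_mdd=3, n_hc=3, duration_s=40.0, seed=7)


@pytest.fixture(scope="session")
def hc_meta():
    return simulate.SubjectMeta(subject_id="sub-hc", group="HC", sex="F",
                                age=30.0, hdrs17=None, hama=None)


@pytest.fixture(scope="session")
def mdd_meta():
    return simulate.SubjectMeta(subject_id="sub-mdd", group="MDD", sex="M",
                                age=28.0, hdrs17=24.0, hama=20.0)


@pytest.fixture(scope="session")
def clean_recording(tiny_spec, hc_meta):
    """One artifact-free 40-s eyes-open recording."""
    return simulate.generate_recording(tiny_spec, hc_meta, "EO", subject_seed=11)


def make_tone(freq_hz, fs=500.0, duration_s=20.0, amplitude_uv=10.0,
              n_channels=19, subject_id="tone"):
    """Recording whose every channel is the same sinusoid."""
    t = np.arange(int(duration_s * fs)) / fs
    x = amplitude_uv * np.sin(2 * np.pi * freq_hz * t)
    return Recording(subject_id=subject_id, eye_state="EO", sampling_rate_hz=fs,
                     channel_labels=montage.CHANNELS[:n_channels],
                     samples=np.tile(x, (n_channels, 1)))


@pytest.fixture
def tone_10hz():
    return make_tone(10.0)
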