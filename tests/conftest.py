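import numpy as np
import pytest

from iscpipe.layout import ClipLayout
from iscpipe.recording import MultiSubjectRecording, default_channel_labels
from iscpipe.synthkit import SynthConfig, generate_eeg


def make_recording(data_by_subject, fs=100.0, clip_lengths=None, n_blocks=1):
    """Recording from a dict of (channels, samples) arrays."""
    subjects = list(data_by_subject)
    n_ch, n = next(iter(data_by_subject.values())).shape
    duration = n / fs / n_blocks
    layout = ClipLayout.from_clip_lengths(clip_lengths or [duration], n_blocks)
    return MultiSubjectRecording(
        subjects=subjects,
        data={s: np.asarray(v, dtype=float) for s, v in data_by_subject.items()},
        fs=fs,
        channel_labels=default_channel_labels(n_ch),
        layout=layout,
    )


@pytest.fixture
def small_cfg():
    return SynthConfig(n_subjects=4, n_channels=6, fs=100.0, duration=30.0, seed=7)


@pytest.fixture
def identical_rec():
    """All subjects carry the identical shared signal: noise-free, no gains."""
    cfg = SynthConfig(n_subjects=4, n_channels=6, fs=100.0, duration=20.0,
                      noise_sd=0.0, base_gain=1.0,
                      movement_gains={"arm": 0.0, "leg": 0.0, "both": 0.0},
                      seed=11)
    rec, gt = generate_eeg(cfg)
    return rec, gt


@pytest.fixture
def noise_rec():
    """Independent-noise subjects: no shared signal at all."""
    cfg = SynthConfig(n_subjects=5, n_channels=6, fs=100.0, duration=30.0,
                      noise_sd=1.0, base_gain=0.0,
                      movement_gains={"arm": 0.0, "leg": 0.0, "both": 0.0},
                      seed=13)
    rec, gt = generate_eeg(cfg)
    return rec, gt
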