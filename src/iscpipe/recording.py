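"""Aligned multi-subject EEG recordings."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .layout import ClipLayout


def default_channel_labels(n: int) -> list[str]:
    """Label channels with a 10-20-ish montage when n fits, else generic names."""
    montage32 = [
        "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8", "FC5", "FC1", "FC2", "FC6",
        "T7", "C3", "Cz", "C4", "T8", "CP5", "CP1", "CP2", "CP6", "P7", "P3",
        "Pz", "P4", "P8", "PO7", "PO3", "POz", "PO4", "PO8", "O1", "O2",
    ]
    if n <= len(montage32):
        return montage32[:n]
    return montage32 + [f"CH{i}" for i in range(len(montage32), n)]


@dataclass
class MultiSubjectRecording:
    """Per-subject channels x samples matrices aligned on a common time base.

    Invariants: all subjects share channel count, sample count and sampling
    rate; the sample count is consistent with the clip layout.
    """

    subjects: list[str]
    data: dict[str, np.ndarray]  # subject -> (channels, samples)
    fs: float
    channel_labels: list[str]
    layout: ClipLayout = field(default_factory=ClipLayout)

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if set(self.subjects) != set(self.data):
            raise ValueError("subjects and data keys disagree")
        shapes = {self.data[s].shape for s in self.subjects}
        if len(shapes) != 1:
            raise ValueError(f"subjects have mismatched shapes: {shapes}")
        n_ch, _ = shapes.pop()
        if n_ch != len(self.channel_labels):
            raise ValueError("channel_labels length does not match data")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_channels(self) -> int:
        return len(self.channel_labels)

    @property
    def n_samples(self) -> int:
        return self.data[self.subjects[0]].shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def stack(self) -> np.ndarray:
        """(subjects, channels, samples) array in subject order."""
        return np.stack([self.data[s] for s in self.subjects])

    def with_data(self, stacked: np.ndarray) -> "MultiSubjectRecording":
        """New recording from a (subjects, channels, samples) array."""
        return replace(
            self, data={s: stacked[i].copy() for i, s in enumerate(self.subjects)}
        )

    def copy(self) -> "MultiSubjectRecording":
        return self.with_data(self.stack())
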