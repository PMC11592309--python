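"""In-memory containers for raw and epoched single-channel EEG recordings."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

EPOCH_SECONDS = 30.0
DEFAULT_FS = 100.0
EPOCH_SAMPLES = int(DEFAULT_FS * EPOCH_SECONDS)  # 3000


@dataclass
class RawRecording:
    """A continuous single-channel EEG trace plus its hypnogram annotations.

    Parameters
    ----------
    samples : ndarray
        Signal in microvolts.
    sampling_rate : float
        Samples per second (Hz).
    channel_name : str
        EDF channel label, e.g. ``"EEG Fpz-Cz"``.
    annotations : list of (onset_s, duration_s, label) tuples
        Hypnogram spans; onsets must be non-decreasing.
    """

    samples: np.ndarray
    sampling_rate: float
    channel_name: str = "EEG Fpz-Cz"
    annotations: list[tuple[float, float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        onsets = [a[0] for a in self.annotations]
        if any(b < a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("annotation onsets must be non-decreasing")

    @property
    def duration_seconds(self) -> float:
        return len(self.samples) / self.sampling_rate


@dataclass
class EpochedRecording:
    """One night's EEG as aligned 30 s epochs and 5-class stage labels.

    ``epochs`` has shape (n_epochs, 3000) at 100 Hz; ``labels`` holds the
    integer stage codes 0..4 (W, N1, N2, N3, REM) of :mod:`wavesleep.stages`.
    """

    epochs: np.ndarray
    labels: np.ndarray
    sampling_rate: float = DEFAULT_FS
    night_id: str = ""
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.epochs = np.atleast_2d(np.asarray(self.epochs, dtype=float))
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.epochs) != len(self.labels):
            raise ValueError(
                f"{len(self.epochs)} epochs but {len(self.labels)} labels"
            )
        expected = int(self.sampling_rate * EPOCH_SECONDS)
        if self.epochs.shape[0] and self.epochs.shape[1] != expected:
            raise ValueError(
                f"epochs have {self.epochs.shape[1]} samples, expected {expected}"
            )

    @property
    def n_epochs(self) -> int:
        return len(self.labels)

    def __len__(self) -> int:
        return self.n_epochs
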