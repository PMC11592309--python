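"""Reading, filtering, epoching and label mapping for single-channel EEG.

The processing order mirrors a standard sleep-cassette workflow: read the
EDF and its hypnogram, band-pass filter the continuous record, cut it into
non-overlapping 30 s epochs aligned to the annotation grid, map R&K labels
onto the 5-class AASM scheme (merging stages 3 and 4 into N3, discarding
MOVEMENT/UNKNOWN), and finally trim each night to the sleep period plus a
30 min wake margin on either side.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
from scipy import signal

from .edf import read_hypnogram_text
from .recording import EPOCH_SECONDS, EpochedRecording, RawRecording

#: Hypnogram label -> AASM stage code (0..4) or None for epochs to discard.
#: Accepts bare R&K symbols, Sleep-EDF style annotation strings, and AASM
#: names themselves, so the mapping is idempotent on its output alphabet.
_LABEL_MAP: dict[str, int | None] = {
    "W": 0, "1": 1, "2": 2, "3": 3, "4": 3, "R": 4,
    "N1": 1, "N2": 2, "N3": 3, "REM": 4,
    "MOVEMENT": None, "UNKNOWN": None, "?": None,
    "SLEEP STAGE W": 0, "SLEEP STAGE 1": 1, "SLEEP STAGE 2": 2,
    "SLEEP STAGE 3": 3, "SLEEP STAGE 4": 3, "SLEEP STAGE R": 4,
    "SLEEP STAGE ?": None, "MOVEMENT TIME": None,
}

_TEXT_SUFFIXES = {".txt", ".tsv", ".csv"}


def read_recording(edf_path, hypnogram_path, channel: str = "EEG Fpz-Cz") -> RawRecording:
    """Load an EDF file and its hypnogram into a :class:`RawRecording`.

    The hypnogram may be an EDF+ annotation file or the plain two-column
    text dialect; the dialect is chosen by file suffix.  Samples are
    returned in microvolts at the header sampling rate.
    """
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(edf_path, preload=True, verbose="error")
    if channel not in raw.ch_names:
        raise ValueError(
            f"channel {channel!r} not found; available channels: {raw.ch_names}"
        )
    data = raw.get_data(picks=[channel])[0] * 1e6  # mne loads volts
    fs = float(raw.info["sfreq"])

    hypnogram_path = Path(hypnogram_path)
    if hypnogram_path.suffix.lower() in _TEXT_SUFFIXES:
        annotations = read_hypnogram_text(hypnogram_path)
    else:
        ann = mne.read_annotations(hypnogram_path)
        annotations = [
            (float(o), float(d), str(t))
            for o, d, t in zip(ann.onset, ann.duration, ann.description)
        ]
    return RawRecording(
        samples=data, sampling_rate=fs, channel_name=channel, annotations=annotations
    )


def bandpass_filter(rec: RawRecording, low_hz: float = 0.5, high_hz: float = 49.0) -> RawRecording:
    """Zero-phase 4th-order Butterworth band-pass of the continuous record.

    The upper edge is clipped just below Nyquist when necessary (a nominal
    0.5-100 Hz band at fs=100 collapses to 0.5-49 Hz).
    """
    if low_hz < 0:
        raise ValueError("low_hz must be >= 0")
    nyq = rec.sampling_rate / 2.0
    high = min(high_hz, 0.98 * nyq)
    if low_hz >= high:
        raise ValueError(f"low edge {low_hz} Hz >= effective high edge {high} Hz")
    if low_hz == 0:
        sos = signal.butter(4, high, btype="lowpass", fs=rec.sampling_rate, output="sos")
    else:
        sos = signal.butter(
            4, [low_hz, high], btype="bandpass", fs=rec.sampling_rate, output="sos"
        )
    filtered = signal.sosfiltfilt(sos, rec.samples)
    return RawRecording(
        samples=filtered,
        sampling_rate=rec.sampling_rate,
        channel_name=rec.channel_name,
        annotations=list(rec.annotations),
    )


def _normalize_label(text: str) -> str:
    return " ".join(text.strip().upper().split())


def map_labels(
    annotations: list[tuple[float, float, str]],
    epoch_seconds: float = EPOCH_SECONDS,
) -> tuple[np.ndarray, np.ndarray]:
    """Expand hypnogram spans to per-epoch AASM codes plus a keep mask.

    Returns ``(codes, keep)`` aligned to the epoch grid covered by the
    annotations.  MOVEMENT/UNKNOWN epochs get code -1 and ``keep=False``;
    epochs not covered by any span are likewise flagged for removal.
    """
    if not annotations:
        return np.empty(0, dtype=int), np.empty(0, dtype=bool)
    end = max(onset + duration for onset, duration, _ in annotations)
    n_epochs = int(np.floor(end / epoch_seconds + 1e-9))
    codes = np.full(n_epochs, -1, dtype=int)
    keep = np.zeros(n_epochs, dtype=bool)
    for onset, duration, text in annotations:
        key = _normalize_label(text)
        if key not in _LABEL_MAP:
            raise ValueError(
                f"unknown hypnogram label {text!r} "
                f"(span onset={onset}s duration={duration}s)"
            )
        code = _LABEL_MAP[key]
        first = int(np.floor(onset / epoch_seconds + 1e-9))
        last = int(np.floor((onset + duration) / epoch_seconds + 1e-9))
        for e in range(first, min(last, n_epochs)):
            if code is None:
                codes[e], keep[e] = -1, False
            else:
                codes[e], keep[e] = code, True
    if keep.any() and not keep.all():
        warnings.warn(
            f"discarding {int((~keep).sum())} MOVEMENT/UNKNOWN/uncovered epochs",
            stacklevel=2,
        )
    if not keep.any():
        warnings.warn("no usable epochs after label mapping", stacklevel=2)
    return codes, keep


def epoch_recording(
    rec: RawRecording,
    codes: np.ndarray,
    keep: np.ndarray,
    night_id: str = "",
    subject_id: str = "",
) -> EpochedRecording:
    """Cut the continuous signal into labelled 30 s epochs.

    Epochs flagged for removal are dropped and the survivors re-indexed
    contiguously; a trailing partial epoch is discarded.  Inputs that are
    not sampled at 100 Hz are rejected rather than resampled.
    """
    if not np.isclose(rec.sampling_rate, 100.0):
        raise ValueError(
            f"expected 100 Hz input, got {rec.sampling_rate} Hz (resampling not supported)"
        )
    spe = int(round(rec.sampling_rate * EPOCH_SECONDS))
    n_signal = len(rec.samples) // spe
    n = min(n_signal, len(codes))
    if n == 0:
        raise ValueError("recording shorter than one epoch")
    epochs = rec.samples[: n * spe].reshape(n, spe)
    mask = keep[:n]
    return EpochedRecording(
        epochs=epochs[mask],
        labels=codes[:n][mask],
        sampling_rate=rec.sampling_rate,
        night_id=night_id,
        subject_id=subject_id,
    )


def trim_to_sleep_period(rec: EpochedRecording, margin_minutes: float = 30.0) -> EpochedRecording:
    """Keep the sleep period plus a wake margin on each side.

    Sleep onset is the first epoch labelled anything other than W; the
    window runs from (onset - margin) to (final non-W epoch + margin),
    clipped to the recording bounds.
    """
    non_wake = np.flatnonzero(rec.labels != 0)
    if non_wake.size == 0:
        raise ValueError("no sleep period: every epoch is labelled W")
    margin_epochs = int(round(margin_minutes * 60.0 / EPOCH_SECONDS))
    start = max(0, int(non_wake[0]) - margin_epochs)
    stop = min(rec.n_epochs, int(non_wake[-1]) + 1 + margin_epochs)
    return EpochedRecording(
        epochs=rec.epochs[start:stop],
        labels=rec.labels[start:stop],
        sampling_rate=rec.sampling_rate,
        night_id=rec.night_id,
        subject_id=rec.subject_id,
    )
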