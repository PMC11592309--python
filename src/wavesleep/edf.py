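"""Minimal EDF (European Data Format) writing and hypnogram text I/O.

Reading EDF goes through :mod:`mne` (see :mod:`wavesleep.preprocessing`);
this module provides the complementary 16-bit EDF *writer* used to export
synthetic nights, plus the plain two-column hypnogram dialect
(``epoch_index<TAB>stage``) used by the synthetic fixtures.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .recording import EPOCH_SECONDS
from .stages import STAGES

_DIG_MAX = 32767


def _field(text: str, width: int) -> bytes:
    b = text.encode("ascii")
    if len(b) > width:
        raise ValueError(f"EDF header field {text!r} exceeds {width} bytes")
    return b.ljust(width)


def write_edf(
    path,
    samples: np.ndarray,
    sampling_rate: float = 100.0,
    channel_name: str = "EEG Fpz-Cz",
    physical_unit: str = "uV",
) -> None:
    """Write a single-channel EDF file with 1 s data records.

    Samples are quantized to 16 bits over a symmetric physical range; the
    trailing partial record, if any, is zero-padded.
    """
    samples = np.asarray(samples, dtype=float).ravel()
    fs = int(round(sampling_rate))
    if not np.isclose(fs, sampling_rate):
        raise ValueError("sampling_rate must be an integer number of Hz")
    n_records = int(np.ceil(len(samples) / fs)) if len(samples) else 0
    padded = np.zeros(n_records * fs)
    padded[: len(samples)] = samples

    phys_max = float(np.max(np.abs(padded))) if padded.size else 1.0
    if phys_max == 0.0:
        phys_max = 1.0
    scale = _DIG_MAX / phys_max
    digital = np.clip(np.round(padded * scale), -_DIG_MAX, _DIG_MAX).astype("<i2")

    header = b"".join(
        [
            _field("0", 8),
            _field("X X X X", 80),                 # patient id
            _field("Startdate X X X X", 80),       # recording id
            _field("01.01.00", 8),
            _field("00.00.00", 8),
            _field(str(256 + 256), 8),             # header bytes: 1 signal
            _field("", 44),
            _field(str(n_records), 8),
            _field("1", 8),                        # record duration, seconds
            _field("1", 4),
        ]
    )
    sig = b"".join(
        [
            _field(channel_name, 16),
            _field("", 80),                        # transducer
            _field(physical_unit, 8),
            _field(f"{-phys_max:.6g}"[:8], 8),
            _field(f"{phys_max:.6g}"[:8], 8),
            _field(str(-_DIG_MAX), 8),
            _field(str(_DIG_MAX), 8),
            _field("", 80),                        # prefiltering
            _field(str(fs), 8),
            _field("", 32),
        ]
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig)
        fh.write(digital.tobytes())


def write_hypnogram_text(path, labels: np.ndarray) -> None:
    """Write per-epoch stage codes as ``epoch_index<TAB>stage_name`` lines."""
    labels = np.asarray(labels, dtype=int)
    with open(path, "w") as fh:
        fh.write("# epoch\tstage\n")
        for i, lab in enumerate(labels):
            fh.write(f"{i}\t{STAGES[lab]}\n")


def read_hypnogram_text(path) -> list[tuple[float, float, str]]:
    """Read the two-column dialect into (onset_s, duration_s, label) spans."""
    annotations = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"malformed hypnogram line: {line!r}")
        idx, label = int(parts[0]), parts[1]
        annotations.append((idx * EPOCH_SECONDS, EPOCH_SECONDS, label))
    return annotations
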