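"""Four-level DWT sub-band decomposition of 30 s EEG epochs.

Each epoch x(t) is split into five time-domain component signals
d1..d4 (detail levels) and a4 (level-4 approximation) such that
x = a4 + d4 + d3 + d2 + d1 exactly.  Components are obtained by
single-branch inverse reconstruction: all other coefficient bands are
zeroed and the inverse transform taken, so every component has the full
epoch length and the additivity identity holds to machine precision.
At fs = 100 Hz the nominal dyadic bands are d1 25-50, d2 12.5-25,
d3 6.25-12.5, d4 3.125-6.25 and a4 0-3.125 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

#: The 20 wavelet functions the pipeline supports, four from each of five
#: families (Daubechies, Symlets, Coiflets, Biorthogonal, Reverse
#: biorthogonal).  db4 is the default.
WAVELET_FUNCTIONS: tuple[str, ...] = (
    "bior1.1", "bior2.2", "bior3.3", "bior4.4",
    "coif1", "coif2", "coif3", "coif4",
    "db2", "db4", "db6", "db8",
    "rbio1.1", "rbio2.2", "rbio3.3", "rbio4.4",
    "sym2", "sym4", "sym6", "sym8",
)

BAND_NAMES: tuple[str, ...] = ("d1", "d2", "d3", "d4", "a4")

DEFAULT_LEVELS = 4
_BOUNDARY_MODE = "symmetric"


def nominal_bands(fs: float = 100.0, levels: int = DEFAULT_LEVELS) -> dict[str, tuple[float, float]]:
    """Dyadic (low_hz, high_hz) band edges for each component at rate fs."""
    bands = {}
    hi = fs / 2.0
    for level in range(1, levels + 1):
        lo = hi / 2.0
        bands[f"d{level}"] = (lo, hi)
        hi = lo
    bands[f"a{levels}"] = (0.0, hi)
    return bands


@dataclass
class SubBandSet:
    """Five reconstructed sub-band signals of one epoch."""

    components: dict[str, np.ndarray]
    wavelet_name: str
    nominal_bands: dict[str, tuple[float, float]]
    sampling_rate: float = 100.0

    def __getitem__(self, band: str) -> np.ndarray:
        return self.components[band]

    def stacked(self) -> np.ndarray:
        """Components as a (5, epoch_length) array in d1..d4, a4 order."""
        return np.stack([self.components[b] for b in BAND_NAMES])

    def reconstruct(self) -> np.ndarray:
        """Sum of the five components; equals the input epoch."""
        return self.stacked().sum(axis=0)


def list_wavelets() -> tuple[str, ...]:
    """The supported wavelet function names."""
    return WAVELET_FUNCTIONS


def decompose(
    epoch: np.ndarray,
    wavelet_name: str = "db4",
    levels: int = DEFAULT_LEVELS,
    fs: float = 100.0,
) -> SubBandSet:
    """Decompose one epoch into its five sub-band component signals."""
    if wavelet_name not in WAVELET_FUNCTIONS:
        raise ValueError(
            f"unknown wavelet {wavelet_name!r}; choose one of {WAVELET_FUNCTIONS}"
        )
    x = np.asarray(epoch, dtype=float)
    if x.ndim != 1:
        raise ValueError("epoch must be one-dimensional")
    wavelet = pywt.Wavelet(wavelet_name)
    max_level = pywt.dwt_max_level(len(x), wavelet.dec_len)
    if levels > max_level:
        raise ValueError(
            f"epoch of length {len(x)} supports at most {max_level} levels "
            f"with {wavelet_name}"
        )
    coeffs = pywt.wavedec(x, wavelet, level=levels, mode=_BOUNDARY_MODE)
    # coeffs = [aL, dL, dL-1, ..., d1]
    components: dict[str, np.ndarray] = {}
    for idx in range(len(coeffs)):
        branch = [np.zeros_like(c) for c in coeffs]
        branch[idx] = coeffs[idx]
        rec = pywt.waverec(branch, wavelet, mode=_BOUNDARY_MODE)[: len(x)]
        name = f"a{levels}" if idx == 0 else f"d{levels - idx + 1}"
        components[name] = rec
    return SubBandSet(
        components=components,
        wavelet_name=wavelet_name,
        nominal_bands=nominal_bands(fs, levels),
        sampling_rate=fs,
    )
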