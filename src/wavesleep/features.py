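"""Multi-domain feature extraction for sub-band decomposed EEG epochs.

Per epoch, each of the five sub-band signals contributes 19 features:

* 7 time-domain — absolute mean (MA), population standard deviation (Std),
  skewness (Ske), kurtosis (Kur), and the Hjorth activity/mobility/
  complexity triplet (HA, HM, HC) with derivatives taken as first
  differences;
* 7 frequency-domain — mean, standard deviation, skewness, kurtosis and
  mean square of the FFT magnitude spectrum, plus the average power
  spectral density (Mpsd) and total power (P) from the periodogram;
* 5 nonlinear — approximate entropy (AE), differential entropy (DE),
  Shannon entropy (SE), C0 complexity (CC) and Higuchi fractal
  dimension (FD).

The 10 ordered inter-band power ratios (Pd1/d2 ... Pd4/a4) complete the
105-dimensional epoch feature vector.  All guards (zero variance, zero
power) return finite sentinel values so no NaN ever reaches the
classifier.  This module is fully deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy import signal as _signal

from .recording import EpochedRecording
from .wavelets import BAND_NAMES, SubBandSet, decompose

DE_FLOOR = -30.0      # floor for differential entropy of ~zero-variance input
RATIO_EPS = 1e-12     # added to power-ratio denominators

TIME_FEATURE_NAMES = ("MA", "Std", "Ske", "Kur", "HA", "HM", "HC")
FREQ_FEATURE_NAMES = ("Fmean", "Fstd", "Fske", "Fkur", "Fms", "Mpsd", "P")
NONLINEAR_FEATURE_NAMES = ("AE", "DE", "SE", "CC", "FD")
RATIO_PAIRS = (
    ("d1", "d2"), ("d1", "d3"), ("d1", "d4"), ("d1", "a4"),
    ("d2", "d3"), ("d2", "d4"), ("d2", "a4"),
    ("d3", "d4"), ("d3", "a4"), ("d4", "a4"),
)

N_FEATURES = 105


@dataclass
class FeatureConfig:
    """Tunable parameters of the nonlinear features."""

    ae_m: int = 2                 # approximate-entropy template length
    ae_r_mult: float = 0.2        # tolerance r = mult * Std(x)
    se_bins: int = 16             # Shannon-entropy histogram bins
    higuchi_t_max: int = 10       # largest Higuchi interval
    mean_square_of: str = "spectrum"   # "spectrum" (|X|^2) or "signal"


# ---------------------------------------------------------------- time domain

def time_features(x: np.ndarray) -> np.ndarray:
    """MA, Std, Ske, Kur, HA, HM, HC of one signal (population moments)."""
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    mean = x.mean()
    constant = x.min() == x.max()
    var = 0.0 if constant else np.mean((x - mean) ** 2)
    std = np.sqrt(var)
    ma = np.abs(x).mean()
    if std > 0:
        z = (x - mean) / std
        ske = np.mean(z**3)
        kur = np.mean(z**4)
    else:
        ske = kur = 0.0
    ha = var
    dx = np.diff(x)
    var_dx = np.mean((dx - dx.mean()) ** 2)
    if var > 0:
        hm = np.sqrt(var_dx / var)
    else:
        warnings.warn("constant signal: Hjorth mobility undefined, returning 0",
                      stacklevel=2)
        hm = 0.0
    if var_dx > 0 and hm > 0:
        ddx = np.diff(dx)
        var_ddx = np.mean((ddx - ddx.mean()) ** 2)
        hc = np.sqrt(var_ddx / var_dx) / hm
    else:
        hc = 0.0
    return np.array([ma, std, ske, kur, ha, hm, hc])


# ----------------------------------------------------------- frequency domain

def frequency_features(
    x: np.ndarray, fs: float = 100.0, mean_square_of: str = "spectrum"
) -> np.ndarray:
    """Statistics of the magnitude spectrum plus Mpsd and total power P.

    Mpsd is the mean of the periodogram PSD bins and P its trapezoidal
    integral over frequency.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 8:
        raise ValueError("need at least 8 samples")
    mag = np.abs(np.fft.rfft(x))
    mean = mag.mean()
    var = np.mean((mag - mean) ** 2)
    std = np.sqrt(var)
    if std > 0:
        z = (mag - mean) / std
        ske, kur = np.mean(z**3), np.mean(z**4)
    else:
        ske = kur = 0.0
    if mean_square_of == "spectrum":
        ms = np.mean(mag**2)
    elif mean_square_of == "signal":
        ms = np.mean(x**2)
    else:
        raise ValueError("mean_square_of must be 'spectrum' or 'signal'")
    freqs, psd = _signal.periodogram(x, fs=fs)
    mpsd = psd.mean()
    p = np.trapezoid(psd, freqs)
    return np.array([mean, std, ske, kur, ms, mpsd, p])


def band_power(x: np.ndarray, fs: float = 100.0) -> float:
    """Total periodogram power P = ∫ PSD(w) dw of one signal."""
    freqs, psd = _signal.periodogram(np.asarray(x, dtype=float), fs=fs)
    return float(np.trapezoid(psd, freqs))


def power_ratios(p_by_band: np.ndarray) -> np.ndarray:
    """The 10 ordered inter-band power ratios Pd1/d2 ... Pd4/a4."""
    p = np.asarray(p_by_band, dtype=float)
    if p.shape != (5,):
        raise ValueError("expected five band powers (d1, d2, d3, d4, a4)")
    if np.any(p < 0):
        raise ValueError("band powers must be non-negative")
    by_name = dict(zip(BAND_NAMES, p))
    return np.array(
        [by_name[num] / (by_name[den] + RATIO_EPS) for num, den in RATIO_PAIRS]
    )


# --------------------------------------------------------------- nonlinear

@njit(cache=True)
def _apen_phis(x: np.ndarray, m: int, r: float) -> tuple[float, float]:
    """Φ_m(r) and Φ_{m+1}(r) with max-norm template matching, self-matches
    included.

    Templates are visited in order of their first element, so only pairs
    already within r in that coordinate are checked against the remaining
    coordinates (a sorted two-pointer sweep); the counts are identical to
    the quadratic double loop over all template pairs.
    """
    n = x.shape[0]
    n_m = n - m + 1        # templates of length m
    n_m1 = n - m           # templates of length m+1
    order = np.argsort(x[:n_m])
    xs = x[:n_m][order]
    c_m = np.ones(n_m)     # self-matches
    c_m1 = np.ones(n_m1)
    hi = 0
    for a in range(n_m):
        if hi < a + 1:
            hi = a + 1
        while hi < n_m and xs[hi] - xs[a] <= r:
            hi += 1
        i0 = order[a]
        for b in range(a + 1, hi):
            j0 = order[b]
            match = True
            for k in range(1, m):
                if abs(x[i0 + k] - x[j0 + k]) > r:
                    match = False
                    break
            if match:
                c_m[i0] += 1.0
                c_m[j0] += 1.0
                if i0 < n_m1 and j0 < n_m1 and abs(x[i0 + m] - x[j0 + m]) <= r:
                    c_m1[i0] += 1.0
                    c_m1[j0] += 1.0
    phi_m = 0.0
    for i in range(n_m):
        phi_m += np.log(c_m[i] / n_m)
    phi_m /= n_m
    phi_m1 = 0.0
    for i in range(n_m1):
        phi_m1 += np.log(c_m1[i] / n_m1)
    phi_m1 /= n_m1
    return phi_m, phi_m1


def approximate_entropy(x: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """Approximate entropy AE = Φ_m(r) − Φ_{m+1}(r).

    ``r`` defaults to 0.2 × Std(x).  A constant signal has AE = 0.
    """
    x = np.asarray(x, dtype=float)
    if x.size <= m + 1:
        raise ValueError(f"need more than m+1={m + 1} samples")
    if x.min() == x.max():
        return 0.0  # all templates identical at any tolerance
    if r is None:
        r = 0.2 * float(np.sqrt(np.mean((x - x.mean()) ** 2)))
    if r <= 0:
        raise ValueError("tolerance r must be positive")
    phi_m, phi_m1 = _apen_phis(x, m, float(r))
    return float(phi_m - phi_m1)


def shannon_entropy(x: np.ndarray, n_bins: int = 16) -> float:
    """Histogram estimate of −Σ p log p (natural log) over n_bins bins."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    x = np.asarray(x, dtype=float)
    if x.min() == x.max():
        return 0.0
    counts, _ = np.histogram(x, bins=n_bins)
    p = counts[counts > 0] / x.size
    return float(-np.sum(p * np.log(p)))


def differential_entropy(x: np.ndarray) -> float:
    """DE = ½ log(2πσ²) with σ² the population variance, floored at −30.

    This is the Gaussian closed form as used throughout the pipeline (note
    it omits the additive ½ of the exact Gaussian differential entropy).
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    var = float(np.mean((x - x.mean()) ** 2))
    if var <= 0 or x.min() == x.max():
        return DE_FLOOR
    return max(0.5 * float(np.log(2.0 * np.pi * var)), DE_FLOOR)


def c0_complexity(x: np.ndarray) -> float:
    """Fraction of energy outside above-mean-power spectral components.

    Bins of the FFT whose power exceeds the mean power form the regular
    part y; CC = Σ|x−y|² / Σ|x|² ∈ [0, 1].
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    total = float(np.sum(x**2))
    if total == 0.0:
        return 0.0
    spec = np.fft.fft(x)
    power = np.abs(spec) ** 2
    mean_power = power.mean()
    y = np.fft.ifft(np.where(power > mean_power, spec, 0.0))
    residual = float(np.sum(np.abs(x - y) ** 2))
    return residual / total


def higuchi_fd(x: np.ndarray, t_max: int = 10) -> float:
    """Higuchi fractal dimension from multi-scale curve lengths.

    For each interval T the T decimated sub-series lengths are averaged;
    the FD is the slope of ln L(T) against ln(1/T).
    """
    if t_max < 2:
        raise ValueError("t_max must be >= 2")
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 10 * t_max:
        raise ValueError(f"need at least {10 * t_max} samples for t_max={t_max}")
    log_l = np.empty(t_max)
    for k in range(1, t_max + 1):
        lengths = np.empty(k)
        for m in range(k):
            sub = x[m::k]
            n_int = sub.size - 1
            if n_int < 1:
                lengths[m] = 0.0
                continue
            norm = (n - 1) / (n_int * k)
            lengths[m] = np.sum(np.abs(np.diff(sub))) * norm / k
        mean_len = lengths.mean()
        if mean_len <= 0:
            return 0.0  # flat signal: curve length vanishes at every scale
        log_l[k - 1] = np.log(mean_len)
    log_inv_t = -np.log(np.arange(1, t_max + 1, dtype=float))
    slope = np.polyfit(log_inv_t, log_l, 1)[0]
    return float(slope)


# --------------------------------------------------------------- assembly

@dataclass
class FeatureVector:
    """The 105 per-epoch features in fixed documented order."""

    values: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_FEATURES,):
            raise ValueError(f"expected {N_FEATURES} features, got {self.values.shape}")
        if len(self.names) != N_FEATURES:
            raise ValueError("names/values length mismatch")
        if not np.all(np.isfinite(self.values)):
            bad = [n for n, v in zip(self.names, self.values) if not np.isfinite(v)]
            raise ValueError(f"non-finite features: {bad}")


def feature_names() -> tuple[str, ...]:
    """Names of the 105 features: 5 band blocks of 19, then the 10 ratios."""
    names: list[str] = []
    for band in BAND_NAMES:
        for feat in TIME_FEATURE_NAMES + FREQ_FEATURE_NAMES + NONLINEAR_FEATURE_NAMES:
            names.append(f"{band}_{feat}")
    for num, den in RATIO_PAIRS:
        names.append(f"ratio_P{num}/{den}")
    return tuple(names)


_FEATURE_NAMES = feature_names()


def extract_epoch_features(
    bands: SubBandSet, fs: float | None = None, config: FeatureConfig | None = None
) -> FeatureVector:
    """Assemble the 105-dimensional feature vector of one epoch.

    Order: for each band d1, d2, d3, d4, a4 the 7 time + 7 frequency +
    5 nonlinear features, then the 10 inter-band power ratios.
    """
    if config is None:
        config = FeatureConfig()
    if fs is None:
        fs = bands.sampling_rate
    values: list[float] = []
    powers = np.empty(5)
    for bi, band in enumerate(BAND_NAMES):
        x = bands[band]
        try:
            tf = time_features(x)
            ff = frequency_features(x, fs=fs, mean_square_of=config.mean_square_of)
            r = config.ae_r_mult * float(np.std(x))
            nl = [
                approximate_entropy(x, m=config.ae_m, r=r if r > 0 else None),
                differential_entropy(x),
                shannon_entropy(x, n_bins=config.se_bins),
                c0_complexity(x),
                higuchi_fd(x, t_max=config.higuchi_t_max),
            ]
        except ValueError as err:
            raise ValueError(f"feature extraction failed on band {band}: {err}") from err
        powers[bi] = ff[-1]
        values.extend(tf)
        values.extend(ff)
        values.extend(nl)
    values.extend(power_ratios(powers))
    return FeatureVector(values=np.array(values), names=_FEATURE_NAMES)


def extract_night_features(
    rec: EpochedRecording,
    wavelet: str = "db4",
    config: FeatureConfig | None = None,
) -> np.ndarray:
    """Feature matrix (n_epochs × 105) of one epoched night."""
    out = np.empty((rec.n_epochs, N_FEATURES))
    for i in range(rec.n_epochs):
        bands = decompose(rec.epochs[i], wavelet, fs=rec.sampling_rate)
        out[i] = extract_epoch_features(bands, fs=rec.sampling_rate, config=config).values
    return out
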