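"""Feature formulas against closed forms and independent oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wavesleep import (
    approximate_entropy,
    c0_complexity,
    differential_entropy,
    extract_epoch_features,
    feature_names,
    frequency_features,
    higuchi_fd,
    power_ratios,
    shannon_entropy,
    time_features,
)
from wavesleep.features import DE_FLOOR, N_FEATURES
from wavesleep.wavelets import decompose


# ------------------------------------------------------------- time domain

def test_alternating_signal_moments():
    ma, std, ske, kur, ha, hm, hc = time_features(np.array([1.0, -1, 1, -1]))
    assert (ma, std, ske) == (1.0, 1.0, 0.0)
    assert ha == 1.0


def test_constant_signal_guards():
    with pytest.warns(UserWarning, match="mobility"):
        feats = time_features(np.full(100, 3.14))
    assert np.all(feats[1:] == 0.0)  # Std, Ske, Kur, HA, HM, HC


def test_gaussian_sample_matches_direct_formulas(rng):
    x = rng.normal(size=100_000)
    ma, std, ske, kur, ha, hm, hc = time_features(x)
    assert kur == pytest.approx(3.0, abs=0.1)
    assert ske == pytest.approx(0.0, abs=0.05)
    # Hjorth oracle: direct evaluation of the finite-difference definition
    var = np.mean((x - x.mean()) ** 2)
    dx = np.diff(x)
    var_dx = np.mean((dx - dx.mean()) ** 2)
    assert hm == pytest.approx(np.sqrt(var_dx / var), rel=1e-12)
    ddx = np.diff(dx)
    var_ddx = np.mean((ddx - ddx.mean()) ** 2)
    assert hc == pytest.approx(
        np.sqrt(var_ddx / var_dx) / np.sqrt(var_dx / var), rel=1e-12
    )


@settings(max_examples=30, derandomize=True, deadline=None)
@given(seed=st.integers(0, 2**31 - 1))
def test_moments_permutation_invariant_but_dynamics_not(seed):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=200)
    perm = rng.permutation(200)
    a, b = time_features(x), time_features(x[perm])
    assert np.allclose(a[:5], b[:5])          # MA..HA are order-free
    # mobility/complexity depend on sample order (generic permutation)
    assert not np.allclose(a[5:], b[5:])
    assert approximate_entropy(x) != approximate_entropy(x[perm])


# -------------------------------------------------------- frequency domain

def test_zero_signal_frequency_features_vanish():
    assert np.all(frequency_features(np.zeros(3000)) == 0.0)


def test_tone_power_parseval():
    t = np.arange(3000) / 100.0
    for amp in (1.0, 3.0):
        feats = frequency_features(amp * np.sin(2 * np.pi * 5.0 * t), fs=100.0)
        assert feats[-1] == pytest.approx(amp**2 / 2, rel=0.05)  # P = A^2/2


def test_power_scales_quadratically(rng):
    x = rng.normal(size=3000)
    f1 = frequency_features(x)
    f2 = frequency_features(2 * x)
    assert f2[-1] == pytest.approx(4 * f1[-1], rel=1e-9)   # P
    assert f2[-2] == pytest.approx(4 * f1[-2], rel=1e-9)   # Mpsd


def test_power_ratio_order_and_asymmetry():
    assert np.allclose(power_ratios(np.ones(5)), 1.0)
    ratios = power_ratios(np.array([4.0, 2.0, 1.0, 1.0, 1.0]))
    assert ratios[0] == pytest.approx(2.0)      # Pd1/d2
    swapped = power_ratios(np.array([2.0, 4.0, 1.0, 1.0, 1.0]))
    assert swapped[0] == pytest.approx(0.5)     # not symmetric


def test_zero_denominator_ratio_is_large_but_finite():
    ratios = power_ratios(np.array([1.0, 0.0, 1.0, 1.0, 1.0]))
    assert np.isfinite(ratios[0]) and ratios[0] > 1e10


# ------------------------------------------------------------- entropies

def brute_force_apen(x, m=2, r=None):
    """Independent O(n^2) double-loop evaluation of Φ_m − Φ_{m+1}."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if r is None:
        r = 0.2 * np.std(x)

    def phi(mm):
        nm = n - mm + 1
        total = 0.0
        for i in range(nm):
            count = 0.0
            for j in range(nm):
                if max(abs(x[i + k] - x[j + k]) for k in range(mm)) <= r:
                    count += 1.0
            total += math.log(count / nm)
        return total / nm

    return phi(m) - phi(m + 1)


@pytest.mark.parametrize("n", [20, 50, 100])
def test_apen_equals_brute_force_exactly(n, rng):
    for _ in range(5):
        x = rng.normal(size=n)
        assert approximate_entropy(x, m=2) == brute_force_apen(x, m=2)


def test_apen_constant_signal_is_zero():
    assert approximate_entropy(np.full(50, 2.0)) == 0.0


def test_apen_periodic_below_noise(rng):
    periodic = np.tile([0.0, 1.0, -1.0, 0.5], 50)
    noise = rng.normal(size=200)
    assert approximate_entropy(periodic) < approximate_entropy(noise)


def test_apen_parameter_validation():
    with pytest.raises(ValueError, match="r must be positive"):
        approximate_entropy(np.arange(50.0), r=-1.0)
    with pytest.raises(ValueError, match="samples"):
        approximate_entropy(np.array([1.0, 2.0]), m=2)


def test_shannon_entropy_closed_forms():
    # exactly uniform over 16 bins
    x = np.repeat(np.arange(16.0), 10) + 0.25
    assert shannon_entropy(x, n_bins=16) == pytest.approx(np.log(16), rel=1e-12)
    assert shannon_entropy(np.full(100, 1.0)) == 0.0
    two_bins = np.array([0.0] * 50 + [1.0] * 50)
    assert shannon_entropy(two_bins, n_bins=2) == pytest.approx(np.log(2), rel=1e-12)


def test_differential_entropy_closed_forms(rng):
    x = rng.normal(size=10_000)
    x = (x - x.mean()) / x.std()  # exact unit population variance
    assert differential_entropy(x) == pytest.approx(0.5 * np.log(2 * np.pi), rel=1e-9)
    # scaling law: DE(cx) = DE(x) + log|c|
    y = rng.normal(size=1000)
    assert differential_entropy(3 * y) == pytest.approx(
        differential_entropy(y) + np.log(3), rel=1e-9
    )
    z = rng.normal(size=1000)
    z = (z - z.mean()) / z.std() / np.sqrt(2 * np.pi)
    assert differential_entropy(z) == pytest.approx(0.0, abs=1e-9)
    assert differential_entropy(np.full(10, 5.0)) == DE_FLOOR


def test_c0_complexity_bounds_and_ordering(rng):
    t = np.arange(3000) / 100.0
    tone = np.sin(2 * np.pi * 5.0 * t)
    noise = rng.normal(size=3000)
    cc_tone = c0_complexity(tone)
    cc_noise = c0_complexity(noise)
    assert cc_tone == pytest.approx(0.0, abs=1e-3)
    assert cc_tone < cc_noise
    for x in (tone, noise, rng.normal(size=500)):
        assert 0.0 <= c0_complexity(x) <= 1.0
    assert c0_complexity(np.zeros(100)) == 0.0


# ------------------------------------------------------------- Higuchi FD

def test_higuchi_line_has_dimension_one():
    assert higuchi_fd(np.arange(3000.0)) == pytest.approx(1.0, abs=0.05)


def test_higuchi_white_noise_dimension_two():
    fds = [
        higuchi_fd(np.random.default_rng(seed).normal(size=3000))
        for seed in range(20)
    ]
    assert np.mean(fds) == pytest.approx(2.0, abs=0.15)


def test_higuchi_noise_raises_line_dimension(rng):
    line = np.arange(3000.0)
    noisy = line + rng.normal(scale=20.0, size=3000)
    assert higuchi_fd(noisy) > higuchi_fd(line)


def test_higuchi_validation():
    with pytest.raises(ValueError, match="t_max"):
        higuchi_fd(np.arange(3000.0), t_max=1)
    with pytest.raises(ValueError, match="samples"):
        higuchi_fd(np.arange(50.0), t_max=10)


# ------------------------------------------------------------- assembly

def test_epoch_vector_has_105_named_features(random_bands):
    fv = extract_epoch_features(random_bands)
    assert fv.values.shape == (N_FEATURES,)
    assert len(fv.names) == N_FEATURES
    names = feature_names()
    # Table-style accounting: 35 time, 45 frequency (incl. 10 ratios), 25 nonlinear
    time_n = [n for n in names if n.split("_")[-1] in
              ("MA", "Std", "Ske", "Kur", "HA", "HM", "HC")]
    freq_n = [n for n in names if n.split("_")[-1] in
              ("Fmean", "Fstd", "Fske", "Fkur", "Fms", "Mpsd", "P")
              or n.startswith("ratio_")]
    nonlin_n = [n for n in names if n.split("_")[-1] in
                ("AE", "DE", "SE", "CC", "FD")]
    assert (len(time_n), len(freq_n), len(nonlin_n)) == (35, 45, 25)


def test_all_zero_epoch_features_are_guarded():
    bands = decompose(np.zeros(3000), "db4")
    with pytest.warns(UserWarning):
        fv = extract_epoch_features(bands)
    de_idx = [i for i, n in enumerate(fv.names) if n.endswith("_DE")]
    others = np.delete(fv.values, de_idx)
    assert np.all(others == 0.0)
    assert np.all(fv.values[de_idx] == DE_FLOOR)


def test_extraction_is_deterministic(random_bands):
    a = extract_epoch_features(random_bands).values
    b = extract_epoch_features(random_bands).values
    assert np.array_equal(a, b)
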