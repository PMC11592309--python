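"""EDF round trip, filtering oracle, label mapping and sleep-period trimming."""

import numpy as np
import pytest
from scipy import signal as sps

from wavesleep import (
    EpochedRecording,
    RawRecording,
    bandpass_filter,
    map_labels,
    read_recording,
    trim_to_sleep_period,
)
from wavesleep.preprocessing import epoch_recording
from wavesleep.synthetic import export_night


@pytest.fixture(scope="module")
def exported_night(tmp_path_factory, small_night):
    d = tmp_path_factory.mktemp("edf")
    edf, hyp = d / "night.edf", d / "night.txt"
    export_night(small_night, edf, hyp)
    return small_night, edf, hyp


def test_edf_round_trip_within_quantization(exported_night):
    rec, edf, hyp = exported_night
    raw = read_recording(edf, hyp)
    assert raw.sampling_rate == 100.0
    original = rec.epochs.ravel()
    assert raw.samples.shape == original.shape
    quantum = 2 * np.max(np.abs(original)) / (2 * 32767)
    assert np.max(np.abs(raw.samples - original)) <= 2 * quantum
    # hypnogram spans align with the stored labels
    codes, keep = map_labels(raw.annotations)
    assert np.array_equal(codes, rec.labels)
    assert keep.all()


def test_missing_channel_error_names_available(exported_night):
    _, edf, hyp = exported_night
    with pytest.raises(ValueError, match="EEG Fpz-Cz"):
        read_recording(edf, hyp, channel="EEG Pz-Oz")


def test_bandpass_removes_dc_offset():
    rec = RawRecording(samples=np.full(6000, 50.0), sampling_rate=100.0)
    out = bandpass_filter(rec, 0.5, 49.0)
    assert abs(out.samples.mean()) < 0.5  # <1% of the 50 uV offset


@pytest.mark.parametrize(
    "freq,min_gain,max_gain",
    [(10.0, 0.95, 1.05), (0.05, 0.0, 0.1)],  # passband tone kept; slow drift crushed
)
def test_bandpass_gain_matches_designed_response(freq, min_gain, max_gain):
    # oracle: the gain of the designed filter evaluated from its coefficients
    sos = sps.butter(4, [0.5, 49.0], btype="bandpass", fs=100.0, output="sos")
    _, h = sps.sosfreqz(sos, worN=[freq], fs=100.0)
    designed = np.abs(h[0]) ** 2  # filtfilt applies the filter twice
    t = np.arange(120_000) / 100.0
    rec = RawRecording(samples=np.sin(2 * np.pi * freq * t), sampling_rate=100.0)
    out = bandpass_filter(rec, 0.5, 49.0)
    mid = slice(30_000, 90_000)  # ignore transients at the edges
    gain = np.sqrt(np.mean(out.samples[mid] ** 2) / np.mean(rec.samples[mid] ** 2))
    assert min_gain <= gain <= max_gain
    assert gain == pytest.approx(designed, abs=0.03)


def test_band_edges_validated():
    rec = RawRecording(samples=np.zeros(1000), sampling_rate=100.0)
    with pytest.raises(ValueError, match="edge"):
        bandpass_filter(rec, 49.5, 100.0)


def _spans(labels):
    return [(30.0 * i, 30.0, lab) for i, lab in enumerate(labels)]


def test_rk_to_aasm_merge_rule():
    codes, keep = map_labels(_spans(["W", "1", "2", "3", "4", "R"]))
    assert codes.tolist() == [0, 1, 2, 3, 3, 4]
    assert keep.all()


def test_mapping_idempotent_on_aasm_names():
    once, _ = map_labels(_spans(["W", "1", "2", "3", "4", "R"]))
    twice, _ = map_labels(_spans([["W", "N1", "N2", "N3", "REM"][c] for c in once]))
    assert np.array_equal(once, twice)


def test_movement_and_unknown_flagged_for_removal():
    with pytest.warns(UserWarning, match="discarding"):
        codes, keep = map_labels(_spans(["W", "MOVEMENT", "2", "UNKNOWN", "R"]))
    assert keep.tolist() == [True, False, True, False, True]
    assert codes[keep].tolist() == [0, 2, 4]


def test_all_movement_night_warns_empty():
    with pytest.warns(UserWarning, match="no usable"):
        _, keep = map_labels(_spans(["MOVEMENT"] * 4))
    assert not keep.any()


def test_unknown_label_reports_span():
    with pytest.raises(ValueError, match="banana"):
        map_labels(_spans(["W", "banana"]))


def test_removed_epochs_reindexed_contiguously():
    rng = np.random.default_rng(0)
    samples = rng.normal(size=5 * 3000)
    raw = RawRecording(samples=samples, sampling_rate=100.0)
    with pytest.warns(UserWarning):
        codes, keep = map_labels(_spans(["W", "UNKNOWN", "2", "2", "R"]))
    rec = epoch_recording(raw, codes, keep)
    assert rec.n_epochs == 4
    assert np.array_equal(rec.epochs[1], samples[2 * 3000 : 3 * 3000])


def _epoched(labels):
    n = len(labels)
    return EpochedRecording(epochs=np.zeros((n, 3000)), labels=np.array(labels))


def test_trim_keeps_margin_of_60_epochs():
    labels = [0] * 100 + [2] * 10 + [0] * 100
    out = trim_to_sleep_period(_epoched(labels), margin_minutes=30)
    assert out.n_epochs == 60 + 10 + 60
    assert out.labels[0] == 0 and out.labels[60] == 2


def test_trim_clips_at_recording_start():
    labels = [2] * 5 + [0] * 100
    out = trim_to_sleep_period(_epoched(labels))
    assert out.n_epochs == 5 + 60


def test_trim_never_removes_sleep():
    rng = np.random.default_rng(5)
    labels = rng.integers(0, 5, size=300)
    out = trim_to_sleep_period(_epoched(labels))
    assert (out.labels != 0).sum() == (np.array(labels) != 0).sum()


def test_all_sleep_night_unchanged():
    out = trim_to_sleep_period(_epoched([2] * 50))
    assert out.n_epochs == 50


def test_all_wake_night_rejected():
    with pytest.raises(ValueError, match="no sleep"):
        trim_to_sleep_period(_epoched([0] * 50))
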