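"""ECG chain: filter response, R binarization, R-R heart rate, resampling."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import signal as sp_signal

from vigilband.ecg import (BeatTimes, InstantHR, ThresholdPolicy,
                           bandpass_filter, binarize_r_peaks, compute_hr,
                           ecg_to_hr, resample_hr_1hz)
from vigilband.series import SampleSeries
from vigilband.synthetic import generate_ecg


def _sine(freq_hz, rate=250.0, duration=20.0):
    t = np.arange(int(duration * rate)) / rate
    return SampleSeries(start_time=0, rate=rate, values=np.sin(2 * np.pi * freq_hz * t),
                        units="mV", channel="ecg")


def _analytic_gain_db(freq_hz, low=5.0, high=15.0, order=2, rate=250.0):
    """Independent oracle: Butterworth magnitude response, doubled for the
    forward-backward (zero-phase) application."""
    sos = sp_signal.butter(order, [low, high], btype="bandpass", fs=rate, output="sos")
    _, h = sp_signal.sosfreqz(sos, worN=[freq_hz], fs=rate)
    return 2 * 20 * np.log10(np.abs(h[0]))


def test_zero_input_filters_to_zero():
    zero = SampleSeries(start_time=0, rate=250.0, values=np.zeros(1000),
                        units="mV", channel="ecg")
    out = bandpass_filter(zero)
    assert np.allclose(out.values, 0.0)
    assert out.rate == zero.rate and len(out) == len(zero)


@pytest.mark.parametrize("freq", [0.5, 10.0])
def test_band_edges_match_analytic_response(freq):
    series = _sine(freq)
    out = bandpass_filter(series, 5.0, 15.0, order=2)
    mid = slice(len(series) // 4, 3 * len(series) // 4)  # steady-state section
    measured_db = 20 * np.log10(np.std(out.values[mid]) / np.std(series.values[mid]))
    expected_db = _analytic_gain_db(freq)
    assert measured_db == pytest.approx(expected_db, abs=1.0)
    if freq == 0.5:
        assert measured_db <= -20.0   # baseline wander strongly attenuated
    else:
        assert measured_db >= -3.0    # QRS band essentially preserved


def test_band_outside_nyquist_rejected():
    series = _sine(10.0, rate=100.0)
    with pytest.raises(ValueError):
        bandpass_filter(series, 5.0, 60.0)
    with pytest.raises(ValueError):
        bandpass_filter(series, 0.0, 15.0)


def test_all_zero_input_yields_no_beats():
    zero = SampleSeries(start_time=0, rate=250.0, values=np.zeros(500),
                        units="mV", channel="ecg")
    binary, beats = binarize_r_peaks(zero)
    assert np.all(binary.values == 0)
    assert len(beats) == 0


def test_refractory_keeps_only_largest_of_close_pair():
    values = np.zeros(100)
    values[10] = 0.8
    values[20] = 1.0   # 100 ms later at 100 Hz
    series = SampleSeries(start_time=0, rate=100.0, values=values,
                          units="mV", channel="ecg")
    binary, beats = binarize_r_peaks(series, threshold_policy=0.5,
                                     refractory_ms=250.0)
    assert binary.values.sum() == 1
    assert beats.instants.tolist() == [200]  # the larger sample survives


def test_detections_match_truth_on_noisy_synthetic_ecg():
    ecg, truth = generate_ecg(60, 10.0, 250.0, noise_level=1.0, seed=2)
    filtered = bandpass_filter(ecg)
    binary, beats = binarize_r_peaks(filtered)
    assert abs(len(beats) - 10) <= 1
    for t in beats.instants:
        assert np.min(np.abs(truth - t)) <= 60
    # binary stream consistency: 1s count and positions roundtrip
    assert int(binary.values.sum()) == len(beats)
    assert np.array_equal(binary.times_ms[binary.values == 1], beats.instants)


def test_detector_agrees_with_independent_peak_finder():
    """Cross-check against scipy's generic peak finder on the filtered trace."""
    ecg, _ = generate_ecg(75, 30.0, 250.0, noise_level=1.0, seed=8)
    filtered = bandpass_filter(ecg)
    _, beats = binarize_r_peaks(filtered)
    ref_idx, _ = sp_signal.find_peaks(filtered.values,
                                      height=0.5 * filtered.values.max(),
                                      distance=int(0.25 * filtered.rate))
    ref_ms = filtered.times_ms[ref_idx]
    assert abs(len(beats) - len(ref_ms)) <= 1
    for t in beats.instants:
        assert np.min(np.abs(ref_ms - t)) <= 40


@pytest.mark.parametrize("rr_ms,expected_bpm", [(1000, 60.0), (500, 120.0), (750, 80.0)])
def test_rr_interval_to_bpm(rr_ms, expected_bpm):
    beats = BeatTimes(np.array([0, rr_ms]))
    (pair,) = compute_hr(beats)
    assert pair.bpm == pytest.approx(expected_bpm)
    assert pair.t_ms == rr_ms and pair.plausible


def test_fewer_than_two_beats_means_unavailable():
    assert compute_hr(BeatTimes(np.array([500]))) == []
    assert compute_hr(BeatTimes(np.array([], dtype=np.int64))) == []


@given(st.lists(st.integers(min_value=200, max_value=3000), min_size=1, max_size=30))
def test_hr_times_interval_identity(gaps):
    """HR·(TR1−TR0) = 60000 for every emitted pair, and implausible intervals
    are flagged."""
    instants = np.cumsum([0] + gaps)
    pairs = compute_hr(BeatTimes(instants))
    assert len(pairs) == len(gaps)
    for pair, gap in zip(pairs, gaps):
        assert pair.bpm * gap == pytest.approx(60000.0, rel=1e-12)
        assert pair.plausible == (20.0 <= pair.bpm <= 300.0)
    # monotonicity: longer interval, strictly lower rate
    bpms_sorted = [p.bpm for _, p in sorted(zip(gaps, pairs), key=lambda x: x[0])]
    assert all(a >= b for a, b in zip(bpms_sorted, bpms_sorted[1:]))


def test_resample_constant_rate_and_leading_unavailable():
    beats = BeatTimes(np.arange(0, 11000, 1000))
    ticks = np.arange(1000, 12000, 1000)
    hr = resample_hr_1hz(compute_hr(beats), ticks)
    assert np.all(hr.valid)
    assert np.allclose(hr.series.values, 60.0)
    # no beats at all: every tick unavailable
    empty = resample_hr_1hz([], ticks)
    assert not empty.valid.any()
    assert np.all(np.isnan(empty.series.values))


def test_resample_median_rejects_outlier():
    pairs = [InstantHR(t_ms=1000 * (i + 1), bpm=b, plausible=True)
             for i, b in enumerate([60.0, 60.0, 60.0, 60.0, 200.0])]
    hr = resample_hr_1hz(pairs, np.array([6000]))
    assert hr.valid[0]
    assert hr.series.values[0] == pytest.approx(60.0)


@pytest.mark.parametrize("zero_phase", [True, False])
def test_full_chain_recovers_constant_heart_rate(zero_phase):
    """Offline (zero-phase) and streaming (causal, delay-corrected) modes both
    recover the simulated rate."""
    ecg, _ = generate_ecg(80, 60.0, 250.0, noise_level=1.0, seed=1)
    hr = ecg_to_hr(ecg, zero_phase=zero_phase)
    med = np.median(hr.series.values[hr.valid])
    assert med == pytest.approx(80.0, abs=2.0)
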