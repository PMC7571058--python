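"""ECG to heart rate: Butterworth band-pass → threshold → R-R timing.

The chain is a deliberately simplified QRS detector in the Pan–Tompkins
tradition: a band-pass filter isolates the QRS energy (default 5–15 Hz,
order 2), an adaptive amplitude threshold converts the filtered trace into a
binary stream with a single 1 per detected R wave, and consecutive R
instants TR0, TR1 give the instantaneous heart rate

    HR = 1000 / (TR1 - TR0) * 60   [BPM, with TR in ms].

Offline processing filters zero-phase (forward–backward) so R timing is
preserved; the causal/streaming mode instead corrects detected instants by
the filter's nominal group delay at the pass-band centre.
"""

from __future__ import annotations

from bisect import bisect_left, insort
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import signal as sp_signal
from scipy.ndimage import maximum_filter1d

from .series import SampleSeries

__all__ = [
    "ThresholdPolicy", "BeatTimes", "InstantHR", "HRSeries",
    "bandpass_filter", "filter_delay_ms", "binarize_r_peaks",
    "compute_hr", "resample_hr_1hz", "ecg_to_hr",
]

HR_PLAUSIBLE_BPM = (20.0, 300.0)


@dataclass(frozen=True)
class ThresholdPolicy:
    """Adaptive peak threshold: ``fraction`` of the rolling maximum of the
    filtered signal over ``window_s``, never below ``floor_mv``."""

    fraction: float = 0.6
    window_s: float = 2.0
    floor_mv: float = 0.2

    def thresholds(self, filtered: SampleSeries) -> np.ndarray:
        size = max(1, int(round(self.window_s * filtered.rate)) | 1)
        roll = maximum_filter1d(filtered.values, size=size, mode="nearest")
        return np.maximum(self.fraction * roll, self.floor_mv)


@dataclass(frozen=True)
class BeatTimes:
    """Detected R-wave instants in ms, strictly increasing."""

    instants: np.ndarray

    def __post_init__(self) -> None:
        inst = np.asarray(self.instants, dtype=np.int64)
        if inst.size and np.any(np.diff(inst) <= 0):
            raise ValueError("beat instants must be strictly increasing")
        object.__setattr__(self, "instants", inst)

    def __len__(self) -> int:
        return self.instants.size


@dataclass(frozen=True)
class InstantHR:
    """One beat-to-beat heart-rate estimate, stamped at the later beat."""

    t_ms: int
    bpm: float
    plausible: bool


@dataclass(frozen=True)
class HRSeries:
    """1 Hz heart-rate channel with per-tick availability flags.

    Ticks with no usable beat pair carry NaN and ``valid`` False; valid
    samples lie within the physiologically plausible 20–300 BPM band.
    """

    series: SampleSeries
    valid: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.valid, dtype=bool)
        if v.size != self.series.values.size:
            raise ValueError("valid mask must match the series length")
        object.__setattr__(self, "valid", v)


def bandpass_filter(ecg: SampleSeries, low_hz: float = 5.0, high_hz: float = 15.0,
                    order: int = 2, zero_phase: bool = True) -> SampleSeries:
    """Butterworth band-pass; zero-phase by default, causal for streaming."""
    nyq = ecg.rate / 2.0
    if not (0 < low_hz < high_hz < nyq):
        raise ValueError(
            f"band ({low_hz}, {high_hz}) must satisfy 0 < low < high < Nyquist ({nyq})")
    sos = sp_signal.butter(order, [low_hz, high_hz], btype="bandpass",
                           fs=ecg.rate, output="sos")
    if zero_phase:
        out = sp_signal.sosfiltfilt(sos, ecg.values)
    else:
        out = sp_signal.sosfilt(sos, ecg.values)
    return ecg.with_values(out)


def filter_delay_ms(rate_hz: float, low_hz: float = 5.0, high_hz: float = 15.0,
                    order: int = 2) -> float:
    """Nominal group delay of the causal filter at the pass-band centre."""
    b, a = sp_signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=rate_hz)
    fc = float(np.sqrt(low_hz * high_hz))
    _, gd = sp_signal.group_delay((b, a), w=np.array([fc]), fs=rate_hz)
    return float(gd[0]) / rate_hz * 1000.0


def binarize_r_peaks(filtered: SampleSeries,
                     threshold_policy: ThresholdPolicy | float | None = None,
                     refractory_ms: float = 250.0,
                     ) -> tuple[SampleSeries, BeatTimes]:
    """Threshold the filtered ECG into a binary stream of R detections.

    A sample is a detection when it is a suprathreshold local maximum; within
    any refractory window only the largest such sample survives.  Returns the
    binary stream (same length/rate as the input, 1 at detections) and the
    detection timestamps.
    """
    x = filtered.values
    n = x.size
    if threshold_policy is None:
        threshold_policy = ThresholdPolicy()
    if isinstance(threshold_policy, ThresholdPolicy):
        thr = threshold_policy.thresholds(filtered)
    else:
        thr = np.full(n, float(threshold_policy))

    binary = np.zeros(n)
    if n == 0:
        return filtered.with_values(binary, units="", channel="r_binary"), BeatTimes(np.array([], dtype=np.int64))

    # suprathreshold local maxima (plateaus keep their left edge)
    cand = []
    for i in np.flatnonzero(x >= thr):
        left_ok = i == 0 or x[i] >= x[i - 1]
        right_ok = i == n - 1 or x[i] > x[i + 1]
        if left_ok and right_ok:
            cand.append(i)
    cand = np.asarray(cand, dtype=int)

    refractory_samples = refractory_ms * filtered.rate / 1000.0
    kept: list[int] = []
    for i in cand[np.argsort(-x[cand], kind="stable")] if cand.size else []:
        pos = bisect_left(kept, i)
        if pos > 0 and i - kept[pos - 1] < refractory_samples:
            continue
        if pos < len(kept) and kept[pos] - i < refractory_samples:
            continue
        insort(kept, int(i))

    idx = np.asarray(kept, dtype=int)
    binary[idx] = 1.0
    beats = BeatTimes(filtered.times_ms[idx])
    return filtered.with_values(binary, units="", channel="r_binary"), beats


def compute_hr(beats: BeatTimes) -> list[InstantHR]:
    """Instantaneous HR for each consecutive beat pair, stamped at TR1.

    Pairs whose rate falls outside the plausible 20–300 BPM band are flagged
    implausible (and excluded from smoothing downstream).  Fewer than two
    beats yields an empty list — HR unavailable.
    """
    inst = beats.instants
    out: list[InstantHR] = []
    lo, hi = HR_PLAUSIBLE_BPM
    for t0, t1 in zip(inst[:-1], inst[1:]):
        bpm = 1000.0 / float(t1 - t0) * 60.0
        out.append(InstantHR(t_ms=int(t1), bpm=bpm, plausible=lo <= bpm <= hi))
    return out


def resample_hr_1hz(instant_hr: Sequence[InstantHR], ticks_ms: np.ndarray,
                    k: int = 5) -> HRSeries:
    """Median-of-last-``k`` resampling of beat-to-beat HR onto a 1 Hz grid.

    Each tick carries the median of the most recent ``k`` plausible
    instantaneous values at or before it; ticks preceding the first usable
    pair are flagged unavailable.
    """
    ticks = np.asarray(ticks_ms, dtype=np.int64)
    good = [(h.t_ms, h.bpm) for h in instant_hr if h.plausible]
    times = np.array([t for t, _ in good], dtype=np.int64)
    bpms = np.array([b for _, b in good])
    values = np.full(ticks.size, np.nan)
    valid = np.zeros(ticks.size, dtype=bool)
    upto = np.searchsorted(times, ticks, side="right")
    for j, m in enumerate(upto):
        if m > 0:
            values[j] = float(np.median(bpms[max(0, m - k):m]))
            valid[j] = True
    rate = 1.0
    if ticks.size >= 2:
        rate = 1000.0 / float(np.median(np.diff(ticks)))
    start = int(ticks[0]) if ticks.size else 0
    series = SampleSeries(start_time=start, rate=rate, values=values,
                          units="BPM", channel="heart_rate")
    return HRSeries(series=series, valid=valid)


def ecg_to_hr(ecg: SampleSeries, ticks_ms: np.ndarray | None = None, *,
              low_hz: float = 5.0, high_hz: float = 15.0, order: int = 2,
              threshold_policy: ThresholdPolicy | float | None = None,
              refractory_ms: float = 250.0, median_k: int = 5,
              zero_phase: bool = True) -> HRSeries:
    """Full chain: filter, detect R waves, compute HR, resample to 1 Hz.

    ``ticks_ms`` defaults to one tick at the end of each whole second of the
    recording.  In streaming (causal) mode detected instants are shifted back
    by the filter's nominal group delay.
    """
    filtered = bandpass_filter(ecg, low_hz, high_hz, order, zero_phase=zero_phase)
    _, beats = binarize_r_peaks(filtered, threshold_policy, refractory_ms)
    if not zero_phase and len(beats):
        delay = filter_delay_ms(ecg.rate, low_hz, high_hz, order)
        beats = BeatTimes(beats.instants - int(round(delay)))
    if ticks_ms is None:
        n_ticks = int(np.floor(ecg.duration_s))
        ticks_ms = ecg.start_time + 1000 * (1 + np.arange(n_ticks, dtype=np.int64))
    return resample_hr_1hz(compute_hr(beats), ticks_ms, k=median_k)
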