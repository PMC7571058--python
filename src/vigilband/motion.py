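"""Acceleration magnitude and the gravity-referenced activity score.

The magnitude of the 3-axis acceleration vector, ‖a‖ = √(aX² + aY² + aZ²),
is close to 1 g for a still patient (gravity only) regardless of device
orientation, so the informative quantity for movement is the deviation
|‖a‖ − 1|.  The activity score averages that deviation over a short trailing
window at 1 Hz.
"""

from __future__ import annotations

import numpy as np

from .series import SampleSeries

__all__ = ["accel_magnitude", "activity_score"]


def accel_magnitude(ax: SampleSeries, ay: SampleSeries, az: SampleSeries) -> SampleSeries:
    """Element-wise Euclidean norm of the three acceleration axes (g)."""
    for other in (ay, az):
        if (other.rate != ax.rate or len(other) != len(ax)
                or other.start_time != ax.start_time):
            raise ValueError("acceleration axes must share rate, length and start time")
    mag = np.sqrt(ax.values ** 2 + ay.values ** 2 + az.values ** 2)
    return ax.with_values(mag, units="g", channel="accel_mag")


def activity_score(mag: SampleSeries, window_s: float = 2.0) -> SampleSeries:
    """Mean deviation of ‖a‖ from 1 g over a trailing window, at 1 Hz.

    One tick per whole second of input; the tick at the end of second ``k``
    averages |‖a‖ − 1| over samples in the trailing ``window_s`` seconds
    (clipped at the start of the recording).
    """
    if window_s < 1.0 / mag.rate:
        raise ValueError("window must cover at least one sample")
    dev = np.abs(mag.values - 1.0)
    times = mag.times_ms
    n_ticks = int(np.floor(mag.duration_s))
    window_ms = int(round(window_s * 1000))
    scores = np.zeros(n_ticks)
    for k in range(n_ticks):
        tick = mag.start_time + 1000 * (k + 1)
        lo = np.searchsorted(times, tick - window_ms, side="left")
        hi = np.searchsorted(times, tick, side="right")
        if hi > lo:
            scores[k] = dev[lo:hi].mean()
    return SampleSeries(start_time=mag.start_time + 1000, rate=1.0,
                        values=scores, units="g", channel="activity")
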