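"""Timestamped channel containers shared by every pipeline stage.

A :class:`SampleSeries` is the universal carrier between stages: a uniformly
sampled scalar channel whose timestamps are implied by the start time and the
sampling rate.  A :class:`StateSchedule` scripts the patient state (idle vs.
agitated) over a session and doubles as the ground-truth labelling.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: canonical units per channel label
CHANNEL_UNITS = {
    "ecg": "mV",
    "accel_x": "g",
    "accel_y": "g",
    "accel_z": "g",
    "accel_mag": "g",
    "activity": "g",
    "temperature": "°C",
    "humidity": "%RH",
    "heart_rate": "BPM",
}

VALID_STATES = ("idle", "agitated")


@dataclass(frozen=True, eq=False)
class SampleSeries:
    """A uniformly sampled scalar channel.

    Parameters
    ----------
    start_time : int
        Timestamp of the first sample, in integer milliseconds since epoch.
    rate : float
        Sampling rate in Hz; must be positive.  Sample ``i`` is stamped
        ``start_time + round(1000 * i / rate)`` ms.
    values : array-like of float
        The sample values.
    units : str
        Physical units (mV, g, °C, %RH, BPM).
    channel : str
        Channel label (e.g. ``"ecg"``, ``"accel_x"``).
    """

    start_time: int
    rate: float
    values: np.ndarray
    units: str
    channel: str

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.rate}")
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1:
            raise ValueError("values must be one-dimensional")
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "start_time", int(self.start_time))

    def __len__(self) -> int:
        return self.values.size

    @property
    def duration_s(self) -> float:
        return self.values.size / self.rate

    @property
    def times_ms(self) -> np.ndarray:
        """Implied per-sample timestamps in ms (int64, strictly increasing)."""
        idx = np.arange(self.values.size, dtype=np.int64)
        return self.start_time + np.round(1000.0 * idx / self.rate).astype(np.int64)

    def with_values(self, values: np.ndarray, *, units: str | None = None,
                    channel: str | None = None) -> "SampleSeries":
        """Copy of this series with new values (and optionally new labels)."""
        return dataclasses.replace(
            self, values=values,
            units=self.units if units is None else units,
            channel=self.channel if channel is None else channel)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SampleSeries):
            return NotImplemented
        return (self.start_time == other.start_time
                and self.rate == other.rate
                and self.units == other.units
                and self.channel == other.channel
                and self.values.shape == other.values.shape
                and bool(np.array_equal(self.values, other.values)))


@dataclass(frozen=True)
class StateSchedule:
    """Ordered, contiguous patient-state segments covering ``[0, duration)``.

    Each segment is ``(start_s, end_s, state)`` with ``state`` one of
    ``"idle"`` or ``"agitated"``.  Segments must start at 0, be sorted,
    non-overlapping and gap-free, with no zero-length entries.
    """

    segments: tuple[tuple[float, float, str], ...]

    def __post_init__(self) -> None:
        segs = tuple((float(s), float(e), str(state)) for s, e, state in self.segments)
        if not segs:
            raise ValueError("schedule needs at least one segment")
        if segs[0][0] != 0.0:
            raise ValueError("schedule must start at t=0")
        prev_end = 0.0
        for s, e, state in segs:
            if state not in VALID_STATES:
                raise ValueError(f"unknown state {state!r}")
            if e <= s:
                raise ValueError(f"zero- or negative-length segment ({s}, {e})")
            if s != prev_end:
                raise ValueError(f"segments must be contiguous; gap/overlap at t={s}")
            prev_end = e
        object.__setattr__(self, "segments", segs)

    @classmethod
    def single(cls, state: str, duration_s: float) -> "StateSchedule":
        return cls(((0.0, float(duration_s), state),))

    @property
    def duration_s(self) -> float:
        return self.segments[-1][1]

    def covers(self, duration_s: float) -> bool:
        return self.duration_s >= duration_s

    def state_at(self, t_s: float) -> str:
        for s, e, state in self.segments:
            if s <= t_s < e:
                return state
        return self.segments[-1][2]

    def states_at(self, times_s: np.ndarray) -> np.ndarray:
        """Vectorised state lookup; times past the end take the last state."""
        ends = np.array([e for _, e, _ in self.segments])
        labels = np.array([st for _, _, st in self.segments])
        idx = np.minimum(np.searchsorted(ends, times_s, side="right"),
                         len(labels) - 1)
        return labels[idx]

    def agitated_mask(self, times_s: np.ndarray) -> np.ndarray:
        return self.states_at(np.asarray(times_s)) == "agitated"

    def segments_of(self, state: str) -> list[tuple[float, float]]:
        return [(s, e) for s, e, st in self.segments if st == state]


def write_channel_csv(series: SampleSeries, path: str | Path) -> None:
    """Write one channel as a two-column CSV (``time_ms,value``)."""
    frame = pd.DataFrame({"time_ms": series.times_ms, "value": series.values})
    frame.to_csv(path, index=False)


def read_channel_csv(path: str | Path, *, channel: str | None = None,
                     units: str | None = None) -> SampleSeries:
    """Read a ``time_ms,value`` CSV back into a :class:`SampleSeries`.

    The rate is inferred from the median timestamp spacing; the channel label
    defaults to the file stem and units to the canonical unit for that label.
    """
    frame = pd.read_csv(path)
    t = frame["time_ms"].to_numpy(dtype=np.int64)
    if t.size < 2:
        raise ValueError("need at least two samples to infer the rate")
    rate = 1000.0 / float(np.median(np.diff(t)))
    label = channel if channel is not None else Path(path).stem
    return SampleSeries(
        start_time=int(t[0]), rate=rate,
        values=frame["value"].to_numpy(dtype=float),
        units=units if units is not None else CHANNEL_UNITS.get(label, ""),
        channel=label)


def parse_schedule(text: str) -> StateSchedule:
    """Parse ``"idle:0-30,agitated:30-60"`` into a :class:`StateSchedule`."""
    segments = []
    for part in text.split(","):
        state, _, span = part.strip().partition(":")
        lo, _, hi = span.partition("-")
        segments.append((float(lo), float(hi), state.strip()))
    return StateSchedule(tuple(segments))
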