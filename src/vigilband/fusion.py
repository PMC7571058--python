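"""Multi-rate fusion into 10 Hz sensor frames and their binary encoding.

Channels sampled slower than the frame rate (temperature, humidity, heart
rate at 1 Hz) are aligned to the fast timeline by sample-and-hold: each
frame repeats the most recent slow sample.  A frame carries exactly six
payload values — temperature, humidity, heart rate, and the three raw
acceleration axes — encoded as six little-endian IEEE-754 binary32 numbers,
i.e. a fixed 24-byte payload (240 bytes/s at the default 10 Hz).  The frame
timestamp travels separately in an 8-byte record header, outside the 24-byte
payload.  An unavailable heart rate (no beat pair seen yet) is encoded as a
binary32 NaN sentinel and decoded back to the unavailable marker.
"""

from __future__ import annotations

import math
import struct
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .ecg import HRSeries, ecg_to_hr
from .series import SampleSeries

__all__ = [
    "SensorFrame", "MalformedPayload", "PAYLOAD_ORDER", "PAYLOAD_BYTES",
    "sample_and_hold", "build_frames", "fuse_session",
    "encode_frame", "decode_frame",
    "write_vbf", "read_vbf", "write_frames_ndjson", "read_frames_ndjson",
    "frame_to_obj", "obj_to_frame",
]

PAYLOAD_ORDER = ("temperature", "humidity", "heart_rate",
                 "accel_x", "accel_y", "accel_z")
PAYLOAD_BYTES = 24  # six binary32 values
_PAYLOAD_STRUCT = struct.Struct("<6f")
_RECORD_STRUCT = struct.Struct(f"<Q{PAYLOAD_BYTES}s")
VBF_MAGIC = b"VBF1"


class MalformedPayload(ValueError):
    """Raised when a binary payload or record cannot be decoded."""


@dataclass(frozen=True)
class SensorFrame:
    """One fused record: six payload values plus a header timestamp.

    ``heart_rate`` is ``None`` while the ECG stage has not yet produced a
    valid beat pair.
    """

    timestamp_ms: int
    temperature: float
    humidity: float
    heart_rate: float | None
    accel_x: float
    accel_y: float
    accel_z: float

    def payload_values(self) -> tuple[float, ...]:
        hr = math.nan if self.heart_rate is None else self.heart_rate
        return (self.temperature, self.humidity, hr,
                self.accel_x, self.accel_y, self.accel_z)


def sample_and_hold(slow: SampleSeries, times_ms: np.ndarray,
                    rate_hz: float) -> tuple[SampleSeries, np.ndarray]:
    """Repeat each slow sample at every fast tick at or after it.

    Returns the held series on the fast timeline plus an availability mask;
    ticks preceding the first slow sample carry NaN and mask False.
    """
    ticks = np.asarray(times_ms, dtype=np.int64)
    idx = np.searchsorted(slow.times_ms, ticks, side="right") - 1
    available = idx >= 0
    values = np.full(ticks.size, np.nan)
    values[available] = slow.values[idx[available]]
    start = int(ticks[0]) if ticks.size else slow.start_time
    held = SampleSeries(start_time=start, rate=rate_hz, values=values,
                        units=slow.units, channel=slow.channel)
    return held, available


def build_frames(*, temperature: SampleSeries, humidity: SampleSeries,
                 heart_rate: HRSeries | SampleSeries | None,
                 accel_x: SampleSeries, accel_y: SampleSeries,
                 accel_z: SampleSeries,
                 frame_rate_hz: float = 10.0) -> list[SensorFrame]:
    """Assemble the fused frame stream on the accelerometer time base.

    One frame per tick at ``frame_rate_hz``; slow channels are held.  The
    heart-rate channel may be unavailable at the head of the stream; any
    other channel failing to cover the timeline is an error.
    """
    for name, ch in (("temperature", temperature), ("humidity", humidity),
                     ("accel_x", accel_x), ("accel_y", accel_y), ("accel_z", accel_z)):
        if ch is None:
            raise ValueError(f"missing channel: {name}")
    if heart_rate is None:
        raise ValueError("missing channel: heart_rate")

    n = int(np.floor(accel_x.duration_s * frame_rate_hz))
    idx = np.arange(n, dtype=np.int64)
    ticks = accel_x.start_time + np.round(1000.0 * idx / frame_rate_hz).astype(np.int64)

    held = {}
    for name, ch in (("temperature", temperature), ("humidity", humidity),
                     ("accel_x", accel_x), ("accel_y", accel_y), ("accel_z", accel_z)):
        series, ok = sample_and_hold(ch, ticks, frame_rate_hz)
        if not ok.all():
            raise ValueError(f"channel {name} does not cover the frame timeline")
        held[name] = series.values

    if isinstance(heart_rate, HRSeries):
        hr_src = heart_rate.series.with_values(
            np.where(heart_rate.valid, heart_rate.series.values, np.nan))
    else:
        hr_src = heart_rate
    hr_series, hr_ok = sample_and_hold(hr_src, ticks, frame_rate_hz)
    hr_vals = hr_series.values

    frames = []
    for i in range(n):
        hr = hr_vals[i]
        frames.append(SensorFrame(
            timestamp_ms=int(ticks[i]),
            temperature=float(held["temperature"][i]),
            humidity=float(held["humidity"][i]),
            heart_rate=None if (not hr_ok[i] or math.isnan(hr)) else float(hr),
            accel_x=float(held["accel_x"][i]),
            accel_y=float(held["accel_y"][i]),
            accel_z=float(held["accel_z"][i])))
    return frames


def fuse_session(recording, frame_rate_hz: float = 10.0,
                 **ecg_kwargs) -> list[SensorFrame]:
    """Process a session recording end to end into fused frames.

    Runs the ECG chain to a 1 Hz heart-rate series, then fuses it with the
    environment and raw acceleration channels.
    """
    hr = ecg_to_hr(recording.ecg, **ecg_kwargs)
    return build_frames(temperature=recording.temperature,
                        humidity=recording.humidity, heart_rate=hr,
                        accel_x=recording.accel_x, accel_y=recording.accel_y,
                        accel_z=recording.accel_z, frame_rate_hz=frame_rate_hz)


def encode_frame(frame: SensorFrame) -> bytes:
    """Pack the six payload values as little-endian binary32 — 24 bytes.

    Order: temperature, humidity, heart_rate, accel_x, accel_y, accel_z.
    The only admissible non-finite value is the NaN heart-rate sentinel.
    """
    vals = frame.payload_values()
    for name, v in zip(PAYLOAD_ORDER, vals):
        if not math.isfinite(v) and not (name == "heart_rate" and math.isnan(v)):
            raise ValueError(f"non-finite value for {name}: {v}")
    return _PAYLOAD_STRUCT.pack(*vals)


def decode_frame(payload: bytes, timestamp_ms: int) -> SensorFrame:
    """Exact inverse of :func:`encode_frame` (NaN heart rate → unavailable)."""
    if len(payload) != PAYLOAD_BYTES:
        raise MalformedPayload(
            f"payload must be exactly {PAYLOAD_BYTES} bytes, got {len(payload)}")
    temp, hum, hr, ax, ay, az = _PAYLOAD_STRUCT.unpack(payload)
    return SensorFrame(timestamp_ms=int(timestamp_ms), temperature=temp,
                       humidity=hum, heart_rate=None if math.isnan(hr) else hr,
                       accel_x=ax, accel_y=ay, accel_z=az)


def write_vbf(frames: Iterable[SensorFrame], path: str | Path) -> None:
    """Binary frame stream: magic ``VBF1`` then (uint64 ts, 24-byte payload)."""
    with open(path, "wb") as fh:
        fh.write(VBF_MAGIC)
        for frame in frames:
            fh.write(_RECORD_STRUCT.pack(frame.timestamp_ms, encode_frame(frame)))


def read_vbf(path: str | Path) -> list[SensorFrame]:
    raw = Path(path).read_bytes()
    if raw[:4] != VBF_MAGIC:
        raise MalformedPayload("not a VBF1 stream")
    body = raw[4:]
    if len(body) % _RECORD_STRUCT.size:
        raise MalformedPayload("truncated VBF1 record")
    frames = []
    for ts, payload in _RECORD_STRUCT.iter_unpack(body):
        frames.append(decode_frame(payload, ts))
    return frames


def _f32(v: float) -> float:
    return float(np.float32(v))


def frame_to_obj(frame: SensorFrame) -> dict:
    """JSON object form (binary32 fidelity; unavailable HR → null)."""
    return {"t": frame.timestamp_ms,
            "temp": _f32(frame.temperature), "hum": _f32(frame.humidity),
            "hr": None if frame.heart_rate is None else _f32(frame.heart_rate),
            "ax": _f32(frame.accel_x), "ay": _f32(frame.accel_y),
            "az": _f32(frame.accel_z)}


def obj_to_frame(obj: dict) -> SensorFrame:
    return SensorFrame(timestamp_ms=int(obj["t"]), temperature=float(obj["temp"]),
                       humidity=float(obj["hum"]),
                       heart_rate=None if obj["hr"] is None else float(obj["hr"]),
                       accel_x=float(obj["ax"]), accel_y=float(obj["ay"]),
                       accel_z=float(obj["az"]))


def write_frames_ndjson(frames: Iterable[SensorFrame], path: str | Path) -> None:
    import json
    with open(path, "w") as fh:
        for frame in frames:
            fh.write(json.dumps(frame_to_obj(frame)) + "\n")


def read_frames_ndjson(path: str | Path) -> list[SensorFrame]:
    import json
    frames = []
    with open(path) as fh:
        for line in fh:
            if line.strip():
                frames.append(obj_to_frame(json.loads(line)))
    return frames
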