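"""Multi-rate fusion, the 24-byte frame codec, and frame-stream files."""

import math
import struct

import numpy as np
import pytest
from hypothesis import given, strategies as st

from vigilband.ecg import HRSeries
from vigilband.fusion import (MalformedPayload, SensorFrame, build_frames,
                              decode_frame, encode_frame, frame_to_obj,
                              obj_to_frame, read_frames_ndjson, read_vbf,
                              sample_and_hold, write_frames_ndjson, write_vbf)
from vigilband.series import SampleSeries


def _series(values, rate, start=0, units="°C", channel="temperature"):
    return SampleSeries(start_time=start, rate=rate,
                        values=np.asarray(values, dtype=float),
                        units=units, channel=channel)


def _ticks(n, rate=10.0, start=0):
    return start + np.round(1000.0 * np.arange(n) / rate).astype(np.int64)


finite32 = st.floats(min_value=-1e6, max_value=1e6, allow_nan=False,
                     width=32)


def frames_strategy():
    return st.builds(
        SensorFrame,
        timestamp_ms=st.integers(min_value=0, max_value=2**40),
        temperature=finite32, humidity=finite32,
        heart_rate=st.one_of(st.none(), finite32),
        accel_x=finite32, accel_y=finite32, accel_z=finite32)


def test_slow_sample_repeats_in_ten_fast_frames():
    slow = _series([40.0, 41.0, 42.0], rate=1.0)
    held, ok = sample_and_hold(slow, _ticks(30), 10.0)
    assert ok.all()
    expected = np.repeat([40.0, 41.0, 42.0], 10)
    np.testing.assert_array_equal(held.values, expected)


def test_equal_rates_hold_is_identity():
    slow = _series(np.arange(20.0), rate=10.0)
    held, ok = sample_and_hold(slow, _ticks(20), 10.0)
    assert ok.all()
    np.testing.assert_array_equal(held.values, slow.values)


def test_ticks_before_first_slow_sample_flagged_missing():
    slow = _series([40.0, 41.0], rate=1.0, start=500)
    held, ok = sample_and_hold(slow, _ticks(15), 10.0)
    assert (~ok[:5]).all() and ok[5:].all()
    assert np.all(np.isnan(held.values[:5]))


def _session_channels(duration_s=10.0):
    n_fast = int(duration_s * 10)
    n_slow = int(duration_s)
    accel = {name: _series(np.full(n_fast, v), 10.0, units="g", channel=name)
             for name, v in (("accel_x", 0.0), ("accel_y", 0.0), ("accel_z", 1.0))}
    temp = _series(36.5 + 0.01 * np.arange(n_slow), 1.0)
    hum = _series(40.0 + 0.1 * np.arange(n_slow), 1.0, units="%RH", channel="humidity")
    hr_vals = np.full(n_slow, 72.0)
    hr_vals[0] = np.nan
    hr = HRSeries(series=_series(hr_vals, 1.0, start=1000, units="BPM",
                                 channel="heart_rate"),
                  valid=~np.isnan(hr_vals))
    return dict(temperature=temp, humidity=hum, heart_rate=hr,
                accel_x=accel["accel_x"], accel_y=accel["accel_y"],
                accel_z=accel["accel_z"])


def test_frame_stream_shape_and_timing():
    frames = build_frames(**_session_channels(10.0), frame_rate_hz=10.0)
    assert len(frames) == 100
    stamps = np.array([f.timestamp_ms for f in frames])
    assert np.all(np.diff(stamps) == 100)
    assert all(len(f.payload_values()) == 6 for f in frames)


def test_each_slow_value_held_for_ten_consecutive_frames():
    frames = build_frames(**_session_channels(10.0))
    hum = np.array([f.humidity for f in frames])
    # interior slow samples each occupy exactly round(10/1)=10 frames
    values, counts = np.unique(hum, return_counts=True)
    assert np.all(counts == 10) and values.size == 10


def test_missing_channel_rejected():
    channels = _session_channels(5.0)
    channels["humidity"] = None
    with pytest.raises(ValueError):
        build_frames(**channels)


@given(frames_strategy())
def test_payload_is_exactly_24_bytes_and_roundtrips(frame):
    payload = encode_frame(frame)
    assert len(payload) == 24
    back = decode_frame(payload, frame.timestamp_ms)
    assert back.timestamp_ms == frame.timestamp_ms
    for got, want in zip(back.payload_values(), frame.payload_values()):
        if math.isnan(want):
            assert math.isnan(got)
        else:
            assert got == np.float32(want)
    # binary32 re-encoding is the exact identity
    assert encode_frame(back) == payload


def test_payload_byte_layout_is_little_endian_binary32():
    frame = SensorFrame(timestamp_ms=0, temperature=1.0, humidity=0.0,
                        heart_rate=0.0, accel_x=0.0, accel_y=0.0, accel_z=0.0)
    payload = encode_frame(frame)
    assert payload[:4] == bytes([0x00, 0x00, 0x80, 0x3F])


def test_unavailable_hr_uses_nan_sentinel():
    frame = SensorFrame(timestamp_ms=10, temperature=36.5, humidity=40.0,
                        heart_rate=None, accel_x=0.0, accel_y=0.0, accel_z=1.0)
    payload = encode_frame(frame)
    assert math.isnan(struct.unpack("<6f", payload)[2])
    assert decode_frame(payload, 10).heart_rate is None


def test_nonfinite_values_rejected_except_hr_sentinel():
    frame = SensorFrame(timestamp_ms=0, temperature=math.inf, humidity=40.0,
                        heart_rate=70.0, accel_x=0.0, accel_y=0.0, accel_z=1.0)
    with pytest.raises(ValueError):
        encode_frame(frame)


def test_wrong_length_payload_rejected():
    with pytest.raises(MalformedPayload):
        decode_frame(b"\x00" * 23, 0)
    frame = decode_frame(b"\x00" * 24, 0)
    assert frame.payload_values() == (0.0,) * 6


def test_vbf_and_ndjson_files_roundtrip(tmp_path):
    rng = np.random.default_rng(3)
    frames = [SensorFrame(timestamp_ms=100 * i,
                          temperature=float(np.float32(rng.normal(36.5, 0.1))),
                          humidity=float(np.float32(rng.normal(40, 1))),
                          heart_rate=None if i == 0 else float(np.float32(70 + i)),
                          accel_x=float(np.float32(rng.normal())),
                          accel_y=float(np.float32(rng.normal())),
                          accel_z=float(np.float32(rng.normal(1, 0.1))))
              for i in range(50)]
    write_vbf(frames, tmp_path / "s.vbf")
    assert read_vbf(tmp_path / "s.vbf") == frames
    write_frames_ndjson(frames, tmp_path / "s.ndjson")
    assert read_frames_ndjson(tmp_path / "s.ndjson") == frames
    # JSON object mapping keeps the unavailable-HR sentinel
    assert frame_to_obj(frames[0])["hr"] is None
    assert obj_to_frame(frame_to_obj(frames[0])) == frames[0]
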