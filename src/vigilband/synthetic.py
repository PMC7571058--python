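"""Synthetic patient sessions with known ground truth.

Generates the four channel groups the band records — single-lead ECG,
3-axis acceleration, skin temperature and skin humidity (a perspiration
proxy) — following a scripted idle/agitated schedule, so that every
downstream stage can be tested against known beat instants and agitation
labels without any hardware.

The ECG is a train of stylised beats (Gaussian P, Q, R, S, T bumps with a
dominant 1 mV R wave) plus broadband noise and low-frequency baseline
wander.  Idle acceleration is gravity plus small sensor noise; agitation is
modelled as bouts of violent movement — multi-second bursts of high-variance
zero-mean acceleration on all three axes occupying about half of the
agitated time.  Humidity relaxes first-order toward an elevated level during
agitation and decays slowly afterwards; temperature stays near its baseline.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .series import CHANNEL_UNITS, SampleSeries, StateSchedule, read_channel_csv, write_channel_csv

__all__ = [
    "SimulatorConfig", "SessionRecording",
    "generate_ecg", "generate_imu", "generate_environment", "generate_session",
    "write_session", "read_session",
]

# Gaussian beat morphology: (amplitude mV, offset from R in s, width in s).
_WAVES = (
    (0.10, -0.200, 0.040),   # P
    (-0.15, -0.026, 0.010),  # Q
    (1.00, 0.000, 0.012),    # R
    (-0.20, 0.028, 0.010),   # S
    (0.30, 0.220, 0.060),    # T
)

_BASELINE_WANDER_HZ = 0.4


@dataclass(frozen=True)
class SimulatorConfig:
    """Session-level defaults for all channel generators.

    Rates follow the device: 10 Hz IMU, 1 Hz temperature/humidity/HR; the
    ECG front end is sampled at 250 Hz (a standard single-lead rate).
    ``noise_level`` scales every stochastic term; 0 gives clean channels.
    """

    ecg_rate_hz: float = 250.0
    imu_rate_hz: float = 10.0
    env_rate_hz: float = 1.0
    noise_level: float = 1.0
    idle_hr_bpm: float = 70.0
    agitated_hr_bpm: float = 120.0
    temp_baseline_c: float = 36.5
    temp_sigma_c: float = 0.05
    humidity_baseline_rh: float = 40.0
    humidity_rise_rh: float = 20.0
    humidity_tau_rise_s: float = 30.0
    humidity_tau_decay_s: float = 120.0
    humidity_sigma_rh: float = 0.2
    imu_idle_sigma_g: float = 0.02
    imu_burst_sigma_g: float = 0.6
    imu_burst_occupancy: float = 0.5
    imu_burst_len_s: tuple[float, float] = (3.0, 8.0)


@dataclass(frozen=True)
class SessionRecording:
    """All channels of one simulated session plus its ground truth."""

    ecg: SampleSeries
    accel_x: SampleSeries
    accel_y: SampleSeries
    accel_z: SampleSeries
    temperature: SampleSeries
    humidity: SampleSeries
    truth_beats: np.ndarray          # ms instants, strictly increasing
    truth_schedule: StateSchedule
    seed: int

    def channels(self) -> dict[str, SampleSeries]:
        return {
            "ecg": self.ecg,
            "accel_x": self.accel_x, "accel_y": self.accel_y, "accel_z": self.accel_z,
            "temperature": self.temperature, "humidity": self.humidity,
        }


def _hr_profile(hr_bpm, duration_s: float):
    """Normalise a scalar HR or piecewise [(start, end, bpm), ...] profile."""
    if np.isscalar(hr_bpm):
        segs = [(0.0, float(duration_s), float(hr_bpm))]
    else:
        segs = [(float(s), float(e), float(h)) for s, e, h in hr_bpm]
    for _, _, h in segs:
        if not 30.0 <= h <= 220.0:
            raise ValueError(f"heart rate {h} BPM outside the supported [30, 220] range")

    def at(t: float) -> float:
        for s, e, h in segs:
            if s <= t < e:
                return h
        return segs[-1][2]

    return at


def generate_ecg(hr_bpm, duration_s: float, rate_hz: float = 250.0,
                 noise_level: float = 1.0, seed: int | None = None,
                 start_time: int = 0) -> tuple[SampleSeries, np.ndarray]:
    """Synthesise a single-lead ECG and return it with its true beat instants.

    Parameters
    ----------
    hr_bpm : float or sequence of (start_s, end_s, bpm)
        Constant heart rate, or a piecewise-constant profile.
    duration_s, rate_hz : float
        Length and sampling rate of the trace; the rate must be ≥ 100 Hz to
        resolve the QRS complex.
    noise_level : float
        Scales both the white noise (σ = 0.1 mV at level 1) and the 0.4 Hz
        baseline wander (0.3 mV amplitude at level 1).

    Returns
    -------
    (SampleSeries, ndarray)
        The ECG in mV and the ground-truth R instants in ms.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    if rate_hz < 100:
        raise ValueError("ECG rate must be at least 100 Hz")
    if noise_level < 0:
        raise ValueError("noise_level must be non-negative")
    hr_at = _hr_profile(hr_bpm, duration_s)
    rng = np.random.default_rng(seed)

    # R instants: first beat half an interval in, then RR(t) steps.
    beats_s: list[float] = []
    t = 30.0 / hr_at(0.0)
    while t < duration_s:
        beats_s.append(t)
        t += 60.0 / hr_at(t)

    n = int(np.floor(duration_s * rate_hz))
    sig = np.zeros(n)
    tgrid = np.arange(n) / rate_hz
    half = 0.45  # beat support in s
    for tb in beats_s:
        i0 = max(0, int((tb - half) * rate_hz))
        i1 = min(n, int((tb + half) * rate_hz) + 1)
        dt = tgrid[i0:i1] - tb
        for amp, mu, sd in _WAVES:
            sig[i0:i1] += amp * np.exp(-0.5 * ((dt - mu) / sd) ** 2)

    if noise_level > 0:
        phase = rng.uniform(0, 2 * np.pi)
        sig = (sig
               + 0.3 * noise_level * np.sin(2 * np.pi * _BASELINE_WANDER_HZ * tgrid + phase)
               + rng.normal(0.0, 0.1 * noise_level, n))

    series = SampleSeries(start_time=start_time, rate=rate_hz, values=sig,
                          units="mV", channel="ecg")
    truth = start_time + np.round(1000.0 * np.asarray(beats_s)).astype(np.int64)
    return series, truth


def _burst_mask(rng: np.random.Generator, n: int, rate_hz: float,
                agitated: np.ndarray, occupancy: float,
                len_s: tuple[float, float]) -> np.ndarray:
    """Boolean per-sample mask of violent-movement bouts inside agitated spans.

    On-runs are uniform in ``len_s``; off-runs are scaled so the expected
    on-fraction equals ``occupancy``.
    """
    mask = np.zeros(n, dtype=bool)
    off_scale = (1.0 - occupancy) / max(occupancy, 1e-9)
    # walk each maximal agitated run independently
    edges = np.flatnonzero(np.diff(np.concatenate(([0], agitated.view(np.int8), [0]))))
    for a, b in zip(edges[::2], edges[1::2]):
        t = 0.0
        span = (b - a) / rate_hz
        on = rng.random() < occupancy
        while t < span:
            run = rng.uniform(*len_s) * (1.0 if on else off_scale)
            i0 = a + int(t * rate_hz)
            i1 = min(b, a + int((t + run) * rate_hz))
            if on:
                mask[i0:i1] = True
            t += run
            on = not on
    return mask


def generate_imu(schedule: StateSchedule, duration_s: float, rate_hz: float = 10.0,
                 seed: int | None = None, *, idle_sigma_g: float = 0.02,
                 burst_sigma_g: float = 0.6, burst_occupancy: float = 0.5,
                 burst_len_s: tuple[float, float] = (3.0, 8.0),
                 start_time: int = 0) -> tuple[SampleSeries, SampleSeries, SampleSeries]:
    """Generate 3-axis acceleration (g) for a scheduled session.

    Idle: resting orientation (gravity on +z) plus per-axis Gaussian sensor
    noise.  Agitated: the same, with multi-second bouts of zero-mean
    high-variance movement superposed on all axes.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    if rate_hz < 10:
        raise ValueError("IMU rate must be at least 10 Hz")
    if not schedule.covers(duration_s):
        raise ValueError("schedule does not cover the requested duration")
    rng = np.random.default_rng(seed)
    n = int(np.floor(duration_s * rate_hz))
    times_s = np.arange(n) / rate_hz
    agitated = schedule.agitated_mask(times_s)
    burst = _burst_mask(rng, n, rate_hz, agitated, burst_occupancy, burst_len_s)
    sigma = np.where(burst, burst_sigma_g, idle_sigma_g)
    acc = np.array([0.0, 0.0, 1.0]) + rng.standard_normal((n, 3)) * sigma[:, None]
    out = []
    for axis, label in enumerate(("accel_x", "accel_y", "accel_z")):
        out.append(SampleSeries(start_time=start_time, rate=rate_hz,
                                values=acc[:, axis], units="g", channel=label))
    return tuple(out)


def generate_environment(schedule: StateSchedule, duration_s: float,
                         seed: int | None = None, *, rate_hz: float = 1.0,
                         temp_baseline_c: float = 36.5, temp_sigma_c: float = 0.05,
                         humidity_baseline_rh: float = 40.0,
                         humidity_rise_rh: float = 20.0,
                         humidity_tau_rise_s: float = 30.0,
                         humidity_tau_decay_s: float = 120.0,
                         humidity_sigma_rh: float = 0.2,
                         noise_level: float = 1.0,
                         start_time: int = 0) -> tuple[SampleSeries, SampleSeries]:
    """Generate temperature (°C) and humidity (%RH) at the environment rate.

    Humidity follows first-order relaxation: toward ``baseline + rise`` with
    time constant ``tau_rise`` while agitated, back toward the baseline with
    the slower ``tau_decay`` otherwise.  With ``noise_level`` 0 both channels
    are deterministic and humidity is non-decreasing throughout any agitated
    segment.
    """
    if duration_s < 1:
        raise ValueError("duration must be at least 1 s")
    if not schedule.covers(duration_s):
        raise ValueError("schedule does not cover the requested duration")
    rng = np.random.default_rng(seed)
    n = int(np.floor(duration_s * rate_hz))
    dt = 1.0 / rate_hz
    times_s = np.arange(n) * dt
    agitated = schedule.agitated_mask(times_s)

    hum = np.empty(n)
    level = humidity_baseline_rh
    for i in range(n):
        hum[i] = level
        if agitated[i]:
            target, tau = humidity_baseline_rh + humidity_rise_rh, humidity_tau_rise_s
        else:
            target, tau = humidity_baseline_rh, humidity_tau_decay_s
        level += dt * (target - level) / tau

    temp = np.full(n, temp_baseline_c)
    if noise_level > 0:
        temp = temp + rng.normal(0.0, temp_sigma_c * noise_level, n)
        hum = hum + rng.normal(0.0, humidity_sigma_rh * noise_level, n)

    t_series = SampleSeries(start_time=start_time, rate=rate_hz, values=temp,
                            units="°C", channel="temperature")
    h_series = SampleSeries(start_time=start_time, rate=rate_hz, values=hum,
                            units="%RH", channel="humidity")
    return t_series, h_series


def generate_session(script: StateSchedule, duration_s: float, seed: int,
                     config: SimulatorConfig | None = None,
                     start_time: int = 0) -> SessionRecording:
    """Bundle all channels of one scripted session with its ground truth.

    Heart rate follows the script (idle vs. agitated baseline HR); all
    channels share the time base and are reproducible from ``seed``.
    """
    cfg = config or SimulatorConfig()
    if not script.covers(duration_s):
        raise ValueError("schedule does not cover the requested duration")
    sub = np.random.SeedSequence(seed).generate_state(3, np.uint32)
    hr_profile = [(s, e, cfg.agitated_hr_bpm if st == "agitated" else cfg.idle_hr_bpm)
                  for s, e, st in script.segments]
    ecg, beats = generate_ecg(hr_profile, duration_s, cfg.ecg_rate_hz,
                              cfg.noise_level, int(sub[0]), start_time)
    ax, ay, az = generate_imu(
        script, duration_s, cfg.imu_rate_hz, int(sub[1]),
        idle_sigma_g=cfg.imu_idle_sigma_g * cfg.noise_level,
        burst_sigma_g=cfg.imu_burst_sigma_g, burst_occupancy=cfg.imu_burst_occupancy,
        burst_len_s=cfg.imu_burst_len_s, start_time=start_time)
    temp, hum = generate_environment(
        script, duration_s, int(sub[2]), rate_hz=cfg.env_rate_hz,
        temp_baseline_c=cfg.temp_baseline_c, temp_sigma_c=cfg.temp_sigma_c,
        humidity_baseline_rh=cfg.humidity_baseline_rh,
        humidity_rise_rh=cfg.humidity_rise_rh,
        humidity_tau_rise_s=cfg.humidity_tau_rise_s,
        humidity_tau_decay_s=cfg.humidity_tau_decay_s,
        humidity_sigma_rh=cfg.humidity_sigma_rh,
        noise_level=cfg.noise_level, start_time=start_time)
    return SessionRecording(ecg=ecg, accel_x=ax, accel_y=ay, accel_z=az,
                            temperature=temp, humidity=hum, truth_beats=beats,
                            truth_schedule=script, seed=int(seed))


def write_session(rec: SessionRecording, out_dir: str | Path) -> None:
    """Write one CSV per channel plus a JSON manifest with the ground truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, series in rec.channels().items():
        write_channel_csv(series, out / f"{name}.csv")
    manifest = {
        "seed": rec.seed,
        "rates": {name: s.rate for name, s in rec.channels().items()},
        "units": {name: s.units for name, s in rec.channels().items()},
        "start_time": {name: s.start_time for name, s in rec.channels().items()},
        "schedule": [list(seg) for seg in rec.truth_schedule.segments],
        "truth_beats_ms": [int(b) for b in rec.truth_beats],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))


def read_session(session_dir: str | Path) -> SessionRecording:
    """Inverse of :func:`write_session`."""
    src = Path(session_dir)
    manifest = json.loads((src / "manifest.json").read_text())
    series = {}
    for name in ("ecg", "accel_x", "accel_y", "accel_z", "temperature", "humidity"):
        s = read_channel_csv(src / f"{name}.csv", channel=name,
                             units=manifest["units"][name])
        # trust the manifest rate over the inferred one (exact, not rounded)
        series[name] = SampleSeries(start_time=s.start_time,
                                    rate=manifest["rates"][name],
                                    values=s.values, units=s.units, channel=name)
    return SessionRecording(
        ecg=series["ecg"], accel_x=series["accel_x"], accel_y=series["accel_y"],
        accel_z=series["accel_z"], temperature=series["temperature"],
        humidity=series["humidity"],
        truth_beats=np.asarray(manifest["truth_beats_ms"], dtype=np.int64),
        truth_schedule=StateSchedule(tuple(tuple(seg) for seg in manifest["schedule"])),
        seed=int(manifest["seed"]))
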