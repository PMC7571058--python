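"""Local agitation detector, low-battery alarm and battery budget.

A single excursion is never enough to alert: violent movement alone, or a
heart-rate or perspiration rise alone, are everyday artefacts.  An agitation
alert therefore requires the movement channel (trailing-window activity
score above threshold, sustained for several seconds) *and* at least one
corroborating physiological excursion — heart rate above threshold or
humidity rising faster than a slope threshold — at the same instant.  After
an alert, repeats are suppressed for a cooldown period.  Every alert names
the device and each parameter that was out of range when it fired.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .fusion import SensorFrame

__all__ = [
    "DetectorConfig", "AlertEvent", "BatterySpec", "BatteryMonitor",
    "evaluate_stream", "battery_energy", "estimate_battery_life",
    "alerts_to_ndjson",
]


@dataclass(frozen=True)
class DetectorConfig:
    """Thresholds and timing of the local detector.

    ``corroborating`` selects which secondary channels may complete the
    boolean combination (movement AND any-of-these); both are enabled by
    default.
    """

    activity_threshold_g: float = 0.3
    hr_threshold_bpm: float = 110.0
    humidity_slope_threshold: float = 5.0      # %RH per minute
    sustain_s: float = 3.0
    cooldown_s: float = 60.0
    battery_alarm_fraction: float = 0.15
    battery_hysteresis: float = 0.05
    activity_window_s: float = 2.0
    humidity_slope_window_s: float = 60.0
    corroborating: tuple[str, ...] = ("heart_rate", "humidity")

    def __post_init__(self) -> None:
        for name in ("activity_threshold_g", "hr_threshold_bpm",
                     "humidity_slope_threshold", "sustain_s", "cooldown_s",
                     "activity_window_s", "humidity_slope_window_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.battery_alarm_fraction < 1:
            raise ValueError("battery_alarm_fraction must be in (0, 1)")
        unknown = set(self.corroborating) - {"heart_rate", "humidity"}
        if unknown:
            raise ValueError(f"unknown corroborating channels: {sorted(unknown)}")
        if not self.corroborating:
            raise ValueError("at least one corroborating channel is required")


@dataclass(frozen=True)
class AlertEvent:
    """Notification payload: who, when, what kind, which parameters."""

    device_id: str
    timestamp_ms: int
    kind: str                                  # "agitation" | "low_battery"
    parameters_out_of_range: tuple[str, ...]
    details: str = ""

    def to_obj(self) -> dict:
        return {"device_id": self.device_id, "t": self.timestamp_ms,
                "kind": self.kind,
                "params": list(self.parameters_out_of_range),
                "details": self.details}


@dataclass(frozen=True)
class BatterySpec:
    """Prototype battery: 3.7 V, 2.6 Ah — 9.62 Wh."""

    voltage_v: float = 3.7
    capacity_ah: float = 2.6
    energy_wh: float = 9.62

    def __post_init__(self) -> None:
        if self.voltage_v <= 0 or self.capacity_ah <= 0:
            raise ValueError("voltage and capacity must be positive")
        nominal = self.voltage_v * self.capacity_ah
        if abs(self.energy_wh - nominal) > 0.005 * nominal:
            raise ValueError(
                f"energy {self.energy_wh} Wh inconsistent with "
                f"{self.voltage_v} V x {self.capacity_ah} Ah = {nominal} Wh")


def battery_energy(spec: BatterySpec) -> float:
    """Stored energy in Wh (voltage × capacity)."""
    return spec.voltage_v * spec.capacity_ah


def estimate_battery_life(spec: BatterySpec, avg_current_a: float) -> float:
    """Runtime in hours at a constant average current draw."""
    if avg_current_a <= 0:
        raise ValueError("average current must be positive")
    return spec.capacity_ah / avg_current_a


def _slope_rh_per_min(ts_ms: Sequence[int], values: Sequence[float]) -> float:
    """Least-squares humidity slope over the trailing window, %RH/min."""
    if len(values) < 2:
        return 0.0
    t = np.asarray(ts_ms, dtype=float) / 60000.0
    if t[-1] - t[0] <= 0:
        return 0.0
    return float(np.polyfit(t - t[0], np.asarray(values, dtype=float), 1)[0])


def evaluate_stream(frames: Iterable[SensorFrame], config: DetectorConfig | None = None,
                    device_id: str = "vigilband-0") -> list[AlertEvent]:
    """Scan an ordered frame stream and return the agitation alerts raised.

    Per frame, the detector maintains the trailing-window activity score,
    the latest heart rate (unavailable HR never exceeds) and the trailing
    least-squares humidity slope.  An alert fires when the activity score
    has been continuously above threshold for at least ``sustain_s`` and a
    corroborating excursion is present; the cooldown then silences repeats.
    """
    cfg = config or DetectorConfig()
    act_win: deque[tuple[int, float]] = deque()
    hum_win: deque[tuple[int, float]] = deque()
    act_window_ms = cfg.activity_window_s * 1000.0
    hum_window_ms = cfg.humidity_slope_window_s * 1000.0
    exceed_since: int | None = None
    last_alert_ms: int | None = None
    alerts: list[AlertEvent] = []

    for frame in frames:
        t = frame.timestamp_ms
        mag = float(np.sqrt(frame.accel_x ** 2 + frame.accel_y ** 2
                            + frame.accel_z ** 2))
        act_win.append((t, abs(mag - 1.0)))
        while act_win and act_win[0][0] <= t - act_window_ms:
            act_win.popleft()
        score = float(np.mean([d for _, d in act_win]))

        hum_win.append((t, frame.humidity))
        while hum_win and hum_win[0][0] <= t - hum_window_ms:
            hum_win.popleft()
        slope = _slope_rh_per_min([p[0] for p in hum_win], [p[1] for p in hum_win])

        if score > cfg.activity_threshold_g:
            if exceed_since is None:
                exceed_since = t
        else:
            exceed_since = None
        sustained = (exceed_since is not None
                     and t - exceed_since >= cfg.sustain_s * 1000.0)

        out_of_range = []
        if ("heart_rate" in cfg.corroborating and frame.heart_rate is not None
                and frame.heart_rate > cfg.hr_threshold_bpm):
            out_of_range.append("heart_rate")
        if ("humidity" in cfg.corroborating
                and slope > cfg.humidity_slope_threshold):
            out_of_range.append("humidity")

        cooled = (last_alert_ms is None
                  or t - last_alert_ms >= cfg.cooldown_s * 1000.0)
        if sustained and out_of_range and cooled:
            alerts.append(AlertEvent(
                device_id=device_id, timestamp_ms=t, kind="agitation",
                parameters_out_of_range=tuple(["acceleration"] + out_of_range),
                details=(f"activity {score:.3f} g sustained "
                         f">= {cfg.sustain_s:.0f} s; "
                         + ", ".join(out_of_range) + " out of range")))
            last_alert_ms = t
    return alerts


class BatteryMonitor:
    """Latched low-battery alarm: one alert per discharge.

    The alert fires when the charge fraction drops below the configured
    threshold and re-arms only after the level recovers above threshold plus
    hysteresis (i.e. after a recharge).
    """

    def __init__(self, config: DetectorConfig | None = None,
                 device_id: str = "vigilband-0") -> None:
        self.config = config or DetectorConfig()
        self.device_id = device_id
        self._latched = False

    def check(self, level_fraction: float, timestamp_ms: int = 0) -> AlertEvent | None:
        if not 0.0 <= level_fraction <= 1.0:
            raise ValueError(f"battery level must be in [0, 1], got {level_fraction}")
        cfg = self.config
        if self._latched:
            if level_fraction >= cfg.battery_alarm_fraction + cfg.battery_hysteresis:
                self._latched = False
            return None
        if level_fraction < cfg.battery_alarm_fraction:
            self._latched = True
            return AlertEvent(
                device_id=self.device_id, timestamp_ms=int(timestamp_ms),
                kind="low_battery", parameters_out_of_range=("battery",),
                details=f"battery at {100 * level_fraction:.0f}% "
                        f"(alarm below {100 * cfg.battery_alarm_fraction:.0f}%)")
        return None


def low_battery_check(level_fraction: float, config: DetectorConfig | None = None,
                      device_id: str = "vigilband-0",
                      timestamp_ms: int = 0) -> AlertEvent | None:
    """One-shot (unlatched) low-battery check; see :class:`BatteryMonitor`."""
    return BatteryMonitor(config, device_id).check(level_fraction, timestamp_ms)


def alerts_to_ndjson(alerts: Iterable[AlertEvent], path) -> None:
    import json
    with open(path, "w") as fh:
        for alert in alerts:
            fh.write(json.dumps(alert.to_obj()) + "\n")
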