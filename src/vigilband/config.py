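"""TOML configuration mapped onto the per-stage config dataclasses.

A config file may carry ``[simulator]``, ``[ecg]``, ``[detector]`` and
``[uplink]`` tables; every key must match a field of the corresponding
dataclass, and omitted keys keep the documented defaults.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from .detector import DetectorConfig
from .ecg import ThresholdPolicy
from .synthetic import SimulatorConfig

__all__ = ["EcgConfig", "UplinkConfig", "AppConfig", "load_config"]


@dataclass(frozen=True)
class EcgConfig:
    """Parameters of the ECG→HR chain."""

    low_hz: float = 5.0
    high_hz: float = 15.0
    order: int = 2
    threshold_fraction: float = 0.6
    threshold_window_s: float = 2.0
    threshold_floor_mv: float = 0.2
    refractory_ms: float = 250.0
    median_k: int = 5

    def policy(self) -> ThresholdPolicy:
        return ThresholdPolicy(fraction=self.threshold_fraction,
                               window_s=self.threshold_window_s,
                               floor_mv=self.threshold_floor_mv)

    def hr_kwargs(self) -> dict:
        return dict(low_hz=self.low_hz, high_hz=self.high_hz, order=self.order,
                    threshold_policy=self.policy(),
                    refractory_ms=self.refractory_ms, median_k=self.median_k)


@dataclass(frozen=True)
class UplinkConfig:
    batch_size: int = 10
    retries: int = 2
    backoff_s: float = 1.0
    frame_rate_hz: float = 10.0


@dataclass(frozen=True)
class AppConfig:
    simulator: SimulatorConfig = field(default_factory=SimulatorConfig)
    ecg: EcgConfig = field(default_factory=EcgConfig)
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    uplink: UplinkConfig = field(default_factory=UplinkConfig)


_TABLES = {"simulator": SimulatorConfig, "ecg": EcgConfig,
           "detector": DetectorConfig, "uplink": UplinkConfig}


def _build(cls, table: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(table) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    coerced = {k: tuple(v) if isinstance(v, list) else v for k, v in table.items()}
    return cls(**coerced)


def load_config(path: str | Path | None = None) -> AppConfig:
    """Load an :class:`AppConfig`; ``None`` returns all defaults."""
    if path is None:
        return AppConfig()
    data = tomllib.loads(Path(path).read_text())
    unknown = set(data) - set(_TABLES)
    if unknown:
        raise ValueError(f"unknown config tables: {sorted(unknown)}")
    parts = {name: _build(cls, data.get(name, {})) for name, cls in _TABLES.items()}
    return AppConfig(**parts)
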