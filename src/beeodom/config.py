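"""Scenario configuration: defaults, YAML loading, validation, round-trip.

Every default the original SOFIa model specifies is reproduced here (PD gains,
transfer-function constants, oscillation amplitude/frequency, EKF initial
state, wind constants, ramp way-points); the remaining knobs (hill geometry,
EKF noise covariances, sensor floor) are this package's documented choices.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any

import yaml

from .autopilot import ControllerParams, MissionProfile
from .dynamics import DynamicsParams
from .ekf import EkfParams
from .environment import TerrainProfile, WindParams

__all__ = ["SensingParams", "ScenarioConfig", "load_config", "save_config"]


@dataclass(frozen=True)
class SensingParams:
    """Sensor floor (m) and optional Gaussian measurement noise (rad s⁻¹)."""

    h_min: float = 0.01
    noise_sd_omega_T: float = 0.0
    noise_sd_omega_div: float = 0.0

    def __post_init__(self) -> None:
        if self.h_min <= 0:
            raise ValueError("h_min must be > 0")
        if self.noise_sd_omega_T < 0 or self.noise_sd_omega_div < 0:
            raise ValueError("noise SDs must be >= 0")


@dataclass(frozen=True)
class ScenarioConfig:
    """One fully specified simulation condition."""

    terrain: TerrainProfile = field(
        default_factory=lambda: TerrainProfile(ground_length=100.0, relief_kind="three_hills", h_peak=0.0)
    )
    wind: WindParams = field(default_factory=WindParams)
    controller: ControllerParams = field(default_factory=ControllerParams)
    mission: MissionProfile = field(default_factory=MissionProfile)
    dynamics: DynamicsParams = field(default_factory=DynamicsParams)
    ekf: EkfParams = field(default_factory=EkfParams)
    sensing: SensingParams = field(default_factory=SensingParams)
    max_duration: float = 300.0  # s, safety cap; runs exceeding it are flagged

    def __post_init__(self) -> None:
        if self.terrain.ground_length != self.mission.ground_length:
            raise ValueError(
                "terrain.ground_length and mission.ground_length must agree "
                f"({self.terrain.ground_length} != {self.mission.ground_length})"
            )
        if abs(self.wind.k_wind) > 1.5:
            raise ValueError("k_wind outside the modelled range [-1.5, 1.5]")
        if self.max_duration <= 0:
            raise ValueError("max_duration must be > 0")

    def with_overrides(self, **kv: Any) -> "ScenarioConfig":
        """Return a copy with dotted-key overrides, e.g. ``wind.k_wind=1.0``.

        Top-level block names may also be passed with ``__`` in place of the
        dot (``wind__k_wind=1.0``) for keyword-argument friendliness.
        """
        cfg = self
        for key, value in kv.items():
            key = key.replace("__", ".")
            if "." not in key:
                if not hasattr(cfg, key):
                    raise KeyError(f"unknown configuration key {key!r}")
                cfg = replace(cfg, **{key: value})
                continue
            block_name, field_name = key.split(".", 1)
            if not hasattr(cfg, block_name):
                raise KeyError(f"unknown configuration block {block_name!r}")
            block = getattr(cfg, block_name)
            if not hasattr(block, field_name):
                raise KeyError(f"unknown key {field_name!r} in block {block_name!r}")
            cfg = replace(cfg, **{block_name: replace(block, **{field_name: value})})
        return cfg

    def to_dict(self) -> dict:
        def listify(obj):
            if isinstance(obj, dict):
                return {k: listify(v) for k, v in obj.items()}
            if isinstance(obj, tuple):
                return [listify(v) for v in obj]
            return obj

        return listify(dataclasses.asdict(self))


_BLOCKS = {
    "terrain": TerrainProfile,
    "wind": WindParams,
    "controller": ControllerParams,
    "mission": MissionProfile,
    "dynamics": DynamicsParams,
    "ekf": EkfParams,
    "sensing": SensingParams,
}


def _build_block(cls, name: str, data: dict, current) -> Any:
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise KeyError(f"unknown key(s) {sorted(unknown)} in block {name!r}")
    clean = {
        k: tuple(v) if isinstance(v, list) else v for k, v in data.items()
    }
    return replace(current, **clean)


def load_config(path: str | Path | None = None, overrides: dict[str, Any] | None = None) -> ScenarioConfig:
    """Build a ScenarioConfig from defaults, an optional YAML file, and overrides.

    The YAML file holds nested blocks named after the config fields; an empty
    file yields all defaults.  Validation errors name the offending key.
    """
    cfg = ScenarioConfig()
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        updates: dict[str, Any] = {}
        for name, value in raw.items():
            if name in _BLOCKS:
                if not isinstance(value, dict):
                    raise ValueError(f"block {name!r} must be a mapping")
                updates[name] = _build_block(_BLOCKS[name], name, value, getattr(cfg, name))
            elif name == "max_duration":
                updates[name] = float(value)
            else:
                raise KeyError(f"unknown configuration block {name!r}")
        cfg = replace(cfg, **updates)
    if overrides:
        cfg = cfg.with_overrides(**overrides)
    return cfg


def save_config(cfg: ScenarioConfig, path: str | Path) -> None:
    """Write a config as YAML; reloading it reproduces the config exactly."""
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))
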