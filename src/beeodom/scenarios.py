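"""Preset scenario builders for the two reference courses.

The short course is 8 m of flat ground (landing ramp from 5.5 m); the long
course is 100 m (landing ramp from 95.5 m), optionally carrying relief.  Both
use the printed single-run settings: optic-flow setpoint 2.5 rad s⁻¹,
oscillation 18° at 1 Hz, EKF initialized at 0.5 m / 1 m s⁻¹.  The cruise
pitch of single runs is not printed and defaults to the 40° grid midpoint.
"""

from __future__ import annotations

from dataclasses import replace

from .autopilot import ControllerParams, MissionProfile
from .config import ScenarioConfig
from .environment import TerrainProfile

__all__ = ["flat_course_8m", "long_course_100m", "irregular_course_100m"]


def _base(terrain: TerrainProfile, mission: MissionProfile, k_wind: float, **overrides) -> ScenarioConfig:
    cfg = ScenarioConfig(terrain=terrain, mission=mission)
    cfg = cfg.with_overrides(wind__k_wind=k_wind, **overrides)
    return cfg


def flat_course_8m(k_wind: float = 0.0, **overrides) -> ScenarioConfig:
    """8 m flat-ground course with take-off, short cruise and landing."""
    terrain = TerrainProfile(ground_length=8.0, relief_kind="flat")
    mission = MissionProfile(ground_length=8.0, landing_start_x=5.5, u_theta_cruise=40.0)
    return _base(terrain, mission, k_wind, **overrides)


def long_course_100m(k_wind: float = 0.0, h_peak: float = 0.0,
                     hill_scales: tuple = (1.0, 1.0, 1.0), **overrides) -> ScenarioConfig:
    """100 m course; relief is three raised-cosine hills scaled to ``h_peak``."""
    kind = "three_hills" if h_peak > 0 else "flat"
    terrain = TerrainProfile(
        ground_length=100.0, relief_kind=kind, h_peak=h_peak, hill_scales=hill_scales
    )
    mission = MissionProfile(ground_length=100.0, landing_start_x=95.5, u_theta_cruise=40.0)
    return _base(terrain, mission, k_wind, **overrides)


def irregular_course_100m(k_wind: float = 0.0, **overrides) -> ScenarioConfig:
    """100 m course over irregular ground: hills of 1 m, 2 m and 1.5 m."""
    return long_course_100m(
        k_wind=k_wind, h_peak=2.0, hill_scales=(0.5, 1.0, 0.75), **overrides
    )
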