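"""Terrain relief profiles and the height-dependent logarithmic wind model.

The simulated bee flies over either flat ground or a course carrying three
raised-cosine hills separated by flat stretches.  The wind blows along-track
with a magnitude that grows logarithmically with clearance from the ground,
positive coefficients meaning tail wind and negative ones head wind.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TerrainProfile",
    "WindParams",
    "terrain_elevation",
    "terrain_slope",
    "wind_speed",
]


@dataclass(frozen=True)
class TerrainProfile:
    """Parametric ground-elevation profile along a 1-D course.

    Parameters
    ----------
    ground_length:
        Length of the course in metres.
    relief_kind:
        ``"flat"`` or ``"three_hills"``.
    h_peak:
        Peak relief height in metres (the tallest hill reaches exactly this).
    hill_width:
        Footprint of each raised-cosine hill (m).
    hill_centers:
        Along-track centres of the three hills (m).
    hill_scales:
        Per-hill multipliers on ``h_peak`` (max must be 1 so the profile's
        maximum equals ``h_peak``); unequal values give hills of various
        heights and slopes.
    """

    ground_length: float
    relief_kind: str = "flat"
    h_peak: float = 0.0
    hill_width: float = 20.0
    hill_centers: tuple[float, ...] = (25.0, 50.0, 75.0)
    hill_scales: tuple[float, ...] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if self.relief_kind not in ("flat", "three_hills"):
            raise ValueError(f"unknown relief_kind {self.relief_kind!r}")
        if self.ground_length <= 0:
            raise ValueError("ground_length must be > 0")
        if self.h_peak < 0:
            raise ValueError("h_peak must be >= 0")
        if self.relief_kind == "three_hills":
            if len(self.hill_centers) != len(self.hill_scales):
                raise ValueError("hill_centers and hill_scales lengths differ")
            if self.h_peak > 0 and abs(max(self.hill_scales) - 1.0) > 1e-12:
                raise ValueError("max(hill_scales) must equal 1")


@dataclass(frozen=True)
class WindParams:
    """Logarithmic along-track wind profile ``v = k_wind * v0 * ln(h/h0)``.

    ``k_wind`` sets strength and direction (+ tail, − head); ``v0`` is the
    reference speed (m s⁻¹) and ``h0`` the roughness height (m) below which
    the wind is taken as zero.
    """

    k_wind: float = 0.0
    v0: float = 0.2
    h0: float = 0.05

    def __post_init__(self) -> None:
        if self.v0 <= 0:
            raise ValueError("v0 must be > 0")
        if self.h0 <= 0:
            raise ValueError("h0 must be > 0")


def _unit_bumps(x: np.ndarray, profile: TerrainProfile) -> np.ndarray:
    """Sum of raised-cosine bumps with unit h_peak, evaluated at ``x``."""
    x = np.asarray(x, dtype=float)
    w = profile.hill_width
    out = np.zeros(np.broadcast(x).shape if x.shape == () else x.shape)
    for c, s in zip(profile.hill_centers, profile.hill_scales):
        inside = np.abs(x - c) < w / 2.0
        bump = 0.5 * s * (1.0 - np.cos(2.0 * np.pi * (x - (c - w / 2.0)) / w))
        out = out + np.where(inside, bump, 0.0)
    return out


def _unit_bump_slopes(x: np.ndarray, profile: TerrainProfile) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    w = profile.hill_width
    out = np.zeros(np.broadcast(x).shape if x.shape == () else x.shape)
    for c, s in zip(profile.hill_centers, profile.hill_scales):
        inside = np.abs(x - c) < w / 2.0
        slope = s * (np.pi / w) * np.sin(2.0 * np.pi * (x - (c - w / 2.0)) / w)
        out = out + np.where(inside, slope, 0.0)
    return out


def _check_range(profile: TerrainProfile, x) -> None:
    x = np.asarray(x, dtype=float)
    if np.any(x < 0) or np.any(x > profile.ground_length):
        raise ValueError(
            f"x outside [0, {profile.ground_length}] for this terrain profile"
        )


def terrain_elevation(profile: TerrainProfile, x):
    """Ground-surface elevation (m) at along-track position ``x`` (m).

    Accepts scalars or arrays; raises for ``x`` outside the course.
    """
    _check_range(profile, x)
    if profile.relief_kind == "flat" or profile.h_peak == 0.0:
        return np.zeros_like(np.asarray(x, dtype=float)) if np.ndim(x) else 0.0
    val = profile.h_peak * _unit_bumps(np.asarray(x, dtype=float), profile)
    return val if np.ndim(x) else float(val)


def terrain_slope(profile: TerrainProfile, x):
    """d(elevation)/dx (dimensionless) at ``x``; zero on flat stretches."""
    _check_range(profile, x)
    if profile.relief_kind == "flat" or profile.h_peak == 0.0:
        return np.zeros_like(np.asarray(x, dtype=float)) if np.ndim(x) else 0.0
    val = profile.h_peak * _unit_bump_slopes(np.asarray(x, dtype=float), profile)
    return val if np.ndim(x) else float(val)


def wind_speed(wind: WindParams, h):
    """Signed along-track wind speed (m s⁻¹) at clearance ``h`` (m).

    Follows ``k_wind * v0 * ln(h / h0)`` above the roughness height and is
    clamped to zero for ``h <= h0`` so take-off from the ground is well-posed.
    Negative clearance is rejected.
    """
    harr = np.asarray(h, dtype=float)
    if np.any(harr <= 0):
        raise ValueError("clearance h must be > 0 for wind evaluation")
    val = np.where(
        harr > wind.h0,
        wind.k_wind * wind.v0 * np.log(np.maximum(harr, wind.h0) / wind.h0),
        0.0,
    )
    return val if np.ndim(h) else float(val)
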