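"""First-order vertical and forward flight dynamics of the simulated bee.

Two scalar transfer functions model the bee: wing-stroke amplitude delta
(degrees) drives vertical speed through ``K_z / (1 + tau_z s)`` and pitch
(degrees) drives air speed through ``K_surge / (1 + tau_surge s)``.  Both are
advanced with the exact exponential discretization, so the fixed 1 ms step
introduces no solver error for piecewise-constant commands.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .environment import TerrainProfile, WindParams, terrain_elevation, terrain_slope, wind_speed

__all__ = ["DynamicsParams", "BeeState", "step_vertical", "step_forward", "integrate_kinematics"]


@dataclass(frozen=True)
class DynamicsParams:
    """Gains (m s⁻¹ per degree), time constants (s) and integration step (s)."""

    K_z: float = 0.11
    tau_z: float = 0.22
    K_surge: float = 0.10
    tau_surge: float = 0.22
    dt: float = 1e-3

    def __post_init__(self) -> None:
        if self.tau_z <= 0 or self.tau_surge <= 0:
            raise ValueError("time constants must be > 0")
        if not 0 < self.dt < min(self.tau_z, self.tau_surge):
            raise ValueError("dt must be positive and well below the time constants")


@dataclass
class BeeState:
    """Kinematic ground truth at one instant.

    ``h`` is clearance above the local terrain (``z - elevation(x)``); ``V_x``
    is ground speed (``V_air`` plus local wind); ``V_h`` is clearance rate
    (``V_z`` minus the slope-induced term).
    """

    t: float = 0.0
    x: float = 0.0
    z: float = 0.0
    h: float = 0.0
    V_z: float = 0.0
    V_air: float = 0.0
    V_x: float = 0.0
    V_h: float = 0.0


def _first_order_step(y, u, K: float, tau: float, dt: float):
    a = np.exp(-dt / tau)
    return y * a + K * u * (1.0 - a)


def step_vertical(V_z, u_dphi, params: DynamicsParams, dt: float | None = None):
    """One exact step of the vertical-speed dynamics driven by stroke delta (deg)."""
    if not (np.all(np.isfinite(V_z)) and np.all(np.isfinite(u_dphi))):
        raise ValueError("non-finite input to step_vertical")
    return _first_order_step(V_z, u_dphi, params.K_z, params.tau_z, dt or params.dt)


def step_forward(V_air, u_theta, params: DynamicsParams, dt: float | None = None):
    """One exact step of the air-speed dynamics driven by pitch (deg)."""
    if not (np.all(np.isfinite(V_air)) and np.all(np.isfinite(u_theta))):
        raise ValueError("non-finite input to step_forward")
    return _first_order_step(V_air, u_theta, params.K_surge, params.tau_surge, dt or params.dt)


def integrate_kinematics(
    state: BeeState,
    profile: TerrainProfile,
    wind: WindParams,
    dt: float,
) -> BeeState:
    """Advance position/altitude by one step and re-derive the dependent fields.

    Altitude is clamped at the local terrain so the clearance never goes
    negative (ground contact); wind and ground speed are recomputed at the new
    clearance, and the clearance rate picks up the slope-induced term.
    """
    x_new = state.x + state.V_x * dt
    if x_new > profile.ground_length:  # course ends; terrain queries stay in range
        x_new = profile.ground_length
    elev = terrain_elevation(profile, x_new)
    z_new = max(elev, state.z + state.V_z * dt)
    h_new = z_new - elev
    v_wind = wind_speed(wind, max(h_new, 1e-9))
    V_x = state.V_air + v_wind
    V_h = state.V_z - terrain_slope(profile, x_new) * V_x
    return BeeState(
        t=state.t + dt, x=x_new, z=z_new, h=h_new,
        V_z=state.V_z, V_air=state.V_air, V_x=V_x, V_h=V_h,
    )
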