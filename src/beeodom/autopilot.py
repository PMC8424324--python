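"""Optic-flow regulator, self-oscillation injection and mission pitch profile.

The vertical loop is a PD regulator holding the measured translational optic
flow at a setpoint: flying too low (or too fast) raises the optic flow, the
regulator commands a larger wing-stroke amplitude, the bee climbs and the
optic flow falls back — a negative feedback loop acting on the denominator
(clearance) of the optic-flow ratio.  A sine command added to the regulator
output produces the vertical self-oscillation that makes the clearance
observable.  The mission is encoded as a pitch profile over along-track
position: an ascending take-off ramp, a cruise plateau, and a descending
landing ramp.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ControllerParams",
    "MissionProfile",
    "pd_regulator",
    "oscillation_command",
    "pitch_profile",
    "stroke_command",
]


@dataclass(frozen=True)
class ControllerParams:
    """Optic-flow regulator and oscillation parameters.

    ``k_P``/``k_D`` are the PD gains on the optic-flow error (rad s⁻¹ →
    degrees of stroke amplitude); the derivative acts on a first-order
    low-pass filtered error with time constant ``tau_d`` to avoid step-level
    derivative noise.  The oscillation ``A_osc * sin(2*pi*f_osc*t)`` is only
    injected above the gate height ``h_gate`` so take-off and landing stay
    smooth.
    """

    k_P: float = 15.0
    k_D: float = 0.3
    omega_T_set: float = 2.5
    A_osc: float = 18.0
    f_osc: float = 1.0
    h_gate: float = 0.05
    tau_d: float = 0.02

    def __post_init__(self) -> None:
        if self.k_P < 0 or self.k_D < 0:
            raise ValueError("PD gains must be >= 0")
        if self.f_osc <= 0:
            raise ValueError("f_osc must be > 0")
        if self.omega_T_set <= 0:
            raise ValueError("omega_T_set must be > 0")


@dataclass(frozen=True)
class MissionProfile:
    """Pitch-profile way-points of one course.

    Pitch ramps linearly from 0 to ``u_theta_cruise`` over
    ``[0, takeoff_end_x]``, holds in cruise, and ramps back to 0 over
    ``[landing_start_x, ground_length]``.  ``x_boot`` is a small offset inside
    the take-off ramp argument giving a non-zero initial pitch (the ramp is a
    function of position, which would otherwise never leave x = 0).
    """

    ground_length: float = 100.0
    takeoff_end_x: float = 1.0
    landing_start_x: float = 95.5
    u_theta_cruise: float = 40.0
    x_boot: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.takeoff_end_x < self.landing_start_x < self.ground_length:
            raise ValueError(
                "mission requires 0 < takeoff_end_x < landing_start_x < ground_length"
            )
        if not 0 < self.u_theta_cruise:
            raise ValueError("u_theta_cruise must be > 0")


def pd_regulator(omega_T_meas, omega_T_set, e_filt_prev, dt: float, params: ControllerParams):
    """PD feedback on the optic-flow error.

    Returns ``(u_fb, e_filt)`` where ``u_fb`` (deg) is the stroke-amplitude
    correction and ``e_filt`` the updated low-pass-filtered error state used
    by the derivative term.  Error convention: ``e = measured − setpoint``
    with positive gains, so excess optic flow (too low or too fast) commands
    a climb.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    e = np.asarray(omega_T_meas, dtype=float) - omega_T_set
    alpha = dt / (params.tau_d + dt)
    e_filt = e_filt_prev + alpha * (e - e_filt_prev)
    u_fb = params.k_P * e + params.k_D * (e_filt - e_filt_prev) / dt
    return u_fb, e_filt


def oscillation_command(t, params: ControllerParams, h):
    """Self-oscillation stroke command (deg): a sine of time, gated on height."""
    u = params.A_osc * np.sin(2.0 * np.pi * params.f_osc * np.asarray(t, dtype=float))
    val = np.where(np.asarray(h, dtype=float) >= params.h_gate, u, 0.0)
    return val if (np.ndim(t) or np.ndim(h)) else float(val)


def pitch_profile(x, mission: MissionProfile):
    """Commanded pitch (deg) at along-track position ``x`` (m)."""
    xarr = np.asarray(x, dtype=float)
    up = np.clip((xarr + mission.x_boot) / mission.takeoff_end_x, 0.0, 1.0)
    down = np.clip(
        (mission.ground_length - xarr)
        / (mission.ground_length - mission.landing_start_x),
        0.0,
        1.0,
    )
    val = mission.u_theta_cruise * np.minimum(up, down)
    return val if np.ndim(x) else float(val)


def stroke_command(u_fb, u_osc):
    """Total wing-stroke amplitude delta: regulator output plus oscillation."""
    return u_fb + u_osc
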