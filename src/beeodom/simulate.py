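"""Closed-loop flight simulation of one or many scenario conditions.

The simulator advances, at a fixed 1 ms step, the full loop of the
bee-inspired autopilot: mission pitch profile → forward dynamics → wind →
ventral optic-flow sensing → PD optic-flow regulator plus self-oscillation →
vertical dynamics → kinematics over terrain, with the clearance EKF and both
flight-distance odometers running alongside.

All state is carried in NumPy arrays with one lane per condition, so a single
run and the full 630-condition parametric sweep go through exactly the same
code path; lanes terminate independently (final values are snapshotted the
step a lane finishes) and the loop ends when every lane is done.

A run terminates when the bee crosses the end of the course or when it has
touched down (clearance at the sensor floor) after the landing ramp has
begun.  Runs exceeding the safety cap are flagged as diverged, never silently
dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ScenarioConfig
from .ekf import (
    predict_arrays as _ekf_predict_arrays,
    transition_constants,
    update_arrays as _ekf_update_arrays,
)

__all__ = ["SimResult", "simulate", "run_scenario"]

_TRAJ_COLUMNS = [
    "t", "x", "z", "h", "V_x", "V_h", "V_air", "v_wind",
    "u_theta", "u_dphi", "omega_T", "omega_div",
    "h_hat", "v_h_hat", "x_sofia", "of_acc",
]


@dataclass
class SimResult:
    """Per-condition final records and (optionally) decimated trajectories."""

    records: pd.DataFrame
    trajectories: list[pd.DataFrame] | None = None


def _gather(configs, attr_path):
    block, name = attr_path
    return np.array([getattr(getattr(c, block), name) for c in configs], dtype=float)


def _shared(configs, attr_path, what):
    values = {getattr(getattr(c, attr_path[0]), attr_path[1]) for c in configs}
    if len(values) != 1:
        raise ValueError(f"{what} must be identical across a batch, got {values}")
    return values.pop()


def simulate(
    configs: ScenarioConfig | list[ScenarioConfig],
    record: bool = False,
    log_every: int = 10,
    seed: int | None = None,
    check_covariance: bool = False,
) -> SimResult:
    """Run one or many scenarios to termination.

    Parameters
    ----------
    configs:
        A single config or a list; per-condition fields (wind coefficient,
        relief height, optic-flow setpoint, cruise pitch, oscillation
        amplitude/frequency, EKF initial state and noise levels, course
        lengths) may differ between lanes, while the integration step, plant
        constants and regulator gains must be shared.
    record:
        Keep decimated per-step trajectories (one DataFrame per condition).
    log_every:
        Decimation factor for trajectory rows (10 → 100 Hz at the 1 ms step).
    seed:
        Seed for the measurement-noise generator (only used when a config
        enables sensor noise; the default simulations are deterministic).
    check_covariance:
        Assert at every step that each lane's EKF covariance stays symmetric
        positive semi-definite (test mode).
    """
    if isinstance(configs, ScenarioConfig):
        configs = [configs]
    n = len(configs)
    if n == 0:
        raise ValueError("no configs given")

    # shared scalars
    dt = float(_shared(configs, ("dynamics", "dt"), "dt"))
    K_z = float(_shared(configs, ("dynamics", "K_z"), "K_z"))
    tau_z = float(_shared(configs, ("dynamics", "tau_z"), "tau_z"))
    K_s = float(_shared(configs, ("dynamics", "K_surge"), "K_surge"))
    tau_s = float(_shared(configs, ("dynamics", "tau_surge"), "tau_surge"))
    k_P = float(_shared(configs, ("controller", "k_P"), "k_P"))
    k_D = float(_shared(configs, ("controller", "k_D"), "k_D"))
    tau_d = float(_shared(configs, ("controller", "tau_d"), "tau_d"))
    h_gate = float(_shared(configs, ("controller", "h_gate"), "h_gate"))
    h_min = float(_shared(configs, ("sensing", "h_min"), "h_min"))
    v0 = float(_shared(configs, ("wind", "v0"), "v0"))
    h0 = float(_shared(configs, ("wind", "h0"), "h0"))
    sd_T = float(_shared(configs, ("sensing", "noise_sd_omega_T"), "noise sd"))
    sd_D = float(_shared(configs, ("sensing", "noise_sd_omega_div"), "noise sd"))
    width = float(_shared(configs, ("terrain", "hill_width"), "hill_width"))
    centers = configs[0].terrain.hill_centers
    for c in configs:
        if c.terrain.hill_centers != centers:
            raise ValueError("hill_centers must be identical across a batch")

    # per-lane arrays
    k_wind = _gather(configs, ("wind", "k_wind"))
    h_peak = np.array(
        [c.terrain.h_peak if c.terrain.relief_kind == "three_hills" else 0.0 for c in configs]
    )
    scales = np.array([c.terrain.hill_scales for c in configs], dtype=float).T  # (3, n)
    L = _gather(configs, ("mission", "ground_length"))
    x_land = _gather(configs, ("mission", "landing_start_x"))
    x_toff = _gather(configs, ("mission", "takeoff_end_x"))
    x_boot = _gather(configs, ("mission", "x_boot"))
    pitch_cruise = _gather(configs, ("mission", "u_theta_cruise"))
    w_set = _gather(configs, ("controller", "omega_T_set"))
    A_osc = _gather(configs, ("controller", "A_osc"))
    f_osc = _gather(configs, ("controller", "f_osc"))
    q1 = _gather(configs, ("ekf", "q_h")) * dt
    q2 = _gather(configs, ("ekf", "q_v")) * dt
    r_div = _gather(configs, ("ekf", "r_div"))

    any_relief = bool(np.any(h_peak > 0))
    cen = np.asarray(centers, dtype=float)[:, None]  # (3, 1)
    phase_k = 2.0 * np.pi / width
    slope_k = np.pi / width

    # precomputed discrete-transition constants
    az = np.exp(-dt / tau_z)
    bz = K_z * (1.0 - az)
    asur = np.exp(-dt / tau_s)
    bsur = K_s * (1.0 - asur)
    ekf_consts = transition_constants(K_z, tau_z, dt)
    alpha_d = dt / (tau_d + dt)
    two_pi = 2.0 * np.pi

    rng = np.random.default_rng(seed) if (sd_T > 0 or sd_D > 0) else None

    # state
    x = np.zeros(n)
    z = np.zeros(n)
    h = np.zeros(n)
    V_z = np.zeros(n)
    V_air = np.zeros(n)
    V_x = np.zeros(n)
    V_h = np.zeros(n)
    e_f = np.zeros(n)
    hh = _gather(configs, ("ekf", "h_init"))
    vh = _gather(configs, ("ekf", "v_init"))
    p11 = _gather(configs, ("ekf", "p_h_init"))
    p12 = np.zeros(n)
    p22 = _gather(configs, ("ekf", "p_v_init"))
    x_sofia = np.zeros(n)
    of_acc = np.zeros(n)
    x_sofia_true = np.zeros(n)
    lifted = np.zeros(n, dtype=bool)
    done = np.zeros(n, dtype=bool)
    diverged = np.zeros(n, dtype=bool)

    finals = {
        k: np.full(n, np.nan)
        for k in ("t", "x", "x_sofia", "of_acc", "x_sofia_true", "h", "h_hat", "hhat_rel_err")
    }
    landed = np.zeros(n, dtype=bool)
    cruise_n = np.zeros(n)
    cruise_sum_wT = np.zeros(n)
    cruise_sum_h = np.zeros(n)
    cruise_min_h = np.full(n, np.inf)
    cruise_max_h = np.zeros(n)
    max_h = np.zeros(n)
    max_z = np.zeros(n)
    max_vx = np.zeros(n)
    max_avw = np.zeros(n)
    max_hrel = np.zeros(n)

    max_steps = int(np.ceil(max(c.max_duration for c in configs) / dt))
    traj: list[tuple] = []

    def terrain_at(xq):
        if not any_relief:
            zero = np.zeros_like(xq)
            return zero, zero
        d = xq[None, :] - cen
        inside = np.abs(d) < width / 2.0
        phi = phase_k * (d + width / 2.0)
        bump = np.where(inside, 0.5 * (1.0 - np.cos(phi)), 0.0)
        dbump = np.where(inside, slope_k * np.sin(phi), 0.0)
        elev = h_peak * np.sum(scales * bump, axis=0)
        slope = h_peak * np.sum(scales * dbump, axis=0)
        return elev, slope

    elev, slope = terrain_at(x)
    t = 0.0
    for step in range(max_steps):
        t = step * dt
        active = ~done

        # --- mission pitch profile over along-track position
        up = np.clip((x + x_boot) / x_toff, 0.0, 1.0)
        down = np.clip((L - x) / (L - x_land), 0.0, 1.0)
        u_theta = pitch_cruise * np.minimum(up, down)

        # --- ventral optic-flow sensing (floored clearance)
        h_eff = np.maximum(h, h_min)
        w_T = V_x / h_eff
        w_div = V_h / h_eff
        if rng is not None:
            if sd_T > 0:
                w_T = w_T + rng.normal(0.0, sd_T, n)
            if sd_D > 0:
                w_div = w_div + rng.normal(0.0, sd_D, n)

        # --- PD optic-flow regulator (derivative on low-pass filtered error)
        e = w_T - w_set
        e_f_new = e_f + alpha_d * (e - e_f)
        u_fb = k_P * e + k_D * (e_f_new - e_f) / dt
        e_f = e_f_new

        # --- self-oscillation, gated on clearance
        u_osc = np.where(h >= h_gate, A_osc * np.sin(two_pi * f_osc * t), 0.0)
        u_dphi = u_fb + u_osc

        # --- clearance EKF: predict with the efference copy, correct with divergence
        hh, vh, p11, p12, p22 = _ekf_predict_arrays(hh, vh, p11, p12, p22, u_dphi, ekf_consts, q1, q2)
        hh, vh, p11, p12, p22 = _ekf_update_arrays(hh, vh, p11, p12, p22, w_div, r_div)
        if check_covariance:
            det = p11 * p22 - p12 * p12
            if np.any(p11 < -1e-12) or np.any(p22 < -1e-12) or np.any(det < -1e-9):
                raise FloatingPointError("EKF covariance lost positive semi-definiteness")

        # --- odometers (accumulate from lift-off to termination)
        lifted |= h > h_min
        acc = lifted & active
        w_T_acc = np.where(acc, w_T, 0.0)
        x_sofia = x_sofia + w_T_acc * hh * dt
        of_acc = of_acc + w_T_acc * dt
        x_sofia_true = x_sofia_true + w_T_acc * h_eff * dt

        if record and step % log_every == 0:
            traj.append((t, x.copy(), z.copy(), h.copy(), V_x.copy(), V_h.copy(),
                         V_air.copy(), (V_x - V_air).copy(), u_theta, u_dphi,
                         w_T, w_div, hh.copy(), vh.copy(), x_sofia.copy(), of_acc.copy()))

        # --- plant dynamics (exact discretization) and kinematics over terrain
        V_z = az * V_z + bz * u_dphi
        V_air = asur * V_air + bsur * u_theta
        x = x + V_x * dt
        elev, slope = terrain_at(x)
        z_free = z + V_z * dt
        on_ground = z_free <= elev
        z = np.where(on_ground, elev, z_free)
        V_z = np.where(on_ground & (V_z < 0.0), 0.0, V_z)
        h = z - elev
        v_wind = np.where(h > h0, k_wind * v0 * np.log(np.maximum(h, h0) / h0), 0.0)
        V_x = V_air + v_wind
        V_h = V_z - slope * V_x

        # --- aggregates over the active lanes
        in_cruise = active & (x > x_toff + 1.0) & (x < x_land)
        cruise_n += in_cruise
        cruise_sum_wT += np.where(in_cruise, w_T, 0.0)
        cruise_sum_h += np.where(in_cruise, h, 0.0)
        cruise_min_h = np.minimum(cruise_min_h, np.where(in_cruise, h, np.inf))
        cruise_max_h = np.maximum(cruise_max_h, np.where(in_cruise, h, 0.0))
        max_h = np.maximum(max_h, np.where(active, h, 0.0))
        max_z = np.maximum(max_z, np.where(active, z, 0.0))
        max_vx = np.maximum(max_vx, np.where(active, V_x, 0.0))
        max_avw = np.maximum(max_avw, np.where(active, np.abs(v_wind), 0.0))
        hrel = np.abs(hh - h) / np.maximum(h, h_min)
        max_hrel = np.maximum(max_hrel, np.where(acc, hrel, 0.0))

        # --- termination: course crossed, or touchdown after the landing ramp began
        touched = lifted & (h <= h_min) & (x > x_land)
        crossed = x >= L
        newly = active & (touched | crossed)
        if newly.any():
            idx = np.nonzero(newly)[0]
            finals["t"][idx] = t + dt
            finals["x"][idx] = x[idx]
            finals["x_sofia"][idx] = x_sofia[idx]
            finals["of_acc"][idx] = of_acc[idx]
            finals["x_sofia_true"][idx] = x_sofia_true[idx]
            finals["h"][idx] = h[idx]
            finals["h_hat"][idx] = hh[idx]
            finals["hhat_rel_err"][idx] = hrel[idx]
            landed[idx] = touched[idx]
            done[idx] = True
            if done.all():
                break
        if step % 2000 == 0 and not np.all(np.isfinite(h)):
            raise FloatingPointError("simulation state became non-finite")

    if not done.all():
        idx = np.nonzero(~done)[0]
        diverged[idx] = True
        finals["t"][idx] = t
        finals["x"][idx] = x[idx]
        finals["x_sofia"][idx] = x_sofia[idx]
        finals["of_acc"][idx] = of_acc[idx]
        finals["x_sofia_true"][idx] = x_sofia_true[idx]
        finals["h"][idx] = h[idx]
        finals["h_hat"][idx] = hh[idx]
        finals["hhat_rel_err"][idx] = np.abs(hh[idx] - h[idx]) / np.maximum(h[idx], h_min)

    err_pct = (finals["x_sofia"] - finals["x"]) / finals["x"] * 100.0
    records = pd.DataFrame(
        {
            "h_peak": h_peak,
            "k_wind": k_wind,
            "omega_T_set": w_set,
            "u_theta_cruise": pitch_cruise,
            "f_osc": f_osc,
            "A_osc": A_osc,
            "x_final": finals["x"],
            "t_final": finals["t"],
            "x_sofia": finals["x_sofia"],
            "of_acc": finals["of_acc"],
            "x_sofia_true": finals["x_sofia_true"],
            "err_pct_sofia": err_pct,
            "h_final": finals["h"],
            "h_hat_final": finals["h_hat"],
            "hhat_rel_err_final": finals["hhat_rel_err"],
            "max_hhat_rel_err": max_hrel,
            "cruise_mean_omega_T": np.where(cruise_n > 0, cruise_sum_wT / np.maximum(cruise_n, 1), np.nan),
            "cruise_mean_h": np.where(cruise_n > 0, cruise_sum_h / np.maximum(cruise_n, 1), np.nan),
            "cruise_h_p2p": np.where(cruise_n > 0, cruise_max_h - cruise_min_h, np.nan),
            "max_h": max_h,
            "max_z": max_z,
            "max_V_x": max_vx,
            "max_abs_v_wind": max_avw,
            "landed": landed,
            "diverged": diverged,
        }
    )

    trajectories = None
    if record:
        trajectories = []
        stacked = [np.array([row[0] for row in traj])] + [
            np.stack([row[j] for row in traj], axis=0) for j in range(1, len(_TRAJ_COLUMNS))
        ]
        for i in range(n):
            data = {"t": stacked[0]}
            for j, name in enumerate(_TRAJ_COLUMNS[1:], start=1):
                data[name] = stacked[j][:, i]
            df = pd.DataFrame(data)
            end_t = finals["t"][i]
            trajectories.append(df[df["t"] <= end_t].reset_index(drop=True))
    return SimResult(records=records, trajectories=trajectories)


def run_scenario(config: ScenarioConfig, record: bool = True, log_every: int = 10, seed: int | None = None):
    """Run a single scenario; returns ``(trajectory DataFrame or None, record Series)``."""
    res = simulate(config, record=record, log_every=log_every, seed=seed)
    traj = res.trajectories[0] if record else None
    return traj, res.records.iloc[0]
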