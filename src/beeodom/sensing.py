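"""Ventral optic-flow observables derived from the kinematic ground truth.

Two scalar cues are available to the bee: the translational optic flow
``omega_T = V_x / h`` (the ground image sweeping backward) and the optic-flow
divergence ``omega_div = V_h / h`` (expansion/contraction of the ventral
vector field caused by vertical motion).  Both are pure ratios, so they carry
no absolute scale — the ambiguity the clearance estimator resolves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["OpticFlowSample", "measure_optic_flow"]

#: sensor floor on clearance (m) keeping the ratios finite through touchdown
H_MIN = 0.01


@dataclass(frozen=True)
class OpticFlowSample:
    omega_T: float   # rad s⁻¹, translational optic flow
    omega_div: float  # rad s⁻¹, signed divergence (+ ascending)


def measure_optic_flow(V_x, V_h, h, h_min: float = H_MIN, rng=None, noise_sd=(0.0, 0.0)):
    """Measure (omega_T, omega_div) from ground speed, clearance rate and clearance.

    Measurements are noise-free by default; ``noise_sd`` adds independent
    Gaussian noise (rad s⁻¹) for robustness experiments.  Below ``h_min`` the
    clearance is floored so the sensor stays finite through touchdown.
    """
    harr = np.asarray(h, dtype=float)
    if np.any(harr < 0):
        raise ValueError("clearance h must be >= 0")
    h_eff = np.maximum(harr, h_min)
    omega_T = np.asarray(V_x, dtype=float) / h_eff
    omega_div = np.asarray(V_h, dtype=float) / h_eff
    if rng is not None and (noise_sd[0] > 0 or noise_sd[1] > 0):
        omega_T = omega_T + rng.normal(0.0, noise_sd[0], size=omega_T.shape)
        omega_div = omega_div + rng.normal(0.0, noise_sd[1], size=omega_div.shape)
    if np.ndim(h) or np.ndim(V_x):
        return omega_T, omega_div
    return OpticFlowSample(float(omega_T), float(omega_div))
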