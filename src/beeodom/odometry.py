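"""The two flight-distance integrators and their comparison helpers.

The self-scaled odometer (SOFIa) integrates the measured translational optic
flow multiplied by the EKF clearance estimate, giving metres.  The raw
accumulator (OFacc) integrates the optic flow alone, giving radians — the
dimensional gap is the scientific point.  ``k_comparisons`` maps a whole
OFacc distribution onto metres after the fact (100 / median), purely so the
two distributions can be compared statistically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "OdometerState",
    "sofia_step",
    "ofacc_step",
    "k_comparisons",
    "error_percent",
]


@dataclass
class OdometerState:
    x_sofia: float = 0.0  # metres
    of_acc: float = 0.0   # radians


def sofia_step(state: OdometerState, omega_T_meas: float, h_hat: float, dt: float) -> OdometerState:
    """Accumulate the clearance-scaled optic flow: ``x += omega_T * h_hat * dt``."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if h_hat < 0:
        raise ValueError("h_hat must be >= 0")
    state.x_sofia += omega_T_meas * h_hat * dt
    return state


def ofacc_step(state: OdometerState, omega_T_meas: float, dt: float) -> OdometerState:
    """Accumulate the raw optic flow: ``of_acc += omega_T * dt`` (radians)."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    state.of_acc += omega_T_meas * dt
    return state


def k_comparisons(of_acc_finals) -> float:
    """Post-hoc calibration factor ``100 / median(OFacc finals)`` (m rad⁻¹).

    Computed from the experiment's own distribution of final accumulated
    optic flow, never hard-coded; it only serves statistical comparison.
    """
    values = np.asarray(of_acc_finals, dtype=float)
    if values.size == 0:
        raise ValueError("need at least one OFacc final")
    med = float(np.median(values))
    if med <= 0:
        raise ValueError("median OFacc must be > 0")
    return 100.0 / med


def error_percent(x_hat: float, x_true: float) -> float:
    """Signed flight-distance error ``(x_hat − x_true)/x_true × 100`` (%)."""
    if x_true <= 0:
        raise ValueError("x_true must be > 0")
    return (x_hat - x_true) / x_true * 100.0
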