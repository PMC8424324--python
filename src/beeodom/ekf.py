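"""Extended Kalman filter estimating clearance from optic-flow divergence.

State ``[h, v_h]`` (clearance and clearance rate) follows the linear vertical
dynamics driven by the wing-stroke efference copy:

    dh/dt   = v_h
    dv_h/dt = (K_z * u − v_h) / tau_z

while the measurement ``omega_div = v_h / h`` is nonlinear, making this an
EKF.  Clearance enters the measurement only through a ratio, so the state is
observable only while the control input keeps perturbing the vertical
dynamics — the role of the self-oscillation.  After every predict and update
the clearance estimate is replaced by its absolute value (clearance is
physically positive); this guard speeds up and robustifies convergence.

The covariance is propagated in Joseph form and stored as the three unique
elements of the symmetric 2×2 matrix, which lets the same closed-form code
run on scalars or on whole batches of conditions at once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "EkfParams",
    "EkfEstimate",
    "ekf_predict",
    "ekf_update",
    "observability_matrix",
]


@dataclass(frozen=True)
class EkfParams:
    """Noise covariances and initial conditions.

    ``q_h``/``q_v`` are continuous-time process-noise intensities for the
    clearance and clearance-rate states (discretized as ``q*dt``); ``r_div``
    is the divergence measurement variance.  Initial state (0.5 m, 1 m s⁻¹)
    is deliberately far from the truth to exercise convergence.
    """

    q_h: float = 1e-4
    q_v: float = 1e-2
    r_div: float = 1e-2
    h_init: float = 0.5
    v_init: float = 1.0
    p_h_init: float = 1.0
    p_v_init: float = 1.0

    def __post_init__(self) -> None:
        if self.q_h < 0 or self.q_v < 0:
            raise ValueError("process noise intensities must be >= 0")
        if self.r_div <= 0:
            raise ValueError("r_div must be > 0")


@dataclass
class EkfEstimate:
    """Clearance/clearance-rate estimate with 2×2 covariance."""

    h_hat: float
    v_h_hat: float
    P: np.ndarray

    @classmethod
    def from_params(cls, params: EkfParams) -> "EkfEstimate":
        return cls(
            h_hat=params.h_init,
            v_h_hat=params.v_init,
            P=np.diag([params.p_h_init, params.p_v_init]).astype(float),
        )


def transition_constants(K_z: float, tau_z: float, dt: float):
    """Exact discrete transition of the linear vertical model over ``dt``.

    Returns ``(f12, f22, b1, b2)`` with ``F = [[1, f12], [0, f22]]`` and input
    vector ``[b1, b2] * u``.
    """
    a = np.exp(-dt / tau_z)
    f12 = tau_z * (1.0 - a)
    f22 = a
    b2 = K_z * (1.0 - a)
    b1 = K_z * (dt - f12)
    return f12, f22, b1, b2


# ---------------------------------------------------------------------------
# array-form core (scalar or batched); P carried as (p11, p12, p22)

def predict_arrays(h, v, p11, p12, p22, u, consts, q1, q2):
    f12, f22, b1, b2 = consts
    h_new = np.abs(h + f12 * v + b1 * u)
    v_new = f22 * v + b2 * u
    p11_n = p11 + 2.0 * f12 * p12 + f12 * f12 * p22 + q1
    p12_n = f22 * (p12 + f12 * p22)
    p22_n = f22 * f22 * p22 + q2
    return h_new, v_new, p11_n, p12_n, p22_n


def update_arrays(h, v, p11, p12, p22, y, r):
    h1 = -v / (h * h)
    h2 = 1.0 / h
    s = h1 * (h1 * p11 + 2.0 * h2 * p12) + h2 * h2 * p22 + r
    k1 = (p11 * h1 + p12 * h2) / s
    k2 = (p12 * h1 + p22 * h2) / s
    nu = y - v / h
    h_new = np.abs(h + k1 * nu)
    v_new = v + k2 * nu
    a11 = 1.0 - k1 * h1
    a12 = -k1 * h2
    a21 = -k2 * h1
    a22 = 1.0 - k2 * h2
    c11 = a11 * p11 + a12 * p12
    c12 = a11 * p12 + a12 * p22
    c21 = a21 * p11 + a22 * p12
    c22 = a21 * p12 + a22 * p22
    p11_n = c11 * a11 + c12 * a12 + r * k1 * k1
    p12_n = c21 * a11 + c22 * a12 + r * k1 * k2
    p22_n = c21 * a21 + c22 * a22 + r * k2 * k2
    return h_new, v_new, p11_n, p12_n, p22_n


def _check_psd(P: np.ndarray) -> np.ndarray:
    """Symmetrize and clip tiny negative eigenvalues; raise if truly non-PSD."""
    P = 0.5 * (P + P.T)
    w, V = np.linalg.eigh(P)
    if np.any(w < -1e-6 * max(1.0, float(np.max(np.abs(w))))):
        raise FloatingPointError("EKF covariance lost positive semi-definiteness")
    w = np.clip(w, 0.0, None)
    return (V * w) @ V.T


def ekf_predict(est: EkfEstimate, u_dphi: float, dt: float, dyn_params, ekf_params: EkfParams) -> EkfEstimate:
    """Propagate the estimate through the exact discrete vertical model."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    consts = transition_constants(dyn_params.K_z, dyn_params.tau_z, dt)
    p11, p12, p22 = est.P[0, 0], est.P[0, 1], est.P[1, 1]
    h, v, p11, p12, p22 = predict_arrays(
        est.h_hat, est.v_h_hat, p11, p12, p22, u_dphi, consts,
        ekf_params.q_h * dt, ekf_params.q_v * dt,
    )
    P = _check_psd(np.array([[p11, p12], [p12, p22]], dtype=float))
    return EkfEstimate(float(h), float(v), P)


def ekf_update(est: EkfEstimate, omega_div_meas: float, ekf_params: EkfParams) -> EkfEstimate:
    """Joseph-form correction with measurement ``omega_div = v_h / h``."""
    if est.h_hat == 0:
        raise ZeroDivisionError("EKF clearance estimate is zero at update")
    p11, p12, p22 = est.P[0, 0], est.P[0, 1], est.P[1, 1]
    h, v, p11, p12, p22 = update_arrays(
        est.h_hat, est.v_h_hat, p11, p12, p22, omega_div_meas, ekf_params.r_div
    )
    P = _check_psd(np.array([[p11, p12], [p12, p22]], dtype=float))
    return EkfEstimate(float(h), float(v), P)


def observability_matrix(h: float, v_h: float, u: float, tol: float = 1e-10):
    """Jacobian of the observability map and its numerical rank.

    The map stacks the measurement ``v_h/h`` and its Lie derivative along the
    dynamics, ``−v_h²/h² + u/h`` (the decay term of the vertical dynamics
    does not change the rank).  Its Jacobian with respect to ``(h, v_h)`` has
    determinant ``u/h³``: the clearance is locally observable precisely while
    the stroke command is non-zero.  For completeness, the classical
    statement also lists ``v_h ≠ 0``; both conditions are reported.
    """
    if h == 0:
        raise ZeroDivisionError("observability is singular at h = 0")
    J = np.array(
        [
            [-v_h / h**2, 1.0 / h],
            [2.0 * v_h**2 / h**3 - u / h**2, -2.0 * v_h / h**2],
        ]
    )
    rank = int(np.linalg.matrix_rank(J, tol=tol))
    return J, rank
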