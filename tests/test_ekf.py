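import numpy as np
import pytest
import sympy as sp

from beeodom.dynamics import DynamicsParams
from beeodom.ekf import (
    EkfEstimate,
    EkfParams,
    ekf_predict,
    ekf_update,
    observability_matrix,
)
from beeodom import flat_course_8m, irregular_course_100m, long_course_100m
from beeodom.simulate import simulate

DYN = DynamicsParams()
EKF = EkfParams()


def fresh(h=0.5, v=1.0):
    return EkfEstimate(h_hat=h, v_h_hat=v, P=np.eye(2))


class TestPredict:
    def test_zero_dynamics_keeps_state_and_grows_covariance(self):
        est = fresh(h=1.0, v=0.0)
        out = ekf_predict(est, 0.0, 1e-3, DYN, EKF)
        assert out.h_hat == pytest.approx(1.0)
        assert out.v_h_hat == 0.0
        assert out.P[0, 0] > est.P[0, 0] - 1e-12 and out.P[1, 1] >= est.P[1, 1] * np.exp(-2e-3 / 0.22)

    def test_dc_gain_of_vertical_model(self):
        est = fresh(h=1.0, v=0.0)
        for _ in range(20_000):  # 20 s of prediction, no updates
            est = ekf_predict(est, 10.0, 1e-3, DYN, EKF)
        assert est.v_h_hat == pytest.approx(1.1, rel=1e-6)

    def test_absolute_value_guard(self):
        est = EkfEstimate(h_hat=-0.3, v_h_hat=0.0, P=np.eye(2))
        out = ekf_predict(est, 0.0, 1e-6, DYN, EKF)
        assert out.h_hat == pytest.approx(0.3, rel=1e-6)


class TestUpdate:
    def test_zero_innovation_leaves_state(self):
        est = fresh(h=1.25, v=0.5)
        out = ekf_update(est, 0.5 / 1.25, EKF)
        assert out.h_hat == pytest.approx(1.25)
        assert out.v_h_hat == pytest.approx(0.5)

    def test_covariance_stays_symmetric_psd(self):
        est = fresh()
        rng = np.random.default_rng(3)
        for _ in range(500):
            est = ekf_predict(est, rng.uniform(-20, 20), 1e-3, DYN, EKF)
            est = ekf_update(est, rng.uniform(-2, 2), EKF)
            assert np.allclose(est.P, est.P.T)
            assert np.all(np.linalg.eigvalsh(est.P) >= -1e-9)

    def test_recovers_known_oscillating_truth(self):
        """Filter a plant-consistent trajectory oscillating around 1 m
        clearance under the nominal 18 deg / 1 Hz stroke command for 10 s;
        the estimate lands within 5 cm of the truth."""
        from beeodom.ekf import transition_constants

        dt = 1e-3
        f12, f22, b1, b2 = transition_constants(DYN.K_z, DYN.tau_z, dt)
        n = 10_000
        h_true, v_true = 1.0, 0.0
        est = fresh(h=0.5, v=1.0)
        for k in range(n):
            u = 18.0 * np.sin(2 * np.pi * k * dt)
            h_next = h_true + f12 * v_true + b1 * u
            v_next = f22 * v_true + b2 * u
            est = ekf_predict(est, u, dt, DYN, EKF)
            est = ekf_update(est, v_next / h_next, EKF)
            h_true, v_true = h_next, v_next
        assert abs(est.h_hat - h_true) < 0.05


class TestObservability:
    def test_rank_two_with_excitation(self):
        _, rank = observability_matrix(1.5, 0.3, 5.0)
        assert rank == 2

    def test_rank_drops_without_excitation(self):
        _, rank = observability_matrix(1.5, 0.3, 0.0)
        assert rank == 1

    def test_rank_invariant_under_state_scaling(self):
        _, r1 = observability_matrix(1.0, 0.4, 2.0)
        _, r2 = observability_matrix(2.0, 0.8, 2.0)
        assert r1 == r2 == 2

    def test_singular_at_zero_clearance(self):
        with pytest.raises(ZeroDivisionError):
            observability_matrix(0.0, 0.1, 1.0)

    def test_symbolic_determinant_is_u_over_h_cubed(self):
        h, v, u = sp.symbols("h v u", positive=True)
        g = v / h
        lie = -(v**2) / h**2 + u / h
        J = sp.Matrix([[sp.diff(g, h), sp.diff(g, v)], [sp.diff(lie, h), sp.diff(lie, v)]])
        assert sp.simplify(J.det() - u / h**3) == 0
        # numerical Jacobian agrees with the symbolic one
        Jn, _ = observability_matrix(1.5, 0.3, 5.0)
        Js = np.array(J.subs({h: 1.5, v: 0.3, u: 5.0}), dtype=float)
        assert np.allclose(Jn, Js)


class TestClosedLoopEstimation:
    def test_initialization_robustness(self):
        """Estimates started at 0.1, 0.5 and 2 m all converge to within 10%
        of the true clearance within 5 s of the end of take-off."""
        cfgs = [
            long_course_100m(0.0).with_overrides(ekf__h_init=h0) for h0 in (0.1, 0.5, 2.0)
        ]
        res = simulate(cfgs, record=True, log_every=10)
        for traj in res.trajectories:
            row = traj[traj["t"] >= 6.0].iloc[0]  # take-off ends by ~1 s
            assert abs(row["h_hat"] - row["h"]) / row["h"] < 0.10

    def test_oscillation_is_required_for_convergence(self):
        """Without the self-oscillation the clearance scale is unobservable:
        over irregular ground the estimate drifts and its cruise error is far
        larger than with the oscillation on.  (Over perfectly flat ground the
        filter's internal model matches the plant exactly, so dead-reckoning
        masks the loss of observability; relief exposes it.)"""
        cfgs = [
            irregular_course_100m(0.0),
            irregular_course_100m(0.0).with_overrides(controller__A_osc=0.0),
        ]
        res = simulate(cfgs, record=True, log_every=10)
        errs = []
        for traj in res.trajectories:
            c = traj[(traj["x"] > 2.0) & (traj["x"] < 95.5)]
            errs.append(np.mean(np.abs(c["h_hat"] - c["h"]) / c["h"]))
        err_osc, err_noosc = errs
        assert err_noosc > 3.0 * err_osc

    def test_noise_tuning_insensitivity(self):
        """Scaling the process/measurement covariances by 10 either way keeps
        the cruise estimation error below 10% on the short course."""
        scales = [(1, 1), (10, 10), (0.1, 0.1), (10, 0.1), (0.1, 10)]
        cfgs = [
            flat_course_8m(0.0).with_overrides(
                ekf__q_h=1e-4 * s, ekf__q_v=1e-2 * s, ekf__r_div=1e-2 * r
            )
            for s, r in scales
        ]
        res = simulate(cfgs, record=True, log_every=5)
        for traj in res.trajectories:
            c = traj[(traj["x"] > 2.0) & (traj["x"] < 5.5)]
            assert np.mean(np.abs(c["h_hat"] - c["h"]) / c["h"]) < 0.10

    def test_covariance_psd_along_full_scenario(self):
        simulate(flat_course_8m(-1.0), check_covariance=True)
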