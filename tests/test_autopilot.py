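import numpy as np
import pytest

from beeodom.autopilot import (
    ControllerParams,
    MissionProfile,
    oscillation_command,
    pd_regulator,
    pitch_profile,
    stroke_command,
)
from conftest import cruise_window

CTRL = ControllerParams()


class TestRegulator:
    def test_zero_error_gives_zero_command(self):
        u, _ = pd_regulator(2.5, 2.5, 0.0, 1e-3, CTRL)
        assert u == 0.0

    def test_proportional_term(self):
        # constant error with the derivative state already settled
        u, _ = pd_regulator(2.6, 2.5, 0.1, 1e-3, CTRL)
        assert u == pytest.approx(15.0 * 0.1, abs=1e-9)

    def test_derivative_acts_on_filtered_error(self):
        u1, ef = pd_regulator(3.0, 2.5, 0.0, 1e-3, CTRL)
        # filtered error moves a fraction dt/(tau_d+dt) of the step
        assert ef == pytest.approx(0.5 * 1e-3 / (0.02 + 1e-3))
        assert u1 > 15.0 * 0.5  # derivative kick on a rising error

    def test_invalid_dt(self):
        with pytest.raises(ValueError):
            pd_regulator(2.5, 2.5, 0.0, 0.0, CTRL)


class TestOscillation:
    def test_zero_at_t0(self):
        assert oscillation_command(0.0, CTRL, 1.0) == 0.0

    def test_quarter_period_peak(self):
        assert oscillation_command(0.25, CTRL, 1.0) == pytest.approx(18.0)

    def test_gated_off_near_ground(self):
        assert oscillation_command(0.25, CTRL, 0.02) == 0.0

    def test_frequency_parameter(self):
        c = ControllerParams(f_osc=2.0)
        assert oscillation_command(0.125, c, 1.0) == pytest.approx(18.0)


class TestPitchProfile:
    M100 = MissionProfile()

    def test_zero_at_liftoff_point(self):
        # only the small bootstrap offset remains at x = 0
        assert pitch_profile(0.0, self.M100) == pytest.approx(40.0 * 0.05)

    def test_cruise_plateau(self):
        assert pitch_profile(50.0, self.M100) == 40.0

    def test_takeoff_ramp_interpolates(self):
        assert pitch_profile(0.5, self.M100) == pytest.approx(40.0 * 0.55)

    def test_landing_ramp_reaches_zero(self):
        assert pitch_profile(100.0, self.M100) == 0.0
        assert pitch_profile(97.75, self.M100) == pytest.approx(20.0)

    def test_stroke_command_is_sum(self):
        assert stroke_command(1.5, 18.0) == 19.5

    def test_degenerate_mission_rejected(self):
        with pytest.raises(ValueError):
            MissionProfile(ground_length=1.0, takeoff_end_x=1.0, landing_start_x=0.5)


class TestClosedLoop:
    def test_cruise_optic_flow_tracks_setpoint(self, long_flat_runs):
        rec = long_flat_runs.records
        assert np.all(
            np.abs(rec["cruise_mean_omega_T"] / rec["omega_T_set"] - 1.0) < 0.10
        )

    def test_cruise_height_matches_speed_over_setpoint(self, long_flat_runs):
        # no wind: h settles near V_x / omega_set = 4.0 / 2.5 = 1.6 m
        rec = long_flat_runs.records
        none = rec[rec["k_wind"] == 0].iloc[0]
        assert none["cruise_mean_h"] == pytest.approx(1.6, rel=0.10)

    def test_wind_orders_cruise_height(self, long_flat_runs):
        rec = long_flat_runs.records.set_index("k_wind")
        h_tail = rec.loc[1.0, "cruise_mean_h"]
        h_none = rec.loc[0.0, "cruise_mean_h"]
        h_head = rec.loc[-1.0, "cruise_mean_h"]
        assert h_tail > h_none > h_head

    def test_oscillation_amplitude_band(self, long_flat_runs):
        """Cruise clearance oscillates at ~1 Hz with a total excursion in the
        0.35-0.55 m band (widened ±30% — loop-gain dependent).  The slow
        wind-induced drift is removed with a one-period rolling mean."""
        for traj in long_flat_runs.trajectories:
            c = cruise_window(traj, x_lo=10.0)
            h = c["h"].to_numpy()
            n = 100  # one oscillation period at the 100 Hz logging rate
            trend = np.convolve(h, np.ones(n) / n, mode="valid")
            resid = h[n // 2: n // 2 + len(trend)] - trend
            p2p = resid.max() - resid.min()
            assert 0.35 * 0.7 < p2p < 0.55 * 1.3

    def test_stroke_command_spectrum_peaks_at_oscillation_frequency(self, short_course_runs):
        traj = short_course_runs.trajectories[1]  # no wind, 1 kHz log
        c = traj[(traj["x"] > 2.0) & (traj["x"] < 5.5)]
        u = c["u_dphi"].to_numpy()
        u = u - u.mean()
        freqs = np.fft.rfftfreq(len(u), d=1e-3)
        power = np.abs(np.fft.rfft(u))
        assert freqs[np.argmax(power)] == pytest.approx(1.0, abs=0.2)
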