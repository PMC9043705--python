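import numpy as np
import pandas as pd
import pytest

import udlbias as u
from udlbias.generate import DT, Trajectory, min_jerk_speed
from udlbias.kinematics import _speed

QUIET = u.GenerativeParams(sigma_motor=1e-9, p_lapse=0.0, start_jitter_sd=0.0)


class TestDetectOnset:
    def test_stationary_trajectory_has_no_onset(self):
        t = np.arange(100) * DT
        tr = Trajectory(t, np.zeros(100), np.zeros(100))
        with pytest.raises(u.NoOnsetError):
            u.detect_onset(tr)

    def test_min_jerk_onset_matches_analytic_oracle(self, rng):
        # oracle: evaluate the analytic minimum-jerk speed curve on a
        # dense 1 kHz grid and take the first 200 Hz sample beyond the
        # 3 cm/s crossing
        rt, mt = 0.25, 0.30
        tr = u.render_trajectory(30.0, rt, mt, QUIET, rng)
        dense = np.arange(0, rt + mt, 0.001)
        crossing = dense[min_jerk_speed(dense, rt, mt) > 3.0][0]
        expected = np.ceil(crossing / DT) * DT
        detected = u.detect_onset(tr)
        assert abs(detected - expected) <= DT + 1e-9

    def test_threshold_default_is_3_cm_per_s(self):
        from udlbias.kinematics import V_THRESH_CM_S
        assert V_THRESH_CM_S == 3.0


class TestHeadingAt:
    def test_straight_ray_heading(self, rng):
        tr = u.render_trajectory(45.0, 0.2, 0.3, QUIET, rng)
        onset = u.detect_onset(tr)
        for dt in (0.02, 0.04, 0.08):
            assert u.heading_at(tr, onset, dt) == pytest.approx(45.0, abs=1e-9)

    def test_circular_arc_heading_equals_chord_angle(self):
        # arc of radius R about (R, 0): chord angle has a closed form
        R = 10.0
        t = np.arange(0, 0.5, DT)
        phi = np.pi * t / 0.5  # half-turn over 0.5 s
        x = R - R * np.cos(phi)
        y = R * np.sin(phi)
        tr = Trajectory(t, x, y)
        onset, dt = 0.1, 0.04
        p0 = np.array([np.interp(onset, t, x), np.interp(onset, t, y)])
        p1 = np.array([np.interp(onset + dt, t, x), np.interp(onset + dt, t, y)])
        chord = np.degrees(np.arctan2(*(p1 - p0)[::-1]))
        assert u.heading_at(tr, onset, dt) == pytest.approx(chord, abs=1e-9)

    def test_too_short_trajectory_raises(self):
        t = np.arange(5) * DT
        tr = Trajectory(t, t.copy(), t.copy())
        with pytest.raises(ValueError):
            u.heading_at(tr, t[-1] - 0.01, 0.04)

    def test_default_window_is_40_ms(self):
        from udlbias.kinematics import HEADING_DT_S
        assert HEADING_DT_S == 0.040


@pytest.mark.parametrize("rt,mt,expected", [
    (0.069, 0.300, "too_fast"),   # anticipation criterion
    (0.300, 0.401, "too_slow"),   # movement-time cap
    (0.070, 0.400, "ok"),         # boundaries are inclusive
    (0.300, 0.300, "ok"),
])
def test_flag_validity(rt, mt, expected):
    assert u.flag_validity(rt, mt) == expected


class TestBaseline:
    def test_zero_deviations_give_zero_table(self):
        obs = pd.DataFrame({
            "participant": 0,
            "target_deg": np.repeat([0, 30, 60, 90, 120, 150, 330], 3),
            "deviation_deg": 0.0,
        })
        tbl = u.build_baseline(obs)
        assert (tbl.baseline_deg == 0).all()
        assert len(tbl) == 7

    def test_mean_of_signed_deviations(self):
        obs = pd.DataFrame({
            "participant": 0,
            "target_deg": ([0.0] * 3) + [30, 60, 90, 120, 150, 330],
            "deviation_deg": [2.0, -2.0, 6.0] + [0.0] * 6,
        })
        tbl = u.build_baseline(obs)
        assert tbl.set_index("target_deg").baseline_deg[0.0] == pytest.approx(2.0)

    def test_missing_cell_names_participant(self):
        obs = pd.DataFrame({"participant": [1, 1], "target_deg": [0.0, 30.0],
                            "deviation_deg": [0.0, 0.0]})
        with pytest.raises(ValueError, match="1"):
            u.build_baseline(obs)


class TestRecodeBias:
    def test_sign_convention_toward_frequent(self):
        d, b = u.recode_bias(heading=80, target=90, frequent_loc=60)
        assert (d, b) == (30.0, pytest.approx(10.0))

    def test_mirror_case_antisymmetry(self):
        d, b = u.recode_bias(heading=40, target=30, frequent_loc=60)
        assert (d, b) == (30.0, pytest.approx(10.0))

    def test_identity_at_frequent_target(self):
        d, b = u.recode_bias(heading=150, target=150, frequent_loc=150)
        assert (d, b) == (0.0, pytest.approx(0.0))

    def test_wraparound_target(self):
        # from a 330 deg target the frequent target at 60 deg lies 90 deg
        # counterclockwise (through 0); heading 340 deg moves toward it
        d, b = u.recode_bias(heading=340, target=330, frequent_loc=60)
        assert (d, b) == (90.0, pytest.approx(10.0))

    def test_baseline_subtracted_before_sign_flip(self):
        # raw deviation +5 away from frequent; a +5 idiosyncratic
        # baseline fully accounts for it
        _, b = u.recode_bias(heading=95, target=90, frequent_loc=60, baseline=5.0)
        assert b == pytest.approx(0.0)
        _, b2 = u.recode_bias(heading=95, target=90, frequent_loc=60)
        assert b2 == pytest.approx(-5.0)

    def test_target_outside_session_set(self):
        with pytest.raises(ValueError):
            u.recode_bias(heading=0, target=45, frequent_loc=60)


class TestReduceDataset:
    def test_zero_noise_recovery_of_latent_bias(self):
        # with noise off, the reduction returns the planned bias to
        # within interpolation error
        ds = u.generate_dataset("exp1", QUIET, 1, seed=21)
        obs = u.reduce_dataset(ds)
        m = (obs.valid & (obs.phase == "test")).to_numpy()
        err = obs.bias_deg.to_numpy()[m] - ds.latent.bias_planned_deg.to_numpy()[m]
        assert np.abs(err).max() < 0.1

    def test_onset_recovers_latent_rt(self):
        ds = u.generate_dataset("exp1", QUIET, 1, seed=22)
        obs = u.reduce_dataset(ds)
        lat = ds.latent
        m = obs.valid.to_numpy()
        rt_d = obs.rt_s.to_numpy()[m]
        rt_l = lat.rt_latent_s.to_numpy()[m]
        mt_l = lat.move_time_s.to_numpy()[m]
        # analytic oracle: threshold-crossing offset of the min-jerk
        # speed profile, then one sample of grid slack either way
        dense = np.linspace(0, 1, 2001)
        for i in np.random.default_rng(0).choice(len(rt_d), 50, replace=False):
            v = min_jerk_speed(rt_l[i] + dense * mt_l[i], rt_l[i], mt_l[i])
            crossing = rt_l[i] + dense[v > 3.0][0] * mt_l[i]
            assert rt_d[i] == pytest.approx(np.ceil(crossing / DT - 1e-9) * DT,
                                            abs=DT + 1e-9)

    def test_rotation_equivariance(self):
        # rotating the whole workspace (trajectories, targets, frequent
        # location) by a common angle leaves every bias unchanged
        ds = u.generate_dataset("exp1", QUIET, 1, seed=23)
        obs = u.reduce_dataset(ds)

        delta = 40.0
        c, s = np.cos(np.deg2rad(delta)), np.sin(np.deg2rad(delta))
        rx = ds.traj_x * c - ds.traj_y * s
        ry = ds.traj_x * s + ds.traj_y * c
        trials = ds.trials.copy()
        trials["target_deg"] = (trials["target_deg"] + delta) % 360
        trials["frequent_deg"] = (trials["frequent_deg"] + delta) % 360
        rot = u.SimulatedDataset(trials=trials, traj_x=rx, traj_y=ry,
                                 traj_len=ds.traj_len, latent=ds.latent)
        obs_rot = u.reduce_dataset(rot)
        np.testing.assert_allclose(obs_rot.bias_deg.to_numpy(),
                                   obs.bias_deg.to_numpy(), atol=1e-6)

    def test_speed_estimator_is_central_difference(self):
        x = np.array([[0.0, 1.0, 4.0, 9.0]])
        y = np.zeros_like(x)
        sp = _speed(x, y, 1.0)
        np.testing.assert_allclose(sp[0], [1.0, 2.0, 4.0, 5.0])
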