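"""Marker preprocessing, gait-cycle handling, joint angles and IK."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import caninegait as cg
from caninegait.kinematics import (
    KinematicsError,
    MarkerTrajectorySet,
    butterworth_lowpass,
    fill_gaps_quintic,
    included_angle_deg,
    resample_cycle,
    segment_gait_cycle,
)


class TestButterworth:
    def test_constant_passthrough(self):
        x = np.full(200, 3.7)
        assert np.allclose(butterworth_lowpass(x, 6.0, 100.0), x, atol=1e-9)

    def test_passband_sinusoid_preserved(self):
        t = np.arange(0, 10, 0.01)
        x = np.sin(2 * np.pi * 1.0 * t)
        y = butterworth_lowpass(x, 6.0, 100.0)
        mid = slice(200, -200)
        assert np.abs(y[mid]).max() == pytest.approx(1.0, rel=0.01)

    def test_stopband_sinusoid_attenuated(self):
        t = np.arange(0, 10, 0.01)
        x = np.sin(2 * np.pi * 40.0 * t)
        y = butterworth_lowpass(x, 6.0, 100.0)
        assert np.abs(y[200:-200]).max() < 0.05

    def test_nyquist_violation_rejected(self):
        with pytest.raises(KinematicsError):
            butterworth_lowpass(np.zeros(100), 6.0, 10.0)


def _traj_from_poly(n=60, gap=None):
    t = np.arange(n, dtype=float)
    # a quintic polynomial trajectory is reproduced exactly by quintic splines
    coef = np.array([1e-6, -3e-5, 2e-4, -0.01, 0.5, 10.0])
    pos = np.stack([np.polyval(coef, t), 2 * np.polyval(coef, t), t], axis=-1)
    vis = np.ones((n, 1), dtype=bool)
    if gap is not None:
        vis[gap[0] : gap[0] + gap[1], 0] = False
    return MarkerTrajectorySet(["m"], pos[:, None, :], 100.0, vis)


class TestGapFill:
    def test_no_gaps_identity(self):
        traj = _traj_from_poly()
        out = fill_gaps_quintic(traj)
        assert np.array_equal(out.positions_mm, traj.positions_mm)
        assert out.visible.all()

    def test_short_gap_exact_recovery(self):
        clean = _traj_from_poly()
        gapped = _traj_from_poly(gap=(20, 3))
        out = fill_gaps_quintic(gapped)
        assert out.visible.all()
        assert np.abs(out.positions_mm - clean.positions_mm).max() < 1e-8

    def test_five_frame_gap_left_flagged(self):
        gapped = _traj_from_poly(gap=(20, 5))
        out = fill_gaps_quintic(gapped)
        assert not out.visible[20:25, 0].any()
        assert out.has_long_gaps()

    def test_boundary_gap_not_fillable(self):
        gapped = _traj_from_poly(gap=(0, 2))
        out = fill_gaps_quintic(gapped)
        assert not out.visible[0:2, 0].any()


class TestCycleSegmentation:
    def test_constructed_contacts_recovered_exactly(self):
        f = np.zeros(200)
        f[10:70] = 30.0  # stance 1
        f[110:170] = 30.0  # stance 2
        cyc = segment_gait_cycle(f, threshold=5.0, rate_hz=100.0)
        assert (cyc.start_frame, cyc.end_frame) == (10, 110)
        assert cyc.stance_fraction == pytest.approx(0.6)

    def test_zero_threshold_rejected(self):
        with pytest.raises(KinematicsError):
            segment_gait_cycle(np.abs(np.random.default_rng(0).normal(size=100)), 0.0)

    def test_chatter_shorter_than_debounce_ignored(self):
        f = np.zeros(300)
        f[5:7] = 50.0  # 20 ms blip: not a contact
        f[50:110] = 50.0
        f[150:210] = 50.0
        cyc = segment_gait_cycle(f, threshold=5.0, rate_hz=100.0)
        assert cyc.start_frame == 50

    def test_no_contact_raises(self):
        with pytest.raises(KinematicsError):
            segment_gait_cycle(np.zeros(100), threshold=5.0)

    def test_synthetic_trial_stance_fraction(self, noise_free_trial):
        trial = noise_free_trial
        plate = trial.grf.plates[0]
        fy, _, _ = plate.resample_to(trial.times)
        bw = trial.spec.body_mass_kg * 9.81
        cyc = segment_gait_cycle(fy[:, 1], threshold=0.02 * bw, rate_hz=trial.spec.rate_hz)
        assert cyc.stance_fraction == pytest.approx(0.6, abs=0.05)


class TestIncludedAngle:
    @pytest.mark.parametrize(
        "u,v,expected",
        [
            ((1, 0, 0), (0, 1, 0), 90.0),
            ((1, 0, 0), (2, 0, 0), 0.0),
            ((1, 0, 0), (1, 1, 0), 45.0),
        ],
    )
    def test_hand_cases(self, u, v, expected):
        assert included_angle_deg(np.array(u, float), np.array(v, float)) == pytest.approx(
            expected, abs=1e-9
        )

    def test_zero_vector_rejected(self):
        with pytest.raises(KinematicsError):
            included_angle_deg(np.zeros(3), np.ones(3))

    @given(
        angle=st.floats(5.0, 175.0),
        rot=st.floats(0, 2 * np.pi),
        tilt=st.floats(0, np.pi),
        shift=st.floats(-50, 50),
    )
    @settings(max_examples=60, deadline=None)
    def test_invariant_under_global_rigid_transform(self, angle, rot, tilt, shift):
        u = np.array([1.0, 0.0, 0.0])
        v = np.array([np.cos(np.radians(angle)), np.sin(np.radians(angle)), 0.0])
        c, s = np.cos(rot), np.sin(rot)
        rz = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
        c, s = np.cos(tilt), np.sin(tilt)
        rx = np.array([[1.0, 0, 0], [0, c, -s], [0, s, c]])
        r = rx @ rz
        # difference vectors are translation-invariant; rotation preserves angles
        assert included_angle_deg(r @ u, r @ v) == pytest.approx(angle, abs=1e-8)


class TestResample:
    def test_constant(self):
        assert np.allclose(resample_cycle(np.full(37, 2.5), 100), 2.5)

    def test_linear_ramp_endpoints_exact(self):
        out = resample_cycle(np.linspace(3.0, 9.0, 61), 100)
        assert out[0] == 3.0 and out[-1] == 9.0
        assert np.allclose(out, np.linspace(3.0, 9.0, 100), atol=1e-12)

    def test_same_grid_identity(self):
        x = np.sin(np.linspace(0, 2 * np.pi, 100))
        assert np.abs(resample_cycle(x, 100) - x).max() < 1e-12

    def test_too_short_rejected(self):
        with pytest.raises(KinematicsError):
            resample_cycle(np.array([1.0]), 100)


class TestInverseKinematics:
    def test_noise_free_round_trip(self, gait_model, noise_free_trial):
        model, _ = gait_model
        trial = noise_free_trial
        sub = MarkerTrajectorySet(
            trial.markers.names, trial.markers.positions_mm[:15], trial.spec.rate_hz
        )
        ik = cg.inverse_kinematics(model, sub)
        assert ik.converged.all()
        assert ik.marker_rms_mm.max() < 1e-6
        err = np.abs(ik.coordinates - trial.truth_q[:15])
        assert np.degrees(err[:, 3:]).max() < 0.1  # all rotational coords
        assert err[:, :3].max() < 1e-6  # root translations (m)

    def test_zero_weight_removes_corrupted_marker(self, gait_model, noise_free_trial):
        model, _ = gait_model
        trial = noise_free_trial
        pos = trial.markers.positions_mm[:8].copy()
        name = "L_DORSAL_PAW"
        pos[:, trial.markers.names.index(name), :] += 80.0  # gross corruption
        bad = MarkerTrajectorySet(trial.markers.names, pos, trial.spec.rate_hz)
        clean = MarkerTrajectorySet(
            trial.markers.names, trial.markers.positions_mm[:8], trial.spec.rate_hz
        )
        ik_clean = cg.inverse_kinematics(model, clean)
        ik_down = cg.inverse_kinematics(model, bad, weights={name: 0.0})
        assert np.allclose(ik_down.coordinates, ik_clean.coordinates, atol=1e-6)

    def test_filter_resample_commute_for_bandlimited_angles(self):
        t = np.arange(0, 1.2, 0.01)
        angle = 20 * np.sin(2 * np.pi * 1.6 * t) + 5 * np.sin(2 * np.pi * 3.2 * t)
        a = resample_cycle(butterworth_lowpass(angle, 6.0, 100.0), 100)
        b = butterworth_lowpass(resample_cycle(angle, 100), 6.0, 100.0 * 100 / len(t))
        assert np.abs(a - b)[5:-5].max() < 0.5
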