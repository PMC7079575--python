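"""Inverse dynamics, residual handling and joint power."""

import copy

import numpy as np
import pytest

import caninegait as cg
from caninegait.dynamics import (
    DynamicsError,
    JointMomentSeries,
    inverse_dynamics,
    joint_power,
    reduce_residuals,
)
from conftest import make_pendulum


class TestPendulumOracle:
    def test_matches_closed_form(self):
        m, length = 0.5, 0.2
        model = make_pendulum(m, length)
        t = np.linspace(0, 1, 1001)
        theta = 0.3 * np.sin(2 * np.pi * 1.2 * t)
        q = np.zeros((len(t), model.n_coords))
        q[:, 6] = theta
        moments, _ = inverse_dynamics(model, q, t)
        thdd = np.gradient(np.gradient(theta, t), t)
        closed = m * length**2 * thdd + m * 9.81 * length * np.sin(theta)
        got = moments.moments["pin_rz"]
        sl = slice(5, -5)
        rel = np.abs(got[sl] - closed[sl]).max() / np.abs(closed).max()
        assert rel < 0.01

    def test_zero_gravity_zero_motion_zero_load(self):
        model = make_pendulum()
        t = np.linspace(0, 0.5, 51)
        q = np.zeros((51, model.n_coords))
        moments, residuals = inverse_dynamics(model, q, t, gravity=np.zeros(3))
        assert np.allclose(moments.moments["pin_rz"], 0.0, atol=1e-12)
        assert np.allclose(residuals.residual_force_n, 0.0, atol=1e-12)


class TestStaticChain:
    def test_standing_pose_closed_form(self, gait_model):
        """With vertical plate forces equal to the model weight, the pelvis
        force residual vanishes and every joint moment equals the static
        balance of its distal subtree (gravity + ground reaction)."""
        model, _ = gait_model
        n = 21
        t = np.arange(n) / 100.0
        q = np.zeros((n, model.n_coords))
        q[:, 1] = 0.21  # root height
        weight = model.total_mass() * 9.81

        poses = model.forward_kinematics(q[0])
        plates = []
        for side in ("L", "R"):
            paw = poses[f"{side}_phalanges"][1]
            cop = np.tile([paw[0], 0.0, paw[2]], (n, 1))
            force = np.tile([0.0, weight / 2, 0.0], (n, 1))
            plates.append(cg.PlateData(f"{side}_phalanges", t, force, np.zeros(n), cop))
        grf = cg.GroundReaction(plates)
        moments, residuals = inverse_dynamics(model, q, t, grf)
        assert np.abs(residuals.residual_force_n).max() < 1e-6

        g_vec = np.array([0.0, -9.81, 0.0])
        subtrees = {
            "L_tarsus": ["L_tarsus", "L_phalanges"],
            "L_stifle": ["L_tibia", "L_tarsus", "L_phalanges"],
            "L_hip": ["L_femur", "L_tibia", "L_tarsus", "L_phalanges"],
        }
        for joint_name, segs in subtrees.items():
            j = next(jj for jj in model.joints if jj.name == joint_name)
            r_j = poses[j.child][1]
            tau = np.zeros(3)
            for s in segs:
                p = poses[s][1] + poses[s][0] @ model.segments[s].com_local_m
                tau -= np.cross(p - r_j, model.segments[s].mass_kg * g_vec)
            if "L_phalanges" in segs:
                plate = plates[0]
                tau -= np.cross(plate.cop_m[0] - r_j, plate.force_n[0])
            axis = poses[j.parent][0] @ j.neutral_rotation @ np.array([0.0, 0.0, 1.0])
            expected = float(tau @ axis)
            got = moments.moments[f"{joint_name}_rz"][n // 2]
            assert got == pytest.approx(expected, abs=max(1e-8, 1e-3 * abs(expected)))


class TestEnergyBookkeeping:
    def test_joint_work_equals_energy_change(self):
        """For a driven pendulum with no ground reaction, the integral of
        joint power equals the change in mechanical energy."""
        m, length = 0.5, 0.2
        model = make_pendulum(m, length)
        t = np.linspace(0, 0.35, 351)
        theta = 0.8 * np.sin(2 * np.pi * 1.3 * t)
        q = np.zeros((len(t), model.n_coords))
        q[:, 6] = theta
        moments, _ = inverse_dynamics(model, q, t)
        thdot = np.gradient(theta, t)
        power = moments.moments["pin_rz"] * thdot
        sl = slice(3, -3)
        work = np.trapezoid(power[sl], t[sl])
        energy = 0.5 * m * (length * thdot) ** 2 - m * 9.81 * length * np.cos(theta)
        d_energy = energy[sl][-1] - energy[sl][0]
        assert work == pytest.approx(d_energy, rel=0.02)


class TestClosure:
    def test_ik_then_id_recovers_generator_moments(self, gait_model, noise_free_trial):
        model, _ = gait_model
        trial = noise_free_trial
        ik = cg.inverse_kinematics(model, trial.markers)
        moments, _ = inverse_dynamics(model, ik.coordinates, trial.times, trial.grf)
        for name in ("L_hip_rz", "L_stifle_rz", "L_tarsus_rz"):
            truth = trial.truth_moments.moments[name]
            got = moments.moments[name]
            rms = np.sqrt(np.mean((got - truth) ** 2))
            assert rms < 0.01 * np.abs(truth).max(), name

    def test_residuals_scale_linearly_with_plate_bias(self, consistent_trial):
        trial = consistent_trial
        bias = np.array([1.0, 2.0, 0.5])
        res = {}
        for k in (0, 1, 2):
            tr = cg.corrupt_trial(trial, force_bias_n=k * bias) if k else trial
            _, r = inverse_dynamics(tr.model, tr.truth_q, tr.times, tr.grf)
            res[k] = r.residual_force_n
        d1 = res[1] - res[0]
        d2 = res[2] - res[0]
        assert np.allclose(d2, 2 * d1, atol=1e-8)
        # each of the two plates injects the bias once
        assert np.allclose(d1.mean(axis=0), -2 * bias, atol=1e-6)

    def test_misaligned_time_base_rejected(self, gait_model):
        model, _ = gait_model
        with pytest.raises(DynamicsError):
            inverse_dynamics(model, np.zeros((10, model.n_coords)), np.zeros(9))


class TestResidualReduction:
    def test_consistent_data_needs_no_shift(self, consistent_trial):
        trial = consistent_trial
        _, _, report = reduce_residuals(
            copy.deepcopy(trial.model), trial.truth_q, trial.times, trial.grf
        )
        assert np.abs(report.com_shift_m).max() < 2e-3
        assert report.rms_after_nm <= report.rms_before_nm + 1e-12

    def test_torso_offset_recovered(self, consistent_trial):
        offset = np.array([0.010, 0.0, 0.0])
        corrupted = cg.corrupt_trial(consistent_trial, torso_com_offset_m=offset)
        _, _, report = reduce_residuals(
            corrupted.model, corrupted.truth_q, corrupted.times, corrupted.grf
        )
        assert report.applied
        assert report.com_shift_m[0] == pytest.approx(-0.010, abs=0.002)

    def test_rms_never_increases(self, noise_free_trial):
        trial = noise_free_trial  # template GRF: not dynamically consistent
        _, _, report = reduce_residuals(
            copy.deepcopy(trial.model), trial.truth_q, trial.times, trial.grf
        )
        assert report.rms_after_nm <= report.rms_before_nm + 1e-12


class TestJointPower:
    def _series(self, moment, times=None):
        t = np.arange(len(moment)) / 100.0 if times is None else times
        return JointMomentSeries(t, {"hip_rz": np.asarray(moment, float)})

    def test_zero_velocity_zero_power(self):
        p = joint_power(self._series(np.ones(10)), {"hip_rz": np.zeros(10)})
        assert np.allclose(p.power_w["hip_rz"], 0.0)

    def test_unit_conversion(self):
        p = joint_power(self._series([1.0, 1.0, 1.0]), {"hip_rz": np.full(3, 57.29577951308232)})
        assert np.allclose(p.power_w["hip_rz"], 1.0, atol=1e-12)

    def test_extensor_moment_during_flexion_absorbs(self):
        p = joint_power(self._series([2.0]), {"hip_rz": np.array([-30.0])})
        assert p.power_w["hip_rz"][0] < 0

    def test_length_mismatch_rejected(self):
        with pytest.raises(DynamicsError):
            joint_power(self._series(np.ones(5)), {"hip_rz": np.zeros(4)})
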