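"""Hill-type muscle mechanics, muscle geometry and static optimization."""

import numpy as np
import pytest

from caninegait.hill import HillCurves, rigid_tendon_fiber_length, tendon_force
from caninegait.muscles import MuscleParameters
from caninegait.optimization import (
    ActivationSolution,
    OptimizationError,
    solve_frame,
    summarize_peaks,
)
from conftest import make_hinge_with_muscles

HINGE_DOF = 6  # after the 6 root coordinates


def simple_muscle(name="m", vol=10.0, pen=0.0, fib=3.0, tsl=2.0, **kw):
    return MuscleParameters(name, vol, pen, fib, tsl, **kw)


class TestHillCurves:
    def setup_method(self):
        self.c = HillCurves()

    def test_active_peak_at_optimal_length(self):
        assert self.c.active_fl(1.0) == pytest.approx(1.0)
        assert self.c.active_fl(0.6) < 1.0 and self.c.active_fl(1.4) < 1.0

    def test_passive_zero_at_and_below_optimal(self):
        assert self.c.passive_fl(1.0) == 0.0
        assert self.c.passive_fl(0.7) == 0.0
        assert self.c.passive_fl(1.0 + self.c.passive_strain_at_fiso) == pytest.approx(1.0)

    def test_fv_unity_at_rest_and_bounds(self):
        assert self.c.fv(0.0) == pytest.approx(1.0)
        assert self.c.fv(-self.c.max_contraction_velocity) == pytest.approx(0.0)
        v = np.linspace(-15, 15, 301)
        out = self.c.fv(v)
        assert (out >= 0).all() and (out <= self.c.eccentric_plateau + 1e-12).all()


class TestTendonForce:
    def test_definition_of_max_isometric_force(self):
        p = simple_muscle()
        f = tendon_force(1.0, 1.0, 0.0, p)
        assert f == pytest.approx(p.max_isometric_force())

    def test_zero_activation_no_passive(self):
        p = simple_muscle()
        assert tendon_force(0.0, 0.95, 0.0, p) == 0.0

    def test_linear_in_activation_at_optimal(self):
        p = simple_muscle()
        assert tendon_force(0.5, 1.0, 0.0, p) == pytest.approx(0.5 * p.max_isometric_force())

    def test_rigid_tendon_fiber_length(self):
        p = simple_muscle(fib=3.0, tsl=2.0)
        assert rigid_tendon_fiber_length(5.0, p) == pytest.approx(1.0)
        assert rigid_tendon_fiber_length(6.5, p) == pytest.approx(1.5)


class TestMuscleGeometry:
    def test_straight_path_on_one_segment_pose_invariant(self):
        model = make_hinge_with_muscles(
            [("m", 10, 0, 3, 2, (0.0, 0.1, 0.0), (0.0, -0.1, 0.0))]
        )
        # re-anchor both points on the link
        model.muscles[0].path = [
            ("link", np.array([0.0, -0.02, 0.0])),
            ("link", np.array([0.03, -0.08, 0.01])),
        ]
        q = np.zeros(model.n_coords)
        l0 = model.musculotendon_length(q, "m")
        q[HINGE_DOF] = 0.7
        assert model.musculotendon_length(q, "m") == pytest.approx(l0, abs=1e-12)
        assert l0 == pytest.approx(np.linalg.norm([0.03, 0.06, 0.01]) * 100)
        assert model.moment_arm(q, "m", HINGE_DOF) == pytest.approx(0.0, abs=1e-9)

    def test_two_link_length_matches_trigonometry(self):
        a, b = 0.05, 0.08
        model = make_hinge_with_muscles([("m", 10, 0, 3, 2, (0.0, a, 0.0), (0.0, -b, 0.0))])
        theta = np.radians(10.0)
        q = np.zeros(model.n_coords)
        q[HINGE_DOF] = theta
        expected_cm = np.sqrt(a**2 + b**2 + 2 * a * b * np.cos(theta)) * 100
        assert model.musculotendon_length(q, "m") == pytest.approx(expected_cm, abs=1e-9)

    def test_collinear_via_point_leaves_length_unchanged(self):
        model = make_hinge_with_muscles(
            [("m", 10, 0, 3, 2, (0.0, 0.05, 0.0), (0.0, -0.08, 0.0))]
        )
        q = np.zeros(model.n_coords)
        l0 = model.musculotendon_length(q, "m")
        # at q=0 the straight line passes through the hinge: add that point
        model.muscles[0].path.insert(1, ("base", np.zeros(3)))
        assert model.musculotendon_length(q, "m") == pytest.approx(l0, abs=1e-12)

    def test_pulley_arm_equals_radius(self):
        radius, far = 0.02, 1.0
        model = make_hinge_with_muscles(
            [("m", 10, 0, 3, 2, (far, 0.0, 0.0), (0.0, -radius, 0.0))]
        )
        q = np.zeros(model.n_coords)
        arm = model.moment_arm(q, "m", HINGE_DOF)
        assert abs(abs(arm) - radius * 100) / (radius * 100) < 1e-3

    def test_arm_equals_perpendicular_distance_random_poses(self):
        """Tendon-excursion arms match the geometric perpendicular distance
        from the hinge to the straight line of action."""
        model = make_hinge_with_muscles(
            [("m", 10, 0, 3, 2, (0.04, 0.06, 0.0), (0.01, -0.09, 0.0))]
        )
        rng = np.random.default_rng(5)
        for theta in rng.uniform(-1.2, 1.2, 100):
            q = np.zeros(model.n_coords)
            q[HINGE_DOF] = theta
            poses = model.forward_kinematics(q)
            a = poses["base"][1] + poses["base"][0] @ model.muscles[0].path[0][1]
            b = poses["link"][1] + poses["link"][0] @ model.muscles[0].path[1][1]
            d = abs(np.cross(b - a, -a)[2]) / np.linalg.norm(b - a) * 100
            arm = abs(model.moment_arm(q, "m", HINGE_DOF))
            assert arm == pytest.approx(d, rel=5e-3)

    def test_muscle_not_spanning_joint_has_zero_arm(self):
        model = make_hinge_with_muscles(
            [("m", 10, 0, 3, 2, (0.0, 0.1, 0.0), (0.0, -0.1, 0.0))]
        )
        model.muscles[0].path = [
            ("base", np.array([0.0, 0.1, 0.0])),
            ("base", np.array([0.1, 0.1, 0.0])),
        ]
        q = np.zeros(model.n_coords)
        assert model.moment_arm(q, "m", HINGE_DOF) == pytest.approx(0.0, abs=1e-12)

    def test_antagonist_mirror_flips_arm_sign(self):
        common = dict(vol=10, pen=0, fib=3, tsl=2)
        model = make_hinge_with_muscles(
            [
                ("ag", 10, 0, 3, 2, (0.03, 0.05, 0.0), (0.02, -0.08, 0.0)),
                ("an", 10, 0, 3, 2, (-0.03, 0.05, 0.0), (-0.02, -0.08, 0.0)),
            ]
        )
        q = np.zeros(model.n_coords)
        a1 = model.moment_arm(q, "ag", HINGE_DOF)
        a2 = model.moment_arm(q, "an", HINGE_DOF)
        assert a1 == pytest.approx(-a2, rel=1e-9)


class TestStaticOptimization:
    def test_two_identical_agonists_share_equally(self):
        arms = np.array([[2.0], [2.0]])
        gains = np.array([100.0, 100.0])
        a, res, _ = solve_frame(np.array([0.5]), arms, gains, np.zeros(2))
        assert a[0] == pytest.approx(a[1], abs=1e-10)
        assert abs(res[0]) < 1e-6

    def test_zero_moment_no_passive_gives_zero_activation(self):
        arms = np.array([[2.0], [3.0], [1.5]])
        gains = np.array([100.0, 150.0, 80.0])
        a, res, obj = solve_frame(np.zeros(1), arms, gains, np.zeros(3))
        assert np.allclose(a, 0.0, atol=1e-12)
        assert obj == 0.0

    def test_matches_grid_search_oracle(self):
        """Three heterogeneous muscles on one hinge: the bounded
        least-squares solution matches a 0.001-resolution brute-force grid."""
        arms_cm = np.array([[2.0], [3.0], [1.5]])
        gains = np.array([100.0, 150.0, 80.0])
        target = 2.2  # N·m
        a, res, obj = solve_frame(np.array([target]), arms_cm, gains, np.zeros(3))
        assert abs(res[0]) < 1e-6

        # grid over (a1, a2); a3 solved exactly from the moment balance
        r = (arms_cm[:, 0] * 1e-2) * gains
        step = 0.001
        g = np.arange(0, 1 + step / 2, step)
        a1, a2 = np.meshgrid(g, g, indexing="ij")
        a3 = (target - r[0] * a1 - r[1] * a2) / r[2]
        valid = (a3 >= 0) & (a3 <= 1)
        objective = np.where(valid, a1**2 + a2**2 + a3**2, np.inf)
        grid_best = objective.min()
        assert obj <= grid_best + 1e-4
        assert abs(obj - grid_best) < 1e-4

    def test_kkt_no_feasible_descent_direction(self):
        arms_cm = np.array([[2.0], [3.0], [1.5]])
        gains = np.array([100.0, 150.0, 80.0])
        a, _, obj = solve_frame(np.array([2.2]), arms_cm, gains, np.zeros(3))
        r = (arms_cm[:, 0] * 1e-2) * gains
        rng = np.random.default_rng(0)
        for _ in range(200):
            d = rng.normal(size=3)
            d -= d @ r / (r @ r) * r  # stay on the moment-balance plane
            trial = np.clip(a + 1e-4 * d, 0, 1)
            # re-project the clipped point onto the constraint
            trial += (2.2 - r @ trial) / (r @ r) * r
            if (trial < 0).any() or (trial > 1).any():
                continue
            assert np.sum(trial**2) >= obj - 1e-9

    def test_objective_monotone_in_moment(self):
        arms_cm = np.array([[2.0], [3.0], [1.5]])
        gains = np.array([100.0, 150.0, 80.0])
        objs = [
            solve_frame(np.array([m]), arms_cm, gains, np.zeros(3))[2]
            for m in np.linspace(0, 3.5, 15)
        ]
        assert all(b >= a - 1e-12 for a, b in zip(objs, objs[1:]))

    def test_recovers_minimum_norm_activations(self):
        arms_cm = np.array([[2.0], [3.0], [1.5]])
        gains = np.array([100.0, 150.0, 80.0])
        r = (arms_cm[:, 0] * 1e-2) * gains
        a_true = 0.08 * r / r.max()  # minimum-norm pattern is ∝ r
        target = r @ a_true
        a, _, _ = solve_frame(np.array([target]), arms_cm, gains, np.zeros(3))
        assert np.allclose(a, a_true, atol=1e-8)

    def test_reserves_absorb_infeasible_demand(self):
        arms_cm = np.array([[2.0]])
        gains = np.array([10.0])  # max muscle moment 0.2 N·m
        a, res, _ = solve_frame(np.array([5.0]), arms_cm, gains, np.zeros(1))
        assert a[0] == pytest.approx(1.0)
        assert res[0] == pytest.approx(5.0 - 0.2, abs=1e-6)


class TestSummarizePeaks:
    def _solution(self, activations):
        act = np.asarray(activations, dtype=float)
        nf, nm = act.shape
        return ActivationSolution(
            times=np.arange(nf) / 100.0,
            muscle_names=[f"m{i}" for i in range(nm)],
            dof_names=["hinge_rz"],
            activations=act,
            forces_n=2.0 * act,
            reserves_nm=np.zeros((nf, 1)),
            objective=(act**2).sum(axis=1),
        )

    def test_constant_series_peaks_at_zero(self):
        sol = self._solution(np.full((101, 1), 0.4))
        peaks = summarize_peaks(sol)
        assert peaks.table.loc[0, "peak_activation"] == 0.4
        assert peaks.table.loc[0, "peak_activation_pct_cycle"] == 0.0

    def test_triangular_peak_timing(self):
        act = np.zeros((101, 1))
        act[:28, 0] = np.linspace(0, 1, 28)
        act[27:, 0] = np.linspace(1, 0, 74)
        peaks = summarize_peaks(self._solution(act))
        assert peaks.table.loc[0, "peak_activation_pct_cycle"] == pytest.approx(27.0)

    def test_stance_swing_means_exact(self):
        act = np.concatenate([np.full(61, 0.2), np.full(40, 0.05)])[:, None]
        peaks = summarize_peaks(self._solution(act), stance_fraction=0.6)
        assert peaks.stance_mean_activation == pytest.approx(0.2)
        assert peaks.swing_mean_activation == pytest.approx(0.05)

    def test_empty_solution_rejected(self):
        with pytest.raises(OptimizationError):
            summarize_peaks(self._solution(np.zeros((0, 1))))
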