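"""Static optimization: distribute net joint moments into muscle activations.

Per cycle frame the solver minimizes

    Σ_j a_j²  +  w_r Σ_i (reserve_i / reserve_opt)²

subject to moment balance  Σ_j r_ij F_j(a_j) + reserve_i = M_i  and
0 ≤ a_j ≤ 1.  With the rigid-tendon Hill model the tendon force is affine
in activation, F_j(a) = c_j a + d_j, so after eliminating the reserves the
problem is a bound-constrained linear least squares (convex, unique
solution), solved with scipy's ``lsq_linear``.  Reserve actuators carry an
optimal moment of 1 N·m with a heavy weight so they stay expensive relative
to muscles and only absorb demands the muscles cannot meet.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import lsq_linear

from .dynamics import JointMomentSeries
from .hill import HillCurves, force_coefficients, rigid_tendon_fiber_length
from .model import MusculoskeletalModel

#: Reserve-actuator optimal moment (N·m) and quadratic weight.
RESERVE_OPT_NM = 1.0
RESERVE_WEIGHT = 1.0e8


class OptimizationError(ValueError):
    pass


@dataclass
class MuscleStateSeries:
    """Per-muscle kinematic state over the cycle: MTU length (cm),
    normalized fiber length, fiber velocity (optimal lengths/s) and the
    moment-arm tensor (frames × muscles × DOFs, cm)."""

    times: np.ndarray
    muscle_names: list[str]
    dof_names: list[str]
    mtu_length_cm: np.ndarray         # frames × muscles
    norm_fiber_length: np.ndarray     # frames × muscles
    fiber_velocity_norm: np.ndarray   # frames × muscles
    moment_arms_cm: np.ndarray        # frames × muscles × DOFs


def compute_muscle_states(
    model: MusculoskeletalModel,
    q_series: np.ndarray,
    times: np.ndarray,
    dofs: list[int],
    curves: HillCurves | None = None,
) -> MuscleStateSeries:
    """Muscle lengths, velocities and moment arms along a pose history."""
    q_series = np.asarray(q_series, dtype=float)
    times = np.asarray(times, dtype=float)
    nf = q_series.shape[0]
    mtu = np.array([model.all_mtu_lengths(q) for q in q_series])
    arms = np.array([model.moment_arm_matrix(q, dofs) for q in q_series])
    lnorm = np.column_stack(
        [rigid_tendon_fiber_length(mtu[:, j], m) for j, m in enumerate(model.muscles)]
    )
    # fiber velocity in optimal fiber lengths per second (shortening negative)
    dmtu = np.gradient(mtu, times, axis=0)  # cm/s
    vel = np.column_stack(
        [
            dmtu[:, j] / (np.cos(m.pennation_rad) * m.fiber_length_cm)
            for j, m in enumerate(model.muscles)
        ]
    )
    names = [m.name for m in model.muscles]
    dof_names = [model.coordinate_names[d] for d in dofs]
    return MuscleStateSeries(times, names, dof_names, mtu, lnorm, vel, arms)


@dataclass
class ActivationSolution:
    """Per-muscle activations/forces and per-DOF reserve usage over the cycle."""

    times: np.ndarray
    muscle_names: list[str]
    dof_names: list[str]
    activations: np.ndarray       # frames × muscles, in [0, 1]
    forces_n: np.ndarray          # frames × muscles
    reserves_nm: np.ndarray       # frames × DOFs
    objective: np.ndarray         # frames, Σ a²
    states: MuscleStateSeries | None = None
    infeasible_frames: list[int] = field(default_factory=list)

    def activation(self, muscle: str) -> np.ndarray:
        return self.activations[:, self.muscle_names.index(muscle)]

    def force(self, muscle: str) -> np.ndarray:
        return self.forces_n[:, self.muscle_names.index(muscle)]


def solve_frame(
    target_moments_nm: np.ndarray,
    moment_arms_cm: np.ndarray,
    gains_n: np.ndarray,
    offsets_n: np.ndarray,
    reserve_weight: float = RESERVE_WEIGHT,
    reserve_opt_nm: float = RESERVE_OPT_NM,
) -> tuple[np.ndarray, np.ndarray, float]:
    """One static-optimization frame.

    Returns (activations, reserves per DOF, objective Σa²).  ``moment_arms_cm``
    is muscles × DOFs; gains/offsets give each muscle's force c·a + d.
    """
    arms_m = np.asarray(moment_arms_cm, dtype=float) * 1e-2
    m_target = np.asarray(target_moments_nm, dtype=float)
    nmus = arms_m.shape[0]
    sqw = np.sqrt(reserve_weight) / reserve_opt_nm
    # moment contributed by activations: (arms_m.T * gains) @ a
    a_mat = np.vstack([np.eye(nmus), sqw * (arms_m.T * gains_n[None, :])])
    b_vec = np.concatenate([np.zeros(nmus), sqw * (m_target - arms_m.T @ offsets_n)])
    sol = lsq_linear(a_mat, b_vec, bounds=(0.0, 1.0), tol=1e-12)
    a = sol.x
    forces = gains_n * a + offsets_n
    reserves = m_target - arms_m.T @ forces
    return a, reserves, float(np.sum(a**2))


def static_optimization(
    moments: JointMomentSeries,
    model: MusculoskeletalModel,
    states: MuscleStateSeries,
    curves: HillCurves | None = None,
    reserve_weight: float = RESERVE_WEIGHT,
    reserve_tolerance_nm: float = 5.0,
) -> ActivationSolution:
    """Distribute the net joint moments of each frame into muscle activations.

    Frames where even the reserves cannot balance the demand (reserve above
    ``reserve_tolerance_nm``) are recorded in ``infeasible_frames``.
    """
    curves = curves or HillCurves()
    nf = len(states.times)
    dof_names = states.dof_names
    missing = [d for d in dof_names if d not in moments.moments]
    if missing:
        raise OptimizationError(f"moment series missing DOFs: {missing}")
    m_mat = np.column_stack([moments.moments[d] for d in dof_names])
    nmus = len(states.muscle_names)
    activations = np.empty((nf, nmus))
    forces = np.empty((nf, nmus))
    reserves = np.empty((nf, len(dof_names)))
    objective = np.empty(nf)
    bad: list[int] = []
    for f in range(nf):
        gains = np.empty(nmus)
        offsets = np.empty(nmus)
        for j, mus in enumerate(model.muscles):
            g, o = force_coefficients(
                mus, states.norm_fiber_length[f, j], states.fiber_velocity_norm[f, j], curves
            )
            gains[j], offsets[j] = float(g), float(o)
        a, res, obj = solve_frame(m_mat[f], states.moment_arms_cm[f], gains, offsets,
                                  reserve_weight=reserve_weight)
        activations[f] = a
        forces[f] = gains * a + offsets
        reserves[f] = res
        objective[f] = obj
        if np.any(np.abs(res) > reserve_tolerance_nm):
            bad.append(f)
    return ActivationSolution(
        states.times, list(states.muscle_names), list(dof_names),
        activations, forces, reserves, objective, states, bad,
    )


@dataclass
class PeakSummary:
    """Per-muscle peak activation/force with timing as % of the gait cycle."""

    table: "pd.DataFrame"
    stance_mean_activation: float
    swing_mean_activation: float


def summarize_peaks(solution: ActivationSolution, stance_fraction: float = 0.6) -> PeakSummary:
    """Peak activation and force per muscle, their timing (% cycle), and the
    mean activation across all muscles during stance and during swing."""
    import pandas as pd

    nf = len(solution.times)
    if nf == 0:
        raise OptimizationError("empty solution")
    pct = np.linspace(0.0, 100.0, nf) if nf > 1 else np.zeros(1)
    rows = []
    for j, name in enumerate(solution.muscle_names):
        a = solution.activations[:, j]
        fo = solution.forces_n[:, j]
        rows.append(
            {
                "muscle": name,
                "peak_activation": float(a.max()),
                "peak_activation_pct_cycle": float(pct[int(np.argmax(a))]),
                "peak_force_N": float(fo.max()),
                "peak_force_pct_cycle": float(pct[int(np.argmax(fo))]),
            }
        )
    stance = pct <= stance_fraction * 100.0
    stance_mean = float(solution.activations[stance].mean()) if stance.any() else float("nan")
    swing_mean = float(solution.activations[~stance].mean()) if (~stance).any() else float("nan")
    return PeakSummary(pd.DataFrame(rows), stance_mean, swing_mean)
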