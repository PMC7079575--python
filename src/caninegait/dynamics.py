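"""Inverse dynamics over the segment tree, residual handling, joint power.

Net joint moments are obtained by a distal-to-proximal Newton–Euler
recursion: segment angular velocity/acceleration and COM acceleration are
finite-differenced from the (filtered) pose history, external ground
reactions are applied at the centre of pressure to the paw segments, and the
unbalanced wrench remaining at the pelvis root is reported as the residual
force/moment — the dynamic inconsistency between measured kinematics and
ground reactions that a simplified residual-reduction pass then minimizes by
shifting the torso COM and re-filtering the kinematics.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .kinematics import butterworth_lowpass
from .model import GRAVITY, MusculoskeletalModel


class DynamicsError(ValueError):
    pass


@dataclass
class PlateData:
    """One force platform: 3-D force, vertical torque and COP time series,
    applied to ``segment`` (the paw in contact)."""

    segment: str
    time_s: np.ndarray
    force_n: np.ndarray       # n × 3
    torque_z_nm: np.ndarray   # n
    cop_m: np.ndarray         # n × 3 (NaN when unloaded)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.force_n = np.asarray(self.force_n, dtype=float)
        self.torque_z_nm = np.asarray(self.torque_z_nm, dtype=float)
        self.cop_m = np.asarray(self.cop_m, dtype=float)
        n = len(self.time_s)
        if self.force_n.shape != (n, 3) or self.cop_m.shape != (n, 3) or len(self.torque_z_nm) != n:
            raise DynamicsError("plate channels must share one time base")

    def resample_to(self, times: np.ndarray, load_threshold_n: float = 0.5
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Average native-rate samples into kinematic frames (anti-alias).

        Returns (force n×3, torque_z n, cop n×3); frames whose mean vertical
        force is below ``load_threshold_n`` are zeroed with NaN COP.
        """
        times = np.asarray(times, dtype=float)
        edges = np.concatenate([
            [times[0] - (times[1] - times[0]) / 2],
            (times[1:] + times[:-1]) / 2,
            [times[-1] + (times[-1] - times[-2]) / 2],
        ])
        which = np.digitize(self.time_s, edges) - 1
        force = np.zeros((len(times), 3))
        torque = np.zeros(len(times))
        cop = np.full((len(times), 3), np.nan)
        for i in range(len(times)):
            sel = which == i
            if not sel.any():
                # frame between samples: nearest-sample fallback
                sel = np.array([np.argmin(np.abs(self.time_s - times[i]))])
            force[i] = self.force_n[sel].mean(axis=0)
            torque[i] = self.torque_z_nm[sel].mean()
            if force[i, 1] > load_threshold_n:
                loaded = sel if np.isscalar(sel) else np.asarray(sel)
                c = self.cop_m[loaded]
                good = np.isfinite(c).all(axis=1)
                if not good.any():
                    raise DynamicsError(
                        f"plate on {self.segment!r}: COP missing during loaded frame {i}"
                    )
                cop[i] = c[good].mean(axis=0)
            else:
                force[i] = 0.0
                torque[i] = 0.0
        return force, torque, cop


@dataclass
class GroundReaction:
    """Ground reactions from one or more force platforms (1000 Hz native)."""

    plates: list[PlateData]


@dataclass
class JointMomentSeries:
    """Net internal joint moments (N·m) per rotational DOF over the cycle.

    ``moments[name]`` is the time series for generalized coordinate ``name``;
    extension is positive about the segment z-axes.
    """

    times: np.ndarray
    moments: dict[str, np.ndarray]
    joint_wrench: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)


@dataclass
class ResidualReserveSeries:
    """Pelvis residual wrench (about the pelvis COM) and per-DOF reserves."""

    times: np.ndarray
    residual_force_n: np.ndarray   # frames × 3
    residual_moment_nm: np.ndarray  # frames × 3
    reserve_moments_nm: dict[str, np.ndarray] = field(default_factory=dict)
    flag_threshold_nm: float = 2.0

    @property
    def moment_rms(self) -> float:
        return float(np.sqrt(np.mean(self.residual_moment_nm**2)))

    @property
    def force_rms(self) -> float:
        return float(np.sqrt(np.mean(self.residual_force_n**2)))

    @property
    def flagged(self) -> bool:
        return bool(np.any(np.abs(self.residual_moment_nm) > self.flag_threshold_nm))


@dataclass
class JointPowerSeries:
    """Joint power (W): moment × angular velocity; positive = generation."""

    times: np.ndarray
    power_w: dict[str, np.ndarray]


def _angular_velocity(rots: np.ndarray, times: np.ndarray) -> np.ndarray:
    """World angular velocity (frames × 3) from a rotation-matrix history."""
    rdot = np.gradient(rots, times, axis=0)
    omega_hat = np.einsum("fij,fkj->fik", rdot, rots)  # Ṙ Rᵀ
    return np.stack([
        (omega_hat[:, 2, 1] - omega_hat[:, 1, 2]) / 2,
        (omega_hat[:, 0, 2] - omega_hat[:, 2, 0]) / 2,
        (omega_hat[:, 1, 0] - omega_hat[:, 0, 1]) / 2,
    ], axis=1)


def inverse_dynamics(
    model: MusculoskeletalModel,
    q_series: np.ndarray,
    times: np.ndarray,
    grf: GroundReaction | None = None,
    gravity: np.ndarray = GRAVITY,
) -> tuple[JointMomentSeries, ResidualReserveSeries]:
    """Newton–Euler inverse dynamics over the pose history.

    ``q_series`` is frames × n_coords; accelerations are estimated by central
    differences, so the coordinates should already be low-pass filtered.
    Ground reactions are applied at the COP to each plate's paw segment; the
    wrench left unbalanced at the pelvis is returned as the residual series.
    """
    q_series = np.asarray(q_series, dtype=float)
    times = np.asarray(times, dtype=float)
    nf = q_series.shape[0]
    if len(times) != nf:
        raise DynamicsError("kinematics and time base are misaligned")
    if nf < 3:
        raise DynamicsError("need at least 3 frames to differentiate")

    seg_names = list(model.segments)
    poses = [model.forward_kinematics(q) for q in q_series]
    rots = {s: np.array([p[s][0] for p in poses]) for s in seg_names}
    origins = {s: np.array([p[s][1] for p in poses]) for s in seg_names}
    coms = {
        s: origins[s] + np.einsum("fij,j->fi", rots[s], model.segments[s].com_local_m)
        for s in seg_names
    }
    omega = {s: _angular_velocity(rots[s], times) for s in seg_names}
    alpha = {s: np.gradient(omega[s], times, axis=0) for s in seg_names}
    acc = {s: np.gradient(np.gradient(coms[s], times, axis=0), times, axis=0) for s in seg_names}

    ext_force = {s: np.zeros((nf, 3)) for s in seg_names}
    ext_torque = {s: np.zeros((nf, 3)) for s in seg_names}
    ext_point = {s: coms[s].copy() for s in seg_names}
    if grf is not None:
        for plate in grf.plates:
            if plate.segment not in model.segments:
                raise DynamicsError(f"plate references unknown segment {plate.segment!r}")
            force, torque_z, cop = plate.resample_to(times)
            ext_force[plate.segment] = ext_force[plate.segment] + force
            ext_torque[plate.segment][:, 1] += torque_z
            loaded = np.isfinite(cop).all(axis=1)
            ext_point[plate.segment][loaded] = cop[loaded]

    children: dict[str, list[str]] = {s: [] for s in seg_names}
    for j in model.joints:
        if j.parent is not None:
            children[j.parent].append(j.child)

    # distal-to-proximal recursion
    joint_force: dict[str, np.ndarray] = {}
    joint_moment: dict[str, np.ndarray] = {}
    order = [j.child for j in model.joints][::-1]
    for s in order:
        seg = model.segments[s]
        inertia_w = np.einsum("fij,jk,flk->fil", rots[s], seg.inertia_com, rots[s])
        f = seg.mass_kg * (acc[s] - gravity) - ext_force[s]
        tau = (
            np.einsum("fij,fj->fi", inertia_w, alpha[s])
            + np.cross(omega[s], np.einsum("fij,fj->fi", inertia_w, omega[s]))
            - np.cross(ext_point[s] - coms[s], ext_force[s])
            - ext_torque[s]
        )
        for c in children[s]:
            f = f + joint_force[c]
            tau = tau + joint_moment[c] + np.cross(origins[c] - coms[s], joint_force[c])
        joint_centre = coms[s] if s == model.root_segment else origins[s]
        tau = tau - np.cross(joint_centre - coms[s], f)  # move to the joint centre
        joint_force[s] = f
        joint_moment[s] = tau

    # project onto joint axes
    moments: dict[str, np.ndarray] = {}
    wrench: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for j in model.joints:
        if j.parent is None:
            continue
        wrench[j.name] = (joint_force[j.child], joint_moment[j.child])
        rp = rots[j.parent]
        base = np.einsum("fij,jk->fik", rp, j.neutral_rotation)
        q_j = q_series[:, model.coord_slice(j.name)]
        if j.joint_type in ("hinge", "sliding_hinge"):
            axes = {"rz": base[:, :, 2]}
        elif j.joint_type == "ball":
            from .model import rot_x, rot_z
            axes = {"rz": base[:, :, 2]}
            rz = np.array([rot_z(a) for a in q_j[:, 0]])
            bz = np.einsum("fij,fjk->fik", base, rz)
            axes["rx"] = bz[:, :, 0]
            rx = np.array([rot_x(a) for a in q_j[:, 1]])
            bzx = np.einsum("fij,fjk->fik", bz, rx)
            axes["ry"] = bzx[:, :, 1]
        else:
            axes = {}
        for dof, axis in axes.items():
            moments[f"{j.name}_{dof}"] = np.einsum("fi,fi->f", joint_moment[j.child], axis)

    root = model.root_segment
    residuals = ResidualReserveSeries(
        times=times,
        residual_force_n=joint_force[root],
        residual_moment_nm=joint_moment[root],
    )
    return JointMomentSeries(times, moments, wrench), residuals


@dataclass
class ResidualReductionReport:
    """Before/after audit of the simplified residual-reduction pass."""

    com_shift_m: np.ndarray
    rms_before_nm: float
    rms_after_nm: float
    applied: bool
    flagged: bool = False
    note: str = ""


def reduce_residuals(
    model: MusculoskeletalModel,
    q_series: np.ndarray,
    times: np.ndarray,
    grf: GroundReaction | None,
    rate_hz: float = 100.0,
    cutoff_hz: float = 6.0,
    max_shift_fraction: float = 0.3,
    pelvis_length_m: float | None = None,
) -> tuple[MusculoskeletalModel, np.ndarray, ResidualReductionReport]:
    """Simplified residual reduction: re-filter kinematics at 6 Hz, then shift
    the torso-COM horizontal position to minimize the pelvis residual-moment
    RMS.  The shift is bounded to ±``max_shift_fraction`` of the pelvis
    length; a larger optimum is flagged and not applied.  The residual RMS
    never increases (zero shift is kept when no improvement is found).
    """
    if model.torso_segment is None:
        raise DynamicsError("model has no torso segment to adjust")
    q_filt = butterworth_lowpass(q_series, cutoff_hz, rate_hz)
    _, res0 = inverse_dynamics(model, q_filt, times, grf)
    rms0 = res0.moment_rms

    if pelvis_length_m is None:
        pelvis_length_m = 0.09
    bound = max_shift_fraction * pelvis_length_m
    torso = model.segments[model.torso_segment]
    base_com = torso.com_local_m.copy()

    def rms_for(shift: np.ndarray) -> float:
        trial = copy.deepcopy(model)
        trial.segments[trial.torso_segment].com_local_m = base_com + np.array(
            [shift[0], 0.0, shift[1]]
        )
        _, res = inverse_dynamics(trial, q_filt, times, grf)
        return res.moment_rms

    sol = minimize(rms_for, x0=np.zeros(2), method="Nelder-Mead",
                   options={"xatol": 1e-5, "fatol": 1e-8, "maxiter": 120})
    shift = sol.x
    rms1 = float(sol.fun)
    flagged = bool(np.any(np.abs(shift) > bound))
    applied = (rms1 < rms0) and not flagged
    if not applied:
        shift_out = np.zeros(2)
        rms_after = rms0
        note = "shift beyond anatomical bound; not applied" if flagged else "no improvement"
    else:
        model.segments[model.torso_segment].com_local_m = base_com + np.array(
            [shift[0], 0.0, shift[1]]
        )
        shift_out = shift
        rms_after = rms1
        note = ""
    report = ResidualReductionReport(
        com_shift_m=np.array([shift_out[0], 0.0, shift_out[1]]),
        rms_before_nm=rms0,
        rms_after_nm=rms_after,
        applied=applied,
        flagged=flagged,
        note=note,
    )
    return model, q_filt, report


def joint_power(
    moments: JointMomentSeries, angular_velocities_deg_s: dict[str, np.ndarray]
) -> JointPowerSeries:
    """Elementwise moment × angular velocity with deg/s → rad/s conversion."""
    power: dict[str, np.ndarray] = {}
    for name, m in moments.moments.items():
        if name not in angular_velocities_deg_s:
            continue
        v = np.asarray(angular_velocities_deg_s[name], dtype=float)
        if v.shape != m.shape:
            raise DynamicsError(f"{name}: moment/velocity length mismatch")
        power[name] = m * np.radians(v)
    return JointPowerSeries(moments.times, power)
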