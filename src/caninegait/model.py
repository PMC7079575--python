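"""Rigid-body musculoskeletal model: segments, joints, markers, muscle paths.

The model is a kinematic tree rooted at the pelvis.  The pelvis connects to
ground through a free 6-DOF joint; each limb chains a 3-DOF ball hip, a
sliding-hinge stifle (flexion plus femorotibial translations coupled to the
flexion angle), a hinge tarsus, and phalanges fixed to the tarsus.  A torso
point-mass segment representing the caudal abdominal mass is fixed to the
pelvis.

All model geometry is SI (m, kg, kg·m²); musculotendon lengths are reported
in cm to match the muscle parameter tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .muscles import MuscleParameters

GRAVITY = np.array([0.0, -9.81, 0.0])  # y is up


class ModelError(ValueError):
    """Inconsistent model definition."""


def rot_z(a: float) -> np.ndarray:
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def rot_x(a: float) -> np.ndarray:
    c, s = math.cos(a), math.sin(a)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def rot_y(a: float) -> np.ndarray:
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


@dataclass
class BodySegment:
    """One rigid segment: mass, COM and inertia in its own (anatomical) frame.

    ``frame`` optionally records the anatomical coordinate system
    (:class:`caninegait.frames.SegmentFrame`) the segment was built from.
    """

    name: str
    mass_kg: float
    com_local_m: np.ndarray
    inertia_com: np.ndarray  # 3×3 about COM, segment axes, kg·m²
    frame: object | None = None

    def __post_init__(self) -> None:
        self.com_local_m = np.asarray(self.com_local_m, dtype=float)
        self.inertia_com = np.asarray(self.inertia_com, dtype=float)
        if self.mass_kg <= 0:
            raise ModelError(f"segment {self.name!r}: mass must be > 0")
        if not np.allclose(self.inertia_com, self.inertia_com.T, atol=1e-12):
            raise ModelError(f"segment {self.name!r}: inertia must be symmetric")
        eig = np.linalg.eigvalsh(self.inertia_com)
        if np.any(eig < -1e-12):
            raise ModelError(f"segment {self.name!r}: inertia must be PSD")


JOINT_DOFS = {
    "free": ("tx", "ty", "tz", "rz", "rx", "ry"),
    "ball": ("rz", "rx", "ry"),
    "sliding_hinge": ("rz",),
    "hinge": ("rz",),
    "fixed": (),
}


@dataclass
class JointDefinition:
    """Joint connecting ``child`` to ``parent`` (None = ground).

    ``location_in_parent_m`` is the joint centre (centre of rotation) in the
    parent frame; ``neutral_rotation`` orients the child frame in the parent
    at zero coordinates.  For a sliding hinge, ``coupling_knots`` gives
    (flexion angle rad, tx m, ty m) rows through which cubic splines define
    the femorotibial translations as functions of flexion; the default is a
    pure hinge (zero translation).
    """

    name: str
    joint_type: str
    parent: str | None
    child: str
    location_in_parent_m: np.ndarray
    neutral_rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    coupling_knots: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.joint_type not in JOINT_DOFS:
            raise ModelError(f"joint {self.name!r}: unknown type {self.joint_type!r}")
        self.location_in_parent_m = np.asarray(self.location_in_parent_m, dtype=float)
        self.neutral_rotation = np.asarray(self.neutral_rotation, dtype=float)
        self._tx = self._ty = None
        if self.coupling_knots is not None:
            k = np.asarray(self.coupling_knots, dtype=float)
            if k.ndim != 2 or k.shape[1] != 3 or k.shape[0] < 2:
                raise ModelError(f"joint {self.name!r}: coupling knots must be n×3, n>=2")
            self.coupling_knots = k
            self._tx = CubicSpline(k[:, 0], k[:, 1])
            self._ty = CubicSpline(k[:, 0], k[:, 2])

    @property
    def dof_names(self) -> tuple[str, ...]:
        return JOINT_DOFS[self.joint_type]

    @property
    def n_dofs(self) -> int:
        return len(self.dof_names)

    def coupled_translation(self, flexion: float) -> np.ndarray:
        """Femorotibial translation (in joint frame) at a flexion angle."""
        if self._tx is None:
            return np.zeros(3)
        return np.array([float(self._tx(flexion)), float(self._ty(flexion)), 0.0])

    def local_transform(self, q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(rotation, translation) of the child frame in the parent frame."""
        t = self.joint_type
        loc = self.location_in_parent_m
        r0 = self.neutral_rotation
        if t == "fixed":
            return r0, loc
        if t == "hinge":
            return r0 @ rot_z(q[0]), loc
        if t == "sliding_hinge":
            return r0 @ rot_z(q[0]), loc + r0 @ self.coupled_translation(q[0])
        if t == "ball":
            return r0 @ rot_z(q[0]) @ rot_x(q[1]) @ rot_y(q[2]), loc
        # free: translations in parent frame, then z-x-y rotations
        rot = r0 @ rot_z(q[3]) @ rot_x(q[4]) @ rot_y(q[5])
        return rot, loc + q[:3]


@dataclass
class MusculoskeletalModel:
    """Assembled rigid-body system: segment tree + markers + muscles."""

    segments: dict[str, BodySegment]
    joints: list[JointDefinition]
    markers: dict[str, tuple[str, np.ndarray]] = field(default_factory=dict)
    muscles: list[MuscleParameters] = field(default_factory=list)
    torso_segment: str | None = None

    def __post_init__(self) -> None:
        self._validate_tree()
        self._coord_slices: dict[str, slice] = {}
        i = 0
        for j in self.joints:
            self._coord_slices[j.name] = slice(i, i + j.n_dofs)
            i += j.n_dofs
        self._n_coords = i
        for name, (seg, _) in self.markers.items():
            if seg not in self.segments:
                raise ModelError(f"marker {name!r} references unknown segment {seg!r}")
        for m in self.muscles:
            for seg, _ in m.path:
                if seg not in self.segments:
                    raise ModelError(f"muscle {m.name!r} references unknown segment {seg!r}")
            if len(m.path) < 2:
                raise ModelError(f"muscle {m.name!r}: path needs >= 2 points")

    def _validate_tree(self) -> None:
        children = {j.child for j in self.joints}
        if children != set(self.segments):
            raise ModelError("every segment must be the child of exactly one joint")
        roots = [j for j in self.joints if j.parent is None]
        if len(roots) != 1:
            raise ModelError("exactly one root joint (parent=None) required")
        placed = {None}
        for j in self.joints:
            if j.parent not in placed and j.parent not in children:
                raise ModelError(f"joint {j.name!r}: parent {j.parent!r} unknown")
            placed.add(j.child)

    # ---- coordinates -------------------------------------------------
    @property
    def n_coords(self) -> int:
        return self._n_coords

    @property
    def coordinate_names(self) -> list[str]:
        return [f"{j.name}_{d}" for j in self.joints for d in j.dof_names]

    def coord_slice(self, joint_name: str) -> slice:
        return self._coord_slices[joint_name]

    @property
    def root_segment(self) -> str:
        return next(j.child for j in self.joints if j.parent is None)

    def joint_for(self, segment: str) -> JointDefinition:
        return next(j for j in self.joints if j.child == segment)

    def total_mass(self) -> float:
        return sum(s.mass_kg for s in self.segments.values())

    # ---- forward kinematics ------------------------------------------
    def forward_kinematics(self, q: np.ndarray) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """World pose per segment: name -> (R 3×3, origin 3)."""
        q = np.asarray(q, dtype=float)
        if q.shape != (self._n_coords,):
            raise ModelError(f"expected {self._n_coords} coordinates, got {q.shape}")
        poses: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for j in self.joints:
            rot, trans = j.local_transform(q[self._coord_slices[j.name]])
            if j.parent is None:
                poses[j.child] = (rot, trans)
            else:
                rp, pp = poses[j.parent]
                poses[j.child] = (rp @ rot, pp + rp @ trans)
        return poses

    def marker_positions(self, q: np.ndarray) -> np.ndarray:
        """World marker positions (n_markers × 3, m), in marker-dict order."""
        poses = self.forward_kinematics(q)
        out = np.empty((len(self.markers), 3))
        for i, (seg, local) in enumerate(self.markers.values()):
            r, p = poses[seg]
            out[i] = p + r @ np.asarray(local, dtype=float)
        return out

    def com_positions(self, q: np.ndarray) -> dict[str, np.ndarray]:
        poses = self.forward_kinematics(q)
        return {n: p + r @ s.com_local_m for n, (r, p) in poses.items() for s in [self.segments[n]]}

    # ---- muscle geometry ---------------------------------------------
    def muscle(self, name: str) -> MuscleParameters:
        try:
            return next(m for m in self.muscles if m.name == name)
        except StopIteration:
            raise ModelError(f"unknown muscle {name!r}") from None

    def musculotendon_length(self, q: np.ndarray, muscle: str | MuscleParameters) -> float:
        """Polyline length (cm) of the muscle line of action at pose q."""
        m = self.muscle(muscle) if isinstance(muscle, str) else muscle
        poses = self.forward_kinematics(q)
        pts = np.array([poses[seg][1] + poses[seg][0] @ np.asarray(loc, float) for seg, loc in m.path])
        return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum()) * 100.0

    def moment_arm(
        self, q: np.ndarray, muscle: str | MuscleParameters, dof: int, delta_deg: float = 0.1
    ) -> float:
        """Tendon-excursion moment arm (cm) about generalized coordinate ``dof``:
        r = −∂L/∂θ, central difference with step ``delta_deg``."""
        d = math.radians(delta_deg)
        qp, qm = np.array(q, dtype=float), np.array(q, dtype=float)
        qp[dof] += d
        qm[dof] -= d
        lp = self.musculotendon_length(qp, muscle)
        lm = self.musculotendon_length(qm, muscle)
        return -(lp - lm) / (2 * d)

    def all_mtu_lengths(self, q: np.ndarray) -> np.ndarray:
        """MTU lengths (cm) of every muscle at pose q from a single FK pass."""
        poses = self.forward_kinematics(q)
        out = np.empty(len(self.muscles))
        for k, m in enumerate(self.muscles):
            pts = np.array(
                [poses[seg][1] + poses[seg][0] @ np.asarray(loc, float) for seg, loc in m.path]
            )
            out[k] = np.linalg.norm(np.diff(pts, axis=0), axis=1).sum() * 100.0
        return out

    def moment_arm_matrix(
        self, q: np.ndarray, dofs: list[int], delta_deg: float = 0.1
    ) -> np.ndarray:
        """Moment arms (n_muscles × n_dofs, cm) for all muscles at pose q,
        by tendon excursion with two FK passes per DOF."""
        d = math.radians(delta_deg)
        arms = np.empty((len(self.muscles), len(dofs)))
        for di, dof in enumerate(dofs):
            qp, qm = np.array(q, dtype=float), np.array(q, dtype=float)
            qp[dof] += d
            qm[dof] -= d
            arms[:, di] = -(self.all_mtu_lengths(qp) - self.all_mtu_lengths(qm)) / (2 * d)
        return arms
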