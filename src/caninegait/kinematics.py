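"""Marker-trajectory preprocessing, gait-cycle handling, joint angles and
marker-based inverse kinematics.

Marker positions are stored in mm at the capture rate (100 Hz default).
Preprocessing follows the conventional gait workflow: zero-phase low-pass
Butterworth smoothing at 6 Hz, quintic-spline interpolation of short marker
gaps (< 5 frames; longer gaps invalidate the trial), gait-cycle definition
from paw contact to the next ipsilateral contact, and resampling onto a
100-point normalized cycle.

Sagittal joint angles are included angles between segment axes:

    hip    α = arccos(x_p · y_f / |x_p||y_f|)
    stifle β = arccos(y_f · y_t / |y_f||y_t|)
    tarsus γ = arccos(y_t · y_tr / |y_t||y_tr|)

with x_p the pelvis cranial axis, y_f the femur proximal–distal axis
(lateral femoral condyle → greater trochanter), y_t the tibia axis (lateral
malleolus → lateral femoral condyle) and y_tr the tarsal axis (5th
metatarsal → calcaneus).

Inverse kinematics solves, frame by frame, the weighted least-squares
problem  min_q Σ_m w_m ‖virtual_m(q) − measured_m‖²  over the model's
generalized coordinates, warm-starting each frame from the previous
solution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import make_interp_spline
from scipy.optimize import least_squares
from scipy.signal import butter, filtfilt

from .model import MusculoskeletalModel


class KinematicsError(ValueError):
    pass


@dataclass
class MarkerTrajectorySet:
    """Marker trajectories: frames × markers × 3, mm, with visibility flags."""

    names: list[str]
    positions_mm: np.ndarray
    rate_hz: float = 100.0
    visible: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions_mm = np.asarray(self.positions_mm, dtype=float)
        if self.positions_mm.ndim != 3 or self.positions_mm.shape[1:] != (len(self.names), 3):
            raise KinematicsError("positions must be frames × markers × 3")
        if self.rate_hz <= 0:
            raise KinematicsError("sampling rate must be > 0")
        if self.visible is None:
            self.visible = np.ones(self.positions_mm.shape[:2], dtype=bool)
        else:
            self.visible = np.asarray(self.visible, dtype=bool)
            if self.visible.shape != self.positions_mm.shape[:2]:
                raise KinematicsError("visibility flags must be frames × markers")

    @property
    def n_frames(self) -> int:
        return self.positions_mm.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.rate_hz

    def marker(self, name: str) -> np.ndarray:
        return self.positions_mm[:, self.names.index(name), :]

    def gap_runs(self, marker_index: int) -> list[tuple[int, int]]:
        """(start, stop) half-open index ranges of invisible samples."""
        vis = self.visible[:, marker_index]
        runs, start = [], None
        for i, v in enumerate(vis):
            if not v and start is None:
                start = i
            elif v and start is not None:
                runs.append((start, i))
                start = None
        if start is not None:
            runs.append((start, len(vis)))
        return runs

    def has_long_gaps(self, min_len: int = 5) -> bool:
        """True if any marker gap is ≥ ``min_len`` frames (trial invalid)."""
        return any(
            stop - start >= min_len
            for mi in range(len(self.names))
            for start, stop in self.gap_runs(mi)
        )


@dataclass
class GaitCycle:
    """One gait cycle: ipsilateral paw contact to the next, plus stance share."""

    trial_id: str
    start_frame: int
    end_frame: int
    stance_fraction: float
    n_points: int = 100

    def __post_init__(self) -> None:
        if self.end_frame <= self.start_frame:
            raise KinematicsError("cycle end must follow start")
        if not 0 < self.stance_fraction < 1:
            raise KinematicsError("stance fraction must be in (0, 1)")


@dataclass
class JointAngleSeries:
    """Hip/stifle/tarsus included angles (deg) and angular velocities (deg/s)
    on the normalized gait cycle."""

    cycle_percent: np.ndarray
    angles_deg: dict[str, np.ndarray]
    velocities_deg_s: dict[str, np.ndarray]


def butterworth_lowpass(series: np.ndarray, cutoff_hz: float = 6.0, rate_hz: float = 100.0,
                        order: int = 4) -> np.ndarray:
    """Zero-phase (forward–backward) low-pass Butterworth filter along axis 0."""
    if rate_hz <= 2 * cutoff_hz:
        raise KinematicsError("sampling rate must exceed twice the cutoff")
    b, a = butter(order, cutoff_hz / (rate_hz / 2.0))
    return filtfilt(b, a, np.asarray(series, dtype=float), axis=0)


def fill_gaps_quintic(traj: MarkerTrajectorySet, max_gap: int = 4,
                      support: int = 3) -> MarkerTrajectorySet:
    """Interpolate marker gaps shorter than 5 frames with quintic splines.

    Each fillable gap needs ``support`` visible frames on both sides; gaps of
    ``max_gap + 1`` or more frames, or gaps at the sequence boundary, are left
    flagged — such trials fail the success rule and should be discarded.
    """
    pos = traj.positions_mm.copy()
    vis = traj.visible.copy()
    for mi in range(len(traj.names)):
        for start, stop in traj.gap_runs(mi):
            if stop - start > max_gap:
                continue
            left = np.arange(start - support, start)
            right = np.arange(stop, stop + support)
            if left[0] < 0 or right[-1] >= traj.n_frames:
                continue  # boundary gap: not fillable
            if not (traj.visible[left, mi].all() and traj.visible[right, mi].all()):
                continue
            knots = np.concatenate([left, right])
            gap = np.arange(start, stop)
            for c in range(3):
                spl = make_interp_spline(knots, traj.positions_mm[knots, mi, c], k=5)
                pos[gap, mi, c] = spl(gap)
            vis[gap, mi] = True
    return MarkerTrajectorySet(list(traj.names), pos, traj.rate_hz, vis)


def segment_gait_cycle(grf_vertical: np.ndarray, threshold: float, rate_hz: float = 100.0,
                       min_contact_s: float = 0.05, trial_id: str = "trial") -> GaitCycle:
    """Locate one full gait cycle in a vertical ground-reaction force series.

    Contact onset is the first frame the vertical force exceeds ``threshold``
    (N) and stays above it for at least ``min_contact_s`` (debounce against
    baseline chatter).  The cycle spans contact → next ipsilateral contact;
    the stance fraction is the loaded share of that span.
    """
    if threshold <= 0:
        raise KinematicsError("contact threshold must be > 0 (chatter rejection)")
    f = np.asarray(grf_vertical, dtype=float)
    loaded = f > threshold
    min_run = max(1, int(round(min_contact_s * rate_hz)))

    def onsets() -> list[int]:
        out, i = [], 0
        while i < len(loaded):
            if loaded[i] and (i == 0 or not loaded[i - 1]):
                run = 0
                while i + run < len(loaded) and loaded[i + run]:
                    run += 1
                if run >= min_run:
                    out.append(i)
                i += max(run, 1)
            else:
                i += 1
        return out

    starts = onsets()
    if not starts:
        raise KinematicsError("no paw contact found above threshold")
    if len(starts) < 2:
        raise KinematicsError("need a successive ipsilateral contact to close the cycle")
    start, end = starts[0], starts[1]
    off = start
    while off < end and loaded[off]:
        off += 1
    return GaitCycle(trial_id, start, end, stance_fraction=(off - start) / (end - start))


def included_angle_deg(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Included angle (deg, 0–180) between vectors along the last axis."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu = np.linalg.norm(u, axis=-1)
    nv = np.linalg.norm(v, axis=-1)
    if np.any(nu < 1e-12) or np.any(nv < 1e-12):
        raise KinematicsError("zero-length axis vector")
    cosang = np.clip(np.einsum("...i,...i", u, v) / (nu * nv), -1.0, 1.0)
    return np.degrees(np.arccos(cosang))


#: Experimental marker names (left side) used for the sagittal angle axes.
ANGLE_MARKERS = {
    "iliac": "L_ILIAC_CREST",
    "ischial": "L_ISCHIAL_TUB",
    "trochanter": "L_GR_TROCHANTER",
    "condyle": "L_LAT_FEM_CONDYLE",
    "malleolus": "L_LAT_MALLEOLUS",
    "calcaneus": "L_CALCANEUS",
    "mt5": "L_MT5_DISTAL",
}


def joint_angles(traj: MarkerTrajectorySet, marker_map: dict[str, str] | None = None,
                 times: np.ndarray | None = None) -> JointAngleSeries:
    """Hip/stifle/tarsus included angles per frame from marker trajectories."""
    mm = dict(ANGLE_MARKERS)
    if marker_map:
        mm.update(marker_map)
    xp = traj.marker(mm["iliac"]) - traj.marker(mm["ischial"])
    yf = traj.marker(mm["trochanter"]) - traj.marker(mm["condyle"])
    yt = traj.marker(mm["condyle"]) - traj.marker(mm["malleolus"])
    ytr = traj.marker(mm["calcaneus"]) - traj.marker(mm["mt5"])
    angles = {
        "hip": included_angle_deg(xp, yf),
        "stifle": included_angle_deg(yf, yt),
        "tarsus": included_angle_deg(yt, ytr),
    }
    t = traj.times if times is None else np.asarray(times, dtype=float)
    vel = {k: np.gradient(v, t) for k, v in angles.items()}
    pct = 100.0 * (t - t[0]) / (t[-1] - t[0]) if len(t) > 1 else np.zeros_like(t)
    return JointAngleSeries(pct, angles, vel)


def resample_cycle(series: np.ndarray, n: int = 100) -> np.ndarray:
    """Resample a series covering one full cycle onto ``n`` evenly spaced
    points (linear interpolation in normalized time, endpoints preserved)."""
    series = np.asarray(series, dtype=float)
    if series.shape[0] < 2:
        raise KinematicsError("need at least 2 samples to resample")
    x_old = np.linspace(0.0, 1.0, series.shape[0])
    x_new = np.linspace(0.0, 1.0, n)
    flat = series.reshape(series.shape[0], -1)
    out = np.column_stack([np.interp(x_new, x_old, flat[:, k]) for k in range(flat.shape[1])])
    return out.reshape((n,) + series.shape[1:])


@dataclass
class IKResult:
    """Generalized coordinates and marker-fit diagnostics per frame."""

    coordinates: np.ndarray          # frames × n_coords (rad, m)
    marker_rms_mm: np.ndarray        # frames
    per_marker_error_mm: np.ndarray  # frames × markers
    converged: np.ndarray            # frames, bool
    coordinate_names: list[str] = field(default_factory=list)


def inverse_kinematics(
    model: MusculoskeletalModel,
    traj: MarkerTrajectorySet,
    weights: dict[str, float] | None = None,
    q0: np.ndarray | None = None,
) -> IKResult:
    """Track measured markers with the model's virtual markers.

    Markers in ``traj`` are matched to model markers by name; unmatched or
    invisible samples get zero weight.  Default weight 1 per marker,
    overridable per marker (down-weight corrupted markers).
    """
    model_names = list(model.markers)
    idx = [(mi, model_names.index(nm)) for mi, nm in enumerate(traj.names) if nm in model_names]
    if len(idx) < 3:
        raise KinematicsError("need at least 3 markers shared between data and model")
    traj_idx = np.array([i for i, _ in idx])
    model_idx = np.array([j for _, j in idx])
    w = np.array([1.0 if weights is None else weights.get(traj.names[i], 1.0) for i in traj_idx])
    if np.any(w < 0):
        raise KinematicsError("marker weights must be >= 0")

    measured_m = traj.positions_mm * 1e-3
    nq = model.n_coords
    q = np.zeros(nq) if q0 is None else np.asarray(q0, dtype=float).copy()
    coords = np.empty((traj.n_frames, nq))
    rms = np.empty(traj.n_frames)
    per_marker = np.full((traj.n_frames, len(traj.names)), np.nan)
    converged = np.zeros(traj.n_frames, dtype=bool)

    for f in range(traj.n_frames):
        vis = traj.visible[f, traj_idx]
        sw = np.sqrt(w * vis)

        def residuals(qq: np.ndarray) -> np.ndarray:
            virtual = model.marker_positions(qq)[model_idx]
            return ((virtual - measured_m[f, traj_idx]) * sw[:, None]).ravel()

        sol = least_squares(residuals, q, method="trf", xtol=1e-10, ftol=1e-10, gtol=1e-10)
        q = sol.x
        coords[f] = q
        err = np.linalg.norm(
            model.marker_positions(q)[model_idx] - measured_m[f, traj_idx], axis=1
        ) * 1e3
        per_marker[f, traj_idx] = err
        active = (w > 0) & vis
        rms[f] = float(np.sqrt(np.mean(err[active] ** 2))) if active.any() else np.nan
        converged[f] = sol.status > 0
    return IKResult(coords, rms, per_marker, converged, model.coordinate_names)
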