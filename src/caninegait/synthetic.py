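"""Self-consistent synthetic canine gait trials.

The study's capture and CT data are not deposited, so this module emulates
them: a small-dog (5.4 kg, dachshund-proportioned) pelvic-limb morphology
with the packaged 33-muscle parameter roster, smooth periodic joint-angle
waveforms at a slow walk (0.6 m/s), forward-kinematics marker trajectories
at the ten experimental marker sites with seeded Gaussian noise, and a
parameterized double-peaked ground-reaction template (first vertical peak
51% body weight at 16% of the cycle, braking-to-propulsion transition at
one third of stance).  Ground-truth generalized coordinates and the
noise-free inverse-dynamics moments are stored with every trial so each
pipeline stage can be checked by recovery rather than against unavailable
experimental curves.

Everything is deterministic given the spec (identical spec → bit-identical
outputs).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np

from .dynamics import GroundReaction, JointMomentSeries, PlateData, inverse_dynamics
from .kinematics import GaitCycle, MarkerTrajectorySet
from .model import BodySegment, JointDefinition, MusculoskeletalModel, rot_z
from .morphometry import (
    DEFAULT_DENSITIES,
    TissueVolumeTable,
    VoxelCloud,
    compute_segment_inertia,
    compute_segment_mass,
    compute_torso_mass,
)
from .muscles import adjust_fiber_and_tendon, roster_parameters


class SyntheticGaitError(ValueError):
    pass


@dataclass
class SyntheticGaitSpec:
    """Parameters of a synthetic gait trial.

    Defaults reproduce the study conditions: a 5.4 kg dog walking at
    0.6 m/s with a 0.6 stance fraction, vertical GRF first peak of 51% BW
    at 16% of the cycle, braking/propulsion split at 1/3 of stance, 100 Hz
    markers with 2 mm isotropic noise.
    """

    seed: int = 0
    body_mass_kg: float = 5.4
    speed_m_s: float = 0.6
    cycle_duration_s: float = 0.6
    stance_fraction: float = 0.6
    rate_hz: float = 100.0
    grf_rate_hz: float = 1000.0
    marker_noise_mm: float = 2.0
    grf_first_peak_bw: float = 0.51
    grf_peak_time_fraction: float = 0.16
    braking_fraction: float = 1.0 / 3.0
    mediolateral_amp_bw: float = 0.05
    trial_cycles: float = 1.15  # extra tail so the closing contact is detectable
    #: when True, plate wrenches are computed from the inverse-dynamics
    #: closure of the kinematics (zero pelvis residuals by construction)
    #: instead of the parameterized template — used by residual-reduction
    #: and energy-bookkeeping fixtures
    dynamically_consistent_grf: bool = False

    def __post_init__(self) -> None:
        if self.body_mass_kg <= 0 or self.speed_m_s <= 0 or self.cycle_duration_s <= 0:
            raise SyntheticGaitError("mass, speed and cycle duration must be > 0")
        if not 0 < self.stance_fraction < 1:
            raise SyntheticGaitError("stance fraction must be in (0, 1)")
        if not 0 < self.grf_peak_time_fraction < self.stance_fraction:
            raise SyntheticGaitError("vertical peak must fall within stance")


# ---------------------------------------------------------------------------
# morphology
# ---------------------------------------------------------------------------

# segment lengths (m) and target masses (kg at 5.4 kg body mass);
# the nine bony segments sum to 0.89 kg so the torso closes to ~1.81 kg
_SEGMENT_GEOMETRY = {
    # name: (length_m, half_width_m, mass_at_reference_kg)
    "pelvis": (0.090, 0.030, 0.280),
    "femur": (0.090, 0.014, 0.155),
    "tibia": (0.095, 0.011, 0.095),
    "tarsus": (0.050, 0.009, 0.040),
    "phalanges": (0.035, 0.008, 0.015),
}
REFERENCE_MASS_KG = 5.4

# mass fractions by tissue class (cortical, trabecular, muscle, fat)
_TISSUE_FRACTIONS = (0.15, 0.10, 0.65, 0.10)

# neutral sagittal tilt of each limb segment (deg, rotation about z in parent)
_NEUTRAL_TILT = {"femur": 30.0, "tibia": -70.0, "tarsus": 55.0, "phalanges": 75.0}

_HIP_IN_PELVIS = np.array([-0.025, -0.010, 0.030])  # left side; z mirrored for right

# markers: name -> (segment base name, local position, lateral z sign applies)
_MARKER_LOCAL = {
    "ILIAC_CREST": ("pelvis", (0.045, 0.015, 0.028)),
    "ISCHIAL_TUB": ("pelvis", (-0.045, 0.000, 0.030)),
    "GR_TROCHANTER": ("femur", (0.000, 0.005, 0.012)),
    "LAT_FEM_CONDYLE": ("femur", (0.000, -0.090, 0.012)),
    "FIBULAR_HEAD": ("tibia", (-0.005, -0.012, 0.010)),
    "TIBIAL_CREST": ("tibia", (0.012, -0.015, 0.005)),
    "LAT_MALLEOLUS": ("tibia", (0.000, -0.095, 0.010)),
    "CALCANEUS": ("tarsus", (-0.018, 0.008, 0.005)),
    "MT5_DISTAL": ("tarsus", (0.000, -0.050, 0.008)),
    "DORSAL_PAW": ("phalanges", (0.000, -0.020, 0.000)),
}

# muscle paths: name -> list of (segment base name, (x, y, z_lateral)) points,
# origin first.  z is lateral-positive and mirrored for the right limb.
_MUSCLE_PATHS: dict[str, list[tuple[str, tuple[float, float, float]]]] = {
    "Adductor longus": [("pelvis", (-0.020, -0.020, 0.020)), ("femur", (-0.005, -0.040, 0.003))],
    "Adductor magnus et brevis": [
        ("pelvis", (-0.035, -0.020, 0.020)), ("femur", (-0.006, -0.060, 0.002))],
    "Biceps femoris (patellar)": [
        ("pelvis", (-0.045, -0.005, 0.028)), ("femur", (0.018, -0.085, 0.012)),
        ("tibia", (0.015, -0.015, 0.008))],
    "Biceps femoris (tibial)": [
        ("pelvis", (-0.045, -0.005, 0.028)), ("femur", (-0.012, -0.080, 0.012)),
        ("tibia", (-0.008, -0.025, 0.008))],
    "Biceps femoris (calcaneal)": [
        ("pelvis", (-0.045, -0.005, 0.028)), ("femur", (-0.014, -0.085, 0.012)),
        ("tarsus", (-0.018, 0.006, 0.004))],
    "Extensor digitorum lateralis": [
        ("tibia", (0.008, -0.020, 0.008)), ("tibia", (0.012, -0.090, 0.006)),
        ("tarsus", (0.012, -0.010, 0.005)), ("phalanges", (0.005, -0.010, 0.004))],
    "Extensor digitorum longus": [
        ("femur", (0.012, -0.085, 0.006)), ("tibia", (0.013, -0.020, 0.004)),
        ("tibia", (0.012, -0.092, 0.003)), ("tarsus", (0.010, -0.045, 0.003)),
        ("phalanges", (0.006, -0.020, 0.002))],
    "Flexor digitorum profundus": [
        ("tibia", (-0.010, -0.030, 0.003)), ("tibia", (-0.012, -0.090, 0.002)),
        ("tarsus", (-0.014, -0.010, 0.002)), ("phalanges", (-0.004, -0.015, 0.001))],
    "Flexor digitorum superficialis": [
        ("femur", (-0.012, -0.080, 0.002)), ("tarsus", (-0.020, 0.008, 0.002)),
        ("phalanges", (-0.005, -0.012, 0.001))],
    "Gastrocnemius lateralis": [
        ("femur", (-0.012, -0.082, 0.008)), ("tarsus", (-0.018, 0.008, 0.004))],
    "Gastrocnemius medialis": [
        ("femur", (-0.012, -0.082, -0.006)), ("tarsus", (-0.018, 0.008, -0.002))],
    "Gemelli": [("pelvis", (-0.035, -0.012, 0.025)), ("femur", (-0.004, -0.010, 0.010))],
    "Gluteus medius": [("pelvis", (0.030, 0.010, 0.020)), ("femur", (0.002, -0.005, 0.014))],
    "Gluteus profundus": [("pelvis", (0.015, 0.000, 0.022)), ("femur", (0.003, -0.008, 0.012))],
    "Gluteus superficialis": [
        ("pelvis", (-0.010, 0.010, 0.028)), ("femur", (-0.002, -0.020, 0.012))],
    "Gracilis": [("pelvis", (-0.030, -0.022, 0.012)), ("tibia", (-0.005, -0.030, -0.004))],
    "Iliopsoas": [("pelvis", (0.035, -0.005, 0.015)), ("femur", (0.004, -0.025, -0.006))],
    "Obturator externus": [
        ("pelvis", (-0.030, -0.018, 0.020)), ("femur", (-0.003, -0.012, 0.008))],
    "Obturator internus": [
        ("pelvis", (-0.032, -0.008, 0.020)), ("femur", (-0.003, -0.010, 0.009))],
    "Pectineus": [("pelvis", (-0.012, -0.022, 0.015)), ("femur", (-0.004, -0.045, -0.004))],
    "Peroneus longus": [
        ("tibia", (0.006, -0.018, 0.009)), ("tibia", (0.004, -0.090, 0.008)),
        ("tarsus", (0.002, -0.030, 0.006))],
    "Popliteus": [("femur", (-0.008, -0.085, 0.006)), ("tibia", (-0.006, -0.025, -0.004))],
    "Quadratus femoris": [
        ("pelvis", (-0.040, -0.015, 0.018)), ("femur", (-0.005, -0.020, 0.006))],
    "Rectus femoris": [
        ("pelvis", (0.020, -0.012, 0.018)), ("femur", (0.016, -0.085, 0.004)),
        ("tibia", (0.014, -0.012, 0.004))],
    "Sartorius caudalis": [("pelvis", (0.035, 0.005, 0.020)), ("tibia", (0.008, -0.020, -0.004))],
    "Sartorius cranialis": [
        ("pelvis", (0.038, 0.008, 0.020)), ("femur", (0.014, -0.050, 0.000)),
        ("tibia", (0.010, -0.015, -0.002))],
    "Semimembranosus (tibial)": [
        ("pelvis", (-0.042, -0.010, 0.020)), ("tibia", (-0.007, -0.028, -0.005))],
    "Semimembranosus (femoral)": [
        ("pelvis", (-0.042, -0.010, 0.020)), ("femur", (-0.006, -0.070, -0.004))],
    "Semitendinosus": [
        ("pelvis", (-0.044, -0.008, 0.024)), ("tibia", (-0.008, -0.040, 0.000)),
        ("tibia", (-0.004, -0.060, -0.002))],
    "Tensor fascia lata": [
        ("pelvis", (0.030, 0.005, 0.026)), ("femur", (0.012, -0.040, 0.012)),
        ("tibia", (0.010, -0.010, 0.008))],
    "Tibialis cranialis": [
        ("tibia", (0.012, -0.020, 0.004)), ("tibia", (0.012, -0.092, 0.003)),
        ("tarsus", (0.008, -0.020, 0.003))],
    "Vastus lateralis and intermedius": [
        ("femur", (0.008, -0.015, 0.008)), ("femur", (0.016, -0.085, 0.005)),
        ("tibia", (0.014, -0.012, 0.003))],
    "Vastus medialis": [
        ("femur", (0.008, -0.018, -0.006)), ("femur", (0.015, -0.085, -0.004)),
        ("tibia", (0.013, -0.012, -0.003))],
}

# generous physiologic coordinate limits (deg, deltas from neutral)
_JOINT_LIMITS_DEG = {"hip": (-60.0, 60.0), "stifle": (-100.0, 25.0), "tarsus": (-60.0, 60.0)}


def _segment_voxel_cloud(length_m: float, half_width_m: float, voxel_mm: float = 2.0) -> VoxelCloud:
    """Coarse uniform muscle-density cuboid along −y used for inertia shape."""
    ny = max(3, int(round(length_m * 1000 / voxel_mm)))
    nxz = max(3, int(round(2 * half_width_m * 1000 / voxel_mm)))
    ys = -(np.arange(ny) + 0.5) * voxel_mm
    xs = (np.arange(nxz) - (nxz - 1) / 2) * voxel_mm
    gx, gy, gz = np.meshgrid(xs, ys, xs, indexing="ij")
    pos = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    return VoxelCloud(pos, np.full(len(pos), 2), pixel_size_mm=voxel_mm, slice_thickness_mm=voxel_mm)


def generate_morphology(
    spec: SyntheticGaitSpec,
) -> tuple[MusculoskeletalModel, TissueVolumeTable]:
    """Build the scaled subject model and its tissue-volume table.

    Segment masses come through the density-weighted voxel-count rule so the
    morphometric pipeline is exercised end to end; the torso point mass
    closes the total to half the body mass.  Muscle fiber/tendon lengths are
    re-split to each muscle's neutral-pose MTU length, preserving the
    roster's fiber:tendon proportions.
    """
    scale = spec.body_mass_kg / REFERENCE_MASS_KG
    table_counts: dict[str, tuple[int, int, int, int]] = {}
    p_mm, s_mm = 0.325, 1.0
    voxel_cm3 = p_mm**2 * s_mm * 1e-3
    seg_names = ["pelvis"] + [
        f"{side}_{base}" for side in ("L", "R") for base in ("femur", "tibia", "tarsus", "phalanges")
    ]
    for name in seg_names:
        base = name.split("_")[-1]
        target = _SEGMENT_GEOMETRY[base][2] * scale
        counts = tuple(
            int(round(target * frac * 1e3 / (rho * voxel_cm3)))
            for frac, rho in zip(_TISSUE_FRACTIONS, DEFAULT_DENSITIES)
        )
        table_counts[name] = counts
    tissue = TissueVolumeTable(table_counts, p_mm, s_mm)

    segments: dict[str, BodySegment] = {}
    for name in seg_names:
        base = name.split("_")[-1]
        length, half_w, _ = _SEGMENT_GEOMETRY[base]
        mass = compute_segment_mass(tissue, name)
        cloud = _segment_voxel_cloud(length, half_w)
        inertia = compute_segment_inertia(cloud) * (mass / cloud.total_mass_kg())
        com = np.array([0.0, -length / 2, 0.0])
        if base == "pelvis":
            com = np.zeros(3)
        segments[name] = BodySegment(name, mass, com, inertia)

    seg_mass_sum = sum(s.mass_kg for s in segments.values())
    torso_mass = compute_torso_mass(spec.body_mass_kg, seg_mass_sum)
    segments["torso"] = BodySegment(
        "torso", torso_mass, np.zeros(3), np.diag([2e-3, 2e-3, 2e-3]) * scale
    )

    joints = [
        JointDefinition("ground_pelvis", "free", None, "pelvis", np.zeros(3)),
        JointDefinition("pelvis_torso", "fixed", "pelvis", "torso",
                        np.array([0.02, 0.02, 0.0])),
    ]
    for side, zsign in (("L", 1.0), ("R", -1.0)):
        hip = _HIP_IN_PELVIS * np.array([1.0, 1.0, zsign])
        joints.append(JointDefinition(
            f"{side}_hip", "ball", "pelvis", f"{side}_femur", hip,
            rot_z(np.radians(_NEUTRAL_TILT["femur"]))))
        joints.append(JointDefinition(
            f"{side}_stifle", "sliding_hinge", f"{side}_femur", f"{side}_tibia",
            np.array([0.0, -_SEGMENT_GEOMETRY["femur"][0], 0.0]),
            rot_z(np.radians(_NEUTRAL_TILT["tibia"]))))
        joints.append(JointDefinition(
            f"{side}_tarsus", "hinge", f"{side}_tibia", f"{side}_tarsus",
            np.array([0.0, -_SEGMENT_GEOMETRY["tibia"][0], 0.0]),
            rot_z(np.radians(_NEUTRAL_TILT["tarsus"]))))
        joints.append(JointDefinition(
            f"{side}_mtp", "fixed", f"{side}_tarsus", f"{side}_phalanges",
            np.array([0.0, -_SEGMENT_GEOMETRY["tarsus"][0], 0.0]),
            rot_z(np.radians(_NEUTRAL_TILT["phalanges"]))))

    markers: dict[str, tuple[str, np.ndarray]] = {}
    for side, zsign in (("L", 1.0), ("R", -1.0)):
        for mname, (base, local) in _MARKER_LOCAL.items():
            seg = "pelvis" if base == "pelvis" else f"{side}_{base}"
            local_v = np.array(local) * np.array([1.0, 1.0, zsign])
            markers[f"{side}_{mname}"] = (seg, local_v)

    muscles = []
    length_scale = scale ** (1.0 / 3.0)
    for side, zsign in (("L", 1.0), ("R", -1.0)):
        for params in roster_parameters():
            path = []
            for base, local in _MUSCLE_PATHS[params.name]:
                seg = "pelvis" if base == "pelvis" else f"{side}_{base}"
                path.append((seg, np.array(local) * np.array([1.0, 1.0, zsign])))
            m = replace(params, name=f"{side}_{params.name}", path=path)
            m.fiber_length_cm *= length_scale
            m.tendon_slack_cm *= length_scale
            muscles.append(m)

    model = MusculoskeletalModel(segments, joints, markers, muscles, torso_segment="torso")

    # re-split fiber/tendon lengths against the neutral-pose MTU length
    q0 = np.zeros(model.n_coords)
    mtu0 = model.all_mtu_lengths(q0)
    for j, m in enumerate(model.muscles):
        f_adj, tsl_adj = adjust_fiber_and_tendon(m.fiber_length_cm, m.tendon_slack_cm, mtu0[j])
        m.fiber_length_cm, m.tendon_slack_cm = f_adj, tsl_adj
    return model, tissue


# ---------------------------------------------------------------------------
# waveforms and ground reactions
# ---------------------------------------------------------------------------

def joint_waveforms_deg(s: np.ndarray) -> dict[str, np.ndarray]:
    """Smooth periodic flexion-extension deltas (deg) vs cycle fraction s.

    Plausible slow-walk shapes: the hip protracts at contact, retracts
    through stance and swings forward (~25° ROM); the stifle flexes up to
    ~30° in swing; the tarsus yields in early stance and extends for push
    off.  These are fixtures emulating the qualitative patterns of a walking
    dog, not reproductions of any measured dog.
    """
    s = np.asarray(s, dtype=float)
    two_pi = 2 * np.pi
    return {
        "hip": 14.0 * np.cos(two_pi * s) + 3.0 * np.sin(2 * two_pi * s),
        "stifle": -15.0 + 15.0 * np.sin(two_pi * s) - 2.0 * np.sin(2 * two_pi * s),
        "tarsus": -6.0 + 6.0 * np.sin(two_pi * (s + 0.1)) + 2.0 * np.sin(2 * two_pi * s),
    }


def _check_limits(wave: dict[str, np.ndarray]) -> None:
    for joint, (lo, hi) in _JOINT_LIMITS_DEG.items():
        w = wave[joint]
        if w.min() < lo or w.max() > hi:
            raise SyntheticGaitError(f"{joint} waveform outside joint limits [{lo}, {hi}] deg")


def vertical_grf_template(s_stance: np.ndarray, spec: SyntheticGaitSpec) -> np.ndarray:
    """Double-peaked vertical GRF (fraction of BW) vs stance fraction.

    Scaled so the first (global) peak equals ``grf_first_peak_bw`` exactly at
    the configured peak time; zero at contact and lift-off.
    """
    s = np.clip(np.asarray(s_stance, dtype=float), 0.0, 1.0)
    p1 = spec.grf_peak_time_fraction / spec.stance_fraction

    def raw(u: np.ndarray) -> np.ndarray:
        # boundary window: smooth rise/fall, flat (=1) where the peaks live,
        # so the first Gaussian's maximum stays put
        up = np.clip(u / 0.08, 0.0, 1.0)
        down = np.clip((1.0 - u) / 0.08, 0.0, 1.0)
        window = (3 - 2 * up) * up**2 * (3 - 2 * down) * down**2
        bumps = np.exp(-(((u - p1) / 0.16) ** 2)) + 0.8 * np.exp(-(((u - 0.72) / 0.20) ** 2))
        return window * bumps

    shape = raw(s)
    inside = (s_stance >= 0) & (s_stance <= 1)
    shape = np.where(inside, shape, 0.0)
    return spec.grf_first_peak_bw * shape / raw(np.array([p1]))[0]


def cranial_grf_template(s_stance: np.ndarray, spec: SyntheticGaitSpec,
                         braking_bw: float = 0.08, propulsion_bw: float = 0.06) -> np.ndarray:
    """Braking-then-propulsion cranial force (fraction of BW): caudal
    (negative) for the first third of stance, cranial after."""
    s = np.asarray(s_stance, dtype=float)
    b = spec.braking_fraction
    out = np.where(
        s < b,
        -braking_bw * np.sin(np.pi * s / b),
        propulsion_bw * np.sin(np.pi * (s - b) / (1 - b)),
    )
    return np.where((s >= 0) & (s <= 1), out, 0.0)


# ---------------------------------------------------------------------------
# trial generation
# ---------------------------------------------------------------------------

@dataclass
class SyntheticTrial:
    """A generated trial with its ground truth."""

    spec: SyntheticGaitSpec
    model: MusculoskeletalModel
    markers: MarkerTrajectorySet
    clean_markers: MarkerTrajectorySet
    grf: GroundReaction
    times: np.ndarray
    truth_q: np.ndarray                     # frames × n_coords
    truth_angles_deg: dict[str, np.ndarray]  # hip/stifle/tarsus deltas, left limb
    truth_moments: JointMomentSeries
    cycle: GaitCycle
    injected: dict = field(default_factory=dict)

    @property
    def cycle_slice(self) -> slice:
        return slice(self.cycle.start_frame, self.cycle.end_frame + 1)


def _truth_coordinates(model: MusculoskeletalModel, spec: SyntheticGaitSpec,
                       times: np.ndarray) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    s = times / spec.cycle_duration_s
    q = np.zeros((len(times), model.n_coords))
    # pelvis root: forward progression + small vertical bob and pitch
    root = model.coord_slice("ground_pelvis")
    q[:, root.start + 0] = spec.speed_m_s * times
    q[:, root.start + 1] = 0.210 + 0.004 * np.sin(4 * np.pi * s)
    q[:, root.start + 3] = np.radians(2.0) * np.sin(2 * np.pi * s)
    waves = {}
    for side, phase in (("L", 0.0), ("R", 0.5)):
        w = joint_waveforms_deg(s + phase)
        _check_limits(w)
        q[:, model.coord_slice(f"{side}_hip").start] = np.radians(w["hip"])
        q[:, model.coord_slice(f"{side}_stifle").start] = np.radians(w["stifle"])
        q[:, model.coord_slice(f"{side}_tarsus").start] = np.radians(w["tarsus"])
        if side == "L":
            waves = w
    return q, waves


def _plate_for_side(model: MusculoskeletalModel, spec: SyntheticGaitSpec, side: str,
                    poses_paw_xz: np.ndarray, phase: float) -> PlateData:
    t = np.arange(0.0, spec.trial_cycles * spec.cycle_duration_s + 1e-9, 1.0 / spec.grf_rate_hz)
    s = (t / spec.cycle_duration_s + phase) % 1.0
    s_st = s / spec.stance_fraction
    bw = spec.body_mass_kg * 9.81
    fy = vertical_grf_template(s_st, spec) * bw
    fx = cranial_grf_template(s_st, spec) * bw
    fz = spec.mediolateral_amp_bw * bw * np.sin(np.pi * np.clip(s_st, 0, 1)) * np.sin(
        2 * np.pi * np.clip(s_st, 0, 1)
    )
    loaded = fy > 0
    fx = np.where(loaded, fx, 0.0)
    fz = np.where(loaded, fz, 0.0)
    tz = np.where(loaded, 0.012 * spec.body_mass_kg / 5.4 * np.sin(2 * np.pi * np.clip(s_st, 0, 1)), 0.0)
    # COP tracks the paw ground-projection, drifting heel → toe during stance
    kin_t = np.linspace(0.0, spec.trial_cycles * spec.cycle_duration_s, poses_paw_xz.shape[0])
    paw_x = np.interp(t, kin_t, poses_paw_xz[:, 0])
    paw_z = np.interp(t, kin_t, poses_paw_xz[:, 1])
    cop = np.full((len(t), 3), np.nan)
    cop[loaded, 0] = paw_x[loaded] + 0.02 * (np.clip(s_st[loaded], 0, 1) - 0.5)
    cop[loaded, 1] = 0.0
    cop[loaded, 2] = paw_z[loaded]
    return PlateData(f"{side}_phalanges", t, np.column_stack([fx, fy, fz]), tz, cop)


def _consistent_plates(model: MusculoskeletalModel, spec: SyntheticGaitSpec,
                       q: np.ndarray, times: np.ndarray) -> list[PlateData]:
    """Plate wrenches that exactly balance the generated kinematics.

    The required external wrench is the pelvis root wrench from inverse
    dynamics with no external load; it is applied at a ground-plane point
    chosen to cancel the residual moment (up to the small component along
    the force line, carried by the vertical plate torque), and split
    between the two plates with the smooth vertical-template load shares.
    """
    _, res = inverse_dynamics(model, q, times, None)
    force_req = res.residual_force_n
    moment_req = res.residual_moment_nm
    pel = model.segments[model.root_segment]
    com = np.array([
        model.forward_kinematics(qf)[model.root_segment][1]
        + model.forward_kinematics(qf)[model.root_segment][0] @ pel.com_local_m
        for qf in q
    ])
    f2 = np.einsum("fi,fi->f", force_req, force_req)
    u = np.cross(force_req, moment_req) / f2[:, None]
    lam = -(com[:, 1] + u[:, 1]) / force_req[:, 1]
    point = com + u + lam[:, None] * force_req
    tau_left = moment_req - np.cross(point - com, force_req)

    s = times / spec.cycle_duration_s
    w_raw = {
        "L": vertical_grf_template((s % 1.0) / spec.stance_fraction, spec),
        "R": vertical_grf_template(((s + 0.5) % 1.0) / spec.stance_fraction, spec),
    }
    total = w_raw["L"] + w_raw["R"]
    total = np.where(total > 0, total, 1.0)
    plates = []
    for side in ("L", "R"):
        w = w_raw[side] / total
        force = w[:, None] * force_req
        torque_z = w * tau_left[:, 1]
        cop = np.where(w[:, None] > 1e-9, point, np.nan)
        plates.append(PlateData(f"{side}_phalanges", times.copy(), force, torque_z, cop))
    return plates


def generate_trial(spec: SyntheticGaitSpec,
                   model: MusculoskeletalModel | None = None) -> SyntheticTrial:
    """Generate one synthetic walking trial with its ground truth.

    Markers are the forward kinematics of the ground-truth pose plus seeded
    isotropic Gaussian noise; ground reactions follow the parameterized
    double-peak/braking-propulsion template; ground-truth joint moments are
    the inverse dynamics of the noise-free kinematics under those reactions.
    """
    if model is None:
        model, _ = generate_morphology(spec)
    n_frames = int(round(spec.trial_cycles * spec.cycle_duration_s * spec.rate_hz)) + 1
    times = np.arange(n_frames) / spec.rate_hz
    q, waves = _truth_coordinates(model, spec, times)

    clean = np.array([model.marker_positions(qf) for qf in q]) * 1e3  # mm
    names = list(model.markers)
    rng = np.random.default_rng(spec.seed)
    noise = rng.normal(0.0, spec.marker_noise_mm, clean.shape)
    noisy = clean + noise if spec.marker_noise_mm > 0 else clean.copy()
    clean_set = MarkerTrajectorySet(names, clean, spec.rate_hz)
    noisy_set = MarkerTrajectorySet(names, noisy, spec.rate_hz)

    if spec.dynamically_consistent_grf:
        plates = _consistent_plates(model, spec, q, times)
    else:
        plates = []
        for side, phase in (("L", 0.0), ("R", 0.5)):
            paw = np.array([model.forward_kinematics(qf)[f"{side}_phalanges"][1] for qf in q])
            plates.append(_plate_for_side(model, spec, side, paw[:, [0, 2]], phase))
    grf = GroundReaction(plates)

    truth_moments, _ = inverse_dynamics(model, q, times, grf)
    cycle_end = int(round(spec.cycle_duration_s * spec.rate_hz))
    cycle = GaitCycle("synthetic", 0, cycle_end, spec.stance_fraction)
    return SyntheticTrial(
        spec, model, noisy_set, clean_set, grf, times, q, waves, truth_moments, cycle
    )


def corrupt_trial(
    trial: SyntheticTrial,
    gaps: list[tuple[str, int, int]] | None = None,
    force_bias_n: np.ndarray | None = None,
    torso_com_offset_m: np.ndarray | None = None,
) -> SyntheticTrial:
    """Inject controlled defects, recording the injected truth.

    ``gaps`` are (marker name, start frame, length) visibility gaps;
    ``force_bias_n`` is a constant 3-D force added to every plate sample
    during the whole record (a force-plate bias); ``torso_com_offset_m``
    displaces the model torso COM so residual reduction can be checked by
    recovery.
    """
    out = copy.deepcopy(trial)
    out.injected = {}
    if gaps:
        for name, start, length in gaps:
            if start < 0 or start + length > out.markers.n_frames:
                raise SyntheticGaitError("gap longer than trial")
            mi = out.markers.names.index(name)
            out.markers.visible[start:start + length, mi] = False
        out.injected["gaps"] = list(gaps)
    if force_bias_n is not None:
        bias = np.asarray(force_bias_n, dtype=float)
        for plate in out.grf.plates:
            plate.force_n = plate.force_n + bias
            # the bias loads previously unloaded samples: give them a COP
            # (nearest defined one) so the plate stays processable
            undefined = ~np.isfinite(plate.cop_m).all(axis=1)
            if undefined.any() and not undefined.all():
                good = np.flatnonzero(~undefined)
                for c in range(3):
                    plate.cop_m[undefined, c] = np.interp(
                        np.flatnonzero(undefined), good, plate.cop_m[good, c]
                    )
        out.injected["force_bias_n"] = bias
    if torso_com_offset_m is not None:
        off = np.asarray(torso_com_offset_m, dtype=float)
        seg = out.model.segments[out.model.torso_segment]
        seg.com_local_m = seg.com_local_m + off
        out.injected["torso_com_offset_m"] = off
    return out
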