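"""End-to-end gait pipeline: model → IK → ID → (RRA) → SO → validation.

The pipeline consumes a model config (YAML), a TRC marker file and a MOT
force file, and writes tabular outputs (angles, moments, power, activations,
forces, peak table, residuals) plus a validation report and a provenance
block to the output directory.  It is the library counterpart of the
``caninegait`` command line.
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dynamics import GroundReaction, JointMomentSeries, inverse_dynamics, joint_power, reduce_residuals
from .io.config import load_model
from .io.mot import grf_from_mot, write_mot
from .io.trc import read_trc
from .kinematics import (
    GaitCycle,
    MarkerTrajectorySet,
    butterworth_lowpass,
    fill_gaps_quintic,
    inverse_kinematics,
    joint_angles,
    resample_cycle,
    segment_gait_cycle,
)
from .model import MusculoskeletalModel
from .optimization import compute_muscle_states, static_optimization, summarize_peaks
from .tuning import tune_fiber_operating_range
from .validation import CurvePair, ValidationResult, validation_report, validity_check


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Paths, stage toggles and numeric settings of one pipeline run.

    Numeric defaults are the study constants: 6 Hz filter cutoff, 100 cycle
    points, 22.5 N/cm² specific tension, validity thresholds r ≥ 0.80 and
    σ_e ≤ 20% of the peak reference value, 2% BW contact threshold.
    """

    model_path: str
    markers_path: str
    grf_path: str
    output_dir: str
    run_ik: bool = True
    run_rra: bool = True
    run_so: bool = True
    run_validate: bool = True
    filter_cutoff_hz: float = 6.0
    cycle_points: int = 100
    specific_tension: float = 22.5
    r_threshold: float = 0.80
    sigma_fraction: float = 0.20
    contact_threshold_bw: float = 0.02
    stance_fraction_hint: float = 0.6
    seed: int = 0


@dataclass
class PipelineResult:
    config: PipelineConfig
    cycle: GaitCycle
    outputs: dict[str, str] = field(default_factory=dict)
    validation: list[ValidationResult] = field(default_factory=list)

    @property
    def all_valid(self) -> bool:
        return bool(self.validation) and all(v.passes for v in self.validation)


def _sagittal_dofs(model: MusculoskeletalModel) -> list[int]:
    names = model.coordinate_names
    wanted = []
    for j in model.joints:
        if j.parent is None or j.joint_type == "fixed":
            continue
        for d in j.dof_names:
            wanted.append(names.index(f"{j.name}_{d}"))
    return wanted


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the requested stages; writes outputs and returns their paths.

    Raises :class:`PipelineError` naming the failing stage.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}

    def emit(name: str, df: pd.DataFrame) -> None:
        p = out / name
        df.to_csv(p, index=False, float_format="%.8g")
        outputs[name] = str(p)

    # ---- load ----
    for label, p in (("model", config.model_path), ("markers", config.markers_path),
                     ("ground reactions", config.grf_path)):
        if not Path(p).exists():
            raise PipelineError(f"load: missing {label} input {p!r}")
    model = load_model(config.model_path)
    traj = read_trc(config.markers_path)
    grf = grf_from_mot(config.grf_path)

    # ---- preprocess ----
    traj = fill_gaps_quintic(traj)
    if traj.has_long_gaps():
        raise PipelineError("preprocess: marker gaps of 5+ frames present; trial unsuccessful")
    smoothed = MarkerTrajectorySet(
        list(traj.names),
        butterworth_lowpass(traj.positions_mm, config.filter_cutoff_hz, traj.rate_hz),
        traj.rate_hz,
        traj.visible,
    )

    # ---- gait cycle from the left plate vertical force ----
    body_weight_n = 2.0 * model.total_mass() * 9.81
    left = next((p for p in grf.plates if p.segment.startswith("L")), grf.plates[0])
    fy, _, _ = left.resample_to(smoothed.times)
    try:
        cycle = segment_gait_cycle(
            fy[:, 1] if fy.ndim > 1 else fy,
            threshold=config.contact_threshold_bw * body_weight_n,
            rate_hz=smoothed.rate_hz,
        )
    except Exception as exc:
        raise PipelineError(f"cycle segmentation: {exc}") from exc
    sl = slice(cycle.start_frame, cycle.end_frame + 1)
    times = smoothed.times[sl]

    # ---- inverse kinematics ----
    if not config.run_ik:
        return PipelineResult(config, cycle, outputs)
    cut = MarkerTrajectorySet(
        list(smoothed.names), smoothed.positions_mm[sl], smoothed.rate_hz, smoothed.visible[sl]
    )
    ik = inverse_kinematics(model, cut)
    if not ik.converged.all():
        bad = int(np.argmin(ik.converged))
        raise PipelineError(f"ik: optimizer failed at frame {bad}")
    q = ik.coordinates

    # ---- residual reduction (optional) ----
    if config.run_rra:
        model, q, rra_report = reduce_residuals(
            model, q, times, grf, smoothed.rate_hz, config.filter_cutoff_hz
        )
        outputs["rra_report.json"] = str(out / "rra_report.json")
        (out / "rra_report.json").write_text(json.dumps({
            "com_shift_m": list(rra_report.com_shift_m),
            "rms_before_nm": rra_report.rms_before_nm,
            "rms_after_nm": rra_report.rms_after_nm,
            "applied": rra_report.applied,
            "flagged": rra_report.flagged,
        }, indent=2))
    else:
        q = butterworth_lowpass(q, config.filter_cutoff_hz, smoothed.rate_hz)

    # ---- angles (model-predicted, via virtual markers) ----
    virt_mm = np.array([model.marker_positions(qf) for qf in q]) * 1e3
    virt = MarkerTrajectorySet(list(model.markers), virt_mm, smoothed.rate_hz)
    model_angles = joint_angles(virt, times=times)
    pct = np.linspace(0.0, 100.0, config.cycle_points)
    ang = {
        f"{j}_deg": resample_cycle(model_angles.angles_deg[j], config.cycle_points)
        for j in ("hip", "stifle", "tarsus")
    }
    vel = {
        f"{j}_deg_s": resample_cycle(model_angles.velocities_deg_s[j], config.cycle_points)
        for j in ("hip", "stifle", "tarsus")
    }
    emit("angles.csv", pd.DataFrame({"pct_cycle": pct, **ang, **vel}))
    coords_df = pd.DataFrame(q, columns=model.coordinate_names)
    coords_df.insert(0, "time", times)
    write_mot(out / "coordinates.mot", coords_df, name="ik coordinates", in_degrees=False)
    outputs["coordinates.mot"] = str(out / "coordinates.mot")

    # ---- inverse dynamics ----
    moments, residuals = inverse_dynamics(model, q, times, grf)
    mom100 = {k: resample_cycle(v, config.cycle_points) for k, v in moments.moments.items()}
    emit("moments.csv", pd.DataFrame({"pct_cycle": pct, **mom100}))
    emit("residuals.csv", pd.DataFrame({
        "time": times,
        "force_x_n": residuals.residual_force_n[:, 0],
        "force_y_n": residuals.residual_force_n[:, 1],
        "force_z_n": residuals.residual_force_n[:, 2],
        "moment_x_nm": residuals.residual_moment_nm[:, 0],
        "moment_y_nm": residuals.residual_moment_nm[:, 1],
        "moment_z_nm": residuals.residual_moment_nm[:, 2],
    }))

    # joint power from the generalized velocities
    qdot_deg = np.degrees(np.gradient(q, times, axis=0))
    vel_map = {n: qdot_deg[:, i] for i, n in enumerate(model.coordinate_names)}
    power = joint_power(moments, vel_map)
    pow100 = {k: resample_cycle(v, config.cycle_points) for k, v in power.power_w.items()}
    emit("power.csv", pd.DataFrame({"pct_cycle": pct, **pow100}))

    # ---- static optimization ----
    if config.run_so:
        for m in model.muscles:
            m.specific_tension = config.specific_tension
        tuning = tune_fiber_operating_range(model, q, stance_fraction=cycle.stance_fraction)
        emit("fiber_tuning.csv", pd.DataFrame([asdict(r) for r in tuning.rows]))
        dofs = _sagittal_dofs(model)
        states = compute_muscle_states(model, q, times, dofs)
        sol = static_optimization(moments, model, states)
        act = pd.DataFrame(
            resample_cycle(sol.activations, config.cycle_points), columns=sol.muscle_names
        )
        act.insert(0, "pct_cycle", pct)
        emit("activations.csv", act)
        forces = pd.DataFrame(
            resample_cycle(sol.forces_n, config.cycle_points), columns=sol.muscle_names
        )
        forces.insert(0, "pct_cycle", pct)
        emit("forces.csv", forces)
        peaks = summarize_peaks(sol, cycle.stance_fraction)
        emit("peaks.csv", peaks.table)

    # ---- validation: model-predicted vs marker-derived angles ----
    validation: list[ValidationResult] = []
    if config.run_validate:
        exp_angles = joint_angles(cut, times=times)
        for j in ("hip", "stifle", "tarsus"):
            pair = CurvePair(
                resample_cycle(model_angles.angles_deg[j], config.cycle_points),
                resample_cycle(exp_angles.angles_deg[j], config.cycle_points),
            )
            res = validity_check(pair, name=j)
            res.r_threshold = config.r_threshold
            res.sigma_fraction = config.sigma_fraction
            validation.append(res)
        report = validation_report(validation)
        (out / "validation.txt").write_text(report + "\n")
        outputs["validation.txt"] = str(out / "validation.txt")
        emit("validation.csv", pd.DataFrame([
            {"joint": v.name, "r": v.r, "sigma_e": v.sigma_e,
             "sigma_threshold": v.sigma_threshold, "passes": v.passes}
            for v in validation
        ]))

    # ---- provenance ----
    prov = {
        "caninegait_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "config": asdict(config),
        "cycle": {"start_frame": cycle.start_frame, "end_frame": cycle.end_frame,
                  "stance_fraction": cycle.stance_fraction},
    }
    (out / "provenance.json").write_text(json.dumps(prov, indent=2))
    outputs["provenance.json"] = str(out / "provenance.json")
    return PipelineResult(config, cycle, outputs, validation)
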