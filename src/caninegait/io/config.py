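"""YAML model configuration: documented schema, validated loader.

Schema (top-level keys)
-----------------------
``caninegait_model``  schema version, currently 1 (required)
``torso_segment``     name of the torso point-mass segment (optional)
``segments``          mapping name -> {``mass_kg`` OR ``tissue_counts``
                      [N_cortical, N_trabecular, N_muscle, N_fat],
                      ``com_m`` [3], ``inertia_com`` [3×3]}
``tissue_table``      {``pixel_size_mm``, ``slice_thickness_mm``,
                      ``densities_g_cm3`` [4]} — required when any segment
                      uses ``tissue_counts``
``joints``            list of {``name``, ``type`` (free/ball/sliding_hinge/
                      hinge/fixed), ``parent`` (null for the root),
                      ``child``, ``location_in_parent_m`` [3],
                      ``neutral_rotation`` [3×3] or ``neutral_tilt_deg``,
                      optional ``coupling_knots`` [[flexion_rad, tx_m,
                      ty_m], ...] for the sliding hinge}
``markers``           mapping name -> {``segment``, ``location_m`` [3]}
``muscles``           list of {``name``, ``volume_cm3``, ``pennation_deg``,
                      ``optimal_fiber_length_cm``,
                      ``tendon_slack_length_cm``, optional
                      ``specific_tension``, ``path`` [{``segment``,
                      ``point_m`` [3]}, ...]}
``landmarks``         optional mapping name -> [x, y, z] (mm), carried as
                      metadata for anatomical-frame construction
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import yaml

from ..model import BodySegment, JointDefinition, MusculoskeletalModel, rot_z
from ..morphometry import DEFAULT_DENSITIES, TissueVolumeTable, compute_segment_mass
from ..muscles import SPECIFIC_TENSION, MuscleParameters


class ConfigError(ValueError):
    pass


def _require(mapping: dict, key: str, ctx: str):
    if key not in mapping:
        raise ConfigError(f"{ctx}: missing required key {key!r}")
    return mapping[key]


def save_model(path: str | Path, model: MusculoskeletalModel) -> None:
    doc: dict = {"caninegait_model": 1, "torso_segment": model.torso_segment}
    doc["segments"] = {
        s.name: {
            "mass_kg": float(s.mass_kg),
            "com_m": [float(v) for v in s.com_local_m],
            "inertia_com": [[float(v) for v in row] for row in s.inertia_com],
        }
        for s in model.segments.values()
    }
    doc["joints"] = [
        {
            "name": j.name,
            "type": j.joint_type,
            "parent": j.parent,
            "child": j.child,
            "location_in_parent_m": [float(v) for v in j.location_in_parent_m],
            "neutral_rotation": [[float(v) for v in row] for row in j.neutral_rotation],
            **(
                {"coupling_knots": [[float(v) for v in row] for row in j.coupling_knots]}
                if j.coupling_knots is not None
                else {}
            ),
        }
        for j in model.joints
    ]
    doc["markers"] = {
        name: {"segment": seg, "location_m": [float(v) for v in loc]}
        for name, (seg, loc) in model.markers.items()
    }
    doc["muscles"] = [
        {
            "name": m.name,
            "volume_cm3": float(m.volume_cm3),
            "pennation_deg": float(m.pennation_deg),
            "optimal_fiber_length_cm": float(m.fiber_length_cm),
            "tendon_slack_length_cm": float(m.tendon_slack_cm),
            "specific_tension": float(m.specific_tension),
            "path": [
                {"segment": seg, "point_m": [float(v) for v in pt]} for seg, pt in m.path
            ],
        }
        for m in model.muscles
    ]
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_model(path: str | Path) -> MusculoskeletalModel:
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict) or doc.get("caninegait_model") != 1:
        raise ConfigError(f"{path}: not a caninegait model config (schema version 1)")

    tissue = None
    if "tissue_table" in doc:
        tt = doc["tissue_table"]
        tissue_kwargs = {
            "pixel_size_mm": float(tt.get("pixel_size_mm", 0.325)),
            "slice_thickness_mm": float(tt.get("slice_thickness_mm", 1.0)),
            "densities_g_cm3": tuple(tt.get("densities_g_cm3", DEFAULT_DENSITIES)),
        }
    segments: dict[str, BodySegment] = {}
    for name, spec in _require(doc, "segments", str(path)).items():
        ctx = f"segment {name!r}"
        if "mass_kg" in spec:
            mass = float(spec["mass_kg"])
        elif "tissue_counts" in spec:
            if "tissue_table" not in doc:
                raise ConfigError(f"{ctx}: tissue_counts given but no tissue_table")
            counts = tuple(int(v) for v in spec["tissue_counts"])
            tab = TissueVolumeTable({name: counts}, **tissue_kwargs)
            mass = compute_segment_mass(tab, name)
        else:
            raise ConfigError(f"{ctx}: needs mass_kg or tissue_counts")
        segments[name] = BodySegment(
            name,
            mass,
            np.array(_require(spec, "com_m", ctx), dtype=float),
            np.array(_require(spec, "inertia_com", ctx), dtype=float),
        )

    joints = []
    for j in _require(doc, "joints", str(path)):
        ctx = f"joint {j.get('name', '?')!r}"
        if "neutral_rotation" in j:
            rot = np.array(j["neutral_rotation"], dtype=float)
        elif "neutral_tilt_deg" in j:
            rot = rot_z(math.radians(float(j["neutral_tilt_deg"])))
        else:
            rot = np.eye(3)
        joints.append(
            JointDefinition(
                _require(j, "name", ctx),
                _require(j, "type", ctx),
                j.get("parent"),
                _require(j, "child", ctx),
                np.array(_require(j, "location_in_parent_m", ctx), dtype=float),
                rot,
                np.array(j["coupling_knots"], dtype=float) if "coupling_knots" in j else None,
            )
        )

    markers = {
        name: (spec["segment"], np.array(spec["location_m"], dtype=float))
        for name, spec in doc.get("markers", {}).items()
    }
    muscles = []
    for m in doc.get("muscles", []):
        ctx = f"muscle {m.get('name', '?')!r}"
        muscles.append(
            MuscleParameters(
                name=_require(m, "name", ctx),
                volume_cm3=float(_require(m, "volume_cm3", ctx)),
                pennation_deg=float(_require(m, "pennation_deg", ctx)),
                fiber_length_cm=float(_require(m, "optimal_fiber_length_cm", ctx)),
                tendon_slack_cm=float(_require(m, "tendon_slack_length_cm", ctx)),
                specific_tension=float(m.get("specific_tension", SPECIFIC_TENSION)),
                path=[
                    (p["segment"], np.array(p["point_m"], dtype=float)) for p in m.get("path", [])
                ],
            )
        )
    return MusculoskeletalModel(segments, joints, markers, muscles,
                                torso_segment=doc.get("torso_segment"))
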