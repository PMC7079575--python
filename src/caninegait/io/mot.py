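"""MOT time-series files (OpenSim-style tab-separated with ``endheader``),
used for joint angles and for force-plate channels.

Ground-reaction columns per plate are prefixed with the paw segment name:
``<segment>_force_vx/vy/vz`` (N), ``<segment>_torque_y`` (N·m) and
``<segment>_force_px/py/pz`` (COP, m).  Unloaded frames carry zero force and
NaN COP.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from ..dynamics import GroundReaction, PlateData


def write_mot(path: str | Path, df: pd.DataFrame, name: str = "caninegait",
              in_degrees: bool = True) -> None:
    if "time" not in df.columns:
        raise ValueError("MOT data needs a 'time' column")
    path = Path(path)
    header = [
        name,
        "version=1",
        f"nRows={len(df)}",
        f"nColumns={len(df.columns)}",
        f"inDegrees={'yes' if in_degrees else 'no'}",
        "endheader",
    ]
    body = df.to_csv(sep="\t", index=False, float_format="%.8f", na_rep="nan")
    path.write_text("\n".join(header) + "\n" + body)


def read_mot(path: str | Path) -> pd.DataFrame:
    lines = Path(path).read_text().splitlines()
    try:
        start = next(i for i, ln in enumerate(lines) if ln.strip().lower() == "endheader") + 1
    except StopIteration:
        raise ValueError(f"{path}: no 'endheader' line; not a MOT file") from None
    from io import StringIO

    return pd.read_csv(StringIO("\n".join(lines[start:])), sep="\t")


def grf_to_mot(path: str | Path, grf: GroundReaction) -> None:
    frames = {}
    time = None
    for plate in grf.plates:
        if time is None:
            time = plate.time_s
        elif len(time) != len(plate.time_s) or not np.allclose(time, plate.time_s):
            raise ValueError("all plates must share one time base for MOT export")
        p = plate.segment
        frames[f"{p}_force_vx"] = plate.force_n[:, 0]
        frames[f"{p}_force_vy"] = plate.force_n[:, 1]
        frames[f"{p}_force_vz"] = plate.force_n[:, 2]
        frames[f"{p}_torque_y"] = plate.torque_z_nm
        frames[f"{p}_force_px"] = plate.cop_m[:, 0]
        frames[f"{p}_force_py"] = plate.cop_m[:, 1]
        frames[f"{p}_force_pz"] = plate.cop_m[:, 2]
    df = pd.DataFrame({"time": time, **frames})
    write_mot(path, df, name="ground reactions", in_degrees=False)


def grf_from_mot(path: str | Path) -> GroundReaction:
    df = read_mot(path)
    time = df["time"].to_numpy()
    segments = sorted({c[: -len("_force_vx")] for c in df.columns if c.endswith("_force_vx")})
    if not segments:
        raise ValueError(f"{path}: no '<segment>_force_vx' columns found")
    plates = []
    for seg in segments:
        force = df[[f"{seg}_force_vx", f"{seg}_force_vy", f"{seg}_force_vz"]].to_numpy()
        torque = df[f"{seg}_torque_y"].to_numpy()
        cop = df[[f"{seg}_force_px", f"{seg}_force_py", f"{seg}_force_pz"]].to_numpy()
        plates.append(PlateData(seg, time, force, torque, cop))
    return GroundReaction(plates)
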