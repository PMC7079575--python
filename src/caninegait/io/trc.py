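"""TRC marker-trajectory files (tab-separated, mm, standard motion-capture
header).  Invisible samples are written as empty fields and read back as
flagged gaps, never as silent zeros."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from ..kinematics import MarkerTrajectorySet


def write_trc(path: str | Path, traj: MarkerTrajectorySet, units: str = "mm") -> None:
    path = Path(path)
    n_frames, n_markers = traj.positions_mm.shape[:2]
    rate = traj.rate_hz
    lines = [
        f"PathFileType\t4\t(X/Y/Z)\t{path.name}",
        "DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\tOrigDataRate\t"
        "OrigDataStartFrame\tOrigNumFrames",
        f"{rate:g}\t{rate:g}\t{n_frames}\t{n_markers}\t{units}\t{rate:g}\t1\t{n_frames}",
    ]
    head = ["Frame#", "Time"]
    for name in traj.names:
        head += [name, "", ""]
    lines.append("\t".join(head))
    sub = ["", ""]
    for i in range(1, n_markers + 1):
        sub += [f"X{i}", f"Y{i}", f"Z{i}"]
    lines.append("\t".join(sub))
    lines.append("")
    for f in range(n_frames):
        row = [str(f + 1), f"{f / rate:.5f}"]
        for m in range(n_markers):
            if traj.visible[f, m]:
                row += [f"{v:.5f}" for v in traj.positions_mm[f, m]]
            else:
                row += ["", "", ""]
        lines.append("\t".join(row))
    path.write_text("\n".join(lines) + "\n")


def read_trc(path: str | Path) -> MarkerTrajectorySet:
    text = Path(path).read_text().splitlines()
    if len(text) < 6:
        raise ValueError(f"{path}: not a TRC file (too short)")
    meta = text[2].split("\t")
    rate = float(meta[0])
    n_markers = int(meta[3])
    units = meta[4].strip().lower()
    scale = {"mm": 1.0, "m": 1000.0, "cm": 10.0}.get(units)
    if scale is None:
        raise ValueError(f"{path}: unsupported units {units!r}")
    header = text[3].split("\t")
    names = [h for h in header[2:] if h.strip()]
    if len(names) != n_markers:
        raise ValueError(f"{path}: header names ({len(names)}) != NumMarkers ({n_markers})")
    rows = [ln.split("\t") for ln in text[5:] if ln.strip()]
    n_frames = len(rows)
    pos = np.zeros((n_frames, n_markers, 3))
    vis = np.ones((n_frames, n_markers), dtype=bool)
    for f, row in enumerate(rows):
        vals = row[2:]
        for m in range(n_markers):
            cell = vals[3 * m : 3 * m + 3]
            if len(cell) < 3 or any(c.strip() == "" for c in cell):
                vis[f, m] = False
            else:
                pos[f, m] = [float(c) * scale for c in cell]
    return MarkerTrajectorySet(names, pos, rate, vis)
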