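"""Anatomical segment coordinate systems from bony landmarks.

Each segment frame is built from named landmarks: x points cranially,
y along the proximal–distal axis, and z completes the right-handed triad
(z = x × y, except the phalanges where z is the metatarsal axis and
x = y × z).  Left- and right-side frames use mirrored condylar/malleolar
orderings so both sides share the same clinical sign conventions.

Landmark abbreviations
----------------------
RIC/LIC   right/left cranial dorsal iliac crest
RIT       right ischiatic tuberosity
CFH       centre of the femoral head
LFC/MFC   lateral/medial femoral condyle
MPTC      midpoint of the proximal tibial condyles
MPM       midpoint of the malleoli
LM/MM     lateral/medial malleolus
2MT/5MT   heads of the 2nd/5th metatarsals
MP25P/MP25D  midpoint of 2nd & 5th metatarsals, proximal/distal
PCOM      phalanges centre of mass
MPMT      midpoint of the metatarsals (left phalanges origin)
COM       segment centre of mass (pelvis origin)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_TOL = 1e-12


class DegenerateFrameError(ValueError):
    """Raised when landmarks are collinear/coincident and no frame exists."""


LandmarkSet = dict[str, np.ndarray]
"""Named 3-D landmark points in mm."""


@dataclass
class SegmentFrame:
    """Origin (mm) and orthonormal right-handed axis matrix.

    ``axes`` columns are the x, y, z unit vectors expressed in the parent
    (global) frame, so ``axes @ v_local + origin`` maps local to global.
    """

    origin: np.ndarray
    axes: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.axes = np.asarray(self.axes, dtype=float)
        if not np.allclose(self.axes.T @ self.axes, np.eye(3), atol=1e-9):
            raise DegenerateFrameError("axes are not orthonormal")
        if np.dot(np.cross(self.axes[:, 0], self.axes[:, 1]), self.axes[:, 2]) < 0:
            raise DegenerateFrameError("axes are not right-handed")

    @property
    def x(self) -> np.ndarray:
        return self.axes[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.axes[:, 1]

    @property
    def z(self) -> np.ndarray:
        return self.axes[:, 2]


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < _TOL:
        raise DegenerateFrameError("zero-length axis vector (collinear or coincident landmarks)")
    return v / n


def _get(landmarks: LandmarkSet, *names: str) -> list[np.ndarray]:
    out = []
    for name in names:
        if name not in landmarks:
            raise KeyError(f"missing landmark {name!r}")
        p = np.asarray(landmarks[name], dtype=float)
        if not np.all(np.isfinite(p)):
            raise ValueError(f"landmark {name!r} is not finite")
        out.append(p)
    return out


def build_coordinate_system(
    landmarks: LandmarkSet, segment: str, side: str = "right"
) -> SegmentFrame:
    """Anatomical frame for ``segment`` ('pelvis', 'femur', 'tibia', 'tarsus',
    'phalanges') on ``side`` ('left'/'right').

    The pelvis frame is side-independent.  Condyle/malleolus/metatarsal
    orderings flip between sides so the z-axis keeps a consistent
    flexion-extension sense; the left phalanges origin sits at the
    metatarsal midpoint rather than MP25D.
    """
    if side not in ("left", "right"):
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    right = side == "right"
    seg = segment.lower()

    if seg == "pelvis":
        com, ric, rit, lic = _get(landmarks, "COM", "RIC", "RIT", "LIC")
        x = _unit(ric - rit)
        y = _unit(np.cross(x, ric - lic))
        z = np.cross(x, y)
        return SegmentFrame(com, np.column_stack([x, y, z]))

    if seg == "femur":
        cfh, lfc, mfc = _get(landmarks, "CFH", "LFC", "MFC")
        y = _unit(cfh - mfc)
        condylar = (lfc - mfc) if right else (mfc - lfc)
        x = _unit(np.cross(y, condylar))
        z = np.cross(x, y)
        return SegmentFrame(cfh, np.column_stack([x, y, z]))

    if seg == "tibia":
        mptc, mpm, lm, mm = _get(landmarks, "MPTC", "MPM", "LM", "MM")
        y = _unit(mptc - mpm)
        malleolar = (lm - mm) if right else (mm - lm)
        x = _unit(np.cross(y, malleolar))
        z = np.cross(x, y)
        return SegmentFrame(mptc, np.column_stack([x, y, z]))

    if seg == "tarsus":
        mpm, mp25p, mp25d, mt5, mt2 = _get(landmarks, "MPM", "MP25P", "MP25D", "5MT", "2MT")
        y = _unit(mp25p - mp25d)
        metatarsal = (mt5 - mt2) if right else (mt2 - mt5)
        x = _unit(np.cross(y, metatarsal))
        z = np.cross(x, y)
        return SegmentFrame(mpm, np.column_stack([x, y, z]))

    if seg == "phalanges":
        mp25d, pcom, mt5, mt2 = _get(landmarks, "MP25D", "PCOM", "5MT", "2MT")
        z = _unit((mt5 - mt2) if right else (mt2 - mt5))
        y = _unit(np.cross(mp25d - pcom, z))
        x = np.cross(y, z)
        # Table-of-record asymmetry: the left phalanges origin is the
        # metatarsal midpoint (MPMT), the right is MP25D.
        origin = mp25d if right else _get(landmarks, "MPMT")[0]
        return SegmentFrame(origin, np.column_stack([x, y, z]))

    raise ValueError(f"unknown segment {segment!r}")
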