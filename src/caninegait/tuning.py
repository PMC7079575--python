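"""Fiber operating-range tuning.

Optimal fiber length and tendon slack length are iteratively rescaled so
that each muscle's normalized fiber length (instantaneous fiber length over
optimal fiber length, rigid tendon) stays between 0.8 and 1.2 at mid-stance
and between 0.5 and 1.5 throughout the whole gait cycle.  The update is a
damped multiplicative rescale of the fiber length toward a mid-stance
normalized length of 1, with the tendon slack length re-split so that fiber
(projected through pennation) plus tendon continue to add up to the
mid-stance MTU length.  Muscles that cannot satisfy both bands within the
iteration budget are flagged, never silently accepted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model import MusculoskeletalModel

MID_STANCE_BAND = (0.8, 1.2)
CYCLE_BAND = (0.5, 1.5)


@dataclass
class TuningRow:
    muscle: str
    min_norm: float
    max_norm: float
    mid_norm: float
    changed: bool
    converged: bool
    iterations: int


@dataclass
class TuningReport:
    rows: list[TuningRow]

    @property
    def all_in_cycle_band(self) -> bool:
        return all(
            CYCLE_BAND[0] <= r.min_norm and r.max_norm <= CYCLE_BAND[1] for r in self.rows
        )

    @property
    def flagged(self) -> list[str]:
        return [r.muscle for r in self.rows if not r.converged]


def tune_fiber_operating_range(
    model: MusculoskeletalModel,
    q_cycle: np.ndarray,
    stance_fraction: float = 0.6,
    mid_band: tuple[float, float] = MID_STANCE_BAND,
    cycle_band: tuple[float, float] = CYCLE_BAND,
    damping: float = 0.5,
    max_iter: int = 50,
) -> TuningReport:
    """Tune the model's muscle fiber/tendon lengths in place over a cycle.

    ``q_cycle`` is a frames × n_coords pose history covering one gait
    cycle; mid-stance is taken at ``stance_fraction / 2`` through it.
    """
    q_cycle = np.asarray(q_cycle, dtype=float)
    mtu = np.array([model.all_mtu_lengths(q) for q in q_cycle])  # frames × muscles
    mid = int(round(stance_fraction / 2 * (len(q_cycle) - 1)))
    rows = []
    for j, m in enumerate(model.muscles):
        cosa = max(math.cos(m.pennation_rad), 1e-6)
        series = mtu[:, j]
        mtu_mid = series[mid]
        f, tsl = m.fiber_length_cm, m.tendon_slack_cm
        changed = False
        converged = False
        it = 0

        def norms(f_: float, tsl_: float) -> np.ndarray:
            return ((series - tsl_) / cosa) / f_

        band_width = cycle_band[1] - cycle_band[0]
        for it in range(1, max_iter + 1):
            n = norms(f, tsl)
            n_mid = float(n[mid])
            if (
                mid_band[0] <= n_mid <= mid_band[1]
                and cycle_band[0] <= n.min()
                and n.max() <= cycle_band[1]
            ):
                converged = True
                break
            # two pulls, damped and multiplicative: recentre the mid-stance
            # norm toward 1, and grow the fiber until the cycle excursions
            # above/below the mid-stance norm fit their half of the band
            # (15% margin keeps norms off the band edges, where the passive
            # curve is steep)
            up_ratio = float(n.max() - n_mid) / (cycle_band[1] - 1.0)
            down_ratio = float(n_mid - n.min()) / (1.0 - cycle_band[0])
            factor = max(n_mid, 1.15 * up_ratio, 1.15 * down_ratio, 1e-3)
            f_new = f * factor**damping
            tsl_new = max(mtu_mid - f_new * cosa, 0.0)
            f_new = (mtu_mid - tsl_new) / cosa if tsl_new == 0.0 else f_new
            if abs(f_new - f) < 1e-12:
                break
            f, tsl = f_new, tsl_new
            changed = True
        n = norms(f, tsl)
        if changed:
            m.fiber_length_cm, m.tendon_slack_cm = f, tsl
        rows.append(
            TuningRow(m.name, float(n.min()), float(n.max()), float(n[mid]),
                      changed, converged, it)
        )
    return TuningReport(rows)
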