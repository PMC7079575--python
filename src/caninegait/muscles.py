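"""Musculotendon parameters: scaling, mid-stance adjustment, and maximum
isometric force.

Literature fiber and tendon-slack lengths are scaled to the subject by the
ratio of subject to reference bony-segment length, then re-split so that
optimal fiber length plus tendon slack length equals the musculotendon (MTU)
length measured at mid-stance, preserving their relative proportions.
Maximum isometric force follows the PCSA formulation

    F_iso = T · Vol · cos(α) / f

with specific tension T (22.5 N/cm² for mammalian muscle), muscle volume
Vol, pennation angle α and optimal fiber length f.  The pennation factor is
applied as a cosine: the cosine projects fiber force onto the tendon line of
action and is the only form consistent with the packaged parameter roster
(see docs/methods.md).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

#: Specific tension of mammalian skeletal muscle, N/cm².
SPECIFIC_TENSION = 22.5


class MuscleParameterError(ValueError):
    """Invalid musculotendon parameter input."""


@dataclass
class MuscleParameters:
    """Architectural parameters of one musculotendon actuator.

    Lengths in cm, volume in cm³, pennation in degrees, force in N.
    ``path`` holds the ordered line-of-action points as
    ``(segment_name, local_point_m)`` tuples when the muscle is attached to
    a model; it may be empty for a bare parameter record.
    """

    name: str
    volume_cm3: float
    pennation_deg: float
    fiber_length_cm: float
    tendon_slack_cm: float
    specific_tension: float = SPECIFIC_TENSION
    path: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.volume_cm3 < 0:
            raise MuscleParameterError(f"{self.name}: volume must be >= 0")
        if not 0 <= self.pennation_deg < 90:
            raise MuscleParameterError(f"{self.name}: pennation must be in [0, 90) deg")
        if self.fiber_length_cm < 0 or self.tendon_slack_cm < 0:
            raise MuscleParameterError(f"{self.name}: lengths must be >= 0")

    @property
    def pennation_rad(self) -> float:
        return math.radians(self.pennation_deg)

    def max_isometric_force(self) -> float:
        return max_isometric_force(
            self.volume_cm3, self.pennation_deg, self.fiber_length_cm, self.specific_tension
        )


def scale_fiber_length(f_ref: float, l: float, l_ref: float) -> float:
    """Subject optimal fiber length from the literature value, scaled by the
    subject/reference bony segment length ratio: f = f_ref · l / l_ref."""
    if l_ref <= 0:
        raise MuscleParameterError("reference segment length must be > 0")
    return f_ref * l / l_ref


def scale_tendon_slack(tsl_ref: float, l: float, l_ref: float) -> float:
    """Subject tendon slack length, scaled like the fiber length."""
    if l_ref <= 0:
        raise MuscleParameterError("reference segment length must be > 0")
    return tsl_ref * l / l_ref


def adjust_fiber_and_tendon(
    f: float, tsl: float, mtu_midstance: float
) -> tuple[float, float]:
    """Redistribute the mid-stance MTU length over fiber and tendon.

    Both lengths absorb the mismatch ``MTU − f − TSL`` in proportion to
    their share of ``f + TSL``:

        f_adj   = (MTU − f − TSL) · f   / (f + TSL) + f
        TSL_adj = (MTU − f − TSL) · TSL / (f + TSL) + TSL

    By construction f_adj + TSL_adj = MTU and f_adj/TSL_adj = f/TSL.
    """
    if f + tsl <= 0:
        raise MuscleParameterError("f + TSL must be > 0")
    if mtu_midstance <= 0:
        raise MuscleParameterError("mid-stance MTU length must be > 0")
    gap = mtu_midstance - f - tsl
    f_adj = gap * f / (f + tsl) + f
    tsl_adj = gap * tsl / (f + tsl) + tsl
    return f_adj, tsl_adj


def max_isometric_force(
    volume_cm3: float,
    pennation_deg: float,
    fiber_length_cm: float,
    specific_tension: float = SPECIFIC_TENSION,
) -> float:
    """Maximum isometric force F_iso = T · Vol · cos(α) / f  (N)."""
    if fiber_length_cm <= 0:
        raise MuscleParameterError("fiber length must be > 0")
    if volume_cm3 < 0:
        raise MuscleParameterError("volume must be >= 0")
    return specific_tension * volume_cm3 * math.cos(math.radians(pennation_deg)) / fiber_length_cm


def load_muscle_roster() -> pd.DataFrame:
    """The packaged pelvic-limb muscle parameter table (33 musculotendon
    actuators; volumes, pennation angles, optimal fiber lengths, tendon
    slack lengths and the tabulated maximum isometric forces)."""
    with resources.files("caninegait.data").joinpath("table2_muscles.csv").open() as fh:
        return pd.read_csv(fh)


def roster_parameters(specific_tension: float = SPECIFIC_TENSION) -> list[MuscleParameters]:
    """The packaged roster as :class:`MuscleParameters` records."""
    df = load_muscle_roster()
    return [
        MuscleParameters(
            name=row.muscle,
            volume_cm3=row.volume_cm3,
            pennation_deg=row.pennation_deg,
            fiber_length_cm=row.optimal_fiber_length_cm,
            tendon_slack_cm=row.tendon_slack_length_cm,
            specific_tension=specific_tension,
        )
        for row in df.itertuples()
    ]
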