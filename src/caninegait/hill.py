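"""Hill-type musculotendon mechanics with a rigid tendon.

Force factors are dimensionless multipliers of the maximum isometric force:

* active force–length: Gaussian bump peaking at 1 at normalized fiber
  length 1, width parameter 0.45;
* passive force–length: exponential toe region engaging above optimal
  length, reaching 1 F_iso at strain 0.6;
* force–velocity: classic Hill hyperbola on the concentric side
  (zero force at the maximum shortening velocity, default 10 optimal fiber
  lengths/s), with an eccentric plateau capped at 1.4.

With a rigid tendon the fiber length follows directly from the MTU length
(fiber·cosα = MTU − TSL), so tendon force is affine in activation — which
keeps per-frame static optimization a convex problem.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .muscles import MuscleParameters


@dataclass
class HillCurves:
    """Parameterized force–length–velocity curves."""

    active_width: float = 0.45
    passive_strain_at_fiso: float = 0.6
    passive_exponent: float = 4.0
    fv_shape: float = 0.25          # Hill a/F_iso parameter
    eccentric_plateau: float = 1.4
    max_contraction_velocity: float = 10.0  # optimal fiber lengths / s

    def active_fl(self, lnorm):
        """Active force–length factor; 1 at optimal length."""
        lnorm = np.asarray(lnorm, dtype=float)
        return np.exp(-(((lnorm - 1.0) / self.active_width) ** 2))

    def passive_fl(self, lnorm):
        """Passive force–length factor; 0 at/below optimal length."""
        lnorm = np.asarray(lnorm, dtype=float)
        strain = np.clip(lnorm - 1.0, 0.0, None) / self.passive_strain_at_fiso
        k = self.passive_exponent
        return (np.expm1(k * strain)) / math.expm1(k)

    def fv(self, vnorm):
        """Force–velocity factor; ``vnorm`` is fiber velocity in optimal
        fiber lengths/s, negative = shortening.  1 at zero velocity."""
        vnorm = np.asarray(vnorm, dtype=float)
        vmax = self.max_contraction_velocity
        a = self.fv_shape
        v = np.clip(vnorm / vmax, -1.0, None)  # normalized to [-1, inf)
        v_c = np.minimum(v, 0.0)
        conc = (1.0 + v_c) / (1.0 - v_c / a)
        # eccentric branch: rises from 1 toward the plateau
        v_e = np.maximum(v, 0.0)
        ecc = 1.0 + (self.eccentric_plateau - 1.0) * v_e / (v_e + a / 2.0 + 1e-12)
        out = np.where(v < 0, conc, ecc)
        return np.clip(out, 0.0, self.eccentric_plateau)


def rigid_tendon_fiber_length(
    mtu_cm, params: MuscleParameters, clamp: tuple[float, float] = (0.01, 2.5)
):
    """Normalized fiber length under the rigid-tendon assumption:
    fiber = (MTU − TSL) / cos α, clamped to the curve support."""
    mtu_cm = np.asarray(mtu_cm, dtype=float)
    fiber = (mtu_cm - params.tendon_slack_cm) / max(math.cos(params.pennation_rad), 1e-6)
    if params.fiber_length_cm <= 0:
        raise ValueError(f"{params.name}: optimal fiber length must be > 0")
    return np.clip(fiber / params.fiber_length_cm, *clamp)


def tendon_force(
    activation,
    normalized_fiber_length,
    fiber_velocity_norm,
    params: MuscleParameters,
    curves: HillCurves | None = None,
):
    """Tendon force (N): F_iso · [a·fl(ℓ̃)·fv(ṽ) + fp(ℓ̃)] · cos α."""
    curves = curves or HillCurves()
    a = np.clip(np.asarray(activation, dtype=float), 0.0, 1.0)
    lnorm = np.asarray(normalized_fiber_length, dtype=float)
    fiso = params.max_isometric_force()
    cosa = math.cos(params.pennation_rad)
    active = curves.active_fl(lnorm) * curves.fv(fiber_velocity_norm)
    return fiso * (a * active + curves.passive_fl(lnorm)) * cosa


def force_coefficients(
    params: MuscleParameters,
    normalized_fiber_length,
    fiber_velocity_norm,
    curves: HillCurves | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """(gain, offset) such that tendon force = gain·a + offset at this state."""
    curves = curves or HillCurves()
    fiso = params.max_isometric_force()
    cosa = math.cos(params.pennation_rad)
    lnorm = np.asarray(normalized_fiber_length, dtype=float)
    gain = fiso * curves.active_fl(lnorm) * curves.fv(fiber_velocity_norm) * cosa
    offset = fiso * curves.passive_fl(lnorm) * cosa
    return np.asarray(gain, dtype=float), np.asarray(offset, dtype=float)
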