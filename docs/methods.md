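# Methods

This note documents the models, numerical choices and limitations of
`caninegait` at the level a maintainer or reviewer needs. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Morphometry

Segment mass is a density-weighted voxel sum over four tissue classes,
`m = Σᵢ ρᵢ P² S Nᵢ`, with default densities 2.003 (cortical bone), 1.911
(trabecular bone), 1.06 (muscle) and 0.95 (fat) g/cm³ and CT geometry
P = 0.325 mm, S = 1 mm. Voxel counts are dimensionless; conversions
(mm³ → cm³, g → kg) happen inside the function, so morphometric inputs stay
in mm/g while everything downstream is SI.

Inertia tensors are computed by voxel-wise parallel-axis summation of
point-mass contributions about the cloud COM, optionally conjugated into
anatomical axes (`I' = RᵀIR`). The method reference behind the original
workflow publishes no formulas, so the voxel summation is this package's
own realization; it converges to closed forms as the grid refines (the test
suite checks a 50³ cuboid to < 2%).

The torso point mass equals half the total body mass minus all modeled
segments, representing the caudal abdominal mass carried by the pelvic
limbs under the assumption that body weight splits evenly between fore- and
hindquarters. A nonpositive torso is rejected rather than clamped.

## Anatomical frames

Segment frames follow the tabulated landmark recipes: x cranial, y
proximal–distal, z = x × y (phalanges use the metatarsal axis as z and
complete with x = y × z). Left-side rows flip the condylar / malleolar /
metatarsal orderings so both sides keep one flexion-extension sense; the
left phalanges origin is the metatarsal midpoint while the right is the
distal 2nd/5th-metatarsal midpoint — an asymmetry in the source table that
is reproduced verbatim rather than "fixed". Frames are validated to be
orthonormal (1e-9) and right-handed; collinear landmarks raise a
degenerate-frame error.

## Muscle parameters

Fiber and tendon-slack lengths scale with the subject/reference bony
segment length ratio, then both are re-split so that
`f_adj + TSL_adj = MTU(mid-stance)` while preserving their ratio — the
closure `f_adj + TSL_adj = MTU` is an algebraic identity and is enforced to
1e-10 in tests.

**Pennation convention.** The PCSA force rule is implemented as
`F_iso = T · Vol · cos(α) / f`. The cosine projects fiber force onto the
tendon line of action; it is the standard PCSA convention and the only form
consistent with the packaged parameter roster (21 of its 33 rows reproduce
the tabulated force to < 1% under the cosine; a sine form reproduces
essentially none). Two roster rows (rectus femoris, quadratus femoris) are
inconsistent with the rule under either convention and are carried with
their tabulated forces but excluded from reproduction checks.

**Operating-range tuning.** Normalized fiber length (rigid tendon:
`(MTU − TSL)/(f·cos α)`) must lie in [0.8, 1.2] at mid-stance and
[0.5, 1.5] over the cycle. The tuning loop applies a damped (exponent 0.5)
multiplicative rescale of f toward a mid-stance norm of 1, growing f when
the cycle excursion above/below the mid-stance norm would not fit its half
of the band (with a 15% margin keeping muscles off the band edges, where
the passive curve is steep), and re-splits TSL against the mid-stance MTU
each step. Up to 50 iterations; non-convergent muscles are flagged in the
report, never silently accepted.

## Kinematics

* Butterworth smoothing: 4th order, applied forward–backward (zero phase,
  effective 8th order), cutoff 6 Hz. The order is this package's choice;
  only the cutoff is inherited from the workflow being modeled.
* Gap filling: quintic splines over 3 support frames on each side; gaps of
  5+ frames or at the record boundary stay flagged and invalidate the
  trial.
* Gait-cycle segmentation: contact when vertical plate force exceeds 2% of
  body weight sustained for 50 ms (both thresholds are declared defaults,
  configurable); a cycle spans paw contact to the next ipsilateral contact.
* Joint angles are included angles (arccos, 0–180°) between the pelvis
  cranial axis and femur axis (hip), femur and tibia axes (stifle), tibia
  and tarsus axes (tarsus), built from the named lateral markers.
* Inverse kinematics: per-frame `scipy.optimize.least_squares` (TRF, 2-point
  Jacobian) over all generalized coordinates, residuals weighted per marker
  (default 1; a zero weight removes a corrupted marker exactly), each frame
  warm-started from the previous solution. Noise-free synthetic markers are
  recovered to < 0.1° and < 1e-6 mm RMS, making IK an exact inverse of the
  generator's forward kinematics.

## Dynamics

Accelerations come from central differences of the (6 Hz-filtered) pose
history: segment angular velocity from `Ṙ Rᵀ`, then one more gradient for
angular and linear accelerations. The Newton–Euler recursion runs leaf to
root; plate forces act at the COP of the plate's paw segment (COP
application is this package's decision; plate torque about vertical is
applied as given). The wrench required at the pelvis root is reported as
the 6-DOF residual series — it is never hidden, and the moment series is
flagged when it exceeds 2 N·m.

The residual-reduction pass is deliberately simplified relative to full
tracking-controller implementations: (1) re-filter the coordinates at 6 Hz,
(2) shift the torso COM horizontally (Nelder–Mead over x/z, bounded to
±30% of pelvis length; larger optima are flagged and not applied) to
minimize the residual-moment RMS. Zero shift is kept when no improvement
exists, so the RMS never increases. On dynamically consistent synthetic
data the recovered shift is ≈ 0, and a deliberately injected 10 mm torso
offset is recovered within ±2 mm (both are test assertions).

Joint power is the elementwise product of moment and angular velocity
(deg/s converted to rad/s); positive = generation.

## Hill model and static optimization

Rigid tendon throughout: fiber length follows algebraically from MTU
length, which keeps tendon force affine in activation and each frame's
optimization convex. Curve shapes (all configurable): Gaussian active
force–length with width 0.45; exponential passive engaging above optimal
length and reaching 1 F_iso at 60% strain (shape exponent 4); Hill
hyperbola force–velocity with a/F_iso = 0.25, max shortening velocity 10
fiber lengths/s, eccentric plateau capped at 1.4.

The per-frame problem — minimize `Σ aⱼ² + w_r Σ (reserveᵢ/1 N·m)²` subject
to moment balance and `0 ≤ a ≤ 1` — is solved by substituting the reserves
(the residual of each balance row) and calling `scipy.optimize.lsq_linear`
on the stacked system, which is exactly the KKT problem of the QP. The
reserve weight (1e8) makes reserves expensive relative to muscles; balance
holds by construction and the effective constraint violation is below
1e-6 N·m (asserted). Moment arms come from tendon excursion
(`r = −∂L/∂θ`, central difference, 0.1° step), which the tests pin against
perpendicular-distance geometry to < 0.5%.

An alternative min/max-stress objective is sometimes quoted for this class
of pipeline; the summed-squared-activation form is what is implemented, and
no claim is made about any external study's actual configuration.

## Synthetic gait generator

The generator defines the study conditions and is not a tuning knob:
5.4 kg dog, 0.6 m/s walk, 0.6 s cycle, 0.6 stance fraction, 100 Hz markers
with 2 mm isotropic Gaussian noise (seeded), vertical GRF first peak at 51%
BW at 16% of the cycle followed by a lower plateau peak, braking-to-
propulsion transition at 1/3 of stance, mediolateral amplitude 5% BW.
Segment lengths and masses are dachshund-proportioned (nine bony segments
summing to 0.89 kg at 5.4 kg body mass, so the torso closes to ≈1.8 kg);
muscle attachment coordinates are plausible anatomical positions chosen to
give each sagittal DOF both agonists and antagonists. Joint waveforms are
low-harmonic Fourier shapes with hip ≈ 25–30° and stifle ≈ 30° ROM —
qualitatively physiologic fixtures, not reproductions of any measured dog.

Two plate-force modes exist: the default **template** mode follows the
measured-GRF shape above (and therefore leaves genuine pelvis residuals,
as real data do); the **consistent** mode computes the plate wrench from
the inverse-dynamics closure of the generated kinematics, yielding
residuals at machine precision (up to the small moment component along the
force line, carried as vertical plate torque). Recovery fixtures
(residual reduction, bias linearity, energy bookkeeping) use the
consistent mode.

What passing tests show — and what they do not: recovery experiments prove
the pipeline inverts its own forward model under realistic noise; they do
not certify accuracy on real dogs, where soft-tissue artifact, marker
placement error, segment-parameter uncertainty and non-ideal force plates
all enter. The generator models none of those beyond isotropic marker
noise and optional injected defects (gaps, plate bias, COM offset).

## Problem sizes and determinism

Default trial: 70 frames (1.15 cycles) at 100 Hz, 20 markers, 16
generalized coordinates, 66 musculotendon actuators; analysis series are
resampled to the 100-point normalized cycle. The IK-recovery experiment
uses 20 seeds × 3 joints. Everything is deterministic given the spec seed;
the only random sources are marker noise and test-internal fixtures, all
seeded.

## Known limitations

* Muscle paths are via-point polylines; no analytic wrapping surfaces, so
  broad-attachment muscles are straight-line approximations.
* The stifle's coupled translations default to zero (pure hinge); knots
  must be supplied for a measured coupling.
* No activation dynamics, elastic-tendon equilibrium or metabolic cost;
  static optimization is purely per-frame.
* The residual-reduction pass adjusts only the torso COM and the filter
  pass, not full tracking kinematics.
* Saturated activations can occur at cycle boundaries of the synthetic
  fixture, where finite-difference accelerations are least accurate and
  the template plate forces are least consistent with the kinematics;
  reserves make such frames auditable.
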