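"""Build subject-specific model parameters from morphometric inputs.

Computes a segment mass from tissue voxel counts, the torso point mass from
the half-body-mass rule, an anatomical femur frame from bony landmarks, and
maximum isometric muscle forces from the packaged parameter roster.
"""

import numpy as np

from caninegait import (
    TissueVolumeTable,
    build_coordinate_system,
    compute_segment_mass,
    compute_torso_mass,
    load_muscle_roster,
    max_isometric_force,
)

# femur-sized block of mostly muscle with a bony core, CT voxel geometry
table = TissueVolumeTable(
    counts={"femur": (180_000, 120_000, 1_050_000, 95_000)},
    pixel_size_mm=0.325,
    slice_thickness_mm=1.0,
)
mass = compute_segment_mass(table, "femur")
print(f"femur mass from tissue voxels: {mass:.4f} kg")

torso = compute_torso_mass(total_mass_kg=5.4, segment_mass_sum_kg=0.9)
print(f"torso point mass (5.4 kg dog, 0.9 kg of modeled segments): {torso:.2f} kg")
# the torso represents the caudal abdominal mass carried by the hind limbs

landmarks = {
    "CFH": np.array([12.0, 80.0, 30.0]),   # femoral head centre (mm)
    "MFC": np.array([10.0, 0.0, 25.0]),    # medial femoral condyle
    "LFC": np.array([11.0, 1.0, 40.0]),    # lateral femoral condyle
}
frame = build_coordinate_system(landmarks, "femur", side="right")
print("right femur proximal-distal axis (unit y):", np.round(frame.y, 4))

roster = load_muscle_roster()
print("\nmax isometric force, F = T*Vol*cos(a)/f with T = 22.5 N/cm^2:")
for name in ("Adductor magnus et brevis", "Iliopsoas", "Semitendinosus"):
    row = roster.set_index("muscle").loc[name]
    force = max_isometric_force(row.volume_cm3, row.pennation_deg, row.optimal_fiber_length_cm)
    print(f"  {name:28s} {force:7.1f} N (tabulated {row.max_isometric_force_N} N)")
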