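"""Segment inertial properties from CT-derived tissue voxel data.

Segment mass is the density-weighted voxel volume summed over four tissue
classes (cortical bone, trabecular bone, muscle, fat).  Inertia tensors are
computed by voxel-wise parallel-axis summation about the segment centre of
mass and expressed in the anatomical axes of the segment frame.

Morphometric quantities are handled in mm and g; results are returned in SI
(kg, kg·m²).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Default tissue densities in g/cm³: cortical bone, trabecular bone, muscle, fat.
DEFAULT_DENSITIES = (2.003, 1.911, 1.06, 0.95)

TISSUE_CLASSES = ("cortical_bone", "trabecular_bone", "muscle", "fat")


class MorphometryError(ValueError):
    """Invalid morphometric input (negative counts, nonpositive voxel size...)."""


@dataclass
class TissueVolumeTable:
    """Per-segment voxel counts by tissue class.

    Parameters
    ----------
    counts
        Mapping ``segment name -> (N_cortical, N_trabecular, N_muscle, N_fat)``,
        dimensionless voxel counts.
    pixel_size_mm
        In-plane pixel width/height P (mm).
    slice_thickness_mm
        Slice thickness S (mm).
    densities_g_cm3
        Tissue densities ρ_i (g/cm³) in the class order above.
    """

    counts: dict[str, tuple[int, int, int, int]]
    pixel_size_mm: float = 0.325
    slice_thickness_mm: float = 1.0
    densities_g_cm3: tuple[float, float, float, float] = DEFAULT_DENSITIES

    def __post_init__(self) -> None:
        if self.pixel_size_mm <= 0 or self.slice_thickness_mm <= 0:
            raise MorphometryError("pixel size and slice thickness must be > 0")
        if len(self.densities_g_cm3) != 4 or any(d <= 0 for d in self.densities_g_cm3):
            raise MorphometryError("all four tissue densities must be > 0")
        for seg, n in self.counts.items():
            if len(n) != 4:
                raise MorphometryError(f"segment {seg!r}: need counts for 4 tissue classes")
            arr = np.asarray(n, dtype=float)
            if np.any(arr < 0) or np.any(arr != np.round(arr)):
                raise MorphometryError(f"segment {seg!r}: counts must be nonnegative integers")

    def segments(self) -> list[str]:
        return list(self.counts)


def compute_segment_mass(table: TissueVolumeTable, segment: str) -> float:
    """Mass (kg) of one segment: m = Σ_i ρ_i · P² · S · N_i.

    The voxel volume P²·S is in mm³; density is g/cm³, hence the
    mm³ → cm³ (1e-3) and g → kg (1e-3) conversions.
    """
    if segment not in table.counts:
        raise MorphometryError(f"unknown segment {segment!r}")
    n = np.asarray(table.counts[segment], dtype=float)
    voxel_cm3 = table.pixel_size_mm**2 * table.slice_thickness_mm * 1e-3
    grams = float(np.dot(table.densities_g_cm3, n) * voxel_cm3)
    return grams * 1e-3


def compute_torso_mass(total_mass_kg: float, segment_mass_sum_kg: float) -> float:
    """Torso point mass: half the dog's mass minus the sum of modeled segments.

    The torso segment stands in for the caudal abdominal mass carried by the
    pelvic limbs, assuming body mass splits evenly between fore- and hindquarters.
    """
    if total_mass_kg <= 0:
        raise MorphometryError("total mass must be > 0")
    if segment_mass_sum_kg < 0:
        raise MorphometryError("segment mass sum must be >= 0")
    torso = total_mass_kg / 2.0 - segment_mass_sum_kg
    if torso <= 0:
        raise MorphometryError(
            f"nonpositive torso mass ({torso:.4f} kg): modeled segments "
            f"({segment_mass_sum_kg} kg) must weigh less than half the dog ({total_mass_kg} kg)"
        )
    return torso


@dataclass
class VoxelCloud:
    """Labeled voxel grid for one segment.

    ``positions_mm`` are voxel centres (n×3, mm) in some acquisition frame;
    ``tissue_index`` assigns each voxel to a tissue class (0..3).
    """

    positions_mm: np.ndarray
    tissue_index: np.ndarray
    pixel_size_mm: float = 0.325
    slice_thickness_mm: float = 1.0
    densities_g_cm3: tuple[float, float, float, float] = DEFAULT_DENSITIES

    def __post_init__(self) -> None:
        self.positions_mm = np.atleast_2d(np.asarray(self.positions_mm, dtype=float))
        self.tissue_index = np.asarray(self.tissue_index, dtype=int)
        if self.positions_mm.size == 0:
            raise MorphometryError("empty voxel set")
        if self.positions_mm.shape[1] != 3:
            raise MorphometryError("voxel positions must be n×3")
        if self.tissue_index.shape[0] != self.positions_mm.shape[0]:
            raise MorphometryError("one tissue label per voxel required")
        if np.any(self.tissue_index < 0) or np.any(self.tissue_index > 3):
            raise MorphometryError("tissue index must be in 0..3")

    def voxel_masses_kg(self) -> np.ndarray:
        vol_cm3 = self.pixel_size_mm**2 * self.slice_thickness_mm * 1e-3
        rho = np.asarray(self.densities_g_cm3)[self.tissue_index]
        return rho * vol_cm3 * 1e-3

    def total_mass_kg(self) -> float:
        return float(self.voxel_masses_kg().sum())

    def com_mm(self) -> np.ndarray:
        m = self.voxel_masses_kg()
        return m @ self.positions_mm / m.sum()


def compute_segment_inertia(
    voxels: VoxelCloud, axes: np.ndarray | None = None
) -> np.ndarray:
    """Inertia tensor (kg·m²) about the voxel-cloud COM in anatomical axes.

    Each voxel contributes a point-mass parallel-axis term
    ``m · ((r·r) E₃ − r rᵀ)`` with r the COM-relative position.  If ``axes``
    (3×3, columns = anatomical unit vectors expressed in the voxel frame) is
    given, the tensor is rotated into those axes: I' = Rᵀ I R.
    """
    m = voxels.voxel_masses_kg()
    r = (voxels.positions_mm - voxels.com_mm()) * 1e-3  # m
    r2 = np.einsum("ij,ij->i", r, r)
    inertia = np.diag([float(np.dot(m, r2))] * 3) - np.einsum("i,ij,ik->jk", m, r, r)
    if axes is not None:
        axes = np.asarray(axes, dtype=float)
        if axes.shape != (3, 3) or not np.allclose(axes.T @ axes, np.eye(3), atol=1e-9):
            raise MorphometryError("axes must be a 3×3 orthonormal matrix")
        inertia = axes.T @ inertia @ axes
    return (inertia + inertia.T) / 2.0
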