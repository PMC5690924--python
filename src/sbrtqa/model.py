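"""Core domain types for radiotherapy plan evaluation.

A plan couples a 3D absorbed-dose grid with a set of boolean structure
masks (PTV, ITV, lungs, cord, ribs, ...) and a prescription.  All grids are
regular and axis-aligned; arrays are indexed ``[ix, iy, iz]`` and the
physical position of a voxel *center* is ``origin + index * spacing`` in
millimetres.  Masks are always stored on the dose grid: every metric in
this package is a dose-grid quantity, so structures read from other
geometries are resampled onto it at load time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional

import numpy as np

from .errors import GeometryError, ValidationError

#: Structure names required for a full RTOG-style evaluation.
REQUIRED_STRUCTURES = ("PTV", "ITV", "lungs_total", "spinal_cord", "ribs")
#: Optional structures that are documented when present.
OPTIONAL_STRUCTURES = ("esophagus", "heart")


@dataclass
class DoseGrid:
    """Regular 3D scalar field of absorbed dose.

    Parameters
    ----------
    origin : (3,) float array, mm
        Physical coordinate of the center of voxel (0, 0, 0).
    spacing : (3,) float array, mm
        Per-axis voxel pitch; may be anisotropic, must be positive.
    dose : (nx, ny, nz) float array, Gy
        Absorbed dose per voxel; must be non-negative and finite.
    frame_id : str
        Opaque geometry identifier; structures must share it.
    """

    origin: np.ndarray
    spacing: np.ndarray
    dose: np.ndarray
    frame_id: str = "frame-0"

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.dose = np.asarray(self.dose, dtype=np.float64)
        if self.dose.ndim != 3:
            raise ValidationError(f"dose must be 3D, got shape {self.dose.shape}")
        if not np.all(self.spacing > 0):
            raise ValidationError(f"spacing must be positive, got {self.spacing}")
        if not np.all(np.isfinite(self.dose)):
            raise ValidationError("dose contains non-finite values")
        if np.any(self.dose < 0):
            raise ValidationError("dose contains negative values")

    @property
    def shape(self) -> tuple:
        return self.dose.shape

    @property
    def voxel_volume_cc(self) -> float:
        """Volume of one voxel in cc (spacing is in mm; 1000 mm^3 = 1 cc)."""
        return float(np.prod(self.spacing)) / 1000.0

    def voxel_centers_mm(self, axis: int) -> np.ndarray:
        """Physical center coordinates along one axis."""
        n = self.shape[axis]
        return self.origin[axis] + np.arange(n) * self.spacing[axis]

    def scaled(self, factor: float) -> "DoseGrid":
        """Return a copy with all doses multiplied by ``factor`` (> 0)."""
        if factor <= 0:
            raise ValidationError(f"scale factor must be positive, got {factor}")
        return DoseGrid(self.origin, self.spacing, self.dose * factor, self.frame_id)


@dataclass
class StructureMask:
    """Boolean voxel occupancy of one named region on a stated grid."""

    name: str
    occupancy: np.ndarray
    frame_id: str = "frame-0"

    def __post_init__(self) -> None:
        self.occupancy = np.asarray(self.occupancy, dtype=bool)
        if self.occupancy.ndim != 3:
            raise ValidationError(f"mask {self.name!r} must be 3D")

    @property
    def voxel_count(self) -> int:
        return int(self.occupancy.sum())

    def volume_cc(self, grid: DoseGrid) -> float:
        check_same_frame(grid, self)
        return self.voxel_count * grid.voxel_volume_cc

    def is_empty(self) -> bool:
        return not self.occupancy.any()


@dataclass
class StructureSet:
    """Named collection of structure masks plus the plan isocenter (mm)."""

    masks: Dict[str, StructureMask]
    isocenter: np.ndarray

    def __post_init__(self) -> None:
        self.isocenter = np.asarray(self.isocenter, dtype=float).reshape(3)
        frames = {m.frame_id for m in self.masks.values()}
        if len(frames) > 1:
            raise GeometryError(f"masks span multiple frames: {sorted(frames)}")

    def __contains__(self, name: str) -> bool:
        return name in self.masks

    def __getitem__(self, name: str) -> StructureMask:
        try:
            return self.masks[name]
        except KeyError:
            raise ValidationError(f"structure {name!r} not present") from None

    def get(self, name: str) -> Optional[StructureMask]:
        return self.masks.get(name)

    @property
    def names(self) -> Iterable[str]:
        return self.masks.keys()

    @property
    def frame_id(self) -> str:
        if not self.masks:
            raise ValidationError("structure set is empty")
        return next(iter(self.masks.values())).frame_id


@dataclass
class Prescription:
    """Prescribed total dose and fractionation.

    The cohort modelled here uses 54 Gy in 3 fractions or 50 Gy in 5
    fractions; ``dose_per_fraction`` is the derived quotient used by the
    linear-quadratic BED.
    """

    total_dose: float
    n_fractions: int

    def __post_init__(self) -> None:
        if self.total_dose <= 0:
            raise ValidationError(f"total_dose must be > 0, got {self.total_dose}")
        if int(self.n_fractions) != self.n_fractions or self.n_fractions < 1:
            raise ValidationError(f"n_fractions must be a positive int, got {self.n_fractions}")
        self.n_fractions = int(self.n_fractions)

    @property
    def dose_per_fraction(self) -> float:
        return self.total_dose / self.n_fractions


@dataclass
class Plan:
    """A dose grid, its structure set, and the prescription."""

    dose: DoseGrid
    structures: StructureSet
    prescription: Prescription
    patient_id: str = "anon"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.structures.masks and self.structures.frame_id != self.dose.frame_id:
            raise GeometryError(
                f"dose frame {self.dose.frame_id!r} != structure frame "
                f"{self.structures.frame_id!r}"
            )
        for m in self.structures.masks.values():
            if m.occupancy.shape != self.dose.shape:
                raise GeometryError(
                    f"mask {m.name!r} shape {m.occupancy.shape} != dose shape {self.dose.shape}"
                )

    def structure_volume_cc(self, name: str) -> float:
        return self.structures[name].volume_cc(self.dose)

    def scaled(self, factor: float) -> "Plan":
        return Plan(
            self.dose.scaled(factor),
            self.structures,
            self.prescription,
            self.patient_id,
            dict(self.meta),
        )


def check_same_frame(grid_or_mask, *others) -> None:
    """Raise :class:`GeometryError` unless all arguments share one frame."""
    ref = grid_or_mask.frame_id
    for o in others:
        if o.frame_id != ref:
            raise GeometryError(f"frame mismatch: {ref!r} vs {o.frame_id!r}")
        a = grid_or_mask.dose.shape if isinstance(grid_or_mask, DoseGrid) else grid_or_mask.occupancy.shape
        b = o.dose.shape if isinstance(o, DoseGrid) else o.occupancy.shape
        if a != b:
            raise GeometryError(f"shape mismatch: {a} vs {b}")
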