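"""Cumulative dose-volume histograms and DVH-based plan normalization.

The DVH here is voxel-exact: the curve is the sorted list of voxel doses
inside a structure, not a binned histogram, so dose and volume queries
carry no bin-width parameter.  Conventions:

* ``V(d)`` uses an inclusive threshold — the volume receiving dose *d or
  more* — matching the protocol wording for lung V20/V5.
* ``D(v)`` ("dose to the hottest v cc") is the largest dose level whose
  covered volume is at least ``v``, linearly interpolated between adjacent
  sorted voxel doses; as ``v -> 0+`` it tends to the maximum voxel dose.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import NormalizationError, ValidationError
from .model import DoseGrid, Plan, StructureMask, check_same_frame


@dataclass
class DVHCurve:
    """Cumulative DVH of one structure as sorted voxel doses."""

    structure_name: str
    doses_desc: np.ndarray  # Gy, sorted descending, one entry per voxel
    voxel_volume_cc: float

    def __post_init__(self) -> None:
        self.doses_desc = np.asarray(self.doses_desc, dtype=float).ravel()
        if self.doses_desc.size == 0:
            raise ValidationError(f"empty DVH for {self.structure_name!r}")
        if self.voxel_volume_cc <= 0:
            raise ValidationError("voxel volume must be positive")
        # enforce the descending-sort invariant rather than trusting callers
        if np.any(np.diff(self.doses_desc) > 0):
            self.doses_desc = np.sort(self.doses_desc)[::-1]

    @property
    def total_volume_cc(self) -> float:
        return self.doses_desc.size * self.voxel_volume_cc

    @property
    def max_dose(self) -> float:
        return float(self.doses_desc[0])

    @property
    def min_dose(self) -> float:
        return float(self.doses_desc[-1])

    def scaled(self, factor: float) -> "DVHCurve":
        if factor <= 0:
            raise ValidationError("scale factor must be positive")
        return DVHCurve(self.structure_name, self.doses_desc * factor, self.voxel_volume_cc)


def compute_dvh(dose: DoseGrid, mask: StructureMask) -> DVHCurve:
    """Cumulative DVH over exactly the voxels where the mask is true."""
    check_same_frame(dose, mask)
    if mask.is_empty():
        raise ValidationError(f"mask {mask.name!r} is empty (missing contour?)")
    samples = dose.dose[mask.occupancy]
    return DVHCurve(mask.name, np.sort(samples)[::-1], dose.voxel_volume_cc)


def volume_at_dose(curve: DVHCurve, level: float, mode: str = "absolute_cc") -> float:
    """Volume receiving ``level`` Gy or more (inclusive threshold)."""
    if level < 0:
        raise ValidationError(f"dose level must be >= 0, got {level}")
    n = int(np.searchsorted(-curve.doses_desc, -level, side="right"))
    vol_cc = n * curve.voxel_volume_cc
    if mode == "absolute_cc":
        return vol_cc
    if mode == "percent":
        return 100.0 * vol_cc / curve.total_volume_cc
    raise ValidationError(f"unknown mode {mode!r}")


def dose_at_volume(curve: DVHCurve, volume: float, mode: str = "absolute_cc") -> float:
    """Minimum dose received by the hottest ``volume`` of the structure.

    Equivalently the largest dose D with ``volume_at_dose(D) >= volume``.
    """
    if mode == "percent":
        volume_cc = volume / 100.0 * curve.total_volume_cc
    elif mode == "absolute_cc":
        volume_cc = volume
    else:
        raise ValidationError(f"unknown mode {mode!r}")
    if volume_cc <= 0:
        raise ValidationError(f"volume must be > 0, got {volume_cc} cc")
    if volume_cc > curve.total_volume_cc * (1 + 1e-9):
        raise ValidationError(
            f"requested {volume_cc:.3f} cc exceeds structure volume "
            f"{curve.total_volume_cc:.3f} cc"
        )
    # volume k * voxel_volume corresponds to the k-th sorted voxel dose;
    # interpolate linearly at fractional voxel counts.
    k = volume_cc / curve.voxel_volume_cc
    n = curve.doses_desc.size
    if k <= 1.0:
        return float(curve.doses_desc[0])
    if k >= n:
        return float(curve.doses_desc[-1])
    lo = int(np.floor(k))  # 1-based index of bracketing voxel
    frac = k - lo
    d_hi = curve.doses_desc[lo - 1]
    d_lo = curve.doses_desc[lo]
    return float(d_hi + (d_lo - d_hi) * frac)


def max_dose(dose: DoseGrid, mask: StructureMask | None = None) -> float:
    """Maximum voxel dose within a region (whole grid when mask is None)."""
    if mask is None:
        return float(dose.dose.max())
    check_same_frame(dose, mask)
    if mask.is_empty():
        raise ValidationError(f"mask {mask.name!r} is empty")
    return float(dose.dose[mask.occupancy].max())


def normalize_to_coverage(
    plan: Plan, coverage_percent: float = 95.0, target_structure: str = "PTV"
) -> Plan:
    """Rescale all doses so D(coverage%) of the target equals the prescription.

    This is DVH normalization: after scaling, ``coverage_percent`` of the
    target volume receives at least 100% of the prescribed dose.  The scale
    factor is recorded in ``plan.meta['normalization_scale']``.
    """
    if not (0 < coverage_percent <= 100):
        raise ValidationError(f"coverage must be in (0, 100], got {coverage_percent}")
    target = plan.structures[target_structure]
    curve = compute_dvh(plan.dose, target)
    d_cov = dose_at_volume(curve, coverage_percent, mode="percent")
    if d_cov <= 0:
        raise NormalizationError(
            f"D{coverage_percent:g}% of {target_structure!r} is zero; cannot normalize"
        )
    scale = plan.prescription.total_dose / d_cov
    out = plan.scaled(scale)
    out.meta["normalization_scale"] = scale
    out.meta["normalization_coverage_percent"] = coverage_percent
    return out


def dvh_to_table(curve: DVHCurve) -> np.ndarray:
    """Two-column (dose Gy, cumulative volume cc) array, descending dose."""
    vols = np.arange(1, curve.doses_desc.size + 1) * curve.voxel_volume_cc
    return np.column_stack([curve.doses_desc, vols])
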