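"""Synthetic lung-SBRT dose phantoms with analytically known metrics.

The phantom emulates the geometry of a peripherally located lung target:
an ellipsoidal PTV centred at the isocenter inside a large lung region,
a rib shell at a configurable 3D distance, and a spinal-cord cylinder.
The dose is an analytic, radially monotone field

    D(x) = Rx * f(r_eff(x)),    f(r) = 1                     for r <= r100
                                f(r) = 2^(-(r - r100)/g50)   for r > r100

where ``r_eff`` is the ellipsoid-equivalent radius (isodose surfaces are
scaled copies of the PTV ellipsoid), ``r100 = r100_scale * r_geo`` is the
prescription-isodose radius and ``g50`` the distance from it to the
half-prescription isodose.  No beam or transport physics is modelled —
only the evaluated distribution's geometry matters for testing the
metrics pipeline — which makes every spillage metric available in closed
form:

* R100% = r100_scale**3
* R50%  = ((r100 + g50) / r_geo)**3
* D2cm  = 100 * f(r_eff at 2 cm from the PTV surface along the longest axis)

so generated plans double as ground-truth oracles for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .errors import GeometryError, ValidationError
from .model import DoseGrid, Plan, Prescription, StructureMask, StructureSet

ITV_MARGIN_MM = 5.0  # PTV = ITV + 5 mm uniform margin; the phantom inverts this

# fraction of a voxel by which the isocenter is displaced from the lattice
_SUBVOXEL_OFFSET = np.array([0.185, 0.305, 0.465])


@dataclass
class PhantomConfig:
    """Geometry, prescription, and falloff parameters of one phantom plan."""

    spacing_mm: Tuple[float, float, float] = (2.0, 2.0, 2.0)
    ptv_semiaxes_mm: Tuple[float, float, float] = (15.0, 15.0, 15.0)
    total_dose_gy: float = 50.0
    n_fractions: int = 5
    r100_scale: float = 1.05  # prescription-isodose radius / PTV radius
    g50_mm: float = 12.0  # distance from r100 to the half-prescription isodose
    iso_to_rib_mm: float = 35.0
    rib_thickness_mm: float = 8.0
    cord_radius_mm: float = 4.0
    noise_sd: float = 0.0  # relative amplitude of optional multiplicative noise
    seed: int = 0
    patient_id: str = "phantom"
    half_extent_mm: Optional[float] = None  # grid half-size; None = auto

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.ptv_semiaxes_mm) or any(s <= 0 for s in self.spacing_mm):
            raise ValidationError("geometric sizes must be positive")
        if self.r100_scale < 1.0:
            raise ValidationError(f"r100_scale must be >= 1, got {self.r100_scale}")
        if self.g50_mm <= 0:
            raise ValidationError(f"g50 must be > 0, got {self.g50_mm}")
        if self.iso_to_rib_mm <= max(self.ptv_semiaxes_mm):
            raise ValidationError("rib shell must lie outside the PTV")

    @property
    def prescription(self) -> Prescription:
        return Prescription(self.total_dose_gy, self.n_fractions)

    @property
    def r_geo_mm(self) -> float:
        """Equivalent-sphere radius (abc)^(1/3) of the PTV ellipsoid."""
        return float(np.prod(self.ptv_semiaxes_mm)) ** (1.0 / 3.0)

    @property
    def r100_radius_mm(self) -> float:
        return self.r100_scale * self.r_geo_mm

    @property
    def ptv_cc(self) -> float:
        return 4.0 / 3.0 * np.pi * float(np.prod(self.ptv_semiaxes_mm)) / 1000.0


def dose_profile(r_eff_mm, config: PhantomConfig):
    """Relative dose f(r_eff): 1 on the plateau, exponential falloff beyond."""
    r = np.asarray(r_eff_mm, dtype=float)
    r100 = config.r100_radius_mm
    out = np.where(r <= r100, 1.0, np.exp2(-(r - r100) / config.g50_mm))
    return out if out.shape else float(out)


def solve_profile_for_targets(
    target_r100: float, target_r50: float, ptv_radius_mm: float
) -> Tuple[float, float]:
    """Closed-form falloff parameters hitting given R100%/R50% targets.

    For spherical (or ellipsoid-equivalent) geometry the prescription
    isodose radius is ``ptv_radius * target_r100^(1/3)`` and the
    half-prescription radius ``ptv_radius * target_r50^(1/3)``; returns
    ``(r100_scale, g50_mm)``.
    """
    if target_r100 < 1.0:
        raise ValidationError(f"target R100 must be >= 1, got {target_r100}")
    if target_r50 <= target_r100:
        raise ValidationError(
            f"target R50 ({target_r50}) must exceed target R100 ({target_r100})"
        )
    if ptv_radius_mm <= 0:
        raise ValidationError("PTV radius must be positive")
    scale = target_r100 ** (1.0 / 3.0)
    g50 = ptv_radius_mm * (target_r50 ** (1.0 / 3.0) - scale)
    return scale, g50


def analytic_metrics(config: PhantomConfig) -> dict:
    """Ground-truth metric values of the continuous phantom dose field."""
    r_geo = config.r_geo_mm
    a_max = max(config.ptv_semiaxes_mm)
    r50_radius = config.r100_radius_mm + config.g50_mm
    # the exclusion-region voxel of least effective radius sits 20 mm past
    # the tip of the longest semi-axis
    r_eff_2cm = r_geo * (a_max + 20.0) / a_max
    return {
        "patient_id": config.patient_id,
        "ptv_cc": config.ptv_cc,
        "r100": config.r100_scale**3,
        "r50": (r50_radius / r_geo) ** 3,
        "d2cm_pct": 100.0 * dose_profile(r_eff_2cm, config),
        "iso_to_rib_mm": config.iso_to_rib_mm,
        "total_dose_gy": config.total_dose_gy,
        "n_fractions": config.n_fractions,
    }


def _auto_half_extent(config: PhantomConfig) -> float:
    a_max = max(config.ptv_semiaxes_mm)
    r_half_phys = a_max * (config.r100_radius_mm + config.g50_mm) / config.r_geo_mm
    return max(
        a_max + 34.0,  # D2cm shell plus margin
        r_half_phys + 10.0,  # half-prescription isodose inside the grid
        config.iso_to_rib_mm + config.rib_thickness_mm + 8.0,
        40.0,
    )


def make_phantom(config: PhantomConfig) -> Plan:
    """Build a deterministic synthetic plan from a configuration."""
    half = config.half_extent_mm or _auto_half_extent(config)
    spacing = np.asarray(config.spacing_mm, dtype=float)
    n = (2 * np.ceil(half / spacing) + 1).astype(int)
    # Isocenter sits at physical (0,0,0) but at an asymmetric sub-voxel
    # position within its voxel: aligning sphere centers with the lattice
    # produces several-percent volume artifacts in voxel-center counts,
    # while this offset keeps rasterized volumes within ~1% of analytic.
    origin = -(n - 1) / 2.0 * spacing - _SUBVOXEL_OFFSET * spacing
    frame = f"phantom-{config.seed}-{config.patient_id}"

    axes = [origin[i] + np.arange(n[i]) * spacing[i] for i in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij", sparse=True)
    r_mm = np.sqrt(gx**2 + gy**2 + gz**2)
    a = np.asarray(config.ptv_semiaxes_mm, dtype=float)
    r_eff = config.r_geo_mm * np.sqrt((gx / a[0]) ** 2 + (gy / a[1]) ** 2 + (gz / a[2]) ** 2)

    if max(config.ptv_semiaxes_mm) >= half:
        raise GeometryError("PTV exceeds the dose grid")
    if config.iso_to_rib_mm + config.rib_thickness_mm >= half:
        raise GeometryError("rib shell exceeds the dose grid")

    dose = config.total_dose_gy * dose_profile(r_eff, config)
    if config.noise_sd > 0:
        rng = np.random.default_rng(config.seed)
        dose = dose * np.clip(rng.normal(1.0, config.noise_sd, size=dose.shape), 0.0, None)

    ptv = r_eff <= config.r_geo_mm
    itv_a = np.maximum(a - ITV_MARGIN_MM, 2.0)
    itv = (gx / itv_a[0]) ** 2 + (gy / itv_a[1]) ** 2 + (gz / itv_a[2]) ** 2 <= 1.0
    lungs = r_mm <= (half - 6.0)
    rib = (
        (r_mm >= config.iso_to_rib_mm)
        & (r_mm <= config.iso_to_rib_mm + config.rib_thickness_mm)
        & (gx > 0)
    )
    cord_x = -(half - 10.0)
    cord = (gx - cord_x) ** 2 + gy**2 <= config.cord_radius_mm**2

    masks = {
        name: StructureMask(name, occ, frame)
        for name, occ in (
            ("PTV", ptv),
            ("ITV", itv),
            ("lungs_total", lungs),
            ("ribs", rib),
            ("spinal_cord", np.broadcast_to(cord, tuple(n)).copy()),
        )
    }
    structures = StructureSet(masks, np.zeros(3))
    grid = DoseGrid(origin, spacing, np.ascontiguousarray(dose), frame)
    return Plan(grid, structures, config.prescription, config.patient_id,
                {"phantom_config": True, "seed": config.seed})


@dataclass
class CohortRanges:
    """Sampling ranges for a synthetic cohort (log-uniform PTV volumes)."""

    ptv_cc: Tuple[float, float] = (11.1, 163.0)
    target_r100: Tuple[float, float] = (1.05, 1.45)
    target_r50: Tuple[float, float] = (3.2, 5.5)
    iso_to_rib_gap_mm: Tuple[float, float] = (2.0, 40.0)  # gap beyond PTV radius
    fraction_3fx: float = 0.25  # share of 54 Gy / 3 fx prescriptions

    def __post_init__(self) -> None:
        for lo, hi in (self.ptv_cc, self.target_r100, self.target_r50, self.iso_to_rib_gap_mm):
            if not (0 < lo <= hi):
                raise ValidationError(f"degenerate range ({lo}, {hi})")


def make_cohort(
    n: int,
    ranges: CohortRanges | None = None,
    seed: int = 0,
    spacing_mm: Tuple[float, float, float] = (2.0, 2.0, 2.0),
) -> Tuple[List[Plan], pd.DataFrame]:
    """Sample ``n`` spherical-target phantoms plus their ground-truth table."""
    if n < 1:
        raise ValidationError("cohort size must be >= 1")
    ranges = ranges or CohortRanges()
    rng = np.random.default_rng(seed)
    plans, truths = [], []
    for i in range(n):
        vol = float(np.exp(rng.uniform(*np.log(ranges.ptv_cc))))
        radius = (3.0 * vol * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
        t100 = float(rng.uniform(*ranges.target_r100))
        t50 = float(rng.uniform(max(ranges.target_r50[0], t100 + 0.5), ranges.target_r50[1]))
        scale, g50 = solve_profile_for_targets(t100, t50, radius)
        rib_dist = radius + float(rng.uniform(*ranges.iso_to_rib_gap_mm))
        three_fx = i < round(ranges.fraction_3fx * n)
        cfg = PhantomConfig(
            spacing_mm=spacing_mm,
            ptv_semiaxes_mm=(radius, radius, radius),
            total_dose_gy=54.0 if three_fx else 50.0,
            n_fractions=3 if three_fx else 5,
            r100_scale=scale,
            g50_mm=g50,
            iso_to_rib_mm=rib_dist,
            seed=int(rng.integers(0, 2**31 - 1)),
            patient_id=f"synth-{i + 1:02d}",
        )
        plans.append(make_phantom(cfg))
        truths.append(analytic_metrics(cfg))
    return plans, pd.DataFrame(truths)
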