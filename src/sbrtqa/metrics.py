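"""Per-plan dosimetric metrics for lung SBRT plan evaluation.

Implements the RTOG 0915 high- and intermediate-dose spillage quantities —
conformity index R100% (prescription isodose volume / PTV volume), R50%
(half-prescription isodose volume / PTV volume), D2cm (maximum dose at
least 2 cm from the PTV in any direction, as % of prescription), normal
lung V20/V5 — plus the documented OAR doses: spinal cord D0.35cc, lung
D1000cc, optional esophagus D5cc and heart D15cc, and the rib set (Dmax,
D1cc, D5cc, D10cc, 3D isocenter-to-rib distance).

All metrics are defined on a DVH-normalized plan (95% of the PTV receiving
the prescription); :func:`extract_metrics` applies that normalization by
default and records the scale factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np

from . import dvh, geometry
from .errors import GeometryError, ValidationError
from .model import Plan, Prescription

D2CM_MARGIN_MM = 20.0


@dataclass
class PlanMetrics:
    """Container for the per-plan metric set (None = not evaluable)."""

    patient_id: str
    prescription: Prescription
    ptv_cc: float
    r100: Optional[float] = None
    r50: Optional[float] = None
    d2cm_pct: Optional[float] = None
    lung_v20_pct: Optional[float] = None
    lung_v5_pct: Optional[float] = None
    lung_d1000cc_gy: Optional[float] = None
    cord_d035cc_gy: Optional[float] = None
    esophagus_d5cc_gy: Optional[float] = None
    heart_d15cc_gy: Optional[float] = None
    rib_dmax_gy: Optional[float] = None
    rib_d1cc_gy: Optional[float] = None
    rib_d5cc_gy: Optional[float] = None
    rib_d10cc_gy: Optional[float] = None
    iso_to_rib_mm: Optional[float] = None
    flags: List[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k not in ("prescription", "flags")}
        d["total_dose_gy"] = self.prescription.total_dose
        d["n_fractions"] = self.prescription.n_fractions
        return d


def compute_r100(plan: Plan) -> float:
    """Conformity index: prescription isodose volume over PTV volume."""
    ptv_cc = plan.structure_volume_cc("PTV")
    if ptv_cc <= 0:
        raise ValidationError("PTV is empty")
    v_iso = geometry.isodose_volume(plan.dose, plan.prescription.total_dose)
    return v_iso / ptv_cc


def compute_r50(plan: Plan) -> float:
    """Intermediate-dose spillage: half-prescription isodose volume / PTV."""
    ptv_cc = plan.structure_volume_cc("PTV")
    if ptv_cc <= 0:
        raise ValidationError("PTV is empty")
    v_iso = geometry.isodose_volume(plan.dose, 0.5 * plan.prescription.total_dose)
    return v_iso / ptv_cc


def compute_d2cm(plan: Plan, flags: Optional[List[str]] = None) -> float:
    """Max dose >= 2 cm from the PTV in any direction, % of prescription.

    The exclusion region is the complement of the 20 mm expansion of the
    PTV (inclusive boundary: a voxel exactly 20 mm away still belongs to
    the expansion).  A warning flag is recorded when the grid does not
    extend 20 mm beyond the PTV on every side.
    """
    ptv = plan.structures["PTV"]
    expanded = geometry.expand_mask(ptv, D2CM_MARGIN_MM, plan.dose.spacing)
    exclusion = geometry.mask_complement(expanded, "d2cm_region")
    if exclusion.is_empty():
        raise GeometryError("no voxels beyond 2 cm of the PTV; grid too small")
    idx = np.argwhere(ptv.occupancy)
    lo_mm = idx.min(axis=0) * plan.dose.spacing
    hi_mm = (np.array(plan.dose.shape) - 1 - idx.max(axis=0)) * plan.dose.spacing
    if flags is not None and (np.any(lo_mm < D2CM_MARGIN_MM) or np.any(hi_mm < D2CM_MARGIN_MM)):
        flags.append("d2cm: grid extends < 20 mm beyond PTV on at least one side")
    dmax = dvh.max_dose(plan.dose, exclusion)
    return 100.0 * dmax / plan.prescription.total_dose


def compute_lung_metrics(plan: Plan, flags: Optional[List[str]] = None):
    """(V20 %, V5 %, D1000cc Gy) on total normal lung = lungs minus ITV."""
    lungs = plan.structures["lungs_total"]
    itv = plan.structures["ITV"]
    normal = geometry.mask_subtract(lungs, itv, "normal_lung")
    if normal.is_empty():
        raise ValidationError("normal lung (lungs minus ITV) is empty")
    curve = dvh.compute_dvh(plan.dose, normal)
    v20 = dvh.volume_at_dose(curve, 20.0, mode="percent")
    v5 = dvh.volume_at_dose(curve, 5.0, mode="percent")
    if curve.total_volume_cc >= 1000.0:
        d1000 = dvh.dose_at_volume(curve, 1000.0)
    else:
        d1000 = curve.min_dose
        if flags is not None:
            flags.append(
                f"lung D1000cc: normal lung is only {curve.total_volume_cc:.0f} cc; "
                "reporting minimum lung dose"
            )
    return v20, v5, d1000


def compute_cord_metric(plan: Plan, flags: Optional[List[str]] = None) -> Optional[float]:
    """Dose to the hottest 0.35 cc of spinal cord (Gy)."""
    cord = plan.structures.get("spinal_cord")
    if cord is None or cord.is_empty():
        if flags is not None:
            flags.append("spinal cord contour missing; cord metric not reported")
        return None
    curve = dvh.compute_dvh(plan.dose, cord)
    if curve.total_volume_cc < 0.35:
        if flags is not None:
            flags.append("spinal cord < 0.35 cc; reporting cord max dose")
        return curve.max_dose
    return dvh.dose_at_volume(curve, 0.35)


def compute_rib_metrics(plan: Plan, flags: Optional[List[str]] = None):
    """(Dmax, D1cc, D5cc, D10cc in Gy, isocenter-to-rib distance in mm)."""
    ribs = plan.structures["ribs"]
    if ribs.is_empty():
        raise ValidationError("ribs mask is empty")
    curve = dvh.compute_dvh(plan.dose, ribs)
    dmax = curve.max_dose
    out = {}
    for cc in (1.0, 5.0, 10.0):
        if curve.total_volume_cc >= cc:
            out[cc] = dvh.dose_at_volume(curve, cc)
        else:
            out[cc] = None
            if flags is not None:
                flags.append(f"ribs only {curve.total_volume_cc:.1f} cc; D{cc:g}cc not defined")
    dist = geometry.min_distance_point_to_mask(plan.structures.isocenter, ribs, plan.dose)
    return dmax, out[1.0], out[5.0], out[10.0], dist


def _fixed_volume_dose(plan: Plan, name: str, cc: float, flags: List[str]) -> Optional[float]:
    mask = plan.structures.get(name)
    if mask is None or mask.is_empty():
        return None
    curve = dvh.compute_dvh(plan.dose, mask)
    if curve.total_volume_cc < cc:
        flags.append(f"{name} < {cc:g} cc; reporting max dose")
        return curve.max_dose
    return dvh.dose_at_volume(curve, cc)


def extract_metrics(plan: Plan, normalize: bool = True, coverage_percent: float = 95.0) -> PlanMetrics:
    """Compute the full metric set, normalizing to PTV coverage first.

    With ``normalize=True`` (the default, matching the evaluation
    protocol) the plan is first rescaled so that ``coverage_percent`` of
    the PTV receives the prescription dose.
    """
    if normalize:
        plan = dvh.normalize_to_coverage(plan, coverage_percent, "PTV")
    flags: List[str] = []
    m = PlanMetrics(
        patient_id=plan.patient_id,
        prescription=plan.prescription,
        ptv_cc=plan.structure_volume_cc("PTV"),
        flags=flags,
    )
    if normalize:
        m.flags.append(f"normalization_scale={plan.meta['normalization_scale']:.4f}")
    m.r100 = compute_r100(plan)
    m.r50 = compute_r50(plan)
    m.d2cm_pct = compute_d2cm(plan, flags)
    if "lungs_total" in plan.structures and "ITV" in plan.structures:
        m.lung_v20_pct, m.lung_v5_pct, m.lung_d1000cc_gy = compute_lung_metrics(plan, flags)
    else:
        flags.append("lungs_total/ITV missing; lung metrics not reported")
    m.cord_d035cc_gy = compute_cord_metric(plan, flags)
    m.esophagus_d5cc_gy = _fixed_volume_dose(plan, "esophagus", 5.0, flags)
    m.heart_d15cc_gy = _fixed_volume_dose(plan, "heart", 15.0, flags)
    if "ribs" in plan.structures:
        (m.rib_dmax_gy, m.rib_d1cc_gy, m.rib_d5cc_gy,
         m.rib_d10cc_gy, m.iso_to_rib_mm) = compute_rib_metrics(plan, flags)
    else:
        flags.append("ribs contour missing; rib metrics not reported")
    return m
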