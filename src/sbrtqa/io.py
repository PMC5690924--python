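"""Plan file formats and report writers.

Two plan representations are supported:

* **portable** — a directory holding ``plan.json`` (geometry, prescription,
  isocenter, structure names) plus one raw little-endian array per field
  (``dose.f64``, ``masks/<name>.u8``).  This is the lossless test surface:
  ``read_plan(write_plan(p))`` is bit-exact.
* **dicom_rt** — read-only import of an RTDOSE + RTSTRUCT pair sharing a
  frame of reference.  Contours are rasterized slice by slice onto the
  dose grid with a voxel-center-inside test (even-odd rule); partial
  voxels are not fractionally weighted.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path as FsPath

import numpy as np
import pandas as pd

from .errors import FormatError, GeometryError, ValidationError
from .model import DoseGrid, Plan, Prescription, StructureMask, StructureSet

log = logging.getLogger(__name__)

_PORTABLE_VERSION = 1

# Common clinical ROI-name aliases mapped onto the canonical names used by
# the metrics modules.
STRUCTURE_ALIASES = {
    "ptv": "PTV",
    "itv": "ITV",
    "lungs_total": "lungs_total",
    "total lung": "lungs_total",
    "total_lung": "lungs_total",
    "lungs": "lungs_total",
    "bilateral lungs": "lungs_total",
    "spinal_cord": "spinal_cord",
    "spinal cord": "spinal_cord",
    "cord": "spinal_cord",
    "ribs": "ribs",
    "rib": "ribs",
    "esophagus": "esophagus",
    "heart": "heart",
}


def canonical_structure_name(raw: str) -> str:
    return STRUCTURE_ALIASES.get(raw.strip().lower(), raw.strip())


# ---------------------------------------------------------------------------
# portable directory format
# ---------------------------------------------------------------------------

def write_plan(plan: Plan, path) -> None:
    """Write a plan as a portable directory (JSON header + raw arrays)."""
    if not plan.structures.masks:
        raise ValidationError("refusing to write a plan with an empty structure set")
    root = FsPath(path)
    root.mkdir(parents=True, exist_ok=True)
    (root / "masks").mkdir(exist_ok=True)
    header = {
        "format_version": _PORTABLE_VERSION,
        "patient_id": plan.patient_id,
        "frame_id": plan.dose.frame_id,
        "origin_mm": plan.dose.origin.tolist(),
        "spacing_mm": plan.dose.spacing.tolist(),
        "shape": list(plan.dose.shape),
        "prescription": {
            "total_dose_gy": plan.prescription.total_dose,
            "n_fractions": plan.prescription.n_fractions,
        },
        "isocenter_mm": plan.structures.isocenter.tolist(),
        "structures": sorted(plan.structures.names),
        "meta": plan.meta,
    }
    (root / "plan.json").write_text(json.dumps(header, indent=2, sort_keys=True) + "\n")
    plan.dose.dose.astype("<f8").tofile(root / "dose.f64")
    for name in sorted(plan.structures.names):
        arr = plan.structures[name].occupancy.astype(np.uint8)
        arr.tofile(root / "masks" / f"{name}.u8")


def _read_portable(root: FsPath) -> Plan:
    header_path = root / "plan.json"
    if not header_path.exists():
        raise FormatError(f"no plan.json under {root}")
    try:
        header = json.loads(header_path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"malformed plan.json: {exc}") from exc
    shape = tuple(header["shape"])
    n = int(np.prod(shape))
    dose_arr = np.fromfile(root / "dose.f64", dtype="<f8")
    if dose_arr.size != n:
        raise FormatError(f"dose array has {dose_arr.size} values, expected {n}")
    grid = DoseGrid(
        np.array(header["origin_mm"]),
        np.array(header["spacing_mm"]),
        dose_arr.reshape(shape),
        header["frame_id"],
    )
    masks = {}
    for name in header["structures"]:
        raw = np.fromfile(root / "masks" / f"{name}.u8", dtype=np.uint8)
        if raw.size != n:
            raise FormatError(f"mask {name!r} has {raw.size} voxels, expected {n}")
        masks[name] = StructureMask(name, raw.reshape(shape).astype(bool), header["frame_id"])
    structures = StructureSet(masks, np.array(header["isocenter_mm"]))
    rx = Prescription(
        header["prescription"]["total_dose_gy"], header["prescription"]["n_fractions"]
    )
    return Plan(grid, structures, rx, header["patient_id"], dict(header.get("meta", {})))


# ---------------------------------------------------------------------------
# DICOM-RT import (read-only)
# ---------------------------------------------------------------------------

def _read_dicom_rt(root: FsPath, prescription: Prescription | None) -> Plan:
    import pydicom

    rtdose = rtstruct = None
    for f in sorted(root.glob("*.dcm")):
        ds = pydicom.dcmread(f)
        modality = getattr(ds, "Modality", "")
        if modality == "RTDOSE":
            rtdose = ds
        elif modality == "RTSTRUCT":
            rtstruct = ds
    if rtdose is None or rtstruct is None:
        raise FormatError(f"need one RTDOSE and one RTSTRUCT .dcm under {root}")

    dose_frame = str(rtdose.FrameOfReferenceUID)
    struct_frame = str(
        rtstruct.ReferencedFrameOfReferenceSequence[0].FrameOfReferenceUID
        if "ReferencedFrameOfReferenceSequence" in rtstruct
        else rtstruct.StructureSetROISequence[0].ReferencedFrameOfReferenceUID
    )
    if dose_frame != struct_frame:
        raise GeometryError(
            f"RTDOSE frame {dose_frame} != RTSTRUCT frame {struct_frame}"
        )

    # RTDOSE pixel array is (frames, rows, cols) == (z, y, x)
    scaling = float(getattr(rtdose, "DoseGridScaling", 1.0))
    arr = rtdose.pixel_array.astype(np.float64) * scaling
    dose_xyz = np.ascontiguousarray(arr.transpose(2, 1, 0))
    ipp = np.asarray(rtdose.ImagePositionPatient, dtype=float)  # (x, y, z)
    dy, dx = (float(v) for v in rtdose.PixelSpacing)  # row pitch, col pitch
    offsets = np.asarray(rtdose.GridFrameOffsetVector, dtype=float)
    dz_steps = np.diff(offsets)
    if offsets.size > 1 and not np.allclose(dz_steps, dz_steps[0], atol=1e-6):
        raise GeometryError("non-uniform RTDOSE slice spacing is not supported")
    dz = float(dz_steps[0]) if offsets.size > 1 else 1.0
    origin = np.array([ipp[0], ipp[1], ipp[2] + offsets[0]])
    grid = DoseGrid(origin, np.array([dx, dy, dz]), dose_xyz, dose_frame)

    roi_names = {
        int(roi.ROINumber): canonical_structure_name(str(roi.ROIName))
        for roi in rtstruct.StructureSetROISequence
    }
    masks = {}
    for rc in rtstruct.ROIContourSequence:
        name = roi_names.get(int(rc.ReferencedROINumber))
        if name is None or "ContourSequence" not in rc:
            continue
        occ = _rasterize_contours(rc.ContourSequence, grid)
        if not occ.any():
            log.warning("structure %r rasterized to zero voxels; skipping", name)
            continue
        masks[name] = StructureMask(name, occ, dose_frame)
    if "PTV" not in masks:
        raise ValidationError("RTSTRUCT does not contain a PTV contour")

    isocenter = _mask_centroid_mm(masks["PTV"], grid)
    structures = StructureSet(masks, isocenter)
    rx = prescription or Prescription(50.0, 5)
    return Plan(grid, structures, rx, str(getattr(rtstruct, "PatientID", "anon")))


def _rasterize_contours(contour_seq, grid: DoseGrid) -> np.ndarray:
    """Voxel-center-inside rasterization of closed planar contours."""
    from matplotlib.path import Path as MplPath

    occ = np.zeros(grid.shape, dtype=bool)
    xs = grid.voxel_centers_mm(0)
    ys = grid.voxel_centers_mm(1)
    zs = grid.voxel_centers_mm(2)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    for item in contour_seq:
        if str(getattr(item, "ContourGeometricType", "CLOSED_PLANAR")) != "CLOSED_PLANAR":
            continue
        data = np.asarray(item.ContourData, dtype=float).reshape(-1, 3)
        z = data[0, 2]
        k = int(round((z - grid.origin[2]) / grid.spacing[2]))
        if not (0 <= k < grid.shape[2]):
            continue
        inside = MplPath(data[:, :2]).contains_points(pts).reshape(len(xs), len(ys))
        # even-odd rule: contours on the same slice toggle (supports holes)
        occ[:, :, k] ^= inside
    return occ


def _mask_centroid_mm(mask: StructureMask, grid: DoseGrid) -> np.ndarray:
    idx = np.argwhere(mask.occupancy)
    return grid.origin + idx.mean(axis=0) * grid.spacing


def read_plan(path, format: str = "portable", prescription: Prescription | None = None) -> Plan:
    """Read a plan from disk.

    ``format='portable'`` reads the directory layout written by
    :func:`write_plan`; ``format='dicom_rt'`` imports an RTDOSE/RTSTRUCT
    pair (a :class:`Prescription` must then normally be supplied, since
    RTDOSE does not carry one).
    """
    root = FsPath(path)
    if not root.exists():
        raise FormatError(f"path does not exist: {root}")
    if format == "portable":
        return _read_portable(root)
    if format == "dicom_rt":
        return _read_dicom_rt(root, prescription)
    raise ValidationError(f"unknown plan format {format!r}")


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

REPORT_COLUMNS = ["patient_id", "metric", "value", "band_low", "band_high", "category"]


def write_report(report, path, format: str = "csv") -> None:
    """Write a compliance report or cohort table as CSV or JSON.

    Accepts anything exposing ``to_frame()`` (e.g. ``ComplianceReport``) or
    a DataFrame.  Row order is deterministic; both formats carry identical
    values.
    """
    frame = report.to_frame() if hasattr(report, "to_frame") else pd.DataFrame(report)
    for col in REPORT_COLUMNS:
        if col not in frame.columns:
            frame[col] = np.nan
    frame = frame[REPORT_COLUMNS + [c for c in frame.columns if c not in REPORT_COLUMNS]]
    out = FsPath(path)
    if format == "csv":
        frame.to_csv(out, index=False)
    elif format == "json":
        frame.to_json(out, orient="records", indent=2)
    else:
        raise ValidationError(f"unknown report format {format!r}")
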