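"""Portable plan round trips, DICOM-RT import, and report writing."""

import json

import numpy as np
import pandas as pd
import pytest

from sbrtqa import Prescription, read_plan, write_plan, write_report
from sbrtqa.compliance import evaluate_plan, load_criteria
from sbrtqa.errors import FormatError, GeometryError, ValidationError
from sbrtqa.model import DoseGrid

from conftest import build_plan


@pytest.fixture
def small_plan():
    rng = np.random.default_rng(4)
    dose = rng.uniform(0, 60, (7, 6, 5))
    masks = {
        "PTV": rng.random((7, 6, 5)) < 0.3,
        "ribs": rng.random((7, 6, 5)) < 0.2,
    }
    masks["PTV"][3, 3, 2] = True
    return build_plan(dose, masks, spacing=(2.0, 2.5, 3.0), isocenter=(1.0, -2.0, 3.5))


class TestPortableFormat:
    def test_round_trip_is_bit_exact(self, small_plan, tmp_path):
        write_plan(small_plan, tmp_path / "p")
        back = read_plan(tmp_path / "p")
        np.testing.assert_array_equal(back.dose.dose, small_plan.dose.dose)
        np.testing.assert_array_equal(back.dose.origin, small_plan.dose.origin)
        np.testing.assert_array_equal(back.dose.spacing, small_plan.dose.spacing)
        assert set(back.structures.names) == set(small_plan.structures.names)
        for name in back.structures.names:
            np.testing.assert_array_equal(
                back.structures[name].occupancy, small_plan.structures[name].occupancy
            )
        np.testing.assert_array_equal(back.structures.isocenter, small_plan.structures.isocenter)
        assert back.prescription == small_plan.prescription
        assert back.patient_id == small_plan.patient_id

    def test_write_twice_is_byte_identical(self, small_plan, tmp_path):
        write_plan(small_plan, tmp_path / "a")
        write_plan(small_plan, tmp_path / "b")
        for rel in ("plan.json", "dose.f64", "masks/PTV.u8", "masks/ribs.u8"):
            assert (tmp_path / "a" / rel).read_bytes() == (tmp_path / "b" / rel).read_bytes()

    def test_empty_structure_set_rejected(self, tmp_path):
        plan = build_plan(np.ones((2, 2, 2)), {"PTV": np.ones((2, 2, 2), bool)})
        plan.structures.masks.clear()
        with pytest.raises(ValidationError):
            write_plan(plan, tmp_path / "p")

    def test_missing_path_and_corrupt_header(self, tmp_path):
        with pytest.raises(FormatError):
            read_plan(tmp_path / "nope")
        bad = tmp_path / "bad"
        bad.mkdir()
        (bad / "plan.json").write_text("{not json")
        with pytest.raises(FormatError):
            read_plan(bad)

    def test_negative_dose_rejected_at_construction(self):
        with pytest.raises(ValidationError):
            DoseGrid(np.zeros(3), np.ones(3), np.full((2, 2, 2), -1.0), "f")


# ---------------------------------------------------------------------------
# DICOM-RT fixtures built in memory with pydicom (synthetic sphere geometry)
# ---------------------------------------------------------------------------

def _write_rtdose(path, dose_xyz, origin, spacing, frame_uid):
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ImplicitVRLittleEndian, generate_uid

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.UID("1.2.840.10008.5.1.4.1.1.481.2")
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ImplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTDOSE"
    ds.FrameOfReferenceUID = frame_uid
    ds.ImagePositionPatient = [float(origin[0]), float(origin[1]), float(origin[2])]
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    ds.PixelSpacing = [float(spacing[1]), float(spacing[0])]  # row (y), col (x)
    nz = dose_xyz.shape[2]
    ds.GridFrameOffsetVector = [float(k * spacing[2]) for k in range(nz)]
    ds.NumberOfFrames = nz
    ds.Rows = dose_xyz.shape[1]
    ds.Columns = dose_xyz.shape[0]
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 32
    ds.BitsStored = 32
    ds.HighBit = 31
    ds.PixelRepresentation = 0
    scaling = max(float(dose_xyz.max()), 1e-6) / (2**31)
    ds.DoseGridScaling = scaling
    ds.DoseUnits = "GY"
    ds.DoseType = "PHYSICAL"
    ds.DoseSummationType = "PLAN"
    arr = np.round(dose_xyz.transpose(2, 1, 0) / scaling).astype("<u4")
    ds.PixelData = arr.tobytes()
    ds.save_as(path, enforce_file_format=True)


def _write_rtstruct(path, rois, frame_uid):
    """rois: {name: list of (z, Nx2 xy polygon)}"""
    import pydicom
    from pydicom.dataset import Dataset, FileDataset, FileMetaDataset
    from pydicom.uid import ImplicitVRLittleEndian, generate_uid

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.UID("1.2.840.10008.5.1.4.1.1.481.3")
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ImplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTSTRUCT"
    ds.PatientID = "dicom-test"
    ref_frame = Dataset()
    ref_frame.FrameOfReferenceUID = frame_uid
    ds.ReferencedFrameOfReferenceSequence = [ref_frame]
    ds.StructureSetROISequence = []
    ds.ROIContourSequence = []
    for num, (name, contours) in enumerate(rois.items(), start=1):
        roi = Dataset()
        roi.ROINumber = num
        roi.ROIName = name
        roi.ReferencedFrameOfReferenceUID = frame_uid
        ds.StructureSetROISequence.append(roi)
        rc = Dataset()
        rc.ReferencedROINumber = num
        rc.ContourSequence = []
        for z, poly in contours:
            item = Dataset()
            item.ContourGeometricType = "CLOSED_PLANAR"
            item.NumberOfContourPoints = len(poly)
            item.ContourData = [
                float(v) for xy in poly for v in (xy[0], xy[1], z)
            ]
            rc.ContourSequence.append(item)
        ds.ROIContourSequence.append(rc)
    ds.save_as(path, enforce_file_format=True)


def _sphere_contours(radius, center, z_values, n_pts=90):
    out = []
    for z in z_values:
        h = radius**2 - (z - center[2]) ** 2
        if h <= 0:
            continue
        rho = np.sqrt(h)
        ang = np.linspace(0, 2 * np.pi, n_pts, endpoint=False)
        poly = np.column_stack([center[0] + rho * np.cos(ang), center[1] + rho * np.sin(ang)])
        out.append((z, poly))
    return out


def _make_dicom_pair(tmp_path, spacing=1.0, frame_mismatch=False, include_ptv=True):
    from pydicom.uid import generate_uid

    n = int(round(50 / spacing)) + 1
    origin = (-25.0, -25.0, -25.0)
    ax = origin[0] + np.arange(n) * spacing
    gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij", sparse=True)
    r = np.sqrt(gx**2 + gy**2 + gz**2)
    dose = 50.0 * np.exp2(-np.maximum(r - 20.0, 0.0) / 12.0)
    frame = generate_uid()
    _write_rtdose(tmp_path / "dose.dcm", dose, origin, (spacing,) * 3, frame)
    name = "PTV" if include_ptv else "GTV"
    rois = {name: _sphere_contours(20.0, (0.2, -0.3, 0.15), ax)}
    _write_rtstruct(
        tmp_path / "struct.dcm", rois, generate_uid() if frame_mismatch else frame
    )


class TestDicomImport:
    def test_sphere_contour_volume_within_2pct(self, tmp_path):
        """A 20 mm spherical PTV rasterized on a 1 mm grid recovers the
        analytic volume 4/3*pi*r^3 = 33.51 cc within 2%."""
        _make_dicom_pair(tmp_path)
        plan = read_plan(tmp_path, format="dicom_rt", prescription=Prescription(50, 5))
        assert plan.structure_volume_cc("PTV") == pytest.approx(33.51, rel=0.02)
        assert plan.dose.dose.max() == pytest.approx(50.0, rel=1e-3)

    def test_rasterization_resolution_consistency(self, tmp_path):
        """Halving the grid spacing moves the sphere volume by < 5%."""
        (tmp_path / "fine").mkdir()
        (tmp_path / "coarse").mkdir()
        _make_dicom_pair(tmp_path / "fine", spacing=1.0)
        _make_dicom_pair(tmp_path / "coarse", spacing=2.0)
        rx = Prescription(50, 5)
        v1 = read_plan(tmp_path / "fine", format="dicom_rt", prescription=rx).structure_volume_cc("PTV")
        v2 = read_plan(tmp_path / "coarse", format="dicom_rt", prescription=rx).structure_volume_cc("PTV")
        assert abs(v1 - v2) / v1 < 0.05

    def test_frame_mismatch_raises(self, tmp_path):
        _make_dicom_pair(tmp_path, frame_mismatch=True)
        with pytest.raises(GeometryError):
            read_plan(tmp_path, format="dicom_rt")

    def test_missing_ptv_raises(self, tmp_path):
        _make_dicom_pair(tmp_path, include_ptv=False)
        with pytest.raises(ValidationError):
            read_plan(tmp_path, format="dicom_rt")


class TestReports:
    def _report(self, criteria):
        row = {"patient_id": "p1", "ptv_cc": 27.1, "r100": 1.1, "r50": 4.0,
               "d2cm_pct": 55.0, "lung_v20_pct": 3.0}
        return evaluate_plan(row, criteria)

    def test_csv_and_json_carry_identical_values(self, tmp_path):
        report = self._report(load_criteria())
        write_report(report, tmp_path / "r.csv", "csv")
        write_report(report, tmp_path / "r.json", "json")
        csv = pd.read_csv(tmp_path / "r.csv")
        js = pd.DataFrame(json.loads((tmp_path / "r.json").read_text()))
        assert len(csv) == len(report.results)
        pd.testing.assert_series_equal(
            csv["value"], js["value"], check_names=False, check_dtype=False
        )

    def test_single_metric_single_row(self, tmp_path):
        df = pd.DataFrame([{"patient_id": "p", "metric": "r100", "value": 1.0,
                            "band_low": 1.2, "band_high": 1.5, "category": "per_protocol"}])
        write_report(df, tmp_path / "one.csv")
        assert len(pd.read_csv(tmp_path / "one.csv")) == 1

    def test_empty_report_writes_header_only(self, tmp_path):
        write_report(pd.DataFrame(), tmp_path / "empty.csv")
        out = pd.read_csv(tmp_path / "empty.csv")
        assert len(out) == 0 and "metric" in out.columns

    def test_unknown_format_rejected(self, tmp_path):
        with pytest.raises(ValidationError):
            write_report(pd.DataFrame(), tmp_path / "x.xml", "xml")
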