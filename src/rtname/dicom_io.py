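"""DICOM I/O: CT series and RT Structure Set readers plus a synthetic writer.

The reader maps files into the internal data model without touching the
physician-given names: ``given_name`` is preserved byte-for-byte, so the
full variability of clinical naming (case, spaces, symbols, abbreviations)
reaches the text featurizer intact.

Only axial series (identity direction cosines) are supported. Slices are
ordered by z ascending with instance number breaking ties. Rescale slope
and intercept are applied at read time so voxels are in Hounsfield Units.

The writer emits standard-conformant CT + RT-STRUCT files for synthetic
phantoms. It is deterministic: UIDs are derived by hashing the patient id
and file role, so identical inputs produce byte-identical files. When a
record carries a ground-truth standard label it is stored in the RT ROI
Observations sequence (ROI Observation Label) and recovered on read.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .datatypes import Contour, ImageSeries, StructureRecord, StructureSet

__all__ = ["read_ct_series", "read_structure_set", "write_synthetic_dicom"]

_CT_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.2"
_RTSTRUCT_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.481.3"
_AXIAL = (1.0, 0.0, 0.0, 0.0, 1.0, 0.0)


def _deterministic_uid(*parts: str) -> str:
    digest = hashlib.sha256("/".join(parts).encode()).hexdigest()
    return generate_uid(entropy_srcs=[digest])


def read_ct_series(path: str | Path) -> ImageSeries:
    """Read one CT series (one file per slice) from a directory.

    Raises ``ValueError("no series found")`` on an empty directory and
    ``ValueError("inconsistent series")`` on mixed series UIDs, mixed
    orientations, or non-axial orientation.
    """
    path = Path(path)
    slices = []
    for f in sorted(path.glob("*")):
        if not f.is_file():
            continue
        try:
            ds = pydicom.dcmread(f)
        except Exception:
            continue
        if getattr(ds, "Modality", None) == "CT" or getattr(ds, "SOPClassUID", "") == _CT_SOP_CLASS:
            slices.append(ds)
    if not slices:
        raise ValueError("no series found")

    series_uids = {ds.SeriesInstanceUID for ds in slices}
    if len(series_uids) > 1:
        raise ValueError("inconsistent series: multiple SeriesInstanceUIDs")
    orientations = {tuple(float(v) for v in ds.ImageOrientationPatient) for ds in slices}
    if len(orientations) > 1:
        raise ValueError("inconsistent series: mixed orientations")
    orient = orientations.pop()
    if not np.allclose(orient, _AXIAL, atol=1e-6):
        raise ValueError("inconsistent series: only axial (identity orientation) supported")

    slices.sort(key=lambda ds: (float(ds.ImagePositionPatient[2]),
                                int(getattr(ds, "InstanceNumber", 0))))
    z = np.array([float(ds.ImagePositionPatient[2]) for ds in slices])
    first = slices[0]
    dy, dx = (float(v) for v in first.PixelSpacing)  # row spacing then column spacing
    dz = float(np.median(np.diff(z))) if len(z) > 1 else float(getattr(first, "SliceThickness", 1.0))
    hu = []
    for ds in slices:
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        hu.append(np.rint(ds.pixel_array.astype(np.float64) * slope + intercept).astype(np.int16))
    voxels = np.stack(hu, axis=0)
    origin = np.array([float(first.ImagePositionPatient[0]),
                       float(first.ImagePositionPatient[1]), z[0]])
    out = ImageSeries(
        voxels=voxels,
        origin=origin,
        spacing=np.array([dx, dy, dz]),
        orientation=np.eye(3),
        slice_positions=z,
        patient_id=str(getattr(first, "PatientID", "")),
    )
    out._frame_of_reference_uid = str(getattr(first, "FrameOfReferenceUID", ""))
    return out


def read_structure_set(path: str | Path, series: ImageSeries, *, strict: bool = False) -> StructureSet:
    """Read an RT Structure Set referencing ``series``.

    A frame-of-reference mismatch warns and keeps the record (multi-vendor
    exports are inconsistent in practice); pass ``strict=True`` to raise
    instead. Raises ``ValueError("no contours")`` when the file has no ROI
    contour module.
    """
    ds = pydicom.dcmread(str(path))
    if "ROIContourSequence" not in ds and "StructureSetROISequence" not in ds:
        raise ValueError("no contours: file lacks the RT ROI contour module")

    series_for = None
    for frame in getattr(ds, "ReferencedFrameOfReferenceSequence", []):
        series_for = getattr(frame, "FrameOfReferenceUID", None)

    roi_meta = {}
    for roi in getattr(ds, "StructureSetROISequence", []):
        roi_meta[int(roi.ROINumber)] = {
            "name": str(roi.ROIName),
            "for_uid": getattr(roi, "ReferencedFrameOfReferenceUID", series_for),
        }
    labels = {}
    for obs in getattr(ds, "RTROIObservationsSequence", []):
        label = getattr(obs, "ROIObservationLabel", None)
        if label:
            labels[int(obs.ReferencedROINumber)] = str(label)

    contours_by_roi: dict[int, list[Contour]] = {n: [] for n in roi_meta}
    for item in getattr(ds, "ROIContourSequence", []):
        n = int(item.ReferencedROINumber)
        contours_by_roi.setdefault(n, [])
        for c in getattr(item, "ContourSequence", []):
            data = np.asarray([float(v) for v in c.ContourData]).reshape(-1, 3)
            contours_by_roi[n].append(Contour(slice_z=float(data[0, 2]), points=data[:, :2]))

    expected_for = getattr(series, "_frame_of_reference_uid", None)
    records = []
    patient_id = str(getattr(ds, "PatientID", series.patient_id))
    for n in sorted(roi_meta):
        meta = roi_meta[n]
        if expected_for and meta["for_uid"] and meta["for_uid"] != expected_for:
            msg = f"frame-of-reference mismatch for ROI {meta['name']!r}"
            if strict:
                raise ValueError(msg)
            warnings.warn(msg, stacklevel=2)
        records.append(StructureRecord(
            given_name=meta["name"],
            contours=contours_by_roi.get(n, []),
            true_label=labels.get(n),
            patient_id=patient_id,
        ))
    return StructureSet(records=records, patient_id=patient_id)


def write_synthetic_dicom(series: ImageSeries, sset: StructureSet, path: str | Path) -> dict:
    """Write a synthetic CT series (one file per slice) plus an RT-STRUCT.

    Round trip through the readers is lossless: names exactly, coordinates
    within 1e-3 mm, HU within rescale quantization. Returns a manifest dict
    (also written as ``manifest.json``) listing the emitted files.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    pid = series.patient_id or "ANON"
    study_uid = _deterministic_uid(pid, "study")
    series_uid = _deterministic_uid(pid, "ct-series")
    for_uid = _deterministic_uid(pid, "frame")

    nz, ny, nx = series.voxels.shape
    ct_files = []
    sop_uids = []
    for k in range(nz):
        sop_uid = _deterministic_uid(pid, "ct", str(k))
        sop_uids.append(sop_uid)
        ds = Dataset()
        ds.SOPClassUID = _CT_SOP_CLASS
        ds.SOPInstanceUID = sop_uid
        ds.Modality = "CT"
        ds.PatientID = pid
        ds.PatientName = pid
        ds.StudyInstanceUID = study_uid
        ds.SeriesInstanceUID = series_uid
        ds.FrameOfReferenceUID = for_uid
        ds.InstanceNumber = k + 1
        ds.ImageOrientationPatient = list(_AXIAL)
        ds.ImagePositionPatient = [float(series.origin[0]), float(series.origin[1]),
                                   float(series.slice_positions[k])]
        ds.PixelSpacing = [float(series.spacing[1]), float(series.spacing[0])]
        ds.SliceThickness = float(series.spacing[2])
        ds.Rows, ds.Columns = ny, nx
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1
        ds.RescaleSlope = "1"
        ds.RescaleIntercept = "0"
        ds.PixelData = np.ascontiguousarray(series.voxels[k].astype(np.int16)).tobytes()
        fname = path / f"CT_{k:04d}.dcm"
        _save(ds, fname)
        ct_files.append(fname.name)

    rs = Dataset()
    rs.SOPClassUID = _RTSTRUCT_SOP_CLASS
    rs.SOPInstanceUID = _deterministic_uid(pid, "rtstruct")
    rs.Modality = "RTSTRUCT"
    rs.PatientID = pid
    rs.PatientName = pid
    rs.StudyInstanceUID = study_uid
    rs.SeriesInstanceUID = _deterministic_uid(pid, "rtstruct-series")
    rs.StructureSetLabel = "SYNTHETIC"

    ref_frame = Dataset()
    ref_frame.FrameOfReferenceUID = for_uid
    rs.ReferencedFrameOfReferenceSequence = [ref_frame]

    roi_seq, contour_seq, obs_seq = [], [], []
    for n, rec in enumerate(sset.records, start=1):
        roi = Dataset()
        roi.ROINumber = n
        roi.ROIName = rec.given_name
        roi.ReferencedFrameOfReferenceUID = for_uid
        roi.ROIGenerationAlgorithm = "AUTOMATIC"
        roi_seq.append(roi)

        item = Dataset()
        item.ReferencedROINumber = n
        cseq = []
        for contour in rec.contours:
            c = Dataset()
            c.ContourGeometricType = "CLOSED_PLANAR"
            pts = np.column_stack([contour.points,
                                   np.full(len(contour.points), contour.slice_z)])
            c.NumberOfContourPoints = len(contour.points)
            c.ContourData = [f"{v:.4f}" for v in pts.ravel()]
            cseq.append(c)
        item.ContourSequence = cseq
        contour_seq.append(item)

        obs = Dataset()
        obs.ObservationNumber = n
        obs.ReferencedROINumber = n
        if rec.true_label is not None:
            obs.ROIObservationLabel = rec.true_label
        obs.RTROIInterpretedType = ""
        obs.ROIInterpreter = ""
        obs_seq.append(obs)

    rs.StructureSetROISequence = roi_seq
    rs.ROIContourSequence = contour_seq
    rs.RTROIObservationsSequence = obs_seq
    rtstruct_name = "RS_structures.dcm"
    _save(rs, path / rtstruct_name)

    manifest = {
        "patient_id": pid,
        "ct_files": ct_files,
        "rtstruct_file": rtstruct_name,
        "n_structures": len(sset.records),
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _save(ds: Dataset, filename: Path) -> None:
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = ds.SOPClassUID
    meta.MediaStorageSOPInstanceUID = ds.SOPInstanceUID
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds.file_meta = meta
    ds.save_as(str(filename), enforce_file_format=True)
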