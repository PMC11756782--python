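"""DICOM RT Dose / RT Structure Set ingest (and a minimal writer).

Real plans arrive as an RT Dose grid plus an RT Structure Set of contours.
Ingest scales stored dose values by ``DoseGridScaling`` to Gy and rasterizes
the named ROI's axial contours onto the dose grid with a voxel-center-in-
polygon test per slice. Only axis-aligned axial geometry (identity
ImageOrientationPatient) is supported.

The writer emits a matching synthetic RT Dose / RT Structure Set pair; it
exists for round-trip interoperability tests and for exporting phantoms to
other planning tools.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pydicom
from matplotlib.path import Path as MplPath
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .geometry import DoseGrid, Grid3D, StructureMask

__all__ = ["ingest_dicom", "write_rt_dose", "write_rt_struct"]

RT_DOSE_SOP = "1.2.840.10008.5.1.4.1.1.481.2"
RT_STRUCT_SOP = "1.2.840.10008.5.1.4.1.1.481.3"

# Internal array convention: axis 0 = x (columns), 1 = y (rows), 2 = z (slices).
# DICOM pixel_array is (frames, rows, cols) = (z, y, x).


def _read_dose(path: str | Path) -> DoseGrid:
    ds = pydicom.dcmread(str(path))
    if ds.SOPClassUID != RT_DOSE_SOP:
        raise ValueError(f"{path} is not an RT Dose object")
    orient = [float(v) for v in ds.ImageOrientationPatient]
    if not np.allclose(orient, [1, 0, 0, 0, 1, 0]):
        raise ValueError("only axial identity orientation is supported")
    scaling = float(ds.DoseGridScaling)
    arr = ds.pixel_array.astype(np.float64) * scaling  # (z, y, x)
    values = np.transpose(arr, (2, 1, 0))  # -> (x, y, z)
    dy, dx = (float(v) for v in ds.PixelSpacing)
    offsets = np.asarray([float(v) for v in ds.GridFrameOffsetVector])
    dz_all = np.diff(offsets)
    if offsets.size > 1 and not np.allclose(dz_all, dz_all[0]):
        raise ValueError("non-uniform slice spacing is not supported")
    dz = float(dz_all[0]) if offsets.size > 1 else 1.0
    ipp = [float(v) for v in ds.ImagePositionPatient]  # center of first voxel
    spacing = (dx, dy, dz)
    origin = tuple(ipp[a] - 0.5 * spacing[a] for a in range(3))
    grid = Grid3D(shape=values.shape, spacing=spacing, origin=origin)
    return DoseGrid(values, grid)


def _rasterize_roi(ds_struct: pydicom.Dataset, roi_name: str,
                   grid: Grid3D) -> StructureMask:
    names = {r.ROIName: int(r.ROINumber) for r in ds_struct.StructureSetROISequence}
    if roi_name not in names:
        raise ValueError(f"ROI {roi_name!r} not found; available: {sorted(names)}")
    number = names[roi_name]
    contour_seq = None
    for rc in ds_struct.ROIContourSequence:
        if int(rc.ReferencedROINumber) == number:
            contour_seq = getattr(rc, "ContourSequence", [])
            break
    voxels = np.zeros(grid.shape, dtype=bool)
    xc = grid.axis_centers(0)
    yc = grid.axis_centers(1)
    zc = grid.axis_centers(2)
    gx, gy = np.meshgrid(xc, yc, indexing="ij")
    centers = np.column_stack([gx.ravel(), gy.ravel()])
    for contour in contour_seq or []:
        if contour.ContourGeometricType != "CLOSED_PLANAR":
            raise ValueError("only CLOSED_PLANAR axial contours are supported")
        pts = np.asarray([float(v) for v in contour.ContourData]).reshape(-1, 3)
        if not np.allclose(pts[:, 2], pts[0, 2], atol=1e-3):
            raise ValueError("non-axial contour")
        k = int(np.argmin(np.abs(zc - pts[0, 2])))
        if abs(zc[k] - pts[0, 2]) > grid.spacing[2]:
            continue  # contour plane outside the dose grid
        inside = MplPath(pts[:, :2]).contains_points(centers)
        voxels[:, :, k] |= inside.reshape(len(xc), len(yc))
    return StructureMask(voxels, grid, label=roi_name)


def ingest_dicom(rtdose_path: str | Path, rtstruct_path: str | Path,
                 roi_name: str) -> tuple[DoseGrid, StructureMask]:
    """Load an RT Dose grid (Gy) and rasterize one named ROI onto it."""
    dose = _read_dose(rtdose_path)
    ds_struct = pydicom.dcmread(str(rtstruct_path))
    if ds_struct.SOPClassUID != RT_STRUCT_SOP:
        raise ValueError(f"{rtstruct_path} is not an RT Structure Set")
    mask = _rasterize_roi(ds_struct, roi_name, dose.grid)
    return dose, mask


def _file_meta(sop_class: str, sop_instance: str) -> FileMetaDataset:
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = sop_class
    meta.MediaStorageSOPInstanceUID = sop_instance
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    return meta


def _common_fields(ds: Dataset, modality: str, frame_uid: str) -> None:
    ds.PatientName = "Synthetic^Phantom"
    ds.PatientID = "LAMELLA"
    ds.StudyInstanceUID = generate_uid(entropy_srcs=["lamella-study", frame_uid])
    ds.SeriesInstanceUID = generate_uid(entropy_srcs=["lamella-series", modality, frame_uid])
    ds.FrameOfReferenceUID = frame_uid
    ds.Modality = modality
    ds.StudyDate = "20240101"
    ds.StudyTime = "000000"


def write_rt_dose(dose: DoseGrid, path: str | Path,
                  frame_uid: str | None = None,
                  scaling: float = 1e-5) -> str:
    """Write a dose grid as a synthetic RT Dose object; returns the
    FrameOfReferenceUID so a matching structure set can reference it."""
    grid = dose.grid
    frame_uid = frame_uid or generate_uid(entropy_srcs=["lamella-frame", repr(grid)])
    sop_instance = generate_uid(entropy_srcs=["lamella-dose", repr(grid)])
    ds = Dataset()
    ds.file_meta = _file_meta(RT_DOSE_SOP, sop_instance)
    ds.SOPClassUID = RT_DOSE_SOP
    ds.SOPInstanceUID = sop_instance
    _common_fields(ds, "RTDOSE", frame_uid)
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    ds.ImagePositionPatient = [grid.origin[a] + 0.5 * grid.spacing[a] for a in range(3)]
    ds.PixelSpacing = [grid.spacing[1], grid.spacing[0]]  # row (y), col (x)
    ds.GridFrameOffsetVector = [k * grid.spacing[2] for k in range(grid.shape[2])]
    ds.DoseUnits = "GY"
    ds.DoseType = "PHYSICAL"
    ds.DoseSummationType = "PLAN"
    ds.DoseGridScaling = scaling
    stored = np.round(dose.values / scaling).astype(np.uint32)
    arr = np.transpose(stored, (2, 1, 0))  # (x,y,z) -> (frames=z, rows=y, cols=x)
    ds.NumberOfFrames = grid.shape[2]
    ds.Rows, ds.Columns = grid.shape[1], grid.shape[0]
    ds.BitsAllocated = 32
    ds.BitsStored = 32
    ds.HighBit = 31
    ds.PixelRepresentation = 0
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.PixelData = np.ascontiguousarray(arr).tobytes()
    ds.save_as(str(path), enforce_file_format=True)
    return frame_uid


def write_rt_struct(mask: StructureMask, path: str | Path, frame_uid: str,
                    roi_name: str = "GTV") -> None:
    """Write a structure set tracing a mask with per-slice polygons.

    Each axial slice is traced with marching squares at the 0.5 level; the
    midpoint contour separates inside from outside voxel centers, so a
    voxel-center-in-polygon re-ingest on the same grid recovers the mask
    exactly.
    """
    from skimage import measure

    grid = mask.grid
    sop_instance = generate_uid(entropy_srcs=["lamella-struct", repr(grid), roi_name])
    ds = Dataset()
    ds.file_meta = _file_meta(RT_STRUCT_SOP, sop_instance)
    ds.SOPClassUID = RT_STRUCT_SOP
    ds.SOPInstanceUID = sop_instance
    _common_fields(ds, "RTSTRUCT", frame_uid)
    ds.StructureSetLabel = "lamella"

    roi = Dataset()
    roi.ROINumber = 1
    roi.ROIName = roi_name
    roi.ReferencedFrameOfReferenceUID = frame_uid
    roi.ROIGenerationAlgorithm = "AUTOMATIC"
    ds.StructureSetROISequence = [roi]

    contours = []
    xc, yc, zc = (grid.axis_centers(a) for a in range(3))
    for k in range(grid.shape[2]):
        sl = mask.voxels[:, :, k].astype(float)
        if not sl.any():
            continue
        for poly in measure.find_contours(np.pad(sl, 1), 0.5):
            ij = poly - 1.0  # remove pad
            xs = np.interp(ij[:, 0], np.arange(len(xc)), xc)
            ys = np.interp(ij[:, 1], np.arange(len(yc)), yc)
            c = Dataset()
            c.ContourGeometricType = "CLOSED_PLANAR"
            c.NumberOfContourPoints = len(xs)
            data = np.column_stack([xs, ys, np.full(len(xs), zc[k])]).ravel()
            c.ContourData = [f"{v:.4f}" for v in data]
            contours.append(c)
    rc = Dataset()
    rc.ReferencedROINumber = 1
    rc.ContourSequence = contours
    ds.ROIContourSequence = [rc]

    obs = Dataset()
    obs.ObservationNumber = 1
    obs.ReferencedROINumber = 1
    obs.RTROIInterpretedType = "GTV"
    ds.RTROIObservationsSequence = [obs]
    ds.save_as(str(path), enforce_file_format=True)
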