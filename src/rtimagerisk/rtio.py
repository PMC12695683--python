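"""DICOM-RT input/output and grid operations.

Reads and writes RTDOSE and RTSTRUCT objects with pydicom, rasterizes
planar contours to voxel masks on a dose lattice, resamples dose grids
between lattices, and accumulates treatment + per-fraction imaging dose
over a course.

Contour rasterization uses voxel-centre sampling with the even-odd rule
(nested contours on one slice toggle in/out), the convention common to
treatment-planning DVH engines; points within ``BOUNDARY_TOL`` of a polygon
edge count as inside.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid
from scipy import ndimage

from .errors import (
    DicomFormatError,
    DicomTypeError,
    EmptyMaskError,
    GridMismatchError,
    ROINotFoundError,
)
from .grids import IDENTITY_ORIENTATION, ROI, DoseGrid, ROIMask, ProtocolSpec, StructureSet

logger = logging.getLogger(__name__)

RTDOSE_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.481.2"
RTSTRUCT_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.481.3"
CT_SOP_CLASS = "1.2.840.10008.5.1.2.1.1.2"

#: tolerance (mm) within which a voxel centre on a contour edge counts inside
BOUNDARY_TOL = 1e-9

#: UID root used for deterministic synthetic-object UIDs
_UID_PREFIX = "2.25."


def deterministic_uid(*entropy) -> str:
    """A DICOM UID that is a pure function of its entropy sources.

    Needed so regeneration of a synthetic cohort under a fixed seed is
    byte-identical.
    """
    return generate_uid(prefix=_UID_PREFIX, entropy_srcs=[str(e) for e in entropy])


# ---------------------------------------------------------------------------
# RTDOSE
# ---------------------------------------------------------------------------

_RTDOSE_REQUIRED = (
    "ImagePositionPatient",
    "PixelSpacing",
    "Rows",
    "Columns",
    "DoseGridScaling",
)


def read_rtdose(path) -> DoseGrid:
    """Read an RTDOSE file into a :class:`DoseGrid` in Gy.

    Applies DoseGridScaling to the stored integer pixel data. Raises
    :class:`DicomTypeError` for non-dose objects and
    :class:`DicomFormatError` naming the first missing mandatory tag.
    """
    try:
        ds = pydicom.dcmread(path)
    except Exception as exc:  # pydicom raises several error types
        raise DicomFormatError(f"cannot parse DICOM file {path}: {exc}") from exc
    modality = getattr(ds, "Modality", None)
    if modality != "RTDOSE":
        raise DicomTypeError(f"{path}: expected RTDOSE, got modality {modality!r}")
    for tag in _RTDOSE_REQUIRED:
        if tag not in ds:
            raise DicomFormatError(f"{path}: missing mandatory tag {tag}")
    origin = np.asarray([float(v) for v in ds.ImagePositionPatient])
    row_spacing, col_spacing = (float(v) for v in ds.PixelSpacing)
    n_frames = int(getattr(ds, "NumberOfFrames", 1))
    if n_frames > 1:
        if "GridFrameOffsetVector" not in ds:
            raise DicomFormatError(f"{path}: missing mandatory tag GridFrameOffsetVector")
        offsets = np.asarray([float(v) for v in ds.GridFrameOffsetVector])
        dz_steps = np.diff(offsets)
        if len(dz_steps) == 0 or not np.allclose(dz_steps, dz_steps[0], atol=1e-6):
            raise DicomFormatError(f"{path}: non-uniform GridFrameOffsetVector")
        dz = float(dz_steps[0])
        origin = origin + np.array([0.0, 0.0, offsets[0]])
    else:
        dz = float(getattr(ds, "SliceThickness", 1.0) or 1.0)
    orientation = tuple(
        float(v) for v in getattr(ds, "ImageOrientationPatient", IDENTITY_ORIENTATION)
    )
    scaling = float(ds.DoseGridScaling)
    values = ds.pixel_array.astype(np.float64) * scaling
    values = values.reshape(n_frames, int(ds.Rows), int(ds.Columns))
    return DoseGrid(
        origin=origin,
        spacing=np.array([col_spacing, row_spacing, dz]),
        values=values,
        orientation=orientation,
        frame_ref=str(getattr(ds, "FrameOfReferenceUID", "")),
    )


def write_rtdose(grid: DoseGrid, path, *, uid_entropy=("rtdose",)) -> None:
    """Write a :class:`DoseGrid` as an RTDOSE file.

    Dose is quantized to 32-bit unsigned integers with a per-file
    DoseGridScaling chosen so the maximum dose maps near full range.
    All UIDs and dates are deterministic functions of ``uid_entropy`` so
    identical grids produce byte-identical files.
    """
    nz, ny, nx = grid.values.shape
    max_dose = float(grid.values.max())
    scaling = max_dose / (2**32 - 1) if max_dose > 0 else 1e-9
    stored = np.round(grid.values / scaling).astype(np.uint32)

    file_meta = FileMetaDataset()
    file_meta.MediaStorageSOPClassUID = RTDOSE_SOP_CLASS
    file_meta.MediaStorageSOPInstanceUID = deterministic_uid("sop", *uid_entropy)
    file_meta.TransferSyntaxUID = ExplicitVRLittleEndian
    file_meta.ImplementationClassUID = deterministic_uid("impl", "rtimagerisk")

    ds = FileDataset(str(path), {}, file_meta=file_meta, preamble=b"\0" * 128)
    ds.SOPClassUID = RTDOSE_SOP_CLASS
    ds.SOPInstanceUID = file_meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTDOSE"
    ds.SeriesInstanceUID = deterministic_uid("series", *uid_entropy)
    ds.StudyInstanceUID = deterministic_uid("study", *uid_entropy)
    ds.FrameOfReferenceUID = grid.frame_ref or deterministic_uid("for", *uid_entropy)
    ds.ContentDate = "20250101"
    ds.ContentTime = "000000"
    ds.PatientName = ""
    ds.PatientID = ""
    ds.ImagePositionPatient = [float(v) for v in grid.origin]
    ds.ImageOrientationPatient = [float(v) for v in grid.orientation]
    ds.PixelSpacing = [float(grid.spacing[1]), float(grid.spacing[0])]  # row, col
    ds.SliceThickness = float(grid.spacing[2])
    ds.Rows = ny
    ds.Columns = nx
    ds.NumberOfFrames = nz
    ds.GridFrameOffsetVector = [float(k * grid.spacing[2]) for k in range(nz)]
    ds.DoseUnits = "GY"
    ds.DoseType = "PHYSICAL"
    ds.DoseSummationType = "PLAN"
    ds.DoseGridScaling = scaling
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 32
    ds.BitsStored = 32
    ds.HighBit = 31
    ds.PixelRepresentation = 0
    ds.PixelData = stored.tobytes()
    ds.save_as(str(path), enforce_file_format=True)


# ---------------------------------------------------------------------------
# RTSTRUCT
# ---------------------------------------------------------------------------


def read_rtstruct(path, name_map: dict | None = None) -> StructureSet:
    """Read an RTSTRUCT into a :class:`StructureSet`.

    ``name_map`` maps raw ROI names to canonical ones; unmapped ROIs keep
    their raw names, and ROIs mapping to the same canonical name are merged.
    Contours with fewer than 3 points are skipped with a warning.
    """
    try:
        ds = pydicom.dcmread(path)
    except Exception as exc:
        raise DicomFormatError(f"cannot parse DICOM file {path}: {exc}") from exc
    modality = getattr(ds, "Modality", None)
    if modality != "RTSTRUCT":
        raise DicomTypeError(f"{path}: expected RTSTRUCT, got modality {modality!r}")
    name_map = name_map or {}

    roi_names = {}
    for item in getattr(ds, "StructureSetROISequence", []):
        roi_names[int(item.ROINumber)] = str(item.ROIName)

    frame_ref = ""
    for item in getattr(ds, "ReferencedFrameOfReferenceSequence", []):
        frame_ref = str(getattr(item, "FrameOfReferenceUID", ""))
        break
    if not frame_ref:
        frame_ref = str(getattr(ds, "FrameOfReferenceUID", ""))

    merged: dict[str, ROI] = {}
    contour_seq = getattr(ds, "ROIContourSequence", None)
    if not contour_seq:
        warnings.warn(f"{path}: structure set contains no contour data")
        return StructureSet(rois=[], frame_ref=frame_ref)
    for item in contour_seq:
        number = int(item.ReferencedROINumber)
        raw = roi_names.get(number, f"ROI_{number}")
        canonical = name_map.get(raw, raw)
        roi = merged.setdefault(canonical, ROI(name=canonical))
        for c in getattr(item, "ContourSequence", []):
            pts = np.asarray([float(v) for v in c.ContourData]).reshape(-1, 3)
            if pts.shape[0] < 3:
                warnings.warn(
                    f"{path}: skipping malformed contour (<3 points) in ROI {raw!r}"
                )
                continue
            roi.contours.append(pts)
    return StructureSet(rois=list(merged.values()), frame_ref=frame_ref)


def write_rtstruct(structure: StructureSet, path, *, uid_entropy=("rtstruct",)) -> None:
    """Write a :class:`StructureSet` as an RTSTRUCT file (deterministic UIDs)."""
    file_meta = FileMetaDataset()
    file_meta.MediaStorageSOPClassUID = RTSTRUCT_SOP_CLASS
    file_meta.MediaStorageSOPInstanceUID = deterministic_uid("sop", *uid_entropy)
    file_meta.TransferSyntaxUID = ExplicitVRLittleEndian
    file_meta.ImplementationClassUID = deterministic_uid("impl", "rtimagerisk")

    ds = FileDataset(str(path), {}, file_meta=file_meta, preamble=b"\0" * 128)
    ds.SOPClassUID = RTSTRUCT_SOP_CLASS
    ds.SOPInstanceUID = file_meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTSTRUCT"
    ds.SeriesInstanceUID = deterministic_uid("series", *uid_entropy)
    ds.StudyInstanceUID = deterministic_uid("study", *uid_entropy)
    ds.StructureSetLabel = "SYNTH"
    ds.StructureSetDate = "20250101"
    ds.StructureSetTime = "000000"
    ds.PatientName = ""
    ds.PatientID = ""

    ref_frame = Dataset()
    ref_frame.FrameOfReferenceUID = structure.frame_ref or deterministic_uid(
        "for", *uid_entropy
    )
    ds.ReferencedFrameOfReferenceSequence = [ref_frame]

    ss_seq, contour_seq = [], []
    for i, roi in enumerate(structure.rois, start=1):
        ss_item = Dataset()
        ss_item.ROINumber = i
        ss_item.ROIName = roi.name
        ss_item.ReferencedFrameOfReferenceUID = ref_frame.FrameOfReferenceUID
        ss_item.ROIGenerationAlgorithm = "AUTOMATIC"
        ss_seq.append(ss_item)

        c_item = Dataset()
        c_item.ReferencedROINumber = i
        contours = []
        for pts in roi.contours:
            c = Dataset()
            c.ContourGeometricType = "CLOSED_PLANAR"
            c.NumberOfContourPoints = int(pts.shape[0])
            c.ContourData = [float(v) for v in np.asarray(pts).ravel()]
            contours.append(c)
        c_item.ContourSequence = contours
        contour_seq.append(c_item)
    ds.StructureSetROISequence = ss_seq
    ds.ROIContourSequence = contour_seq
    ds.save_as(str(path), enforce_file_format=True)


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------


def points_in_polygon(points: np.ndarray, polygon: np.ndarray,
                      boundary_tol: float = BOUNDARY_TOL) -> np.ndarray:
    """Even-odd containment test of 2-D points against one closed polygon.

    Crossing-count parity along a +x ray; points within ``boundary_tol`` of
    any edge count as inside. Vectorized over points and edges.
    """
    points = np.asarray(points, dtype=float)
    poly = np.asarray(polygon, dtype=float)[:, :2]
    px = points[:, 0][:, None]
    py = points[:, 1][:, None]
    x1, y1 = poly[:, 0][None, :], poly[:, 1][None, :]
    x2 = np.roll(poly[:, 0], -1)[None, :]
    y2 = np.roll(poly[:, 1], -1)[None, :]

    # parity of edges whose span straddles the point's y, crossed to the right
    straddles = (y1 > py) != (y2 > py)
    with np.errstate(divide="ignore", invalid="ignore"):
        x_int = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
    crossings = straddles & (px < x_int)
    inside = (crossings.sum(axis=1) % 2).astype(bool)

    # boundary inclusion: distance from point to each edge segment
    ex, ey = x2 - x1, y2 - y1
    seg_len2 = ex * ex + ey * ey
    seg_len2 = np.where(seg_len2 == 0, 1.0, seg_len2)
    t = ((px - x1) * ex + (py - y1) * ey) / seg_len2
    t = np.clip(t, 0.0, 1.0)
    dx, dy = px - (x1 + t * ex), py - (y1 + t * ey)
    on_edge = (dx * dx + dy * dy <= boundary_tol**2).any(axis=1)
    return inside | on_edge


def rasterize(structure: StructureSet, roi_name: str, grid: DoseGrid) -> ROIMask:
    """Voxelize one ROI's contours onto a dose grid lattice.

    A voxel is inside iff its centre lies inside the contour polygon(s) of
    the slice the contour is assigned to (nearest z-centre, tolerance half
    a slice spacing); multiple polygons on one slice combine by the even-odd
    rule, so nested contours carve holes.
    """
    if structure.frame_ref and grid.frame_ref and structure.frame_ref != grid.frame_ref:
        raise GridMismatchError(
            f"frame of reference mismatch: {structure.frame_ref} != {grid.frame_ref}"
        )
    try:
        roi = structure[roi_name]
    except KeyError:
        raise ROINotFoundError(f"ROI {roi_name!r} not in structure set") from None

    nz, ny, nx = grid.values.shape
    x, y, z = grid.axis_centers()
    xx, yy = np.meshgrid(x, y)  # (ny, nx)
    centers = np.column_stack([xx.ravel(), yy.ravel()])
    dz = grid.spacing[2]

    inside = np.zeros((nz, ny, nx), dtype=bool)
    for pts in roi.contours:
        z_vals = pts[:, 2]
        if np.ptp(z_vals) > 1e-6:
            warnings.warn(
                f"ROI {roi_name!r}: contour not planar (z spread {np.ptp(z_vals):.3g} mm), skipped"
            )
            continue
        zc = float(z_vals.mean())
        k = int(np.round((zc - grid.origin[2]) / dz))
        if k < 0 or k >= nz or abs(zc - z[k]) > dz / 2 + 1e-9:
            continue  # contour farther than half a slice from any slice centre
        plane_mask = points_in_polygon(centers, pts).reshape(ny, nx)
        inside[k] ^= plane_mask  # even-odd across polygons on the same slice

    if not inside.any():
        raise EmptyMaskError(f"ROI {roi_name!r} rasterized to an empty mask")
    return ROIMask(grid_ref=grid, inside=inside, roi_name=roi_name)


# ---------------------------------------------------------------------------
# Resampling and accumulation
# ---------------------------------------------------------------------------


def resample_to(grid: DoseGrid, target: DoseGrid) -> DoseGrid:
    """Resample a dose grid onto the lattice of ``target``.

    Trilinear interpolation at the target voxel centres; points outside the
    source extent get 0 Gy. If the geometries are identical the values are
    returned unchanged.
    """
    if grid.same_lattice(target):
        return target.with_values(grid.values.copy())

    tx, ty, tz = target.axis_centers()
    # fractional index of each target centre in the source lattice
    ix = (tx - grid.origin[0]) / grid.spacing[0]
    iy = (ty - grid.origin[1]) / grid.spacing[1]
    iz = (tz - grid.origin[2]) / grid.spacing[2]
    kk, jj, ii = np.meshgrid(iz, iy, ix, indexing="ij")
    coords = np.stack([kk.ravel(), jj.ravel(), ii.ravel()])
    out = ndimage.map_coordinates(
        grid.values, coords, order=1, mode="constant", cval=0.0
    ).reshape(target.values.shape)
    if not out.any() and grid.values.any():
        warnings.warn("resample_to: source and target extents do not overlap; all-zero result")
    return target.with_values(out)


def accumulate_course(
    treatment: DoseGrid | None,
    imaging_per_fraction: DoseGrid,
    protocol: ProtocolSpec,
    reference_mu: float,
) -> DoseGrid:
    """Total course dose: treatment plus MU-scaled per-fraction imaging dose.

    ``total = treatment + (mu_per_fraction / reference_mu) * imaging * n_fractions``

    The per-fraction imaging grid corresponds to an acquisition at
    ``reference_mu`` monitor units; imaging dose is scaled linearly in MU.
    Passing ``treatment=None`` gives the imaging-only accumulation (the
    treatment term set to zero).
    """
    scale = (protocol.mu_per_fraction / reference_mu) * protocol.n_fractions
    total = imaging_per_fraction.values * scale
    if treatment is not None:
        if not treatment.same_lattice(imaging_per_fraction):
            raise GridMismatchError(
                "treatment and imaging grids are not on the same lattice; resample first"
            )
        total = total + treatment.values
    return imaging_per_fraction.with_values(total)
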