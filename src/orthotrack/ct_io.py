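"""CT volume containers and clinical 4DCT / RT-STRUCT input.

Volumes are axis-aligned scalar grids in Hounsfield units.  Voxel ``(i, j,
k)`` has its center at ``origin + (i, j, k) * spacing`` in the room frame
(x = LR, y = AP, z = SI); arrays are indexed ``voxels[i, j, k]`` = (x, y, z).

Besides reading clinical data, this module builds the "GTV-only" companion
volume used for label generation: every voxel outside the tumor mask is set
to air (-1000 HU) so that a projection of the volume shows the tumor's
radiological footprint alone.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pydicom
from matplotlib.path import Path as MplPath
from pydicom.dataset import Dataset, FileDataset, FileMetaDataset
from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, RTStructureSetStorage, generate_uid

__all__ = [
    "AIR_HU",
    "CTVolume",
    "GTVMask",
    "MissingSliceError",
    "MixedSeriesError",
    "ROINotFoundError",
    "ContourPlaneError",
    "read_ct_series",
    "write_ct_series",
    "build_rtstruct",
    "extract_gtv_mask",
    "gtv_only_volume",
    "save_volume",
    "load_volume",
]

AIR_HU = -1000.0


class MixedSeriesError(ValueError):
    """Directory contains slices from more than one CT series."""


class MissingSliceError(ValueError):
    """Gap detected in the slice positions of a CT series."""


class ROINotFoundError(KeyError):
    """Requested ROI name is absent (or empty) in the structure set."""


class ContourPlaneError(ValueError):
    """A contour plane does not coincide with any volume slice."""


@dataclass(eq=False)
class CTVolume:
    """HU scalar grid for one respiratory phase."""

    voxels: np.ndarray  # (nx, ny, nz) float32, HU
    spacing: np.ndarray  # (3,) mm
    origin: np.ndarray  # (3,) mm, center of voxel (0, 0, 0)
    phase: int = 0

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float32)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3D array")
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be positive")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("HU values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def voxel_centers_1d(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis world coordinates of voxel centers."""
        return tuple(
            self.origin[a] + np.arange(self.shape[a]) * self.spacing[a] for a in range(3)
        )  # type: ignore[return-value]


@dataclass(eq=False)
class GTVMask:
    """Binary tumor mask aligned to a :class:`CTVolume`."""

    voxels: np.ndarray  # (nx, ny, nz) bool
    phase: int = 0

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=bool)
        if self.voxels.ndim != 3:
            raise ValueError("mask must be a 3D array")
        if not self.voxels.any():
            raise ValueError("GTV mask is empty")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    def voxel_count(self) -> int:
        return int(self.voxels.sum())


# ---------------------------------------------------------------------------
# DICOM CT series


def read_ct_series(directory) -> CTVolume:
    """Read one single-phase DICOM CT series from ``directory``.

    Slices are sorted by their z position; the HU rescale (slope/intercept)
    is applied.  Raises :class:`MixedSeriesError` for slices of different
    series and :class:`MissingSliceError` when slice positions are not
    uniformly spaced (a removed slice).
    """
    directory = Path(directory)
    files = sorted(p for p in directory.iterdir() if p.suffix.lower() == ".dcm")
    if not files:
        raise FileNotFoundError(f"no DICOM files in {directory}")
    datasets = [pydicom.dcmread(str(p)) for p in files]
    uids = {str(ds.SeriesInstanceUID) for ds in datasets}
    if len(uids) != 1:
        raise MixedSeriesError(f"found {len(uids)} series in {directory}")
    datasets.sort(key=lambda ds: float(ds.ImagePositionPatient[2]))
    zs = np.array([float(ds.ImagePositionPatient[2]) for ds in datasets])
    if len(zs) < 2:
        raise ValueError("CT series needs at least 2 slices")
    gaps = np.diff(zs)
    dz = float(np.median(gaps))
    if dz <= 0 or np.any(np.abs(gaps - dz) > 0.01 * dz):
        raise MissingSliceError("non-uniform slice positions (missing slice?)")
    first = datasets[0]
    sp_row, sp_col = (float(x) for x in first.PixelSpacing)  # row=y, col=x
    slices = []
    for ds in datasets:
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        hu = ds.pixel_array.astype(np.float32) * slope + intercept
        slices.append(hu.T)  # (rows=y, cols=x) -> (x, y)
    voxels = np.stack(slices, axis=-1)  # (x, y, z)
    origin = np.array(
        [float(first.ImagePositionPatient[0]), float(first.ImagePositionPatient[1]), zs[0]]
    )
    return CTVolume(voxels=voxels, spacing=np.array([sp_col, sp_row, dz]), origin=origin)


def write_ct_series(volume: CTVolume, directory, series_uid: str | None = None) -> list[Path]:
    """Export a volume as an axial DICOM CT series (one file per slice)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    series_uid = series_uid or generate_uid()
    study_uid = generate_uid()
    frame_uid = generate_uid()
    now = datetime.datetime.now()
    stored = np.clip(np.rint(volume.voxels + 1024.0), 0, 65535).astype(np.uint16)
    paths = []
    for k in range(volume.shape[2]):
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = CTImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
        ds.SOPClassUID = CTImageStorage
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.Modality = "CT"
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.FrameOfReferenceUID = frame_uid
        ds.PatientName = "PHANTOM"
        ds.PatientID = "PHANTOM"
        ds.ContentDate = now.strftime("%Y%m%d")
        ds.ContentTime = now.strftime("%H%M%S")
        ds.InstanceNumber = k + 1
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.ImagePositionPatient = [
            float(volume.origin[0]),
            float(volume.origin[1]),
            float(volume.origin[2] + k * volume.spacing[2]),
        ]
        ds.PixelSpacing = [float(volume.spacing[1]), float(volume.spacing[0])]
        ds.SliceThickness = float(volume.spacing[2])
        ds.Rows, ds.Columns = volume.shape[1], volume.shape[0]
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.RescaleSlope = 1.0
        ds.RescaleIntercept = -1024.0
        ds.PixelData = np.ascontiguousarray(stored[:, :, k].T).tobytes()
        path = directory / f"slice_{k:04d}.dcm"
        ds.save_as(str(path), enforce_file_format=True)
        paths.append(path)
    return paths


# ---------------------------------------------------------------------------
# RT-STRUCT


def build_rtstruct(roi_contours: dict[str, list[tuple[float, np.ndarray]]]) -> Dataset:
    """Assemble a minimal RT-STRUCT dataset from planar contours.

    ``roi_contours`` maps an ROI name to a list of ``(z, polygon)`` pairs
    where ``polygon`` is an (N, 2) array of in-plane (x, y) vertices [mm].
    Useful for exporting phantom masks and for round-trip tests.
    """
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = RTStructureSetStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = RTStructureSetStorage
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTSTRUCT"
    ds.StructureSetLabel = "orthotrack"
    ds.StructureSetROISequence = []
    ds.ROIContourSequence = []
    for number, (name, contours) in enumerate(roi_contours.items(), start=1):
        roi = Dataset()
        roi.ROINumber = number
        roi.ROIName = name
        roi.ReferencedFrameOfReferenceUID = generate_uid()
        ds.StructureSetROISequence.append(roi)
        rc = Dataset()
        rc.ReferencedROINumber = number
        rc.ContourSequence = []
        for z, poly in contours:
            poly = np.asarray(poly, dtype=float)
            c = Dataset()
            c.ContourGeometricType = "CLOSED_PLANAR"
            c.NumberOfContourPoints = poly.shape[0]
            data = np.column_stack([poly, np.full(poly.shape[0], float(z))])
            c.ContourData = [float(x) for x in data.ravel()]
            rc.ContourSequence.append(c)
        ds.ROIContourSequence.append(rc)
    return ds


def _polygon_slice_mask(poly_xy: np.ndarray, volume: CTVolume) -> np.ndarray:
    """Rasterize one in-plane polygon: voxel centers inside (even-odd rule)."""
    xs, ys, _ = volume.voxel_centers_1d()
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    ring = np.vstack([poly_xy, poly_xy[:1]])  # explicit closing vertex
    inside = MplPath(ring, closed=True).contains_points(pts)
    return inside.reshape(len(xs), len(ys))


def extract_gtv_mask(structure_file, volume: CTVolume, roi_name: str = "GTV") -> GTVMask:
    """Rasterize the named ROI of an RT-STRUCT onto ``volume``'s grid.

    Each planar contour is matched to the volume slice whose z coordinate
    lies within half a slice spacing; voxels whose centers fall inside the
    polygon are set, and slices/components are unioned.  Disjoint polygons
    on one slice are all kept.
    """
    ds = structure_file if isinstance(structure_file, Dataset) else pydicom.dcmread(str(structure_file))
    numbers = {str(roi.ROIName): int(roi.ROINumber) for roi in ds.StructureSetROISequence}
    if roi_name not in numbers:
        raise ROINotFoundError(f"ROI {roi_name!r} not in structure set {sorted(numbers)}")
    target = numbers[roi_name]
    contour_seq = None
    for rc in ds.ROIContourSequence:
        if int(rc.ReferencedROINumber) == target:
            contour_seq = getattr(rc, "ContourSequence", [])
            break
    if not contour_seq:
        raise ROINotFoundError(f"ROI {roi_name!r} has no contours")
    mask = np.zeros(volume.shape, dtype=bool)
    z0, dz = float(volume.origin[2]), float(volume.spacing[2])
    for c in contour_seq:
        data = np.asarray(c.ContourData, dtype=float).reshape(-1, 3)
        z = float(np.mean(data[:, 2]))
        k = int(round((z - z0) / dz))
        if k < 0 or k >= volume.shape[2] or abs(z - (z0 + k * dz)) > dz / 2 + 1e-9:
            raise ContourPlaneError(f"contour plane z={z} matches no volume slice")
        mask[:, :, k] |= _polygon_slice_mask(data[:, :2], volume)
    return GTVMask(voxels=mask, phase=volume.phase)


def gtv_only_volume(volume: CTVolume, mask: GTVMask) -> CTVolume:
    """Companion volume in which everything outside the GTV is air.

    Voxels inside the mask keep their HU; all others are set to -1000 so a
    projection of the result shows only the tumor's radiological footprint.
    Idempotent when re-applied with the same mask.
    """
    if volume.shape != mask.shape:
        raise ValueError(f"shape mismatch: volume {volume.shape} vs mask {mask.shape}")
    voxels = np.where(mask.voxels, volume.voxels, np.float32(AIR_HU))
    return replace(volume, voxels=voxels)


# ---------------------------------------------------------------------------
# MHA / NIfTI export (via SimpleITK)


def save_volume(volume: CTVolume, path) -> None:
    """Write a volume as MHA/NIfTI (extension decides the format)."""
    import SimpleITK as sitk

    img = sitk.GetImageFromArray(np.ascontiguousarray(volume.voxels.T))  # (z, y, x)
    img.SetSpacing(tuple(float(s) for s in volume.spacing))
    img.SetOrigin(tuple(float(o) for o in volume.origin))
    sitk.WriteImage(img, str(path))


def load_volume(path, phase: int = 0) -> CTVolume:
    import SimpleITK as sitk

    img = sitk.ReadImage(str(path))
    voxels = sitk.GetArrayFromImage(img).T  # (x, y, z)
    return CTVolume(
        voxels=voxels,
        spacing=np.asarray(img.GetSpacing(), dtype=float),
        origin=np.asarray(img.GetOrigin(), dtype=float),
        phase=phase,
    )
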