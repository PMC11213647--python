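"""Voxel grids, contours and structure sets shared by every pipeline stage.

Axis convention: arrays are indexed ``(slice, row, col)`` with slices running
inferior -> superior, rows posterior -> anterior and columns patient-right ->
patient-left (LPS-consistent).  Coordinates are voxel-center based with
0-based indices: the center of voxel ``(i, j, k)`` sits at
``origin + (i, j, k) * spacing`` in millimetres.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path as FilePath

import numpy as np
from matplotlib.path import Path as PolyPath
from scipy import ndimage


class FormatError(ValueError):
    """A file could not be parsed under the requested dialect."""


class GeometryError(ValueError):
    """Two grids do not overlap or are otherwise geometrically incompatible."""


class ConfigurationError(ValueError):
    """A configuration object violates its contract."""


@dataclass
class ImageGrid:
    """A 3D scalar volume (HU, Gy, arbitrary MR units or boolean mask).

    Parameters
    ----------
    voxels : ndarray, shape (slices, rows, cols)
    spacing : tuple of float
        Millimetres per axis, ordered (slice, row, col).
    origin : tuple of float
        Physical position (mm) of the center of voxel (0, 0, 0).
    modality : {"CT", "MR", "DOSE", "MASK"}
    units : {"HU", "arbitrary", "Gy", "bool"}
    """

    voxels: np.ndarray
    spacing: tuple = (2.5, 0.98, 0.98)
    origin: tuple = (0.0, 0.0, 0.0)
    modality: str = "CT"
    units: str = "HU"

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise GeometryError("voxels must be a 3D array (slices, rows, cols)")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise GeometryError("spacing must be positive on all axes")
        if self.voxels.dtype != bool and not np.all(np.isfinite(self.voxels)):
            raise GeometryError("voxels must be finite")

    @property
    def shape(self):
        return self.voxels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def copy(self, voxels=None, **overrides) -> "ImageGrid":
        kw = dict(spacing=self.spacing, origin=self.origin,
                  modality=self.modality, units=self.units)
        kw.update(overrides)
        v = self.voxels.copy() if voxels is None else voxels
        return ImageGrid(v, **kw)

    def same_geometry(self, other: "ImageGrid", tol: float = 1e-6) -> bool:
        return (self.shape == other.shape
                and np.allclose(self.spacing, other.spacing, atol=tol)
                and np.allclose(self.origin, other.origin, atol=tol))

    def axis_coords(self, axis: int) -> np.ndarray:
        """Physical coordinates (mm) of voxel centers along one axis."""
        n = self.shape[axis]
        return self.origin[axis] + np.arange(n) * self.spacing[axis]


@dataclass
class Contour:
    """A closed planar polygon on one axial slice, vertices in mm (row, col)."""

    structure_name: str
    slice_index: int
    points: np.ndarray  # (n, 2) ordered (row_mm, col_mm), implicitly closed

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ConfigurationError("contour points must be (n, 2)")
        if len(self.points) < 3:
            raise ConfigurationError("a contour needs at least 3 vertices")
        if abs(self.signed_area()) <= 0:
            raise ConfigurationError("contour polygon area must be positive")

    def signed_area(self) -> float:
        """Shoelace area; sign encodes orientation in the (row, col) plane."""
        r, c = self.points[:, 0], self.points[:, 1]
        return 0.5 * float(np.sum(c * np.roll(r, -1) - np.roll(c, -1) * r))


@dataclass
class StructureSet:
    """Named contours plus boolean masks rasterized on a reference grid."""

    contours: list = field(default_factory=list)
    masks: dict = field(default_factory=dict)
    reference: ImageGrid | None = None

    @classmethod
    def from_contours(cls, contours, reference: ImageGrid) -> "StructureSet":
        ss = cls(contours=list(contours), reference=reference)
        names = {c.structure_name for c in ss.contours}
        for name in sorted(names):
            cs = [c for c in ss.contours if c.structure_name == name]
            ss.masks[name] = rasterize(cs, reference)
        return ss

    def add_mask(self, name: str, mask: ImageGrid):
        self.masks[name] = mask

    def contours_for(self, name: str) -> list:
        return sorted((c for c in self.contours if c.structure_name == name),
                      key=lambda c: c.slice_index)

    def names(self):
        return sorted(self.masks)


# ---------------------------------------------------------------------------
# rasterization / resampling
# ---------------------------------------------------------------------------

def rasterize(contours, reference: ImageGrid) -> ImageGrid:
    """Rasterize closed polygons to a boolean mask on ``reference``.

    A voxel is true iff its center lies inside the polygon of its slice
    (even-odd rule); slices without a contour stay false and no
    between-slice interpolation is performed.
    """
    ns, nr, nc = reference.shape
    mask = np.zeros(reference.shape, dtype=bool)
    rows = reference.axis_coords(1)
    cols = reference.axis_coords(2)
    cc, rr = np.meshgrid(cols, rows)
    centers = np.column_stack([rr.ravel(), cc.ravel()])
    for contour in contours:
        i = contour.slice_index
        if not 0 <= i < ns:
            raise IndexError(
                f"contour for {contour.structure_name!r} on slice {i} "
                f"outside grid with {ns} slices")
        path = PolyPath(contour.points)  # implicitly closed by contains_points
        inside = path.contains_points(centers).reshape(nr, nc)
        mask[i] ^= inside  # even-odd: holes from nested contours
    return ImageGrid(mask, spacing=reference.spacing, origin=reference.origin,
                     modality="MASK", units="bool")


_FILL = {"CT": -1000.0, "MR": 0.0, "DOSE": 0.0, "MASK": 0.0}


def resample(grid: ImageGrid, target: ImageGrid, method: str = "trilinear") -> ImageGrid:
    """Resample ``grid`` onto the geometry of ``target``.

    Trilinear for intensities, nearest for masks/labels.  Voxels outside the
    source extent take a modality fill value (CT -1000, MR 0, mask false).
    """
    if method not in ("nearest", "trilinear"):
        raise ValueError(f"unknown resampling method {method!r}")
    for ax in range(3):
        src_lo = grid.origin[ax]
        src_hi = grid.origin[ax] + (grid.shape[ax] - 1) * grid.spacing[ax]
        tgt_lo = target.origin[ax]
        tgt_hi = target.origin[ax] + (target.shape[ax] - 1) * target.spacing[ax]
        if tgt_hi < src_lo or tgt_lo > src_hi:
            raise GeometryError(f"grids have disjoint extents on axis {ax}")
    coords = np.meshgrid(*(
        (target.axis_coords(ax) - grid.origin[ax]) / grid.spacing[ax]
        for ax in range(3)), indexing="ij")
    order = 0 if method == "nearest" else 1
    cval = _FILL.get(grid.modality, 0.0)
    was_bool = grid.voxels.dtype == bool
    src = grid.voxels.astype(float) if was_bool else grid.voxels.astype(float)
    out = ndimage.map_coordinates(src, np.stack(coords), order=order,
                                  mode="constant", cval=cval)
    if was_bool:
        out = out > 0.5
    return ImageGrid(out, spacing=target.spacing, origin=target.origin,
                     modality=grid.modality, units=grid.units)


# ---------------------------------------------------------------------------
# volume I/O
# ---------------------------------------------------------------------------

def write_volume(grid: ImageGrid, path, dialect: str = "nifti") -> None:
    """Write a volume as a single NIfTI file or a per-slice DICOM series."""
    path = FilePath(path)
    if dialect == "nifti":
        _write_nifti(grid, path)
    elif dialect == "dicom_series":
        _write_dicom_series(grid, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_volume(path, dialect: str = "nifti", modality: str = "CT",
                units: str | None = None) -> ImageGrid:
    """Read a volume written by :func:`write_volume` (or compatible files)."""
    path = FilePath(path)
    if dialect == "nifti":
        return _read_nifti(path, modality, units)
    if dialect == "dicom_series":
        return _read_dicom_series(path, modality, units)
    raise ValueError(f"unknown dialect {dialect!r}")


def _write_nifti(grid: ImageGrid, path: FilePath) -> None:
    import nibabel as nib

    data = grid.voxels
    if data.dtype == bool:
        data = data.astype(np.uint8)
    # nibabel wants (x, y, z) = (col, row, slice)
    arr = np.ascontiguousarray(np.transpose(data, (2, 1, 0)))
    sp = grid.spacing
    affine = np.diag([sp[2], sp[1], sp[0], 1.0])
    affine[:3, 3] = (grid.origin[2], grid.origin[1], grid.origin[0])
    img = nib.Nifti1Image(arr, affine)
    img.header.set_zooms((sp[2], sp[1], sp[0]))
    nib.save(img, str(path))


def _read_nifti(path: FilePath, modality: str, units: str | None) -> ImageGrid:
    import nibabel as nib

    if not path.exists():
        raise FormatError(f"no such NIfTI file: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # pragma: no cover - nibabel error text varies
        raise FormatError(f"unreadable NIfTI file {path}: {exc}") from exc
    affine = img.affine
    if not np.allclose(affine[:3, :3], np.diag(np.diag(affine[:3, :3]))):
        raise FormatError(f"oblique NIfTI orientation not supported: {path}")
    arr = np.asanyarray(img.dataobj)
    voxels = np.transpose(arr, (2, 1, 0))
    d = np.diag(affine[:3, :3])
    spacing = (abs(d[2]), abs(d[1]), abs(d[0]))
    origin = (affine[2, 3], affine[1, 3], affine[0, 3])
    if units is None:
        units = {"CT": "HU", "MR": "arbitrary", "DOSE": "Gy", "MASK": "bool"}[modality]
    if units == "bool":
        voxels = voxels.astype(bool)
    return ImageGrid(voxels, spacing=spacing, origin=origin,
                     modality=modality, units=units)


def _dicom_base_dataset():
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.CTImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.Modality = "CT"
    ds.PatientName = "PHANTOM"
    ds.PatientID = "PHANTOM"
    return ds


def _write_dicom_series(grid: ImageGrid, path: FilePath) -> None:
    from pydicom.uid import generate_uid

    path.mkdir(parents=True, exist_ok=True)
    series_uid = generate_uid()
    data = grid.voxels
    is_int = np.issubdtype(data.dtype, np.integer) or data.dtype == bool
    if is_int:
        stored = data.astype(np.int16)
        slope, intercept = 1.0, 0.0
        bits, signed = 16, 1
    else:
        # float grids (dose): 32-bit scaled storage, round trip within 1e-6
        lo, hi = float(data.min()), float(data.max())
        slope = max((hi - lo), 1e-12) / (2**32 - 1)
        intercept = lo
        stored = np.round((data - lo) / slope).astype(np.uint32)
        bits, signed = 32, 0
    for i in range(grid.shape[0]):
        ds = _dicom_base_dataset()
        ds.SeriesInstanceUID = series_uid
        ds.SOPInstanceUID = generate_uid()
        ds.file_meta.MediaStorageSOPInstanceUID = ds.SOPInstanceUID
        ds.InstanceNumber = i + 1
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        z = grid.origin[0] + i * grid.spacing[0]
        ds.ImagePositionPatient = [grid.origin[2], grid.origin[1], z]
        ds.PixelSpacing = [grid.spacing[1], grid.spacing[2]]
        ds.SliceThickness = grid.spacing[0]
        ds.Rows, ds.Columns = grid.shape[1], grid.shape[2]
        ds.BitsAllocated = ds.BitsStored = bits
        ds.HighBit = bits - 1
        ds.PixelRepresentation = signed
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.RescaleSlope = slope
        ds.RescaleIntercept = intercept
        ds.PixelData = np.ascontiguousarray(stored[i]).tobytes()
        ds.save_as(path / f"slice_{i:04d}.dcm", enforce_file_format=True)


def _read_dicom_series(path: FilePath, modality: str, units: str | None) -> ImageGrid:
    import pydicom

    if not path.is_dir():
        raise FormatError(f"dicom_series dialect expects a directory: {path}")
    files = sorted(path.glob("*.dcm"))
    if not files:
        raise FormatError(f"no DICOM files found in {path}")
    slices = []
    for f in files:
        try:
            slices.append(pydicom.dcmread(str(f)))
        except Exception as exc:
            raise FormatError(f"unreadable DICOM file {f}: {exc}") from exc
    orientations = {tuple(np.round(s.ImageOrientationPatient, 6)) for s in slices}
    if len(orientations) > 1:
        raise FormatError(f"mixed-orientation DICOM series in {path}")
    slices.sort(key=lambda s: float(s.ImagePositionPatient[2]))
    arrs = []
    for s in slices:
        arr = s.pixel_array.astype(np.float64)
        arr = arr * float(s.RescaleSlope) + float(s.RescaleIntercept)
        arrs.append(arr)
    voxels = np.stack(arrs)
    if all(float(s.RescaleSlope) == 1.0 and
           float(s.RescaleIntercept) == int(s.RescaleIntercept) for s in slices) \
            and all(s.BitsAllocated == 16 for s in slices):
        voxels = voxels.astype(np.int16) if np.all(voxels == np.round(voxels)) else voxels
    s0 = slices[0]
    zs = [float(s.ImagePositionPatient[2]) for s in slices]
    dz = float(np.mean(np.diff(zs))) if len(zs) > 1 else float(s0.SliceThickness)
    spacing = (dz, float(s0.PixelSpacing[0]), float(s0.PixelSpacing[1]))
    origin = (zs[0], float(s0.ImagePositionPatient[1]), float(s0.ImagePositionPatient[0]))
    if units is None:
        units = {"CT": "HU", "MR": "arbitrary", "DOSE": "Gy", "MASK": "bool"}[modality]
    return ImageGrid(voxels, spacing=spacing, origin=origin,
                     modality=modality, units=units)


# ---------------------------------------------------------------------------
# DICOM-RT dose and structure sets
# ---------------------------------------------------------------------------

def write_rtdose(dose: ImageGrid, path) -> None:
    """Write a dose grid as a single multi-frame RTDOSE-style file."""
    import pydicom
    from pydicom.uid import generate_uid

    ds = _dicom_base_dataset()
    ds.SOPClassUID = pydicom.uid.RTDoseStorage
    ds.file_meta.MediaStorageSOPClassUID = pydicom.uid.RTDoseStorage
    ds.Modality = "RTDOSE"
    ds.SeriesInstanceUID = generate_uid()
    ds.DoseUnits, ds.DoseType, ds.DoseSummationType = "GY", "PHYSICAL", "PLAN"
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    ds.ImagePositionPatient = [dose.origin[2], dose.origin[1], dose.origin[0]]
    ds.PixelSpacing = [dose.spacing[1], dose.spacing[2]]
    ds.GridFrameOffsetVector = [i * dose.spacing[0]
                                for i in range(dose.shape[0])]
    ds.NumberOfFrames = dose.shape[0]
    ds.Rows, ds.Columns = dose.shape[1], dose.shape[2]
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = ds.BitsStored = 32
    ds.HighBit = 31
    ds.PixelRepresentation = 0
    scaling = max(float(dose.voxels.max()), 1e-12) / (2 ** 32 - 1)
    ds.DoseGridScaling = scaling
    stored = np.round(dose.voxels / scaling).astype(np.uint32)
    ds.PixelData = np.ascontiguousarray(stored).tobytes()
    ds.save_as(FilePath(path), enforce_file_format=True)


def read_rtdose(path) -> ImageGrid:
    import pydicom

    try:
        ds = pydicom.dcmread(str(path))
    except Exception as exc:
        raise FormatError(f"unreadable RTDOSE file {path}: {exc}") from exc
    if getattr(ds, "Modality", "") != "RTDOSE":
        raise FormatError(f"{path} is not an RTDOSE object")
    frames = np.asarray(ds.pixel_array, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    dose = frames * float(ds.DoseGridScaling)
    offsets = np.asarray(ds.GridFrameOffsetVector, dtype=float)
    dz = float(np.mean(np.diff(offsets))) if len(offsets) > 1 else 1.0
    spacing = (dz, float(ds.PixelSpacing[0]), float(ds.PixelSpacing[1]))
    origin = (float(ds.ImagePositionPatient[2]) + offsets[0],
              float(ds.ImagePositionPatient[1]),
              float(ds.ImagePositionPatient[0]))
    return ImageGrid(dose, spacing=spacing, origin=origin, modality="DOSE",
                     units="Gy")


def write_rtstruct(structures: StructureSet, reference: ImageGrid, path) -> None:
    """Write contours as a minimal RTSTRUCT (axial closed-planar ROIs)."""
    import pydicom
    from pydicom.dataset import Dataset
    from pydicom.uid import generate_uid

    ds = _dicom_base_dataset()
    ds.SOPClassUID = pydicom.uid.RTStructureSetStorage
    ds.file_meta.MediaStorageSOPClassUID = pydicom.uid.RTStructureSetStorage
    ds.Modality = "RTSTRUCT"
    ds.SeriesInstanceUID = generate_uid()
    names = sorted({c.structure_name for c in structures.contours})
    ds.StructureSetROISequence = []
    ds.ROIContourSequence = []
    for number, name in enumerate(names, start=1):
        roi = Dataset()
        roi.ROINumber = number
        roi.ROIName = name
        ds.StructureSetROISequence.append(roi)
        rc = Dataset()
        rc.ReferencedROINumber = number
        rc.ContourSequence = []
        for contour in structures.contours:
            if contour.structure_name != name:
                continue
            z = reference.origin[0] + contour.slice_index * reference.spacing[0]
            item = Dataset()
            item.ContourGeometricType = "CLOSED_PLANAR"
            item.NumberOfContourPoints = len(contour.points)
            data = []
            for row_mm, col_mm in contour.points:   # patient (x, y, z) = (col, row, z)
                data.extend([float(col_mm), float(row_mm), float(z)])
            item.ContourData = data
            rc.ContourSequence.append(item)
        ds.ROIContourSequence.append(rc)
    ds.save_as(FilePath(path), enforce_file_format=True)


def read_rtstruct(path, reference: ImageGrid) -> list:
    """Read RTSTRUCT ROI contours, mapping patient z to slice indices."""
    import pydicom

    try:
        ds = pydicom.dcmread(str(path))
    except Exception as exc:
        raise FormatError(f"unreadable RTSTRUCT file {path}: {exc}") from exc
    if getattr(ds, "Modality", "") != "RTSTRUCT":
        raise FormatError(f"{path} is not an RTSTRUCT object")
    names = {int(roi.ROINumber): str(roi.ROIName)
             for roi in ds.StructureSetROISequence}
    contours = []
    for rc in ds.ROIContourSequence:
        name = names[int(rc.ReferencedROINumber)]
        for item in getattr(rc, "ContourSequence", []):
            data = np.asarray(item.ContourData, dtype=float).reshape(-1, 3)
            z = float(np.mean(data[:, 2]))
            idx = int(round((z - reference.origin[0]) / reference.spacing[0]))
            pts = np.column_stack([data[:, 1], data[:, 0]])  # (row, col) mm
            contours.append(Contour(name, idx, pts))
    return contours


# ---------------------------------------------------------------------------
# JSON contour files
# ---------------------------------------------------------------------------

def write_contours(contours, path) -> None:
    """Write contours as a JSON list of {structure, slice, points_mm}."""
    items = [{"structure": c.structure_name, "slice": int(c.slice_index),
              "points_mm": np.asarray(c.points).tolist()} for c in contours]
    FilePath(path).write_text(json.dumps({"contours": items}, indent=1))


def read_contours(path) -> list:
    try:
        payload = json.loads(FilePath(path).read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"invalid contour JSON {path}: {exc}") from exc
    return [Contour(item["structure"], item["slice"], np.asarray(item["points_mm"]))
            for item in payload["contours"]]
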