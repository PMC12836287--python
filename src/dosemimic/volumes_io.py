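"""Volumetric data model and I/O.

Defines the grid-aware containers used throughout the package (images,
doses, binary structure masks, structure sets, deformation fields and
patient cases), together with readers/writers for DICOM-RT (CT series,
RTDOSE, RTSTRUCT) and for a self-describing research volume format
(MetaImage ``.mha`` plus a JSON case manifest), and grid resampling.

Conventions
-----------
* Physical coordinates are DICOM LPS millimetres.
* ``GridGeometry.origin``/``spacing``/``shape`` are ordered ``(x, y, z)``
  (the SimpleITK convention); voxel arrays are ``numpy`` arrays indexed
  ``[z, y, x]`` (the array order SimpleITK returns).
* Voxel indices are 0-based; a mask samples its structure at voxel
  centers; contours rasterize by even-odd filling per axial slice.
"""

from __future__ import annotations

import datetime
import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileDataset, FileMetaDataset
from pydicom.uid import generate_uid
import SimpleITK as sitk
from skimage.draw import polygon2mask
from skimage.measure import find_contours

__all__ = [
    "GridGeometry",
    "ImageVolume",
    "BinaryMask",
    "StructureSet",
    "DeformationField",
    "PatientCase",
    "resample",
    "read_dicom_case",
    "write_dicom_case",
    "save_volume",
    "load_volume",
    "save_case",
    "load_case",
    "save_field",
    "load_field",
]

_IDENTITY_DIRECTION = (1.0, 0.0, 0.0, 0.0, 1.0, 0.0, 0.0, 0.0, 1.0)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GridGeometry:
    """Regular 3D sampling grid in patient (LPS) coordinates.

    Parameters
    ----------
    origin : tuple of float
        Physical position (mm) of the center of voxel ``(0, 0, 0)``,
        ordered ``(x, y, z)``.
    spacing : tuple of float
        Per-axis voxel size in mm, ``(x, y, z)``; strictly positive.
    shape : tuple of int
        Voxel counts per axis, ``(nx, ny, nz)``; at least 1 each.
    direction : tuple of float
        Row-major 3x3 direction-cosine matrix; must be orthonormal.
    """

    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    shape: tuple[int, int, int]
    direction: tuple[float, ...] = _IDENTITY_DIRECTION

    def __post_init__(self) -> None:
        if len(self.origin) != 3 or len(self.spacing) != 3 or len(self.shape) != 3:
            raise ValueError("origin, spacing and shape must have length 3")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if any(n < 1 for n in self.shape):
            raise ValueError(f"shape must be >= 1 per axis, got {self.shape}")
        d = np.asarray(self.direction, dtype=float).reshape(3, 3)
        if not np.allclose(d @ d.T, np.eye(3), atol=1e-6):
            raise ValueError("direction cosines must form an orthonormal matrix")
        object.__setattr__(self, "origin", tuple(float(v) for v in self.origin))
        object.__setattr__(self, "spacing", tuple(float(v) for v in self.spacing))
        object.__setattr__(self, "shape", tuple(int(v) for v in self.shape))
        object.__setattr__(self, "direction", tuple(float(v) for v in self.direction))

    @property
    def array_shape(self) -> tuple[int, int, int]:
        """Numpy array shape ``(nz, ny, nx)`` for volumes on this grid."""
        return (self.shape[2], self.shape[1], self.shape[0])

    @property
    def voxel_volume_cc(self) -> float:
        """Volume of one voxel in cubic centimetres."""
        return float(np.prod(self.spacing)) / 1000.0

    def axis_coordinates(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Physical coordinates of voxel centers along each axis (x, y, z).

        Only valid for identity-direction grids.
        """
        self._require_axis_aligned()
        return tuple(
            self.origin[a] + self.spacing[a] * np.arange(self.shape[a])
            for a in range(3)
        )

    def index_to_physical(self, idx_xyz: np.ndarray) -> np.ndarray:
        """Map continuous voxel indices ``(..., 3)`` (x,y,z order) to mm."""
        d = np.asarray(self.direction).reshape(3, 3)
        return np.asarray(self.origin) + (np.asarray(idx_xyz) * np.asarray(self.spacing)) @ d.T

    def physical_to_index(self, pts_xyz: np.ndarray) -> np.ndarray:
        """Map physical points ``(..., 3)`` in mm to continuous voxel indices."""
        d = np.asarray(self.direction).reshape(3, 3)
        rel = (np.asarray(pts_xyz) - np.asarray(self.origin)) @ d
        return rel / np.asarray(self.spacing)

    def _require_axis_aligned(self) -> None:
        if not np.allclose(self.direction, _IDENTITY_DIRECTION, atol=1e-9):
            raise NotImplementedError(
                "operation requires an axis-aligned (identity direction) grid"
            )


@dataclass
class ImageVolume:
    """Scalar volume (CT in HU or dose in Gy) on a :class:`GridGeometry`."""

    geometry: GridGeometry
    values: np.ndarray
    modality: str = "CT"  # {"CT", "DOSE"}

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.geometry.array_shape:
            raise ValueError(
                f"values shape {self.values.shape} does not match geometry "
                f"array shape {self.geometry.array_shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume values must be finite")
        if self.modality not in ("CT", "DOSE"):
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.modality == "DOSE" and self.values.min() < 0:
            raise ValueError("dose values must be nonnegative")


@dataclass
class BinaryMask:
    """Voxelized structure on a grid; volume is exact voxel counting."""

    geometry: GridGeometry
    values: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values).astype(bool)
        if self.values.shape != self.geometry.array_shape:
            raise ValueError(
                f"mask shape {self.values.shape} does not match geometry "
                f"array shape {self.geometry.array_shape}"
            )

    @property
    def volume_cc(self) -> float:
        """Structure volume in cc: true-voxel count times voxel volume."""
        return int(self.values.sum()) * self.geometry.voxel_volume_cc


class StructureSet:
    """Named collection of :class:`BinaryMask` sharing one geometry."""

    def __init__(self, masks: Mapping[str, BinaryMask] | None = None):
        self._masks: dict[str, BinaryMask] = {}
        if masks:
            for name, m in masks.items():
                self.add(name, m)

    def add(self, name: str, mask: BinaryMask) -> None:
        if name in self._masks:
            raise ValueError(f"duplicate structure name {name!r}")
        if self._masks:
            ref = next(iter(self._masks.values())).geometry
            if mask.geometry != ref:
                raise ValueError("all masks in a StructureSet must share one geometry")
        self._masks[name] = BinaryMask(mask.geometry, mask.values, name=name)

    def __getitem__(self, name: str) -> BinaryMask:
        return self._masks[name]

    def __contains__(self, name: str) -> bool:
        return name in self._masks

    def __iter__(self) -> Iterator[str]:
        return iter(self._masks)

    def __len__(self) -> int:
        return len(self._masks)

    def names(self) -> list[str]:
        return list(self._masks)

    def items(self):
        return self._masks.items()

    @property
    def geometry(self) -> GridGeometry:
        if not self._masks:
            raise ValueError("empty structure set has no geometry")
        return next(iter(self._masks.values())).geometry


@dataclass
class DeformationField:
    """Per-voxel displacement vectors (mm) on a fixed-frame grid.

    ``vectors`` has shape ``(nz, ny, nx, 3)`` with the last axis ordered
    ``(x, y, z)`` in physical mm.  The zero field is the identity mapping;
    the field realizes the pull-back ``out(x) = in(x + u(x))``.
    """

    geometry: GridGeometry
    vectors: np.ndarray

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        expected = self.geometry.array_shape + (3,)
        if self.vectors.shape != expected:
            raise ValueError(
                f"vectors shape {self.vectors.shape} != expected {expected}"
            )
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("deformation vectors must be finite")

    def magnitude(self) -> np.ndarray:
        """Per-voxel displacement magnitude |u| in mm."""
        return np.linalg.norm(self.vectors, axis=-1)


@dataclass
class PatientCase:
    """A planning case: CT, dose grid, structure set and prescription."""

    id: str
    ct: ImageVolume
    dose: ImageVolume | None
    structures: StructureSet
    prescription_gy: float = 50.0

    def __post_init__(self) -> None:
        if self.prescription_gy <= 0:
            raise ValueError("prescription must be positive")
        if self.dose is not None and self.dose.geometry != self.ct.geometry:
            # harmonize at load: all downstream math runs on the CT grid
            self.dose = resample(self.dose, self.ct.geometry, mode="linear")


# ---------------------------------------------------------------------------
# SimpleITK bridging
# ---------------------------------------------------------------------------

def _geometry_from_sitk(img: sitk.Image) -> GridGeometry:
    return GridGeometry(
        origin=tuple(img.GetOrigin()),
        spacing=tuple(img.GetSpacing()),
        shape=tuple(img.GetSize()),
        direction=tuple(img.GetDirection()),
    )


def to_sitk(vol: ImageVolume | BinaryMask) -> sitk.Image:
    """Convert a volume or mask to a SimpleITK image (masks as uint8)."""
    arr = vol.values.astype(np.uint8) if isinstance(vol, BinaryMask) else vol.values
    img = sitk.GetImageFromArray(arr)
    img.SetOrigin(vol.geometry.origin)
    img.SetSpacing(vol.geometry.spacing)
    img.SetDirection(vol.geometry.direction)
    return img


def from_sitk(img: sitk.Image, modality: str = "CT") -> ImageVolume:
    return ImageVolume(
        _geometry_from_sitk(img),
        sitk.GetArrayFromImage(img).astype(np.float64),
        modality=modality,
    )


def _sitk_geometry_reference(geom: GridGeometry) -> sitk.Image:
    ref = sitk.Image(geom.shape, sitk.sitkFloat32)
    ref.SetOrigin(geom.origin)
    ref.SetSpacing(geom.spacing)
    ref.SetDirection(geom.direction)
    return ref


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------

def resample(
    obj: ImageVolume | BinaryMask,
    target: GridGeometry,
    mode: str = "linear",
):
    """Resample a volume or mask onto ``target``.

    Scalar volumes interpolate linearly; masks use nearest neighbour
    (``mode`` is forced to ``nearest`` for masks).  Voxels outside the
    source support are filled with 0 / ``False``.
    """
    if any(s <= 0 for s in target.spacing):
        raise ValueError("degenerate target geometry")
    is_mask = isinstance(obj, BinaryMask)
    if is_mask:
        mode = "nearest"
    if obj.geometry == target:
        if is_mask:
            return BinaryMask(target, obj.values.copy(), name=obj.name)
        return ImageVolume(target, obj.values.copy(), modality=obj.modality)
    interp = sitk.sitkNearestNeighbor if mode == "nearest" else sitk.sitkLinear
    out = sitk.Resample(
        to_sitk(obj),
        _sitk_geometry_reference(target),
        sitk.Transform(),
        interp,
        0.0,
        sitk.sitkFloat64,
    )
    arr = sitk.GetArrayFromImage(out)
    if is_mask:
        return BinaryMask(target, arr > 0.5, name=obj.name)
    return ImageVolume(target, arr, modality=obj.modality)


# ---------------------------------------------------------------------------
# research volume format (MetaImage + JSON manifest)
# ---------------------------------------------------------------------------

def save_volume(vol: ImageVolume | BinaryMask, path: str | Path) -> Path:
    """Write a volume/mask as a self-describing MetaImage (.mha) file."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = to_sitk(vol)
    sitk.WriteImage(img, str(path))
    return path


def load_volume(path: str | Path, kind: str = "image", modality: str = "CT"):
    """Read a .mha volume; ``kind`` is ``image`` or ``mask``."""
    img = sitk.ReadImage(str(path))
    geom = _geometry_from_sitk(img)
    arr = sitk.GetArrayFromImage(img)
    if kind == "mask":
        return BinaryMask(geom, arr > 0.5, name=Path(path).stem)
    return ImageVolume(geom, arr.astype(np.float64), modality=modality)


def save_field(fld: DeformationField, path: str | Path) -> Path:
    """Write a deformation field as a 3-component vector MetaImage."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = sitk.GetImageFromArray(fld.vectors, isVector=True)
    img.SetOrigin(fld.geometry.origin)
    img.SetSpacing(fld.geometry.spacing)
    img.SetDirection(fld.geometry.direction)
    sitk.WriteImage(img, str(path))
    return path


def load_field(path: str | Path) -> DeformationField:
    img = sitk.ReadImage(str(path))
    geom = _geometry_from_sitk(img)
    return DeformationField(geom, sitk.GetArrayFromImage(img).astype(np.float64))


def save_case(case: PatientCase, out_dir: str | Path) -> Path:
    """Persist a case as ct.mha, dose.mha, masks/*.mha and case.json."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    save_volume(case.ct, out_dir / "ct.mha")
    if case.dose is not None:
        save_volume(case.dose, out_dir / "dose.mha")
    for name, mask in case.structures.items():
        save_volume(mask, out_dir / "masks" / f"{name}.mha")
    manifest = {
        "id": case.id,
        "prescription_gy": case.prescription_gy,
        "structures": case.structures.names(),
        "has_dose": case.dose is not None,
    }
    (out_dir / "case.json").write_text(json.dumps(manifest, indent=2))
    return out_dir


def load_case(case_dir: str | Path) -> PatientCase:
    case_dir = Path(case_dir)
    manifest = json.loads((case_dir / "case.json").read_text())
    ct = load_volume(case_dir / "ct.mha", "image", "CT")
    dose = None
    if manifest.get("has_dose"):
        dose = load_volume(case_dir / "dose.mha", "image", "DOSE")
    ss = StructureSet()
    for name in manifest["structures"]:
        mask = load_volume(case_dir / "masks" / f"{name}.mha", "mask")
        mask.name = name
        ss.add(name, mask)
    return PatientCase(
        id=manifest["id"],
        ct=ct,
        dose=dose,
        structures=ss,
        prescription_gy=float(manifest["prescription_gy"]),
    )


# ---------------------------------------------------------------------------
# contour rasterization / extraction
# ---------------------------------------------------------------------------

def rasterize_contours(
    contours: list[np.ndarray], geometry: GridGeometry, name: str = ""
) -> BinaryMask:
    """Rasterize planar (axial) contours in mm into a mask on ``geometry``.

    Each contour is an (N, 3) array of LPS points on one axial plane.
    Multiple contours on a slice combine by even-odd (XOR) filling, so
    nested contours produce holes.
    """
    geometry._require_axis_aligned()
    nz, ny, nx = geometry.array_shape
    out = np.zeros((nz, ny, nx), dtype=bool)
    for pts in contours:
        pts = np.asarray(pts, dtype=float)
        if pts.shape[0] < 3:
            continue
        idx = geometry.physical_to_index(pts)
        k = int(round(float(np.mean(idx[:, 2]))))
        if k < 0 or k >= nz:
            continue
        # polygon2mask takes (row, col) = (y-index, x-index)
        poly = np.column_stack([idx[:, 1], idx[:, 0]])
        out[k] ^= polygon2mask((ny, nx), poly)
    return BinaryMask(geometry, out, name=name)


def extract_contours(mask: BinaryMask) -> list[np.ndarray]:
    """Extract closed axial contours (mm, LPS) from a mask at the 0.5 level."""
    mask.geometry._require_axis_aligned()
    geom = mask.geometry
    contours: list[np.ndarray] = []
    for k in range(geom.array_shape[0]):
        sl = mask.values[k]
        if not sl.any():
            continue
        padded = np.pad(sl.astype(float), 1)
        for c in find_contours(padded, 0.5):
            rc = c - 1.0  # undo padding
            idx = np.column_stack(
                [rc[:, 1], rc[:, 0], np.full(len(rc), float(k))]
            )
            contours.append(geom.index_to_physical(idx))
    return contours


# ---------------------------------------------------------------------------
# DICOM-RT I/O
# ---------------------------------------------------------------------------

_CT_SOP = "1.2.840.10008.5.1.4.1.1.2"
_RTDOSE_SOP = "1.2.840.10008.5.1.4.1.1.481.2"
_RTSTRUCT_SOP = "1.2.840.10008.5.1.4.1.1.481.3"


def _base_dataset(sop_class: str, sop_instance: str) -> FileDataset:
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = sop_class
    meta.MediaStorageSOPInstanceUID = sop_instance
    meta.TransferSyntaxUID = pydicom.uid.ExplicitVRLittleEndian
    ds = FileDataset(None, {}, file_meta=meta, preamble=b"\x00" * 128)
    ds.SOPClassUID = sop_class
    ds.SOPInstanceUID = sop_instance
    now = datetime.datetime(2000, 1, 1)
    ds.ContentDate = now.strftime("%Y%m%d")
    ds.ContentTime = now.strftime("%H%M%S")
    return ds


def write_dicom_case(case: PatientCase, out_dir: str | Path) -> dict[str, Path]:
    """Emit a CT series, RTDOSE and RTSTRUCT for ``case``.

    Only axis-aligned geometries are supported (non-identity direction
    cosines raise).  Returns the paths written, keyed ``ct_dir``,
    ``rtdose`` and ``rtstruct``.
    """
    case.ct.geometry._require_axis_aligned()
    out_dir = Path(out_dir)
    ct_dir = out_dir / "ct"
    ct_dir.mkdir(parents=True, exist_ok=True)
    geom = case.ct.geometry
    frame_uid = generate_uid()
    study_uid = generate_uid()
    ct_series_uid = generate_uid()

    # --- CT series, one file per axial slice
    ct_uids: list[str] = []
    hu = np.clip(np.round(case.ct.values), -32768, 32767).astype(np.int16)
    for k in range(geom.shape[2]):
        sop = generate_uid()
        ct_uids.append(sop)
        ds = _base_dataset(_CT_SOP, sop)
        ds.Modality = "CT"
        ds.PatientName = ds.PatientID = case.id
        ds.StudyInstanceUID = study_uid
        ds.SeriesInstanceUID = ct_series_uid
        ds.FrameOfReferenceUID = frame_uid
        ds.InstanceNumber = k + 1
        ds.ImagePositionPatient = [
            geom.origin[0],
            geom.origin[1],
            geom.origin[2] + k * geom.spacing[2],
        ]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.PixelSpacing = [geom.spacing[1], geom.spacing[0]]  # row, col
        ds.SliceThickness = geom.spacing[2]
        ds.Rows, ds.Columns = geom.shape[1], geom.shape[0]
        ds.BitsAllocated = ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1  # signed (HU)
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.RescaleSlope = 1
        ds.RescaleIntercept = 0
        ds.PixelData = hu[k].tobytes()
        ds.save_as(ct_dir / f"ct_{k:04d}.dcm", enforce_file_format=True)

    # --- RTDOSE
    rtdose_path = out_dir / "rtdose.dcm"
    dose = case.dose
    if dose is None:
        dose = ImageVolume(geom, np.zeros(geom.array_shape), modality="DOSE")
    dmax = float(dose.values.max())
    scaling = dmax / (2**31 - 1) if dmax > 0 else 1.0
    stored = np.round(dose.values / scaling).astype(np.uint32)
    ds = _base_dataset(_RTDOSE_SOP, generate_uid())
    ds.Modality = "RTDOSE"
    ds.PatientName = ds.PatientID = case.id
    ds.StudyInstanceUID = study_uid
    ds.SeriesInstanceUID = generate_uid()
    ds.FrameOfReferenceUID = frame_uid
    dgeom = dose.geometry
    ds.ImagePositionPatient = list(dgeom.origin)
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    ds.PixelSpacing = [dgeom.spacing[1], dgeom.spacing[0]]
    ds.GridFrameOffsetVector = [k * dgeom.spacing[2] for k in range(dgeom.shape[2])]
    ds.NumberOfFrames = dgeom.shape[2]
    ds.Rows, ds.Columns = dgeom.shape[1], dgeom.shape[0]
    ds.BitsAllocated = ds.BitsStored = 32
    ds.HighBit = 31
    ds.PixelRepresentation = 0
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.DoseUnits = "GY"
    ds.DoseType = "PHYSICAL"
    ds.DoseSummationType = "PLAN"
    ds.DoseGridScaling = scaling
    ds.PixelData = stored.tobytes()
    ds.save_as(rtdose_path, enforce_file_format=True)

    # --- RTSTRUCT
    rtstruct_path = out_dir / "rtstruct.dcm"
    _write_rtstruct(
        case.structures,
        rtstruct_path,
        patient_id=case.id,
        frame_uid=frame_uid,
        study_uid=study_uid,
        ct_series_uid=ct_series_uid,
        ct_uids=ct_uids,
        geometry=geom,
    )
    return {"ct_dir": ct_dir, "rtdose": rtdose_path, "rtstruct": rtstruct_path}


def _write_rtstruct(
    structures: StructureSet,
    path: Path,
    *,
    patient_id: str,
    frame_uid: str,
    study_uid: str,
    ct_series_uid: str,
    ct_uids: list[str],
    geometry: GridGeometry,
) -> None:
    ds = _base_dataset(_RTSTRUCT_SOP, generate_uid())
    ds.Modality = "RTSTRUCT"
    ds.PatientName = ds.PatientID = patient_id
    ds.StudyInstanceUID = study_uid
    ds.SeriesInstanceUID = generate_uid()
    ds.StructureSetLabel = "dosemimic"

    ref_frame = Dataset()
    ref_frame.FrameOfReferenceUID = frame_uid
    ref_study = Dataset()
    ref_study.ReferencedSOPClassUID = "1.2.840.10008.3.1.2.3.1"
    ref_study.ReferencedSOPInstanceUID = study_uid
    ref_series = Dataset()
    ref_series.SeriesInstanceUID = ct_series_uid
    ref_series.ContourImageSequence = []
    for uid in ct_uids:
        ci = Dataset()
        ci.ReferencedSOPClassUID = _CT_SOP
        ci.ReferencedSOPInstanceUID = uid
        ref_series.ContourImageSequence.append(ci)
    ref_study.RTReferencedSeriesSequence = [ref_series]
    ref_frame.RTReferencedStudySequence = [ref_study]
    ds.ReferencedFrameOfReferenceSequence = [ref_frame]

    ds.StructureSetROISequence = []
    ds.ROIContourSequence = []
    ds.RTROIObservationsSequence = []
    names = structures.names() if len(structures) else []
    for number, name in enumerate(names, start=1):
        mask = structures[name]
        roi = Dataset()
        roi.ROINumber = number
        roi.ReferencedFrameOfReferenceUID = frame_uid
        roi.ROIName = name
        roi.ROIGenerationAlgorithm = "AUTOMATIC"
        ds.StructureSetROISequence.append(roi)

        rc = Dataset()
        rc.ReferencedROINumber = number
        rc.ContourSequence = []
        if not mask.values.any():
            warnings.warn(f"structure {name!r} is empty; writing zero contours")
        for pts in extract_contours(mask):
            c = Dataset()
            c.ContourGeometricType = "CLOSED_PLANAR"
            c.NumberOfContourPoints = len(pts)
            c.ContourData = [float(v) for v in pts.ravel()]
            k = int(round((pts[0, 2] - geometry.origin[2]) / geometry.spacing[2]))
            if 0 <= k < len(ct_uids):
                ci = Dataset()
                ci.ReferencedSOPClassUID = _CT_SOP
                ci.ReferencedSOPInstanceUID = ct_uids[k]
                c.ContourImageSequence = [ci]
            rc.ContourSequence.append(c)
        ds.ROIContourSequence.append(rc)

        obs = Dataset()
        obs.ObservationNumber = number
        obs.ReferencedROINumber = number
        obs.RTROIInterpretedType = ""
        obs.ROIInterpreter = ""
        ds.RTROIObservationsSequence.append(obs)
    ds.save_as(path, enforce_file_format=True)


def append_roi_to_rtstruct(
    rtstruct_path: str | Path,
    mask: BinaryMask,
    out_path: str | Path,
    name: str = "CompleteBlock",
) -> Path:
    """Copy an RTSTRUCT and append ``mask`` as a new ROI.

    A name collision gets a numeric suffix (logged as a warning).
    """
    ds = pydicom.dcmread(str(rtstruct_path))
    existing = {str(r.ROIName) for r in ds.StructureSetROISequence}
    final_name = name
    suffix = 1
    while final_name in existing:
        final_name = f"{name}_{suffix}"
        suffix += 1
    if final_name != name:
        warnings.warn(f"ROI name {name!r} exists; using {final_name!r}")
    numbers = [int(r.ROINumber) for r in ds.StructureSetROISequence] or [0]
    number = max(numbers) + 1
    frame_uid = ds.ReferencedFrameOfReferenceSequence[0].FrameOfReferenceUID

    roi = Dataset()
    roi.ROINumber = number
    roi.ReferencedFrameOfReferenceUID = frame_uid
    roi.ROIName = final_name
    roi.ROIGenerationAlgorithm = "AUTOMATIC"
    ds.StructureSetROISequence.append(roi)

    rc = Dataset()
    rc.ReferencedROINumber = number
    rc.ContourSequence = []
    if not mask.values.any():
        warnings.warn(f"block {final_name!r} is empty; writing zero contours")
    for pts in extract_contours(mask):
        c = Dataset()
        c.ContourGeometricType = "CLOSED_PLANAR"
        c.NumberOfContourPoints = len(pts)
        c.ContourData = [float(v) for v in pts.ravel()]
        rc.ContourSequence.append(c)
    ds.ROIContourSequence.append(rc)

    obs = Dataset()
    obs.ObservationNumber = number
    obs.ReferencedROINumber = number
    obs.RTROIInterpretedType = "AVOIDANCE"
    obs.ROIInterpreter = ""
    ds.RTROIObservationsSequence.append(obs)

    out_path = Path(out_path)
    ds.save_as(out_path)
    return out_path


def read_dicom_case(
    ct_dir: str | Path,
    rtdose: str | Path | None = None,
    rtstruct: str | Path | None = None,
    case_id: str | None = None,
    prescription_gy: float = 50.0,
) -> PatientCase:
    """Read a CT series plus optional RTDOSE / RTSTRUCT into a case.

    The dose grid is scaled by ``DoseGridScaling`` to Gy and resampled
    onto the CT geometry; contours rasterize to masks on the CT grid.
    A missing frame-of-reference linkage is a hard error; a structure
    with no contours yields an empty mask with a warning.
    """
    ct_dir = Path(ct_dir)
    slices = sorted(
        (pydicom.dcmread(p) for p in sorted(ct_dir.glob("*.dcm"))),
        key=lambda d: float(d.ImagePositionPatient[2]),
    )
    if not slices:
        raise ValueError(f"no DICOM files in {ct_dir}")
    first = slices[0]
    nx, ny, nz = int(first.Columns), int(first.Rows), len(slices)
    sx = float(first.PixelSpacing[1])
    sy = float(first.PixelSpacing[0])
    if nz > 1:
        sz = float(slices[1].ImagePositionPatient[2]) - float(
            first.ImagePositionPatient[2]
        )
    else:
        sz = float(getattr(first, "SliceThickness", 1.0))
    geom = GridGeometry(
        origin=tuple(float(v) for v in first.ImagePositionPatient),
        spacing=(sx, sy, sz),
        shape=(nx, ny, nz),
    )
    frame_uid = str(first.FrameOfReferenceUID)
    hu = np.stack(
        [
            d.pixel_array.astype(np.float64) * float(getattr(d, "RescaleSlope", 1))
            + float(getattr(d, "RescaleIntercept", 0))
            for d in slices
        ]
    )
    ct = ImageVolume(geom, hu, modality="CT")

    dose = None
    if rtdose is not None:
        dd = pydicom.dcmread(str(rtdose))
        if str(dd.FrameOfReferenceUID) != frame_uid:
            raise ValueError("RTDOSE frame of reference does not match CT series")
        offsets = [float(v) for v in dd.GridFrameOffsetVector]
        dz = offsets[1] - offsets[0] if len(offsets) > 1 else sz
        dgeom = GridGeometry(
            origin=(
                float(dd.ImagePositionPatient[0]),
                float(dd.ImagePositionPatient[1]),
                float(dd.ImagePositionPatient[2]) + offsets[0],
            ),
            spacing=(float(dd.PixelSpacing[1]), float(dd.PixelSpacing[0]), dz),
            shape=(int(dd.Columns), int(dd.Rows), int(dd.NumberOfFrames)),
        )
        arr = dd.pixel_array.astype(np.float64) * float(dd.DoseGridScaling)
        dose = ImageVolume(dgeom, arr, modality="DOSE")

    structures = StructureSet()
    if rtstruct is not None:
        rs = pydicom.dcmread(str(rtstruct))
        rs_frame = str(
            rs.ReferencedFrameOfReferenceSequence[0].FrameOfReferenceUID
        )
        if rs_frame != frame_uid:
            raise ValueError("RTSTRUCT frame of reference does not match CT series")
        roi_names = {
            int(r.ROINumber): str(r.ROIName) for r in rs.StructureSetROISequence
        }
        for rc in rs.ROIContourSequence:
            name = roi_names[int(rc.ReferencedROINumber)]
            contour_seq = getattr(rc, "ContourSequence", [])
            contours = [
                np.asarray(c.ContourData, dtype=float).reshape(-1, 3)
                for c in contour_seq
            ]
            if not contours:
                warnings.warn(f"structure {name!r} has no contours; empty mask")
                structures.add(name, BinaryMask(geom, np.zeros(geom.array_shape, bool)))
                continue
            structures.add(name, rasterize_contours(contours, geom, name=name))

    return PatientCase(
        id=case_id or str(getattr(first, "PatientID", "case")),
        ct=ct,
        dose=dose,
        structures=structures,
        prescription_gy=prescription_gy,
    )
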