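"""Image-stack container and I/O.

Two on-disk representations are supported:

* ``dicom_series`` — one CT-storage DICOM file per axial slice, with pixel
  values mapped to Hounsfield units through RescaleSlope/RescaleIntercept.
* ``raw_stack`` — a little-endian 32-bit float binary voxel file (slice-major)
  plus a plain-text sidecar header carrying dimensions and spacing. This
  dialect is fixed bit-exactly so fixtures are portable.

Conventions shared by all analysis modules: slices are ordered ascending along
the slice axis; in-plane coordinates are 0-based (row, col) with pixel centers
at integer coordinates, so physical x = col * pixel_spacing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

__all__ = ["ImageStack", "ProtocolMeta", "read_stack", "write_stack"]

StackFormat = Literal["dicom_series", "raw_stack"]

_HDR_NAME = "stack.hdr"
_RAW_NAME = "stack.raw"


@dataclass
class ProtocolMeta:
    """Acquisition metadata carried through reports (never used in computation)."""

    mode_name: str
    kv: float | None = None
    ma: float | None = None
    exposure_time_s: float | None = None
    ctdi_vol_mgy: float | None = None
    fov_mm: float | None = None
    reconstruction: str = "FBP"

    def __post_init__(self) -> None:
        if self.reconstruction not in ("FBP", "IR"):
            raise ValueError(
                f"reconstruction must be 'FBP' or 'IR', got {self.reconstruction!r}"
            )
        if self.fov_mm is not None and self.fov_mm <= 0:
            raise ValueError("fov_mm must be positive")

    def as_dict(self) -> dict:
        return {
            "mode_name": self.mode_name,
            "kV": self.kv,
            "mA": self.ma,
            "exposure_time_s": self.exposure_time_s,
            "ctdi_vol_mGy": self.ctdi_vol_mgy,
            "fov_mm": self.fov_mm,
            "reconstruction": self.reconstruction,
        }


@dataclass
class ImageStack:
    """A 3D stack of axial slices in Hounsfield units with spatial calibration.

    Parameters
    ----------
    voxels : ndarray, shape (n_slices, n_rows, n_cols)
        HU values, slice-major.
    pixel_spacing_mm : (float, float)
        In-plane (row, col) spacing in mm.
    slice_thickness_mm : float
        Per-slice extent along the stack axis in mm.
    meta : dict
        Free-form metadata (mode/reconstruction labels, acquisition
        parameters, ground-truth fields for synthetic stacks).
    """

    voxels: np.ndarray
    pixel_spacing_mm: tuple[float, float]
    slice_thickness_mm: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be 3D (slice, row, col)")
        sp = tuple(float(s) for s in np.atleast_1d(self.pixel_spacing_mm).ravel()[:2])
        if len(sp) == 1:
            sp = (sp[0], sp[0])
        self.pixel_spacing_mm = sp
        if min(sp) <= 0 or self.slice_thickness_mm <= 0:
            raise ValueError("pixel spacing and slice thickness must be positive")

    # -- convenience accessors -------------------------------------------
    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def validate_finite(self) -> None:
        if not np.isfinite(self.voxels).all():
            raise ValueError("stack contains non-finite voxel values")


# ---------------------------------------------------------------------------
# raw_stack dialect
# ---------------------------------------------------------------------------

def _write_raw(stack: ImageStack, path: Path) -> None:
    path.mkdir(parents=True, exist_ok=True)
    ns, nr, nc = stack.shape
    data = np.ascontiguousarray(stack.voxels, dtype="<f4")
    (path / _RAW_NAME).write_bytes(data.tobytes())
    lines = [
        "format: cbctiq-raw-stack-v1",
        f"n_slices: {ns}",
        f"n_rows: {nr}",
        f"n_cols: {nc}",
        f"pixel_spacing_row_mm: {stack.pixel_spacing_mm[0]!r}",
        f"pixel_spacing_col_mm: {stack.pixel_spacing_mm[1]!r}",
        f"slice_thickness_mm: {stack.slice_thickness_mm!r}",
        "dtype: float32",
        "byte_order: little",
        "order: slice-major",
        f"meta: {json.dumps(stack.meta, default=str)}",
    ]
    (path / _HDR_NAME).write_text("\n".join(lines) + "\n")


def _read_raw(path: Path) -> ImageStack:
    hdr_path = path / _HDR_NAME if path.is_dir() else path
    if not hdr_path.exists():
        raise FileNotFoundError(f"no raw-stack header at {hdr_path}")
    hdr: dict[str, str] = {}
    for line in hdr_path.read_text().splitlines():
        if ":" in line:
            k, v = line.split(":", 1)
            hdr[k.strip()] = v.strip()
    shape = (int(hdr["n_slices"]), int(hdr["n_rows"]), int(hdr["n_cols"]))
    raw = (hdr_path.parent / _RAW_NAME).read_bytes()
    vox = np.frombuffer(raw, dtype="<f4").reshape(shape).astype(np.float64)
    meta = json.loads(hdr.get("meta", "{}"))
    return ImageStack(
        voxels=vox,
        pixel_spacing_mm=(float(hdr["pixel_spacing_row_mm"]), float(hdr["pixel_spacing_col_mm"])),
        slice_thickness_mm=float(hdr["slice_thickness_mm"]),
        meta=meta,
    )


# ---------------------------------------------------------------------------
# dicom_series
# ---------------------------------------------------------------------------

_CT_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.2"
_RESCALE_INTERCEPT = -1024.0


def _write_dicom(stack: ImageStack, path: Path) -> None:
    path.mkdir(parents=True, exist_ok=True)
    series_uid = generate_uid()
    study_uid = generate_uid()
    for i in range(stack.n_slices):
        stored = np.round(stack.voxels[i] - _RESCALE_INTERCEPT)
        stored = np.clip(stored, -32768, 32767).astype("<i2")

        ds = Dataset()
        ds.file_meta = FileMetaDataset()
        ds.file_meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds.file_meta.MediaStorageSOPClassUID = _CT_SOP_CLASS
        ds.file_meta.MediaStorageSOPInstanceUID = generate_uid()
        ds.SOPClassUID = _CT_SOP_CLASS
        ds.SOPInstanceUID = ds.file_meta.MediaStorageSOPInstanceUID
        ds.Modality = "CT"
        ds.StudyInstanceUID = study_uid
        ds.SeriesInstanceUID = series_uid
        ds.InstanceNumber = i + 1
        ds.Rows, ds.Columns = stack.voxels.shape[1:]
        ds.PixelSpacing = [stack.pixel_spacing_mm[0], stack.pixel_spacing_mm[1]]
        ds.SliceThickness = stack.slice_thickness_mm
        ds.ImagePositionPatient = [0.0, 0.0, i * stack.slice_thickness_mm]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.RescaleSlope = 1.0
        ds.RescaleIntercept = _RESCALE_INTERCEPT
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1
        ds.PixelData = stored.tobytes()
        ds.save_as(path / f"slice_{i:04d}.dcm", enforce_file_format=True)


def _read_dicom(path: Path) -> ImageStack:
    files = sorted(path.glob("*.dcm")) if path.is_dir() else [path]
    if not files:
        raise FileNotFoundError(f"no DICOM files found in {path}")
    slices = []
    for f in files:
        ds = pydicom.dcmread(f)
        if "RescaleSlope" not in ds or "RescaleIntercept" not in ds:
            raise ValueError(f"missing rescale tags in {f}")
        spacing = tuple(float(s) for s in ds.PixelSpacing)
        z = float(ds.ImagePositionPatient[2]) if "ImagePositionPatient" in ds else 0.0
        hu = ds.pixel_array.astype(np.float64) * float(ds.RescaleSlope) + float(
            ds.RescaleIntercept
        )
        slices.append((z, spacing, float(ds.SliceThickness), hu))
    spacings = {s[1] for s in slices}
    if len(spacings) > 1:
        raise ValueError(f"mixed pixel spacings in series: {sorted(spacings)}")
    slices.sort(key=lambda s: s[0])
    vox = np.stack([s[3] for s in slices])
    return ImageStack(
        voxels=vox,
        pixel_spacing_mm=slices[0][1],
        slice_thickness_mm=slices[0][2],
    )


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def write_stack(stack: ImageStack, path: str | Path, format: StackFormat = "raw_stack") -> None:
    """Write *stack* to *path* (a directory) in the requested format.

    Refuses to write stacks containing non-finite voxels.
    """
    stack.validate_finite()
    path = Path(path)
    if format == "raw_stack":
        _write_raw(stack, path)
    elif format == "dicom_series":
        _write_dicom(stack, path)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_stack(path: str | Path, format: StackFormat = "raw_stack") -> ImageStack:
    """Read an :class:`ImageStack` from *path*.

    For ``dicom_series``, pixel values are converted to HU through the stored
    rescale slope/intercept and slices are ordered by position along the axis.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if format == "raw_stack":
        return _read_raw(path)
    if format == "dicom_series":
        return _read_dicom(path)
    raise ValueError(f"unknown format {format!r}")
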