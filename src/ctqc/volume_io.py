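"""DICOM series and PNG input/output.

Reads single-frame axial CT series into calibrated Hounsfield-unit (HU)
volumes with deterministic slice ordering, writes phantom volumes back out as
minimal DICOM series, and handles 8-bit grayscale PNG round trips for the
windowed representative images.

Conventions
-----------
* Volumes are indexed ``voxels[z, y, x]`` — slice (longitudinal), row
  (anterior→posterior), column (left→right).
* Slices are sorted ascending by their longitudinal position on load, so the
  result is independent of file naming.
* HU calibration follows the DICOM rescale model
  ``HU = stored * RescaleSlope + RescaleIntercept``; series are written with
  slope 1 / intercept −1024, which represents integer HU in [−1024, 3071]
  exactly in unsigned 12-bit-compatible storage.
"""

from __future__ import annotations

import logging
import uuid
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid
from PIL import Image

logger = logging.getLogger(__name__)

__all__ = [
    "CTVolume",
    "SeriesMeta",
    "SeriesReadError",
    "load_dicom_series",
    "write_dicom_series",
    "write_png",
    "read_png",
]

_CT_STORAGE_UID = "1.2.840.10008.5.1.4.1.1.2"


class SeriesReadError(ValueError):
    """Raised when a directory does not hold one readable, consistent CT series."""


@dataclass
class SeriesMeta:
    """DICOM calibration and geometry metadata for one series."""

    rescale_slope: float = 1.0
    rescale_intercept: float = 0.0
    slice_positions: list[float] = field(default_factory=list)
    modality: str = "CT"


@dataclass
class CTVolume:
    """A 3D CT scan in Hounsfield units; the unit of classification.

    Attributes
    ----------
    voxels : ndarray, shape (n_slices, n_rows, n_cols)
        HU values indexed ``[z, y, x]``, slice index ascending with the
        longitudinal patient-axis position.
    spacing : tuple of float
        ``(dz, dy, dx)`` in millimetres.
    series_id : str
        Opaque series identifier.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    series_id: str = ""
    meta: SeriesMeta | None = None

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be 3D [slice, row, column]")
        if min(self.voxels.shape) < 1:
            raise ValueError("empty volume")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("HU values must be finite")
        if not self.series_id:
            self.series_id = uuid.uuid4().hex[:12]

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def n_rows(self) -> int:
        return self.voxels.shape[1]

    @property
    def n_cols(self) -> int:
        return self.voxels.shape[2]


def load_dicom_series(directory: str | Path) -> CTVolume:
    """Load one single-frame CT DICOM series from *directory*.

    Slices are sorted ascending by ``ImagePositionPatient[2]`` (falling back
    to ``SliceLocation``), so the returned volume does not depend on file
    names or listing order. Stored pixel values are converted to HU with the
    per-file rescale slope/intercept; missing rescale tags default to
    slope 1 / intercept 0 with a warning.

    Raises
    ------
    SeriesReadError
        If the directory holds no DICOM files ("no series found"), files from
        more than one series ("mixed series"), or slices whose in-plane
        shapes disagree ("inconsistent geometry").
    """
    directory = Path(directory)
    paths = sorted(p for p in directory.iterdir() if p.is_file()) if directory.is_dir() else []
    datasets = []
    for p in paths:
        try:
            datasets.append(pydicom.dcmread(p))
        except Exception:  # non-DICOM clutter is skipped
            continue
    if not datasets:
        raise SeriesReadError(f"no series found in {directory}")

    series_uids = {str(getattr(ds, "SeriesInstanceUID", "")) for ds in datasets}
    if len(series_uids) != 1:
        raise SeriesReadError(f"mixed series in {directory}: {sorted(series_uids)}")

    shapes = {(int(ds.Rows), int(ds.Columns)) for ds in datasets}
    if len(shapes) != 1:
        raise SeriesReadError(f"inconsistent geometry in {directory}: {sorted(shapes)}")

    def zpos(ds: Dataset) -> float:
        if getattr(ds, "ImagePositionPatient", None) is not None:
            return float(ds.ImagePositionPatient[2])
        return float(getattr(ds, "SliceLocation", 0.0))

    datasets.sort(key=zpos)
    positions = [zpos(ds) for ds in datasets]

    slices = []
    meta = SeriesMeta(slice_positions=positions)
    for ds in datasets:
        slope = getattr(ds, "RescaleSlope", None)
        intercept = getattr(ds, "RescaleIntercept", None)
        if slope is None or intercept is None:
            logger.warning("missing rescale tags in %s; assuming slope 1, intercept 0",
                           getattr(ds, "SOPInstanceUID", "?"))
            slope = 1.0 if slope is None else slope
            intercept = 0.0 if intercept is None else intercept
        meta.rescale_slope = float(slope)
        meta.rescale_intercept = float(intercept)
        slices.append(ds.pixel_array.astype(np.float64) * float(slope) + float(intercept))

    dy, dx = (float(v) for v in getattr(datasets[0], "PixelSpacing", [1.0, 1.0]))
    if len(positions) > 1:
        dz = float(np.median(np.diff(positions)))
    else:
        dz = float(getattr(datasets[0], "SliceThickness", 1.0))
    series_id = str(
        getattr(datasets[0], "SeriesDescription", "") or datasets[0].SeriesInstanceUID
    )
    return CTVolume(
        voxels=np.stack(slices, axis=0),
        spacing=(dz or 1.0, dy, dx),
        series_id=series_id,
        meta=meta,
    )


def write_dicom_series(volume: CTVolume, directory: str | Path) -> list[Path]:
    """Write *volume* as one minimal single-frame CT DICOM file per slice.

    Uses slope 1 / intercept −1024 so every integer HU value in
    [−1024, 3071] survives the round trip exactly. HU values are rounded to
    the nearest integer on store.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    intercept = -1024.0
    stored = np.round(volume.voxels - intercept)
    if stored.min() < 0 or stored.max() > 4095:
        raise ValueError("HU out of representable range [-1024, 3071]")
    stored = stored.astype(np.uint16)

    series_uid = generate_uid(entropy_srcs=[volume.series_id])
    study_uid = generate_uid(entropy_srcs=[volume.series_id, "study"])
    dz, dy, dx = volume.spacing
    out: list[Path] = []
    for z in range(volume.n_slices):
        ds = Dataset()
        ds.file_meta = FileMetaDataset()
        ds.file_meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds.file_meta.MediaStorageSOPClassUID = _CT_STORAGE_UID
        sop_uid = generate_uid(entropy_srcs=[volume.series_id, str(z)])
        ds.file_meta.MediaStorageSOPInstanceUID = sop_uid
        ds.SOPClassUID = _CT_STORAGE_UID
        ds.SOPInstanceUID = sop_uid
        ds.Modality = "CT"
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.SeriesDescription = volume.series_id
        ds.InstanceNumber = z + 1
        ds.Rows, ds.Columns = volume.n_rows, volume.n_cols
        ds.PixelSpacing = [dy, dx]
        ds.SliceThickness = dz
        ds.ImagePositionPatient = [0.0, 0.0, z * dz]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.SliceLocation = z * dz
        ds.RescaleSlope = 1.0
        ds.RescaleIntercept = intercept
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.PixelData = stored[z].tobytes()
        path = directory / f"slice_{z:04d}.dcm"
        ds.save_as(path, enforce_file_format=True)
        out.append(path)
    return out


def write_png(image: np.ndarray, path: str | Path) -> Path:
    """Write a 2D [0,1] image as an 8-bit single-channel grayscale PNG."""
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("expected a 2D image")
    if image.min() < 0.0 or image.max() > 1.0:
        raise ValueError("pixel values must lie in [0,1]; window the image first")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    quantized = np.round(image * 255.0).astype(np.uint8)
    Image.fromarray(quantized, mode="L").save(path, format="PNG")
    return path


def read_png(path: str | Path) -> np.ndarray:
    """Read an 8-bit grayscale PNG back into a 2D float array in [0,1]."""
    with Image.open(path) as img:
        arr = np.asarray(img.convert("L"), dtype=np.float64)
    return arr / 255.0
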