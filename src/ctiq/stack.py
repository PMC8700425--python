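"""Image stacks and file I/O.

An :class:`ImageStack` is the unit of input for every estimator: a 3D array of
Hounsfield units (slice, row, column) plus the in-plane pixel spacing in mm.
Stacks round-trip through three on-disk representations:

* multi-page TIFF (32-bit float HU) with a JSON sidecar for metadata,
* a DICOM series (one CT Image Storage file per slice, rescale slope and
  intercept set so stored values map back to HU),
* raw little-endian float32 binary with a JSON sidecar carrying the geometry.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import InputError

__all__ = [
    "ImageStack",
    "write_tiff",
    "read_tiff",
    "write_dicom_series",
    "read_dicom_series",
    "write_raw",
    "read_raw",
    "read_stack",
]


@dataclass
class ImageStack:
    """3D HU voxel array with pixel spacing and provenance metadata.

    Parameters
    ----------
    data : ndarray, shape (n_slices, ny, nx)
        Voxel values in HU.
    pixel_spacing : float
        In-plane pixel size in mm (isotropic).
    metadata : dict
        Free-form provenance; simulated stacks record their ground-truth
        geometry, blur and noise parameters here for recovery tests.
    """

    data: np.ndarray
    pixel_spacing: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim == 2:
            self.data = self.data[None]
        if self.data.ndim != 3:
            raise InputError(f"stack data must be 3D, got shape {self.data.shape}")
        if self.pixel_spacing <= 0:
            raise InputError("pixel_spacing must be positive")

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]

    @property
    def nyquist(self) -> float:
        """In-plane Nyquist frequency, 1/(2*pixel_spacing), in mm^-1."""
        return 1.0 / (2.0 * self.pixel_spacing)

    def mean_slice(self) -> np.ndarray:
        return self.data.mean(axis=0)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def _metadata_payload(stack: ImageStack) -> dict:
    return {
        "pixel_spacing_mm": stack.pixel_spacing,
        "shape": list(stack.data.shape),
        "metadata": stack.metadata,
    }


def write_tiff(stack: ImageStack, path: str | Path) -> Path:
    """Write a multi-page float32 TIFF plus a ``<name>.tif.json`` sidecar."""
    import tifffile

    path = Path(path)
    tifffile.imwrite(path, stack.data.astype(np.float32), photometric="minisblack")
    _sidecar_path(path).write_text(json.dumps(_metadata_payload(stack), indent=2))
    return path


def read_tiff(path: str | Path) -> ImageStack:
    import tifffile

    path = Path(path)
    data = np.asarray(tifffile.imread(path), dtype=float)
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        payload = json.loads(sidecar.read_text())
        spacing = float(payload["pixel_spacing_mm"])
        metadata = payload.get("metadata", {})
    else:
        raise InputError(f"missing sidecar metadata file {sidecar}")
    return ImageStack(data, spacing, metadata)


def write_dicom_series(stack: ImageStack, out_dir: str | Path) -> Path:
    """Write one CT Image Storage file per slice.

    Values are stored as rounded int16 with RescaleSlope 1 / RescaleIntercept 0,
    so HU round-trip to within 0.5 HU.
    """
    import pydicom
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    series_uid = generate_uid()
    study_uid = generate_uid()
    for i, sl in enumerate(stack.data):
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = pydicom.uid.CTImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = Dataset()
        ds.file_meta = meta
        ds.SOPClassUID = meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.Modality = "CT"
        ds.InstanceNumber = i + 1
        ds.Rows, ds.Columns = sl.shape
        ds.PixelSpacing = [f"{stack.pixel_spacing:.10g}", f"{stack.pixel_spacing:.10g}"]
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1  # signed
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.RescaleSlope = "1"
        ds.RescaleIntercept = "0"
        ds.PixelData = np.round(sl).astype(np.int16).tobytes()
        pydicom.dcmwrite(out_dir / f"slice_{i:04d}.dcm", ds, enforce_file_format=True)
    (out_dir / "metadata.json").write_text(json.dumps(_metadata_payload(stack), indent=2))
    return out_dir


def read_dicom_series(path: str | Path) -> ImageStack:
    import pydicom

    path = Path(path)
    files = sorted(path.glob("*.dcm"))
    if not files:
        raise InputError(f"no DICOM files in {path}")
    datasets = [pydicom.dcmread(f) for f in files]
    datasets.sort(key=lambda d: int(getattr(d, "InstanceNumber", 0)))
    slices = []
    for ds in datasets:
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        slices.append(ds.pixel_array.astype(float) * slope + intercept)
    spacing = float(datasets[0].PixelSpacing[0])
    metadata = {}
    meta_file = path / "metadata.json"
    if meta_file.exists():
        metadata = json.loads(meta_file.read_text()).get("metadata", {})
    return ImageStack(np.stack(slices), spacing, metadata)


def write_raw(stack: ImageStack, path: str | Path) -> Path:
    """Write little-endian float32 binary plus a ``<name>.bin.json`` sidecar."""
    path = Path(path)
    stack.data.astype("<f4").tofile(path)
    _sidecar_path(path).write_text(json.dumps(_metadata_payload(stack), indent=2))
    return path


def read_raw(path: str | Path) -> ImageStack:
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise InputError(f"missing sidecar geometry file {sidecar}")
    payload = json.loads(sidecar.read_text())
    shape = tuple(payload["shape"])
    data = np.fromfile(path, dtype="<f4").reshape(shape)
    return ImageStack(data, float(payload["pixel_spacing_mm"]), payload.get("metadata", {}))


def read_stack(path: str | Path) -> ImageStack:
    """Dispatch on path: directory -> DICOM series, .tif/.tiff -> TIFF,
    .bin/.raw -> raw binary."""
    path = Path(path)
    if path.is_dir():
        return read_dicom_series(path)
    suffix = path.suffix.lower()
    if suffix in {".tif", ".tiff"}:
        return read_tiff(path)
    if suffix in {".bin", ".raw"}:
        return read_raw(path)
    raise InputError(f"unrecognized stack format: {path}")
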