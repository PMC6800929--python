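"""CT volume I/O: DICOM series reading/writing, 12-bit quantisation, protocol checks.

Volumes are held as integer Hounsfield-unit (HU) lattices indexed ``[z, y, x]``
(z is the slice axis).  Public coordinates such as seed points use ``(x, y, z)``
order, matching how a reader picks a point on an axial slice.

DICOM is the canonical interchange format; a lossless ``.npz`` + JSON-sidecar
archive is provided for fast fixtures and pipeline intermediates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pydicom
from pydicom.dataset import FileDataset, FileMetaDataset
from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid

HU_MIN = -1024
HU_MAX = 3071  # 4096 levels: [-1024, 3071]

#: acquisition-protocol acceptance band for slice thickness (mm)
THICKNESS_RANGE = (0.90, 1.25)
#: required in-plane matrix
REQUIRED_MATRIX = (512, 512)
#: tolerance for inter-slice spacing uniformity (mm); metadata jitter allowance
SPACING_TOLERANCE = 0.01


def round_half_away(x: np.ndarray | float) -> np.ndarray:
    """Round half away from zero (deterministic across platforms, unlike
    numpy's banker's rounding)."""
    x = np.asarray(x, dtype=float)
    return np.copysign(np.floor(np.abs(x) + 0.5), x)


@dataclass
class CTVolume:
    """A CT volume in Hounsfield units.

    Attributes
    ----------
    voxels : ndarray, shape (nz, ny, nx), integer HU
    spacing : (dx, dy, dz) in mm
    slice_thickness : mm
    series_metadata : free-form acquisition record (kV, mA, kernel, ...)
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    slice_thickness: float
    series_metadata: dict[str, Any] = field(default_factory=dict)

    @property
    def matrix_size(self) -> tuple[int, int]:
        """(rows, cols) of the axial plane."""
        return (self.voxels.shape[1], self.voxels.shape[2])

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    def hu_at(self, x: int, y: int, z: int) -> int:
        return int(self.voxels[z, y, x])

    def validate(self) -> None:
        """Raise ValueError if any CTVolume invariant is violated."""
        if self.voxels.ndim != 3:
            raise ValueError("voxel lattice must be 3-D")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing components must be strictly positive")
        v = self.voxels
        if v.size and (v.min() < HU_MIN or v.max() > HU_MAX):
            raise ValueError(
                f"HU values outside the 12-bit range [{HU_MIN}, {HU_MAX}]"
            )


@dataclass
class ProtocolReport:
    """Outcome of checking a volume against the acquisition protocol."""

    violations: list[tuple[str, Any, Any]] = field(default_factory=list)

    @property
    def conformant(self) -> bool:
        return not self.violations


def quantize_12bit(volume: CTVolume) -> CTVolume:
    """Clamp and round HU values onto the 4096 integer levels of a 12-bit
    CT representation, [-1024, 3071].  Idempotent and order-preserving."""
    q = round_half_away(volume.voxels)
    q = np.clip(q, HU_MIN, HU_MAX).astype(np.int16)
    return CTVolume(q, volume.spacing, volume.slice_thickness,
                    dict(volume.series_metadata))


def validate_protocol(volume: CTVolume) -> ProtocolReport:
    """Check slice thickness and in-plane matrix against the study protocol.

    All violations are reported, not just the first; a volume is conformant
    iff the slice thickness lies in [0.90, 1.25] mm and the matrix is 512x512.
    """
    report = ProtocolReport()
    lo, hi = THICKNESS_RANGE
    if not (lo <= volume.slice_thickness <= hi):
        report.violations.append(
            ("slice_thickness", volume.slice_thickness, THICKNESS_RANGE))
    if volume.matrix_size != REQUIRED_MATRIX:
        report.violations.append(
            ("matrix_size", volume.matrix_size, REQUIRED_MATRIX))
    return report


# ---------------------------------------------------------------------------
# DICOM series
# ---------------------------------------------------------------------------

def write_dicom_series(volume: CTVolume, directory: str | Path) -> Path:
    """Write one single-frame CT DICOM file per slice.

    Stored values are HU + 1024 (uint16) with RescaleSlope 1 and
    RescaleIntercept -1024, so reading the series back recovers the HU
    lattice exactly.
    """
    volume.validate()
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    series_uid = generate_uid(entropy_srcs=["noduletex-series"])
    study_uid = generate_uid(entropy_srcs=["noduletex-study"])
    dx, dy, dz = volume.spacing

    for z in range(volume.n_slices):
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = CTImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid(
            entropy_srcs=[f"noduletex-slice-{z}"])
        meta.TransferSyntaxUID = ExplicitVRLittleEndian

        ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
        ds.SOPClassUID = CTImageStorage
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.Modality = "CT"
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.InstanceNumber = z + 1
        ds.ImagePositionPatient = [0.0, 0.0, float(z) * dz]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.PixelSpacing = [dy, dx]  # row spacing, column spacing
        ds.SliceThickness = volume.slice_thickness
        ds.Rows, ds.Columns = volume.matrix_size
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.RescaleSlope = 1
        ds.RescaleIntercept = -1024
        for key, value in volume.series_metadata.items():
            if hasattr(ds, key) or key in pydicom.datadict.keyword_dict:
                setattr(ds, key, value)
        stored = volume.voxels[z].astype(np.int64) + 1024
        if stored.min() < 0 or stored.max() > 0xFFFF:
            raise ValueError("HU outside representable stored range")
        ds.PixelData = stored.astype(np.uint16).tobytes()
        ds.save_as(directory / f"slice_{z:04d}.dcm", enforce_file_format=True)
    return directory


def _slice_position(ds: pydicom.Dataset) -> float:
    """Projection of ImagePositionPatient onto the slice normal."""
    orient = np.asarray(ds.ImageOrientationPatient, dtype=float)
    normal = np.cross(orient[:3], orient[3:])
    pos = np.asarray(ds.ImagePositionPatient, dtype=float)
    return float(pos @ normal)


def read_dicom_series(directory: str | Path) -> CTVolume:
    """Read a single-frame axial CT series into a CTVolume.

    Slices are ordered by the image-position coordinate along the slice
    normal (file names are not trusted).  Stored values are mapped to HU via
    the rescale slope/intercept tags; missing rescale metadata, mixed series,
    or non-uniform inter-slice spacing are errors.
    """
    directory = Path(directory)
    files = sorted(directory.glob("*.dcm"))
    if not files:
        raise FileNotFoundError(f"no DICOM files in {directory}")
    datasets = [pydicom.dcmread(f) for f in files]

    uids = {ds.SeriesInstanceUID for ds in datasets}
    if len(uids) > 1:
        raise ValueError("mixed series identifiers in directory")
    for tag in ("RescaleSlope", "RescaleIntercept"):
        for ds in datasets:
            if getattr(ds, tag, None) is None:
                raise ValueError(f"missing rescale metadata: {tag}")

    datasets.sort(key=_slice_position)
    positions = np.array([_slice_position(ds) for ds in datasets])
    if len(datasets) > 1:
        gaps = np.diff(positions)
        dz = float(np.mean(gaps))
        if np.any(np.abs(gaps - dz) > SPACING_TOLERANCE):
            raise ValueError("non-uniform inter-slice spacing beyond tolerance")
    else:
        dz = float(getattr(datasets[0], "SliceThickness", 1.0))

    slices = []
    for ds in datasets:
        hu = ds.pixel_array.astype(np.float64) * float(ds.RescaleSlope) \
            + float(ds.RescaleIntercept)
        slices.append(round_half_away(hu).astype(np.int16))
    voxels = np.stack(slices, axis=0)

    row_sp, col_sp = (float(v) for v in datasets[0].PixelSpacing)
    thickness = float(getattr(datasets[0], "SliceThickness", dz))
    meta = {}
    for key in ("KVP", "XRayTubeCurrent", "ConvolutionKernel", "Manufacturer"):
        if hasattr(datasets[0], key):
            meta[key] = datasets[0].get(key)
    return CTVolume(voxels, (col_sp, row_sp, dz), thickness, meta)


# ---------------------------------------------------------------------------
# Fixture archive (lossless, fast)
# ---------------------------------------------------------------------------

def save_archive(volume: CTVolume, path: str | Path) -> Path:
    """Save as compressed array container + JSON sidecar; lossless."""
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(path, voxels=volume.voxels)
    sidecar = {
        "spacing": list(volume.spacing),
        "slice_thickness": volume.slice_thickness,
        "series_metadata": {k: str(v) for k, v in volume.series_metadata.items()},
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path


def load_archive(path: str | Path) -> CTVolume:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    with np.load(path) as data:
        voxels = data["voxels"]
    sidecar = json.loads(path.with_suffix(".json").read_text())
    return CTVolume(
        voxels,
        tuple(sidecar["spacing"]),
        float(sidecar["slice_thickness"]),
        dict(sidecar.get("series_metadata", {})),
    )
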