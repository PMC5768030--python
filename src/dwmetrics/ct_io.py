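"""Reading, writing and normalising CT image series.

One reconstructed axial image per DICOM file. On read, stored pixel values
are immediately converted to Hounsfield units (HU = raw * RescaleSlope +
RescaleIntercept) and vendor padding sentinels outside the reconstruction
circle (e.g. -2000, -3024) are replaced by air (-1000 HU), so every
downstream computation sees a physically meaningful HU grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pydicom
import yaml
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid

AIR_HU = -1000.0
DEFAULT_PADDING_SENTINEL = -1500.0

#: rescale convention used by the writer (HU = raw * 1 + (-1024))
_RESCALE_INTERCEPT = -1024.0
_RESCALE_SLOPE = 1.0

EXAM_TYPES = ("chest", "CAP", "phantom")


@dataclass
class PatientBio:
    """Patient biometrics as recorded at examination time."""

    weight: float  # kg
    height: float  # cm
    sex: str  # 'F' | 'M'
    age: Optional[float] = None  # years

    def __post_init__(self) -> None:
        if self.weight <= 0 or self.height <= 0:
            raise ValueError("weight and height must be positive")
        if self.sex not in ("F", "M"):
            raise ValueError(f"sex must be 'F' or 'M', got {self.sex!r}")


@dataclass
class CTSlice:
    """One reconstructed CT image in HU, plus acquisition metadata.

    ``pixels`` is a 2-D float array of CT numbers in HU with padding
    sentinels already masked to air.  ``pixel_spacing`` is (row, col) in mm.
    """

    pixels: np.ndarray
    pixel_spacing: tuple[float, float]
    z_position: float  # mm along the table axis
    tube_current: Optional[float] = None  # mA
    slice_id: int = 0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D array")
        if len(self.pixel_spacing) != 2 or any(s <= 0 for s in self.pixel_spacing):
            raise ValueError("pixel_spacing components must be positive")

    @property
    def pixel_area_mm2(self) -> float:
        """Area of one pixel in mm^2."""
        return float(self.pixel_spacing[0] * self.pixel_spacing[1])


@dataclass
class ScanSeries:
    """An ordered stack of CT slices plus examination metadata."""

    slices: list[CTSlice]
    ctdi_vol: Optional[float] = None  # mGy, 32-cm phantom reference
    exam_type: str = "phantom"
    scanner_id: str = ""
    patient: Optional[PatientBio] = None
    #: analytic ground truth attached by the synthetic generator, if any
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.slices:
            raise ValueError("a series must contain at least one slice")
        z = [s.z_position for s in self.slices]
        if any(b <= a for a, b in zip(z, z[1:])):
            raise ValueError("slices must be strictly ordered by z_position")
        if self.ctdi_vol is not None and self.ctdi_vol < 0:
            raise ValueError("ctdi_vol must be >= 0")
        if self.exam_type not in EXAM_TYPES:
            raise ValueError(f"exam_type must be one of {EXAM_TYPES}")

    @property
    def z_positions(self) -> np.ndarray:
        return np.array([s.z_position for s in self.slices])

    @property
    def tube_currents(self) -> Optional[np.ndarray]:
        """Per-slice tube current in mA, or None if any slice lacks it."""
        currents = [s.tube_current for s in self.slices]
        if any(c is None for c in currents):
            return None
        return np.array(currents, dtype=float)


def mask_padding(pixels: np.ndarray, sentinel_threshold: float = DEFAULT_PADDING_SENTINEL) -> np.ndarray:
    """Replace padding-sentinel pixels (at or below ``sentinel_threshold``) by air.

    Scanners pad the region outside the reconstruction circle with large
    negative sentinels; replacing them by -1000 HU makes them contribute
    zero water-equivalent area, leaving D_w unchanged while removing
    vendor-specific values.  Idempotent.
    """
    if sentinel_threshold > DEFAULT_PADDING_SENTINEL:
        raise ValueError("sentinel_threshold must be <= -1500 HU")
    out = np.asarray(pixels, dtype=float).copy()
    out[out <= sentinel_threshold] = AIR_HU
    return out


def write_series(series: ScanSeries, path: str | Path) -> list[Path]:
    """Write a series as one CT DICOM file per slice; returns the file list.

    Pixels are stored as signed 16-bit with slope 1 / intercept -1024, so a
    read-back reproduces HU within the 0.5 HU rounding of quantisation.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    series_uid = generate_uid()
    study_uid = generate_uid()
    files: list[Path] = []
    for i, sl in enumerate(series.slices):
        ds = Dataset()
        ds.file_meta = FileMetaDataset()
        ds.file_meta.MediaStorageSOPClassUID = CTImageStorage
        ds.file_meta.MediaStorageSOPInstanceUID = generate_uid()
        ds.file_meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds.SOPClassUID = CTImageStorage
        ds.SOPInstanceUID = ds.file_meta.MediaStorageSOPInstanceUID
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.Modality = "CT"
        ds.SeriesDescription = series.exam_type
        ds.StationName = series.scanner_id[:16]
        ds.InstanceNumber = i + 1

        ds.Rows, ds.Columns = sl.pixels.shape
        ds.PixelSpacing = [float(sl.pixel_spacing[0]), float(sl.pixel_spacing[1])]
        ds.SliceLocation = float(sl.z_position)
        ds.ImagePositionPatient = [0.0, 0.0, float(sl.z_position)]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.RescaleSlope = _RESCALE_SLOPE
        ds.RescaleIntercept = _RESCALE_INTERCEPT
        if sl.tube_current is not None:
            # XRayTubeCurrent is integer-valued (IS); keep full precision in
            # the floating-point companion element (0018,9330)
            ds.XRayTubeCurrent = int(round(sl.tube_current))
            ds.XRayTubeCurrentInmA = float(sl.tube_current)
        if series.ctdi_vol is not None:
            ds.CTDIvol = float(series.ctdi_vol)
        if series.patient is not None:
            ds.PatientWeight = float(series.patient.weight)
            ds.PatientSize = float(series.patient.height) / 100.0
            ds.PatientSex = series.patient.sex

        raw = np.round(sl.pixels - _RESCALE_INTERCEPT)
        raw = np.clip(raw, np.iinfo(np.int16).min, np.iinfo(np.int16).max).astype(np.int16)
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1
        ds.PixelData = raw.tobytes()

        fname = path / f"slice_{i:04d}.dcm"
        ds.save_as(fname, enforce_file_format=True)
        files.append(fname)
    return files


def _slice_z(ds: Dataset, fname: Path) -> float:
    if "SliceLocation" in ds:
        return float(ds.SliceLocation)
    if "ImagePositionPatient" in ds:
        return float(ds.ImagePositionPatient[2])
    raise ValueError(f"{fname}: no SliceLocation or ImagePositionPatient")


def read_series(
    path: str | Path | Sequence[str | Path],
    padding_sentinel: float = DEFAULT_PADDING_SENTINEL,
) -> ScanSeries:
    """Read a directory (or explicit file list) of CT DICOM files into a ScanSeries.

    Slices are z-sorted ascending regardless of presentation order; pixel
    values are HU-rescaled and padding-masked.  All files must share one
    SeriesInstanceUID.  Missing CTDIvol metadata leaves ``ctdi_vol`` unset.
    """
    if isinstance(path, (str, Path)):
        p = Path(path)
        files = sorted(p.glob("*.dcm")) if p.is_dir() else [p]
    else:
        files = [Path(f) for f in path]
    if not files:
        raise ValueError(f"no DICOM files found at {path}")

    series_uid = None
    slices: list[tuple[float, CTSlice]] = []
    ctdi_vol = None
    exam_type = "phantom"
    scanner_id = ""
    patient = None
    spacings = set()
    for fname in files:
        ds = pydicom.dcmread(fname)
        uid = getattr(ds, "SeriesInstanceUID", None)
        if series_uid is None:
            series_uid = uid
        elif uid != series_uid:
            raise ValueError(f"mixed SeriesInstanceUID: {fname} does not belong to the series")
        if "RescaleSlope" not in ds or "RescaleIntercept" not in ds:
            raise ValueError(f"{fname}: missing rescale slope/intercept metadata")
        hu = ds.pixel_array.astype(float) * float(ds.RescaleSlope) + float(ds.RescaleIntercept)
        hu = mask_padding(hu, padding_sentinel)
        spacing = (float(ds.PixelSpacing[0]), float(ds.PixelSpacing[1]))
        spacings.add(spacing)
        current = None
        if "XRayTubeCurrentInmA" in ds:
            current = float(ds.XRayTubeCurrentInmA)
        elif "XRayTubeCurrent" in ds:
            current = float(ds.XRayTubeCurrent)
        z = _slice_z(ds, fname)
        slices.append((z, CTSlice(hu, spacing, z, tube_current=current)))
        if "CTDIvol" in ds:
            ctdi_vol = float(ds.CTDIvol)
        if getattr(ds, "SeriesDescription", "") in EXAM_TYPES:
            exam_type = str(ds.SeriesDescription)
        if getattr(ds, "StationName", ""):
            scanner_id = str(ds.StationName)
        if "PatientWeight" in ds and "PatientSize" in ds and "PatientSex" in ds:
            patient = PatientBio(
                weight=float(ds.PatientWeight),
                height=float(ds.PatientSize) * 100.0,
                sex=str(ds.PatientSex),
            )
    if len(spacings) > 1:
        warnings.warn("nonuniform pixel spacing across slices; per-slice spacing retained")

    slices.sort(key=lambda t: t[0])
    ordered = []
    for i, (_, sl) in enumerate(slices):
        sl.slice_id = i
        ordered.append(sl)
    return ScanSeries(
        slices=ordered,
        ctdi_vol=ctdi_vol,
        exam_type=exam_type,
        scanner_id=scanner_id,
        patient=patient,
    )


def load_scanner_config(path: str | Path) -> dict:
    """Load a YAML map of scanner_id -> {table_aw_cm2, padding_sentinel}."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("scanner config must be a mapping of scanner_id to settings")
    out = {}
    for scanner, entry in cfg.items():
        entry = entry or {}
        out[str(scanner)] = {
            "table_aw_cm2": float(entry.get("table_aw_cm2", 0.0)),
            "padding_sentinel": float(entry.get("padding_sentinel", DEFAULT_PADDING_SENTINEL)),
        }
    return out
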