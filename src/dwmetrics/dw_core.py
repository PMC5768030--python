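"""Water-equivalent diameter computation.

The water-equivalent area of a region of interest with mean CT number
<CT> (HU) and geometric area A is

    A_w = (<CT>/1000) * A + A

and the water-equivalent diameter of a slice, after subtracting the
couch's water-equivalent area A_w(table), is

    D_w = 2 * sqrt((A_w - A_w(table)) / pi).

The ROI here is always the whole (padding-masked) image: surrounding air
has <CT> = -1000 HU and contributes nothing to A_w, so no body contour is
needed.  Per-series scalar metrics: D_w_c (mid-scan slice) and D_w_ave
(unweighted mean over slices).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .ct_io import CTSlice, ScanSeries

MM2_PER_CM2 = 100.0


@dataclass
class TableCalibration:
    """Water-equivalent area of the patient couch for one scanner, in cm^2."""

    aw_table: float = 0.0
    scanner_id: str = ""

    def __post_init__(self) -> None:
        if self.aw_table < 0:
            raise ValueError("aw_table must be >= 0")


@dataclass
class DwProfile:
    """Per-slice D_w(z) along a series, with the tube-current trace if known."""

    z: np.ndarray  # mm, strictly increasing
    dw: np.ndarray  # cm
    current: Optional[np.ndarray] = None  # mA
    exam_type: str = "phantom"
    ctdi_vol: Optional[float] = None  # mGy

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.dw = np.asarray(self.dw, dtype=float)
        if self.z.size < 1 or self.z.shape != self.dw.shape:
            raise ValueError("z and dw must be equal-length arrays of length >= 1")
        if np.any(np.diff(self.z) <= 0):
            raise ValueError("z must be strictly increasing")
        if np.any(self.dw < 0):
            raise ValueError("dw values must be >= 0")
        if self.current is not None:
            self.current = np.asarray(self.current, dtype=float)
            if self.current.shape != self.z.shape:
                raise ValueError("current must match z in length")

    def __len__(self) -> int:
        return int(self.z.size)


@dataclass
class DwMetrics:
    """Scalar size metrics of one examination."""

    dw_c: float  # cm, mid-scan
    dw_ave: float  # cm, mean over slices
    dw_min: float
    dw_max: float
    dw_range: float
    n_slices: int


def water_equivalent_area(mean_ct: float, area: float) -> float:
    """Water-equivalent area (cm^2) of a region of mean CT number ``mean_ct``
    (HU) and geometric area ``area`` (cm^2)."""
    if area < 0:
        raise ValueError("area must be >= 0")
    return (mean_ct / 1000.0) * area + area


def slice_dw(ct_slice: CTSlice, cal: TableCalibration | None = None) -> float:
    """Water-equivalent diameter (cm) of one normalised slice.

    Uses the whole image as the ROI; a negative radicand (table calibration
    exceeding slice content, e.g. an air-only slice) clamps to zero with a
    warning rather than aborting the series.
    """
    aw_table = 0.0 if cal is None else cal.aw_table
    area_cm2 = ct_slice.pixels.size * ct_slice.pixel_area_mm2 / MM2_PER_CM2
    mean_ct = float(ct_slice.pixels.mean())
    aw = water_equivalent_area(mean_ct, area_cm2)
    radicand = aw - aw_table
    if radicand < 0:
        warnings.warn(
            f"slice {ct_slice.slice_id}: A_w ({aw:.1f} cm^2) below table "
            f"calibration ({aw_table:.1f} cm^2); clamping D_w to 0"
        )
        radicand = 0.0
    return 2.0 * float(np.sqrt(radicand / np.pi))


def calibrate_table(ct_slice: CTSlice, table_mask: np.ndarray) -> TableCalibration:
    """Determine A_w(table) by contouring the couch in one slice.

    ``table_mask`` is a boolean grid selecting the couch (and nothing of the
    patient).  A_w(table) is Eq.-1 arithmetic on the masked region, clamped
    at zero (a pure-air contour has no water-equivalent area).
    """
    table_mask = np.asarray(table_mask, dtype=bool)
    if table_mask.shape != ct_slice.pixels.shape:
        raise ValueError("table_mask must match the slice shape")
    n = int(table_mask.sum())
    if n == 0:
        raise ValueError("table_mask is empty")
    area_cm2 = n * ct_slice.pixel_area_mm2 / MM2_PER_CM2
    mean_ct = float(ct_slice.pixels[table_mask].mean())
    aw = max(water_equivalent_area(mean_ct, area_cm2), 0.0)
    return TableCalibration(aw_table=aw)


def dw_profile(series: ScanSeries, cal: TableCalibration | None = None) -> DwProfile:
    """D_w(z) for every slice of a series."""
    dw = np.empty(len(series.slices))
    for i, sl in enumerate(series.slices):
        try:
            dw[i] = slice_dw(sl, cal)
        except Exception as exc:  # re-raise with location
            raise type(exc)(f"slice index {i} (z={sl.z_position} mm): {exc}") from exc
    return DwProfile(
        z=series.z_positions,
        dw=dw,
        current=series.tube_currents,
        exam_type=series.exam_type,
        ctdi_vol=series.ctdi_vol,
    )


def _central_index(z: np.ndarray) -> int:
    """Index of the slice nearest the z-midpoint; lower z wins an exact tie."""
    midpoint = 0.5 * (z[0] + z[-1])
    return int(np.argmin(np.abs(z - midpoint)))  # argmin is first-wins => lower z


def dw_central(profile: DwProfile) -> float:
    """D_w_c: the D_w value at the slice in the middle of the scanned region."""
    return float(profile.dw[_central_index(profile.z)])


def dw_average(profile: DwProfile) -> float:
    """D_w_ave: unweighted mean of all D_w(z) values in the imaged region."""
    return float(profile.dw.mean())


def dw_metrics(profile: DwProfile) -> DwMetrics:
    """Bundle the scalar metrics of one profile."""
    dw_min = float(profile.dw.min())
    dw_max = float(profile.dw.max())
    return DwMetrics(
        dw_c=dw_central(profile),
        dw_ave=dw_average(profile),
        dw_min=dw_min,
        dw_max=dw_max,
        dw_range=dw_max - dw_min,
        n_slices=len(profile),
    )


def truncation_fraction(ct_slice: CTSlice, threshold: float = -600.0) -> float:
    """Fraction of border-ring pixels above ``threshold`` HU.

    A nonzero fraction indicates tissue running off the reconstruction
    area (patient contour truncated by the FOV).  The ring is the
    outermost 2-pixel frame of the image; callers compare against a
    config cutoff (default 0.05) to flag examinations for exclusion.
    """
    px = ct_slice.pixels
    if px.shape[0] < 5 or px.shape[1] < 5:
        raise ValueError("image too small for a 2-pixel border ring")
    ring = np.zeros(px.shape, dtype=bool)
    ring[:2, :] = ring[-2:, :] = True
    ring[:, :2] = ring[:, -2:] = True
    return float((px[ring] > threshold).mean())
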