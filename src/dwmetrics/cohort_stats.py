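"""Cohort-level statistics comparing patient-size metrics.

Dose-index monitoring wants the patient-size metric that minimises the
dispersion of dose indices (CTDI_vol, SSDE) across a cohort.  This module
provides the descriptive machinery for that comparison: ordinary
least-squares fits with R-squared per (metric, dose index) pair, the
per-examination differences between the mid-scan diameter D_w_c and the
scan-mean diameter D_w_ave, and mean +/- SD cohort summaries.

All standard deviations are population SDs (n denominator), recorded in
the output metadata.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ct_io import PatientBio

SD_CONVENTION = "population (n denominator)"

RECORD_COLUMNS = [
    "patient_id",
    "scanner_id",
    "exam_type",
    "sex",
    "weight_kg",
    "height_cm",
    "ctdivol_mGy",
    "dwc_cm",
    "dwave_cm",
    "dwmin_cm",
    "dwmax_cm",
    "ssde_mGy",
]


@dataclass
class ExamRecord:
    """One examination's analysis row."""

    ctdi_vol: float  # mGy
    dw_c: float  # cm
    dw_ave: float  # cm
    dw_min: float
    dw_max: float
    ssde: float  # mGy
    exam_type: str = "CAP"
    scanner_id: str = ""
    patient: Optional[PatientBio] = None
    patient_id: str = ""
    ssde_metric: str = "dwc"  # which D_w entered f() for this record
    currents: Optional[np.ndarray] = None  # per-slice tube current, mA

    def __post_init__(self) -> None:
        if not (self.dw_min - 1e-9 <= self.dw_c <= self.dw_max + 1e-9):
            raise ValueError("dw_c must lie within [dw_min, dw_max]")
        if not (self.dw_min - 1e-9 <= self.dw_ave <= self.dw_max + 1e-9):
            raise ValueError("dw_ave must lie within [dw_min, dw_max]")
        if self.currents is not None:
            self.currents = np.asarray(self.currents, dtype=float)

    @property
    def bmi(self) -> Optional[float]:
        if self.patient is None:
            return None
        return bmi(self.patient.weight, self.patient.height)


def bmi(weight: float, height: float) -> float:
    """Body mass index (kg/m^2) from weight in kg and height in cm."""
    if weight <= 0 or height <= 0:
        raise ValueError("weight and height must be positive")
    return weight / (height / 100.0) ** 2


@dataclass
class FitResult:
    """Ordinary least-squares line y = slope*x + intercept with R-squared."""

    slope: float
    intercept: float
    r_squared: float
    n: int
    x_name: str = "x"
    y_name: str = "y"


def linear_fit(x: Sequence[float], y: Sequence[float], x_name: str = "x", y_name: str = "y") -> FitResult:
    """OLS fit with intercept; R^2 = 1 - SS_res/SS_tot.

    A constant y has no variance to explain: R^2 is reported as 0 with a
    warning.  A constant x is an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("x and y must be equal-length arrays of length >= 3")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; no line can be fitted")
    if np.ptp(y) == 0:
        warnings.warn("y is constant; R-squared reported as 0")
        return FitResult(0.0, float(y[0]), 0.0, int(x.size), x_name, y_name)
    res = stats.linregress(x, y)
    return FitResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n=int(x.size),
        x_name=x_name,
        y_name=y_name,
    )


def records_to_frame(records: Iterable[ExamRecord]) -> pd.DataFrame:
    """Flatten records into the canonical analysis table."""
    rows = []
    for r in records:
        rows.append(
            {
                "patient_id": r.patient_id,
                "scanner_id": r.scanner_id,
                "exam_type": r.exam_type,
                "sex": r.patient.sex if r.patient else None,
                "weight_kg": r.patient.weight if r.patient else np.nan,
                "height_cm": r.patient.height if r.patient else np.nan,
                "ctdivol_mGy": r.ctdi_vol,
                "dwc_cm": r.dw_c,
                "dwave_cm": r.dw_ave,
                "dwmin_cm": r.dw_min,
                "dwmax_cm": r.dw_max,
                "ssde_mGy": r.ssde,
            }
        )
    df = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    with np.errstate(invalid="ignore"):
        df["bmi"] = df["weight_kg"] / (df["height_cm"] / 100.0) ** 2
    return df


def frame_to_records(df: pd.DataFrame) -> list[ExamRecord]:
    """Inverse of :func:`records_to_frame` (currents are not round-tripped)."""
    records = []
    for _, row in df.iterrows():
        patient = None
        if pd.notna(row.get("weight_kg")) and pd.notna(row.get("height_cm")) and pd.notna(row.get("sex")):
            patient = PatientBio(float(row["weight_kg"]), float(row["height_cm"]), str(row["sex"]))
        records.append(
            ExamRecord(
                ctdi_vol=float(row["ctdivol_mGy"]),
                dw_c=float(row["dwc_cm"]),
                dw_ave=float(row["dwave_cm"]),
                dw_min=float(row["dwmin_cm"]),
                dw_max=float(row["dwmax_cm"]),
                ssde=float(row["ssde_mGy"]),
                exam_type=str(row["exam_type"]),
                scanner_id=str(row.get("scanner_id", "")),
                patient=patient,
                patient_id=str(row.get("patient_id", "")),
            )
        )
    return records


_METRIC_COLS = {"weight": "weight_kg", "bmi": "bmi", "dw_c": "dwc_cm", "dw_ave": "dwave_cm"}
_DOSE_COLS = {"ctdi_vol": "ctdivol_mGy", "ssde": "ssde_mGy"}


def metric_comparison(
    records: Sequence[ExamRecord],
    metrics: Sequence[str] = ("weight", "bmi", "dw_c", "dw_ave"),
    doses: Sequence[str] = ("ctdi_vol", "ssde"),
) -> pd.DataFrame:
    """R-squared grid of dose index vs. size metric per (scanner, exam type).

    Rows: one per (scanner_id, exam_type, metric, dose) with r_squared,
    slope, intercept, n and n_dropped (records lacking the metric).  Cells
    with fewer than 3 usable records are reported with NaN r_squared.
    """
    df = records_to_frame(records)
    rows = []
    for (scanner, exam), sub in df.groupby(["scanner_id", "exam_type"], sort=True):
        for metric in metrics:
            xcol = _METRIC_COLS[metric]
            for dose in doses:
                ycol = _DOSE_COLS[dose]
                usable = sub[[xcol, ycol]].dropna()
                dropped = len(sub) - len(usable)
                row = {
                    "scanner_id": scanner,
                    "exam_type": exam,
                    "metric": metric,
                    "dose": dose,
                    "n": len(usable),
                    "n_dropped": dropped,
                }
                if len(usable) >= 3 and np.ptp(usable[xcol].to_numpy()) > 0:
                    fit = linear_fit(usable[xcol], usable[ycol], metric, dose)
                    row.update(r_squared=fit.r_squared, slope=fit.slope, intercept=fit.intercept)
                else:
                    row.update(r_squared=np.nan, slope=np.nan, intercept=np.nan)
                rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["sd_convention"] = SD_CONVENTION
    return out


def _pop_sd(x: np.ndarray) -> float:
    return float(np.std(x, ddof=0))


def difference_stats(records: Sequence[ExamRecord]) -> pd.DataFrame:
    """Mean +/- SD of D_w_c - D_w_ave and of the per-exam D_w range.

    Both differences are reported in cm and in percent of D_w_ave (signed),
    stratified by exam type and sex (with an 'All' stratum per exam type).
    """
    df = records_to_frame(records)
    if df.empty:
        raise ValueError("no records")
    df["diff_cm"] = df["dwc_cm"] - df["dwave_cm"]
    df["diff_pct"] = 100.0 * df["diff_cm"] / df["dwave_cm"]
    df["range_cm"] = df["dwmax_cm"] - df["dwmin_cm"]
    df["range_pct"] = 100.0 * df["range_cm"] / df["dwave_cm"]

    rows = []
    for exam, sub in df.groupby("exam_type", sort=True):
        strata = [(sex, grp) for sex, grp in sub.groupby("sex", sort=True)]
        strata.append(("All", sub))
        for sex, grp in strata:
            rows.append(
                {
                    "exam_type": exam,
                    "sex": sex,
                    "n": len(grp),
                    "dwc_minus_dwave_pct_mean": grp["diff_pct"].mean(),
                    "dwc_minus_dwave_pct_sd": _pop_sd(grp["diff_pct"].to_numpy()),
                    "dwc_minus_dwave_cm_mean": grp["diff_cm"].mean(),
                    "dwc_minus_dwave_cm_sd": _pop_sd(grp["diff_cm"].to_numpy()),
                    "dw_range_pct_mean": grp["range_pct"].mean(),
                    "dw_range_pct_sd": _pop_sd(grp["range_pct"].to_numpy()),
                    "dw_range_cm_mean": grp["range_cm"].mean(),
                    "dw_range_cm_sd": _pop_sd(grp["range_cm"].to_numpy()),
                }
            )
    out = pd.DataFrame(rows)
    out.attrs["sd_convention"] = SD_CONVENTION
    return out


def cohort_summary(records: Sequence[ExamRecord]) -> pd.DataFrame:
    """Mean +/- SD of dose indices and mean (min-max) biometrics per stratum."""
    df = records_to_frame(records)
    if df.empty:
        raise ValueError("no records")
    rows = []
    for (scanner, exam), sub in df.groupby(["scanner_id", "exam_type"], sort=True):
        row = {
            "scanner_id": scanner,
            "exam_type": exam,
            "n": len(sub),
            "ctdivol_mean": sub["ctdivol_mGy"].mean(),
            "ctdivol_sd": _pop_sd(sub["ctdivol_mGy"].to_numpy()),
            "ssde_mean": sub["ssde_mGy"].mean(),
            "ssde_sd": _pop_sd(sub["ssde_mGy"].to_numpy()),
        }
        bio = sub.dropna(subset=["weight_kg", "height_cm"])
        for name, col in (("weight", "weight_kg"), ("height", "height_cm"), ("bmi", "bmi")):
            if len(bio):
                row[f"{name}_mean"] = bio[col].mean()
                row[f"{name}_min"] = bio[col].min()
                row[f"{name}_max"] = bio[col].max()
            else:
                row[f"{name}_mean"] = row[f"{name}_min"] = row[f"{name}_max"] = np.nan
        rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["sd_convention"] = SD_CONVENTION
    return out
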