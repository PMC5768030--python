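"""Size-specific dose estimate (SSDE) conversion.

SSDE = CTDI_vol * f(D_w), where f is the size-dependent conversion factor
for the 32-cm body CTDI phantom.  The factor table ships as package data;
lookups interpolate linearly in diameter and clamp (with a warning) outside
the tabulated 6-55 cm range.  The conventional metric for f is the
mid-scan diameter D_w_c; D_w_ave is accepted as well for comparative
analyses, with the metric used recorded by the caller.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

#: constants of the exponential form of the published body-phantom table,
#: kept as an independent cross-check of the tabulated values
FIT_A = 3.704369
FIT_B = 0.03671937  # per cm


@dataclass
class ConversionTable:
    """Monotone map D_w (cm) -> conversion factor, 32-cm phantom reference."""

    diameters: np.ndarray
    factors: np.ndarray
    phantom_ref: str = "body-32cm"

    def __post_init__(self) -> None:
        self.diameters = np.asarray(self.diameters, dtype=float)
        self.factors = np.asarray(self.factors, dtype=float)
        if self.diameters.size == 0:
            raise ValueError("conversion table is empty")
        if self.diameters.shape != self.factors.shape:
            raise ValueError("diameters and factors must have equal length")
        if np.any(np.diff(self.diameters) <= 0):
            raise ValueError("diameters must be strictly increasing")
        if np.any(np.diff(self.factors) >= 0):
            raise ValueError("factors must be strictly decreasing")
        if np.any(self.factors <= 0):
            raise ValueError("factors must be positive")


_cached_table: ConversionTable | None = None


def load_conversion_table() -> ConversionTable:
    """The body-phantom conversion table shipped as package data."""
    global _cached_table
    if _cached_table is None:
        with resources.files("dwmetrics.data").joinpath("ssde_body32_factors.csv").open() as fh:
            df = pd.read_csv(fh, comment="#")
        _cached_table = ConversionTable(
            diameters=df["diameter_cm"].to_numpy(),
            factors=df["factor"].to_numpy(),
        )
    return _cached_table


def conversion_factor(dw: float, table: ConversionTable | None = None) -> float:
    """f(D_w): linear interpolation in diameter; clamped outside the range."""
    if table is None:
        table = load_conversion_table()
    if dw < table.diameters[0] or dw > table.diameters[-1]:
        warnings.warn(
            f"D_w = {dw:.1f} cm outside the tabulated range "
            f"[{table.diameters[0]:.0f}, {table.diameters[-1]:.0f}] cm; "
            "clamping to the nearest endpoint factor"
        )
    return float(np.interp(dw, table.diameters, table.factors))


def ssde(ctdi_vol: float, dw: float, table: ConversionTable | None = None) -> float:
    """Size-specific dose estimate (mGy): CTDI_vol * f(D_w)."""
    if ctdi_vol < 0:
        raise ValueError("ctdi_vol must be >= 0")
    return ctdi_vol * conversion_factor(dw, table)
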