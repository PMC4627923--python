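"""Refractometry: refractive index -> sucrose density along a gradient.

Gradient fractions harvested from a sucrose density gradient are read on
a refractometer; the refractive index is converted to solution density
through a standard sucrose calibration table (20 degC) and an ordinary
least-squares regression of density on refractive index, which is the
conventional near-linear relation over the 0-45 % w/v working range.
Interpolation via the fitted line (not nearest-row lookup) is the
default; readings outside the table's refractive-index range raise
unless extrapolation is explicitly allowed.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvariantError

__all__ = [
    "SucroseCalibration",
    "GradientProfile",
    "load_sucrose_table",
    "ri_to_density",
    "density_to_ri",
    "profile_densities",
    "main_band_shift",
]

_TABLE_RESOURCE = "sucrose_ri_density_20c.csv"


def load_sucrose_table() -> pd.DataFrame:
    """The packaged 20 degC sucrose calibration table as a DataFrame."""
    with resources.files("vesidens.data").joinpath(_TABLE_RESOURCE).open() as fh:
        return pd.read_csv(fh, comment="#")


@dataclass(frozen=True)
class SucroseCalibration:
    """OLS calibration of solution density against refractive index.

    Built from a table of (refractive_index, sucrose_pct_wv, density)
    rows that must be strictly increasing in all three columns.
    """

    table: pd.DataFrame
    slope: float
    intercept: float
    residual_sd: float
    r_squared: float
    ri_min: float
    ri_max: float

    @classmethod
    def from_table(cls, table: pd.DataFrame | None = None) -> "SucroseCalibration":
        if table is None:
            table = load_sucrose_table()
        for col in ("refractive_index", "density_g_ml", "sucrose_pct_wv"):
            if col not in table.columns:
                raise InvariantError(f"calibration table missing column {col!r}")
        by_conc = table.sort_values("sucrose_pct_wv")
        for col in ("refractive_index", "density_g_ml"):
            if not np.all(np.diff(by_conc[col].to_numpy()) > 0):
                raise InvariantError(
                    f"{col} must be strictly increasing with sucrose concentration"
                )
        ri = table["refractive_index"].to_numpy(float)
        rho = table["density_g_ml"].to_numpy(float)
        fit = stats.linregress(ri, rho)
        resid = rho - (fit.intercept + fit.slope * ri)
        dof = max(len(ri) - 2, 1)
        return cls(
            table=table,
            slope=float(fit.slope),
            intercept=float(fit.intercept),
            residual_sd=float(np.sqrt(np.sum(resid**2) / dof)),
            r_squared=float(fit.rvalue**2),
            ri_min=float(ri.min()),
            ri_max=float(ri.max()),
        )


def ri_to_density(
    ri: float, cal: SucroseCalibration, *, allow_extrapolation: bool = False
) -> float:
    """Density (g/mL) predicted by the calibration line at refractive index ``ri``."""
    if not (cal.ri_min <= ri <= cal.ri_max) and not allow_extrapolation:
        raise InvariantError(
            f"refractive index {ri} outside calibration range "
            f"[{cal.ri_min}, {cal.ri_max}]; pass allow_extrapolation=True to override"
        )
    return cal.intercept + cal.slope * ri


def density_to_ri(density: float, cal: SucroseCalibration) -> float:
    """Inverse of the calibration line (used to construct synthetic readings)."""
    return (density - cal.intercept) / cal.slope


@dataclass(frozen=True)
class GradientProfile:
    """Per-fraction values of one quantity along a density gradient.

    ``fractions`` are unique 1-based fraction indices (fraction 1 at the
    top of the tube); ``values`` the measured quantity per fraction
    (density in g/mL, or an assay signal in arbitrary units) and
    ``quantity`` its label.  ``condition`` distinguishes e.g. control vs
    treated profiles.
    """

    quantity: str
    fractions: tuple[int, ...]
    values: tuple[float, ...]
    condition: str = ""

    def __post_init__(self) -> None:
        if len(self.fractions) != len(self.values):
            raise InvariantError("fractions and values must have equal length")
        if len(set(self.fractions)) != len(self.fractions):
            raise InvariantError(f"duplicate fraction index in {sorted(self.fractions)}")
        if any(f < 1 for f in self.fractions):
            raise InvariantError("fraction indices are 1-based and must be >= 1")

    def __len__(self) -> int:
        return len(self.fractions)

    @property
    def total(self) -> float:
        return float(np.sum(self.values))

    def value_at(self, fraction: int) -> float:
        try:
            return self.values[self.fractions.index(fraction)]
        except ValueError:
            raise KeyError(f"no fraction {fraction} in profile") from None

    def peak_fraction(self) -> int:
        """Fraction index holding the largest value."""
        if not self.fractions:
            raise InvariantError("empty profile has no peak")
        return self.fractions[int(np.argmax(self.values))]

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.fractions), name=self.quantity)


def profile_densities(
    readings: list[tuple[int, float]],
    cal: SucroseCalibration,
    *,
    condition: str = "",
    allow_extrapolation: bool = False,
) -> GradientProfile:
    """Convert per-fraction refractive-index readings to a density profile.

    ``readings`` is a list of ``(fraction_index, refractive_index)``
    pairs (at most one per fraction — duplicates raise).
    """
    fractions = tuple(int(f) for f, _ in readings)
    values = tuple(
        ri_to_density(ri, cal, allow_extrapolation=allow_extrapolation)
        for _, ri in readings
    )
    return GradientProfile(
        quantity="density_g_ml", fractions=fractions, values=values, condition=condition
    )


def main_band_shift(
    control_density: GradientProfile,
    treated_density: GradientProfile,
    control_signal: GradientProfile | None = None,
    treated_signal: GradientProfile | None = None,
) -> float:
    """Density shift of the main band: treated peak density minus control peak density.

    The peak fraction is located from the accompanying signal profile
    (e.g. protein band intensity) when given, otherwise from the density
    profile's own maximum.
    """
    peak_ctrl = (control_signal or control_density).peak_fraction()
    peak_trt = (treated_signal or treated_density).peak_fraction()
    return treated_density.value_at(peak_trt) - control_density.value_at(peak_ctrl)
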