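"""Real (inflation-adjusted) price series for fish and fuel.

Ex-vessel tuna prices arrive as nominal yen per kg; fuel as nominal US
dollars per barrel.  Both are converted to a common real-dollar scale:
nominal values are taken to USD with the year's exchange rate, averaged
within year, and deflated with the appropriate index (an FAO fish-price
index for fish, an IMF average-spot-price index for fuel) relative to a
base year (2014 by default):

    real_y = nominal_y * fx_y * (I_base / I_y)

so the base-year real value equals the base-year nominal USD value.
Year-on-year percent changes of the resulting series are the standard
volatility diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DeflatorGapError, ValidationError

DEFAULT_BASE_YEAR = 2014


@dataclass
class NominalPriceSeries:
    """Annual nominal prices plus the FX rates and deflator to realize them.

    ``fx_to_usd`` maps year -> units of USD per unit of ``currency``
    (may be omitted when the series is already in USD);
    ``deflator_index`` maps year -> positive index level.
    """

    label: str
    years: list[int]
    nominal_values: list[float]
    currency: str = "USD"
    fx_to_usd: dict[int, float] = field(default_factory=dict)
    deflator_index: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.years) != len(self.nominal_values):
            raise ValidationError(f"{self.label}: years/values length mismatch")
        if any(v <= 0 for v in self.nominal_values):
            raise ValidationError(f"{self.label}: nominal values must be positive")
        if any(v <= 0 for v in self.deflator_index.values()):
            raise ValidationError(f"{self.label}: deflator index must be positive")


@dataclass
class RealPriceSeries:
    """Deflated series in base-year dollars."""

    label: str
    base_year: int
    years: list[int]
    real_usd: list[float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"label": self.label, "year": self.years, "real_usd": self.real_usd})


def to_real(series: NominalPriceSeries, base_year: int = DEFAULT_BASE_YEAR) -> RealPriceSeries:
    """Convert to USD and deflate to base-year dollars.

    Raises
    ------
    DeflatorGapError
        If the deflator (or a needed FX rate) is missing for any year
        of the series or for the base year.
    """
    gaps = sorted({y for y in series.years if y not in series.deflator_index})
    if base_year not in series.deflator_index:
        gaps = sorted(set(gaps) | {base_year})
    if gaps:
        raise DeflatorGapError(f"{series.label}: deflator missing for years {gaps}")
    if series.currency != "USD":
        fx_gaps = sorted({y for y in series.years if y not in series.fx_to_usd})
        if fx_gaps:
            raise DeflatorGapError(f"{series.label}: FX rate missing for years {fx_gaps}")

    i_base = series.deflator_index[base_year]
    real = []
    for year, nominal in zip(series.years, series.nominal_values):
        fx = 1.0 if series.currency == "USD" else series.fx_to_usd[year]
        real.append(nominal * fx * (i_base / series.deflator_index[year]))
    return RealPriceSeries(series.label, base_year, list(series.years), real)


def annual_average(
    observations: pd.DataFrame,
    value_col: str = "value",
    year_col: str = "year",
    weight_col: str | None = None,
) -> pd.Series:
    """Mean value per year (unweighted by default), indexed by year.

    Years with no observations are simply absent from the result.
    """
    if observations.empty:
        return pd.Series(dtype=float, name=value_col)
    df = observations.dropna(subset=[value_col])
    if weight_col is None:
        return df.groupby(year_col)[value_col].mean()
    wsum = df.groupby(year_col).apply(
        lambda g: np.average(g[value_col], weights=g[weight_col]), include_groups=False
    )
    wsum.name = value_col
    return wsum


def yoy_percent_change(series: pd.Series) -> pd.Series:
    """Year-on-year percent change, 100 * (x_t - x_{t-1}) / x_{t-1}.

    The first year is NaN; a zero previous value yields NaN (flagged in
    ``result.attrs["n_undefined"]``).  The index must be sorted years.
    """
    s = series.sort_index().astype(float)
    prev = s.shift(1)
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = 100.0 * (s - prev) / prev
    pct[prev == 0] = np.nan
    pct.attrs["n_undefined"] = int((prev == 0).sum())
    return pct
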