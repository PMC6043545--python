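"""Human development versus exploitation status, by period.

Contrasts the mean Human Development Index of the countries fishing a
stock region against that stock's mean F/Fmsy, within two eras
(1990-2001 and 2002-2012 by default).  A point above F/Fmsy = 1 marks
a stock experiencing overfishing in that era; a simple linear
regression of mean F/Fmsy on mean HDI per period summarizes whether
development level tracks exploitation pressure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

DEFAULT_PERIODS: dict[str, tuple[int, int]] = {
    "1990-2001": (1990, 2001),
    "2002-2012": (2002, 2012),
}


@dataclass
class HdiStatusPoint:
    """One stock's mean HDI and mean F/Fmsy within one period."""

    stock: str
    period: str
    mean_hdi: float
    mean_f_over_fmsy: float
    n_years: int


def _validate_periods(periods: dict[str, tuple[int, int]]) -> None:
    spans = sorted(periods.values())
    for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
        if b0 <= a1:
            raise ValidationError(f"periods overlap: ({a0}-{a1}) and ({b0}-{b1})")
    for name, (lo, hi) in periods.items():
        if lo > hi:
            raise ValidationError(f"period {name!r} has inverted bounds {lo} > {hi}")


def period_aggregate(
    hdi_table: pd.DataFrame,
    status_series: pd.DataFrame,
    region_map: pd.DataFrame,
    stock_registry=None,
    periods: dict[str, tuple[int, int]] | None = None,
) -> pd.DataFrame:
    """One (mean HDI, mean F/Fmsy) point per stock per period.

    Parameters
    ----------
    hdi_table
        Columns (country, year, hdi).
    status_series
        Columns (stock, year, f_over_fmsy); a gear column, if present,
        is averaged over.
    region_map
        Columns (country, region) assigning countries to stock regions.
    stock_registry
        Mapping stock -> StockInfo (defaults to the shipped registry).
    periods
        Mapping period label -> (first_year, last_year), inclusive and
        non-overlapping.

    Stocks whose region has no mapped country are skipped with a
    warning.
    """
    if stock_registry is None:
        from .stocks import DEFAULT_STOCKS as stock_registry  # noqa: N813
    periods = dict(periods) if periods is not None else dict(DEFAULT_PERIODS)
    _validate_periods(periods)

    hdi_by_region = hdi_table.merge(region_map, on="country")
    status = status_series.groupby(["stock", "year"], as_index=False)["f_over_fmsy"].mean()

    rows = []
    for stock, grp in status.groupby("stock"):
        if stock not in stock_registry:
            raise ValidationError(f"stock {stock!r} absent from registry")
        region = stock_registry[stock].region
        region_hdi = hdi_by_region[hdi_by_region["region"] == region]
        if region_hdi.empty:
            warnings.warn(f"stock {stock}: no countries mapped to region {region}", stacklevel=2)
            continue
        for label, (lo, hi) in periods.items():
            in_period = grp[(grp["year"] >= lo) & (grp["year"] <= hi)]
            hdi_period = region_hdi[(region_hdi["year"] >= lo) & (region_hdi["year"] <= hi)]
            if in_period.empty or hdi_period.empty:
                continue
            rows.append(
                {
                    "stock": stock,
                    "period": label,
                    "mean_hdi": float(hdi_period["hdi"].mean()),
                    "mean_ffmsy": float(in_period["f_over_fmsy"].mean()),
                    "n_years": int(in_period["year"].nunique()),
                }
            )
    return pd.DataFrame(rows, columns=["stock", "period", "mean_hdi", "mean_ffmsy", "n_years"])


def linear_trend(points: pd.DataFrame, by_period: bool = True) -> pd.DataFrame:
    """Least-squares line of mean F/Fmsy on mean HDI.

    One row per period (or a single pooled row with ``by_period=False``)
    with slope, intercept and r_squared.

    Raises
    ------
    ValidationError
        If a group has fewer than 2 points or zero HDI variance.
    """
    groups = points.groupby("period") if by_period else [("pooled", points)]
    rows = []
    for label, grp in groups:
        if len(grp) < 2:
            raise ValidationError(f"period {label!r}: need at least 2 points")
        if np.isclose(grp["mean_hdi"].std(ddof=0), 0.0):
            raise ValidationError(f"period {label!r}: zero variance in mean HDI")
        res = stats.linregress(grp["mean_hdi"], grp["mean_ffmsy"])
        rows.append(
            {
                "period": label,
                "slope": float(res.slope),
                "intercept": float(res.intercept),
                "r_squared": float(res.rvalue) ** 2,
                "n_points": len(grp),
            }
        )
    return pd.DataFrame(rows)


def reference_line_report(points: pd.DataFrame, threshold: float = 1.0) -> pd.DataFrame:
    """Per-period counts of stocks above/below the F/Fmsy = 1 line."""
    rows = []
    for label, grp in points.groupby("period"):
        above = int((grp["mean_ffmsy"] > threshold).sum())
        rows.append(
            {
                "period": label,
                "n_above": above,
                "n_below": len(grp) - above,
                "n_total": len(grp),
            }
        )
    return pd.DataFrame(rows)
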