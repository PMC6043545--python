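"""Assemble the analysis matrix linking drivers to F/Fmsy.

One row per (stock, gear, year) fleet observation.  Predictors are

* 5 continuous drivers: real fuel price (``realfuel``), real frozen and
  fresh fish price for the row's species (``realfrozp``, ``realfresp``),
  the Shannon-Wiener spatial-spread index (``SW``) and the mean Human
  Development Index of the stock region's countries (``HDI``);
* 10 annual climate indices (EA, WP, EP_NP, PNA, DMI, TNA, TSA, PDO,
  SOI, NAO), attached by year;
* dummy variables: all 10 ocean-region levels for stock, species with
  albacore as reference, gear with baitboat as reference.

That makes 34 predictors plus the response ``f_over_fmsy`` — 35 columns.
Rows with any missing driver are dropped (listwise deletion) and
counted.  The full stock-dummy encoding is identifiable downstream
because ridge penalization absorbs the collinearity with the intercept.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import squareform

from .errors import EmptyTableError, ValidationError
from .stocks import (
    CLIMATE_INDICES,
    DEFAULT_STOCKS,
    GEAR_LEVELS,
    GEAR_REFERENCE,
    REGIONS,
    SPECIES_LEVELS,
    SPECIES_REFERENCE,
)

KEY_COLUMNS = ["stock", "gear", "year"]
CONTINUOUS_COLUMNS = ["realfuel", "realfrozp", "realfresp", "SW", "HDI"]
STOCK_DUMMIES = [f"stock_{r}" for r in REGIONS]
SPECIES_DUMMIES = [f"species_{s}" for s in SPECIES_LEVELS]
GEAR_DUMMIES = [f"gear_{g}" for g in GEAR_LEVELS]
RESPONSE_COLUMN = "f_over_fmsy"


def feature_columns() -> list[str]:
    """The 34 predictor columns, in canonical order."""
    return (
        CONTINUOUS_COLUMNS
        + list(CLIMATE_INDICES)
        + STOCK_DUMMIES
        + SPECIES_DUMMIES
        + GEAR_DUMMIES
    )


def encode_dummies(categories: pd.DataFrame) -> pd.DataFrame:
    """0/1 encoding of the region / species / gear columns.

    ``region`` uses the full 10-level encoding; ``species`` and ``gear``
    omit their reference levels (ALB, baitboat), whose rows carry all
    zeros in that block.
    """
    for col, levels, reference in [
        ("region", REGIONS, None),
        ("species", SPECIES_LEVELS, SPECIES_REFERENCE),
        ("gear", GEAR_LEVELS, GEAR_REFERENCE),
    ]:
        allowed = set(levels) | ({reference} if reference else set())
        unknown = set(categories[col].unique()) - allowed
        if unknown:
            raise ValidationError(f"unknown {col} level(s): {sorted(unknown)}")
    out = pd.DataFrame(index=categories.index)
    for r in REGIONS:
        out[f"stock_{r}"] = (categories["region"] == r).astype(int)
    for s in SPECIES_LEVELS:
        out[f"species_{s}"] = (categories["species"] == s).astype(int)
    for g in GEAR_LEVELS:
        out[f"gear_{g}"] = (categories["gear"] == g).astype(int)
    return out


def build_feature_table(
    status: pd.DataFrame,
    sw_indices: pd.DataFrame,
    real_prices: pd.DataFrame,
    fuel: pd.DataFrame,
    climate: pd.DataFrame,
    hdi: pd.DataFrame,
    region_map: pd.DataFrame | None = None,
    stock_registry=None,
) -> pd.DataFrame:
    """Merge all drivers and the response into the analysis matrix.

    Parameters
    ----------
    status
        Columns (stock, year, f_over_fmsy), optionally gear; without a
        gear column the stock-year value is shared across gears.
    sw_indices
        Output of :func:`tunadrivers.diversity.compute_indices`.
    real_prices
        Long table (label, year, real_usd) with labels ``{species}_fresh``
        and ``{species}_frozen``.
    fuel
        Columns (year, real_usd).
    climate
        Long table (index_name, year, value) covering the 10 indices.
    hdi
        Columns (country, year, hdi).
    region_map
        Columns (country, region) assigning countries to stock regions;
        required to attach HDI.
    stock_registry
        Mapping stock code -> StockInfo; defaults to the shipped
        19-stock registry.

    Returns
    -------
    DataFrame with key columns (stock, gear, year), 34 predictors and
    the response; dropped-row counts are in ``result.attrs["n_dropped"]``.
    """
    registry = stock_registry if stock_registry is not None else DEFAULT_STOCKS

    df = sw_indices[["stock", "gear", "year", "shannon_wiener"]].rename(
        columns={"shannon_wiener": "SW"}
    )
    if "gear" in status.columns:
        df = df.merge(status[["stock", "gear", "year", RESPONSE_COLUMN]], on=["stock", "gear", "year"])
    else:
        df = df.merge(status[["stock", "year", RESPONSE_COLUMN]], on=["stock", "year"])
    if df.empty:
        raise EmptyTableError("status and spatial indices share no (stock, year) keys")

    unknown = set(df["stock"].unique()) - set(registry)
    if unknown:
        raise ValidationError(f"stocks absent from registry: {sorted(unknown)}")
    df["region"] = df["stock"].map(lambda s: registry[s].region)
    df["species"] = df["stock"].map(lambda s: registry[s].species)

    # species-matched real prices
    for form, col in [("frozen", "realfrozp"), ("fresh", "realfresp")]:
        sub = real_prices[real_prices["label"].str.endswith(f"_{form}")].copy()
        sub["species"] = sub["label"].str.replace(f"_{form}", "", regex=False)
        sub = sub.rename(columns={"real_usd": col})[["species", "year", col]]
        df = df.merge(sub, on=["species", "year"], how="left")

    df = df.merge(fuel[["year", "real_usd"]].rename(columns={"real_usd": "realfuel"}), on="year", how="left")

    wide = climate.pivot_table(index="year", columns="index_name", values="value")
    missing_idx = set(CLIMATE_INDICES) - set(wide.columns)
    if missing_idx:
        raise ValidationError(f"climate table missing indices: {sorted(missing_idx)}")
    df = df.merge(wide[list(CLIMATE_INDICES)].reset_index(), on="year", how="left")

    if region_map is None:
        raise ValidationError("region_map (country -> region) is required to attach HDI")
    hdi_region = (
        hdi.merge(region_map, on="country")
        .groupby(["region", "year"], as_index=False)["hdi"]
        .mean()
        .rename(columns={"hdi": "HDI"})
    )
    df = df.merge(hdi_region, on=["region", "year"], how="left")

    needed = CONTINUOUS_COLUMNS + list(CLIMATE_INDICES) + [RESPONSE_COLUMN]
    n_before = len(df)
    df = df.dropna(subset=needed)
    n_dropped = n_before - len(df)
    if df.empty:
        raise EmptyTableError("all rows dropped: no complete driver coverage")

    dummies = encode_dummies(df[["region", "species", "gear"]])
    out = pd.concat(
        [df[KEY_COLUMNS].reset_index(drop=True), df[needed[:-1]].reset_index(drop=True),
         dummies.reset_index(drop=True), df[[RESPONSE_COLUMN]].reset_index(drop=True)],
        axis=1,
    )
    out = out[KEY_COLUMNS + feature_columns() + [RESPONSE_COLUMN]]
    out = out.sort_values(KEY_COLUMNS).reset_index(drop=True)
    out.attrs["n_dropped"] = n_dropped
    return out


def correlation_clustering(
    table: pd.DataFrame,
    columns: list[str] | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Pairwise Pearson correlations plus a clustered column order.

    Average-linkage hierarchical clustering on the distance 1 - r, the
    usual heat-map diagnostic for multicollinearity among drivers.
    Zero-variance columns are excluded with a warning.

    Returns
    -------
    (correlation matrix as DataFrame, column order from the dendrogram)
    """
    cols = columns if columns is not None else [c for c in CONTINUOUS_COLUMNS + list(CLIMATE_INDICES) if c in table.columns]
    if len(cols) < 2 or len(table) < 3:
        raise ValidationError("need at least 2 columns and 3 rows for correlation clustering")
    x = table[cols]
    sd = x.std(ddof=0)
    degenerate = sd[sd == 0].index.tolist()
    if degenerate:
        warnings.warn(f"excluding zero-variance columns: {degenerate}", stacklevel=2)
        cols = [c for c in cols if c not in degenerate]
        x = table[cols]
    corr = x.corr(method="pearson")
    dist = 1.0 - corr.to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    link = average(squareform(dist, checks=False))
    order = [cols[i] for i in leaves_list(link)]
    return corr, order
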