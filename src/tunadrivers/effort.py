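"""Harmonize heterogeneous fishing-effort units to a common "days fished".

tRFMO catch-effort extracts report effort in whatever unit each fleet
logs — hooks, sets, trips, hours or days.  Before a spatial-spread index
or any cross-fleet comparison is possible, every record is converted to
days fished with fleet-specific factors:

* ``days``  -> identity
* ``hours`` -> value / hours_per_day (24)
* ``trips`` -> value * days_per_trip
* ``sets``  -> value / sets_per_day
* ``hooks`` -> (value / hooks_per_set) * (soak_hours / 24)

The default factors ship as a versioned CSV registry
(``data/conversion_rules.csv``): hooks-per-set of 2750 for standard
longline (1600 swordfish/shark-target, 1200 fresh, 1865 eastern
Pacific), soak times of 19 h (IATTC) and 22 h (CCSBT) with a 24 h
default, 0.8 sets per day for purse seiners, and trip durations of 11
(small purse seine), 16 (baitboat) and 30 (gillnet) days.  All
conversions are linear, so total days are conserved under any grouping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .errors import AmbiguousRuleError, ConfigurationError, UnmappedUnitError, ValidationError

EFFORT_UNITS = ("hooks", "sets", "trips", "hours", "days")

#: required parameters by source unit
_UNIT_PARAMS = {
    "days": frozenset(),
    "hours": frozenset({"hours_per_day"}),
    "trips": frozenset({"days_per_trip"}),
    "sets": frozenset({"sets_per_day"}),
    "hooks": frozenset({"hooks_per_set", "soak_hours"}),
}

EFFORT_COLUMNS = [
    "org",
    "stock",
    "year",
    "gear",
    "gear_subtype",
    "cell_lat",
    "cell_lon",
    "cell_size_deg",
    "effort_value",
    "effort_unit",
]


@dataclass(frozen=True)
class EffortRecord:
    """One gridded effort observation in its native unit."""

    org: str
    stock: str
    year: int
    gear: str
    effort_value: float
    effort_unit: str
    gear_subtype: Optional[str] = None
    cell_lat: float = 0.0
    cell_lon: float = 0.0
    cell_size_deg: float = 5.0

    def __post_init__(self) -> None:
        if self.effort_value < 0:
            raise ValidationError(f"effort_value must be >= 0, got {self.effort_value}")
        if self.effort_unit not in EFFORT_UNITS:
            raise ValidationError(f"unknown effort_unit {self.effort_unit!r}")
        if self.cell_size_deg not in (1, 5):
            raise ValidationError(f"cell_size_deg must be 1 or 5, got {self.cell_size_deg}")


@dataclass(frozen=True)
class ConversionRule:
    """Factors converting one (org, gear, subtype, unit) to days fished.

    ``gear_subtype=None`` acts as a wildcard; a rule with an explicit
    subtype takes precedence over a wildcard rule for the same key.
    """

    org: str
    gear: str
    source_unit: str
    gear_subtype: Optional[str] = None
    parameters: dict = field(default_factory=dict)
    reference: str = ""

    def __post_init__(self) -> None:
        required = _UNIT_PARAMS.get(self.source_unit)
        if required is None:
            raise ConfigurationError(f"unknown source_unit {self.source_unit!r}")
        given = frozenset(self.parameters)
        if given != required:
            raise ConfigurationError(
                f"rule ({self.org}, {self.gear}, {self.gear_subtype}, {self.source_unit}) "
                f"needs parameters {sorted(required)}, got {sorted(given)}"
            )
        for name, value in self.parameters.items():
            if not value > 0:
                raise ConfigurationError(f"parameter {name} must be positive, got {value}")

    def days_factor(self) -> float:
        """Multiplier taking the native effort value to days fished."""
        p = self.parameters
        if self.source_unit == "days":
            return 1.0
        if self.source_unit == "hours":
            return 1.0 / p["hours_per_day"]
        if self.source_unit == "trips":
            return float(p["days_per_trip"])
        if self.source_unit == "sets":
            return 1.0 / p["sets_per_day"]
        # hooks: hooks -> sets -> days scaled by soak time
        return (1.0 / p["hooks_per_set"]) * (p["soak_hours"] / 24.0)


def load_rules(path=None) -> list[ConversionRule]:
    """Load a rule registry from CSV (long format, one row per parameter).

    With no ``path`` the packaged default registry is used.
    """
    if path is None:
        with resources.files("tunadrivers").joinpath("data/conversion_rules.csv").open() as fh:
            raw = pd.read_csv(fh, dtype=str)
    else:
        raw = pd.read_csv(path, dtype=str)
    expected = {"org", "gear", "gear_subtype", "source_unit", "parameter", "value"}
    missing = expected - set(raw.columns)
    if missing:
        raise ConfigurationError(f"rule registry missing columns: {sorted(missing)}")
    rules = []
    keys = ["org", "gear", "gear_subtype", "source_unit"]
    for (org, gear, sub, unit), grp in raw.groupby(keys, dropna=False):
        params = {}
        for _, row in grp.iterrows():
            if isinstance(row["parameter"], str) and row["parameter"].strip():
                params[row["parameter"].strip()] = float(row["value"])
        ref = str(grp["reference"].iloc[0]) if "reference" in grp.columns else ""
        rules.append(
            ConversionRule(
                org=org,
                gear=gear,
                gear_subtype=None if pd.isna(sub) or sub == "" else sub,
                source_unit=unit,
                parameters=params,
                reference=ref,
            )
        )
    _check_no_duplicates(rules)
    return rules


def _check_no_duplicates(rules: Iterable[ConversionRule]) -> None:
    seen = set()
    for r in rules:
        key = (r.org, r.gear, r.gear_subtype, r.source_unit)
        if key in seen:
            raise AmbiguousRuleError(f"duplicate conversion rule for {key}")
        seen.add(key)


def _resolve_rule(
    rules: Iterable[ConversionRule],
    org: str,
    gear: str,
    gear_subtype: Optional[str],
    unit: str,
) -> ConversionRule:
    exact = [
        r
        for r in rules
        if r.org == org and r.gear == gear and r.source_unit == unit and r.gear_subtype == gear_subtype
    ]
    wild = [
        r
        for r in rules
        if r.org == org and r.gear == gear and r.source_unit == unit and r.gear_subtype is None
    ]
    matches = exact if exact else wild
    if not matches:
        raise UnmappedUnitError(
            f"no conversion rule for org={org!r} gear={gear!r} "
            f"subtype={gear_subtype!r} unit={unit!r}"
        )
    if len(matches) > 1:
        raise AmbiguousRuleError(
            f"{len(matches)} rules match org={org!r} gear={gear!r} "
            f"subtype={gear_subtype!r} unit={unit!r}"
        )
    return matches[0]


def convert_record(record: EffortRecord, rules: Iterable[ConversionRule]) -> float:
    """Days fished for one record under the uniquely matching rule."""
    rule = _resolve_rule(rules, record.org, record.gear, record.gear_subtype, record.effort_unit)
    return record.effort_value * rule.days_factor()


def harmonize_table(
    records: pd.DataFrame,
    rules: Iterable[ConversionRule],
    skip_unmapped: bool = False,
) -> pd.DataFrame:
    """Convert an effort table to days fished and sum over duplicate keys.

    Parameters
    ----------
    records
        DataFrame with :data:`EFFORT_COLUMNS` (``gear_subtype`` may be
        empty/NaN).
    rules
        Conversion rule registry.
    skip_unmapped
        Drop records without a matching rule instead of raising; dropped
        counts are recorded in ``result.attrs["n_skipped"]``.

    Returns
    -------
    DataFrame keyed by (org, stock, year, gear, cell_lat, cell_lon,
    cell_size_deg) with a ``days_fished`` column.  Total days equal the
    sum of the per-record conversions.
    """
    rules = list(rules)
    _check_no_duplicates(rules)
    missing = set(EFFORT_COLUMNS) - set(records.columns)
    if missing:
        raise ValidationError(f"effort table missing columns: {sorted(missing)}")
    if (records["effort_value"] < 0).any():
        raise ValidationError("effort_value must be non-negative")

    df = records.copy()
    sub = df["gear_subtype"]
    df["gear_subtype"] = sub.where(~(sub.isna() | (sub == "")), None)

    factors = np.full(len(df), np.nan)
    n_skipped = 0
    group_cols = ["org", "gear", "gear_subtype", "effort_unit"]
    for key, idx in df.groupby(group_cols, dropna=False).groups.items():
        org, gear, subtype, unit = key
        subtype = None if pd.isna(subtype) else subtype
        try:
            rule = _resolve_rule(rules, org, gear, subtype, unit)
        except UnmappedUnitError:
            if skip_unmapped:
                n_skipped += len(idx)
                continue
            raise
        factors[df.index.get_indexer(idx)] = rule.days_factor()

    df["days_fished"] = df["effort_value"].to_numpy() * factors
    df = df.dropna(subset=["days_fished"])
    keys = ["org", "stock", "year", "gear", "cell_lat", "cell_lon", "cell_size_deg"]
    out = df.groupby(keys, as_index=False)["days_fished"].sum()
    out.attrs["n_skipped"] = n_skipped
    return out
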