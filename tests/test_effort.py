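"""Effort-unit harmonization: conversion factors, linearity, conservation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tunadrivers.effort import (
    ConversionRule,
    EffortRecord,
    convert_record,
    harmonize_table,
    load_rules,
)
from tunadrivers.errors import (
    AmbiguousRuleError,
    ConfigurationError,
    UnmappedUnitError,
    ValidationError,
)


def _record(org="IOTC", gear="baitboat", subtype=None, unit="trips", value=1.0, **kw):
    return EffortRecord(
        org=org, stock="IOSKJ", year=2000, gear=gear, gear_subtype=subtype,
        effort_value=value, effort_unit=unit, **kw,
    )


class TestConvertRecord:
    @pytest.mark.parametrize(
        "org,gear,subtype,unit,value,expected",
        [
            # trip-based fleets
            ("IOTC", "baitboat", None, "trips", 3, 48.0),  # 16 days/trip
            ("IOTC", "purseseine", "PSS", "trips", 2, 22.0),  # 11 days/trip
            ("IOTC", "gillnet", None, "trips", 1, 30.0),
            # identity and hour conversions
            ("WCPFC", "purseseine", None, "days", 7, 7.0),
            ("ICCAT", "purseseine", None, "hours", 48, 2.0),
            ("CCSBT", "baitboat", None, "hours", 24, 1.0),
            # hooks: value / hooks_per_set * soak_hours / 24
            ("IOTC", "longline", "LL", "hooks", 5500, 2.0),
            ("IOTC", "longline", "FLL", "hooks", 1200, 1.0),
            ("IOTC", "longline", "ELL", "hooks", 3200, 2.0),
            ("IATTC", "longline", None, "hooks", 1865, 19 / 24),
            ("CCSBT", "longline", None, "hooks", 2750, 22 / 24),
            # set-based fleets: value / sets_per_day
            ("IATTC", "purseseine", None, "sets", 4, 5.0),
            ("IOTC", "purseseine", "PS", "sets", 0.8, 1.0),
            ("IATTC", "baitboat", None, "sets", 10, 2.0),
        ],
    )
    def test_registry_factors(self, rules, org, gear, subtype, unit, value, expected):
        rec = _record(org=org, gear=gear, subtype=subtype, unit=unit, value=value)
        assert convert_record(rec, rules) == pytest.approx(expected, rel=1e-12)

    def test_every_registry_rule_is_exercised(self, rules):
        """Each shipped rule converts a unit record to a positive, finite factor."""
        assert len(rules) >= 25
        for rule in rules:
            rec = EffortRecord(
                org=rule.org, stock="IOSKJ", year=2001, gear=rule.gear,
                gear_subtype=rule.gear_subtype, effort_value=1.0,
                effort_unit=rule.source_unit,
            )
            days = convert_record(rec, rules)
            assert np.isfinite(days) and days > 0

    def test_unmapped_unit_names_the_key(self, rules):
        rec = _record(org="WCPFC", gear="gillnet", unit="trips")
        with pytest.raises(UnmappedUnitError, match="WCPFC.*gillnet"):
            convert_record(rec, rules)

    def test_ambiguous_rules_rejected(self):
        dup = [
            ConversionRule("IOTC", "baitboat", "trips", parameters={"days_per_trip": 16}),
            ConversionRule("IOTC", "baitboat", "trips", parameters={"days_per_trip": 10}),
        ]
        with pytest.raises(AmbiguousRuleError):
            harmonize_table(
                pd.DataFrame([_record().__dict__]), dup
            )

    def test_explicit_subtype_beats_wildcard(self):
        rules = [
            ConversionRule("IOTC", "longline", "hooks", gear_subtype=None,
                           parameters={"hooks_per_set": 2750, "soak_hours": 24}),
            ConversionRule("IOTC", "longline", "hooks", gear_subtype="FLL",
                           parameters={"hooks_per_set": 1200, "soak_hours": 24}),
        ]
        rec = _record(org="IOTC", gear="longline", subtype="FLL", unit="hooks", value=1200)
        assert convert_record(rec, rules) == pytest.approx(1.0)

    def test_rule_parameter_validation(self):
        with pytest.raises(ConfigurationError):
            ConversionRule("IOTC", "baitboat", "trips", parameters={})
        with pytest.raises(ConfigurationError):
            ConversionRule("IOTC", "baitboat", "trips", parameters={"days_per_trip": -1})

    def test_negative_effort_rejected(self):
        with pytest.raises(ValidationError):
            _record(value=-1.0)

    @given(value=st.floats(0, 1e6), scale=st.floats(0.01, 100))
    @settings(max_examples=50, deadline=None)
    def test_conversion_is_linear(self, value, scale):
        rules = load_rules()
        rec = _record(org="IOTC", gear="longline", subtype="LL", unit="hooks", value=value)
        scaled = _record(org="IOTC", gear="longline", subtype="LL", unit="hooks", value=value * scale)
        assert convert_record(scaled, rules) == pytest.approx(
            scale * convert_record(rec, rules), rel=1e-9, abs=1e-9
        )


class TestHarmonizeTable:
    def _frame(self, rows):
        return pd.DataFrame(
            rows,
            columns=["org", "stock", "year", "gear", "gear_subtype", "cell_lat",
                     "cell_lon", "cell_size_deg", "effort_value", "effort_unit"],
        )

    def test_same_cell_records_sum(self, rules):
        rows = [
            ("IOTC", "IOSKJ", 2000, "baitboat", None, 0.5, 0.5, 1, 1.0, "trips"),
            ("IOTC", "IOSKJ", 2000, "baitboat", None, 0.5, 0.5, 1, 1.0, "trips"),
        ]
        out = harmonize_table(self._frame(rows), rules)
        assert len(out) == 1
        assert out["days_fished"].iloc[0] == pytest.approx(32.0)

    def test_empty_input_gives_empty_table(self, rules):
        out = harmonize_table(self._frame([]), rules)
        assert out.empty

    def test_mixed_units_grouped_by_distinct_keys(self, rules):
        rows = [
            ("IOTC", "IOSKJ", 2000, "purseseine", "PS", 0.5, 0.5, 1, 24.0, "hours"),
            ("IOTC", "IOSKJ", 2000, "purseseine", "PS", 1.5, 0.5, 1, 0.8, "sets"),
            ("IOTC", "IOSKJ", 2001, "purseseine", "PS", 0.5, 0.5, 1, 48.0, "hours"),
        ]
        out = harmonize_table(self._frame(rows), rules)
        assert len(out) == 3  # three distinct (year, cell) keys
        assert out["days_fished"].sum() == pytest.approx(1 + 1 + 2)

    def test_conservation_under_grouping(self, rules, small_bundle):
        records = small_bundle.effort_records
        out = harmonize_table(records, rules)
        per_record = sum(
            convert_record(EffortRecord(**row), rules)
            for row in records.to_dict("records")
        )
        assert out["days_fished"].sum() == pytest.approx(per_record, rel=1e-9)

    def test_skip_unmapped_drops_and_counts(self, rules):
        rows = [
            ("IOTC", "IOSKJ", 2000, "baitboat", None, 0.5, 0.5, 1, 1.0, "trips"),
            ("WCPFC", "WCPOSKJ", 2000, "gillnet", None, 0.5, 0.5, 1, 2.0, "trips"),
        ]
        with pytest.raises(UnmappedUnitError):
            harmonize_table(self._frame(rows), rules)
        out = harmonize_table(self._frame(rows), rules, skip_unmapped=True)
        assert len(out) == 1
        assert out.attrs["n_skipped"] == 1
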