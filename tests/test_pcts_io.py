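"""Parsing, cleaning and recoding: conservation, idempotence, round trips."""

import dataclasses
from datetime import date

import pytest

from concord7 import pcts_io, synthetic_data as sd
from concord7.records import ConsultationRecord, SpeciesDetermination


def _record(**kw):
    base = dict(
        consultation_id="C1",
        agency="Army Corps of Engineers",
        region="Northwest",
        work_type="waterway",
        type="formal",
        complexity="standard",
        start_date=date(2005, 3, 1),
        end_date=date(2005, 6, 1),
        species_rows=(
            SpeciesDetermination("Chinook salmon", None, "LAA", "no jeopardy", "no critical habitat"),
        ),
    )
    base.update(kw)
    return ConsultationRecord(**base)


class TestRoundTrip:
    def test_parse_of_write_fixture_is_identity(self, tmp_path, small_records):
        dest = tmp_path / "rt.csv"
        sd.write_fixture(small_records, dest)
        parsed = pcts_io.parse_records(dest)
        assert parsed.n_rejected == 0
        assert len(parsed.issues) == 0
        assert parsed.records == list(small_records)

    def test_counting_fixture(self, tmp_path, small_records):
        dest = tmp_path / "c.csv"
        recs = small_records[:3]
        sd.write_fixture(recs, dest)
        parsed = pcts_io.parse_records(dest)
        assert len(parsed.records) == 3
        assert parsed.n_attached == sum(len(r.species_rows) for r in recs)

    def test_conservation_rows_in_equals_attached_plus_rejected(self, tmp_path, small_records):
        dest = tmp_path / "cons.csv"
        sd.write_fixture(small_records[:5], dest)
        # corrupt one row: blank species -> rejected
        lines = dest.read_text().splitlines()
        parts = lines[1].split(",")
        parts[7] = ""
        lines[1] = ",".join(parts)
        dest.write_text("\n".join(lines) + "\n")
        parsed = pcts_io.parse_records(dest)
        assert parsed.n_rows == parsed.n_attached + parsed.n_rejected
        assert parsed.n_rejected == 1

    def test_unknown_determination_kept_as_missing_and_logged(self, tmp_path, small_records):
        import pandas as pd

        dest = tmp_path / "u.csv"
        sd.write_fixture(small_records[:2], dest)
        df = pd.read_csv(dest, dtype=str, keep_default_na=False)
        df.loc[0, "agency_determination"] = "mystery outcome"
        df.to_csv(dest, index=False)
        parsed = pcts_io.parse_records(dest)
        kept = parsed.issues[parsed.issues["disposition"] == "kept"]
        assert len(kept) >= 1
        assert parsed.n_rejected == 0
        assert any(
            det.agency_proposed == "missing" or det.expert_final == "missing"
            for r in parsed.records
            for det in r.species_rows
        )

    def test_missing_mandatory_columns_is_schema_error(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("consultation_id,species\nC1,Chinook salmon\n")
        with pytest.raises(pcts_io.SchemaError, match="agency"):
            pcts_io.parse_records(p)


class TestCleanDates:
    def test_ordered_dates_unchanged(self):
        rec = _record()
        assert pcts_io.clean_dates(rec) == rec

    def test_reversed_dates_swapped_and_flagged(self):
        rec = _record(start_date=date(2005, 6, 1), end_date=date(2005, 3, 1))
        out = pcts_io.clean_dates(rec)
        assert out.start_date == date(2005, 3, 1)
        assert out.end_date == date(2005, 6, 1)
        assert "date_corrected" in out.flags

    def test_missing_start_retained(self):
        rec = _record(start_date=None)
        assert pcts_io.clean_dates(rec) == rec

    def test_idempotent(self):
        rec = _record(start_date=date(2005, 6, 1), end_date=date(2005, 3, 1))
        once = pcts_io.clean_dates(rec)
        assert pcts_io.clean_dates(once) == once


class TestHarmonizeNames:
    def test_alias_lookup(self):
        rec = _record(agency="USACE")
        out = pcts_io.harmonize_names(rec)
        assert out.agency == "Army Corps of Engineers"
        assert "unmapped:agency" not in out.flags

    def test_unmapped_passes_through_flagged(self):
        rec = _record(agency="Agency X")
        out = pcts_io.harmonize_names(rec)
        assert out.agency == "Agency X"
        assert "unmapped:agency" in out.flags

    def test_species_alias(self):
        rec = _record(
            species_rows=(
                SpeciesDetermination("chinook", None, "LAA", "no jeopardy", "missing"),
            )
        )
        out = pcts_io.harmonize_names(rec)
        assert out.species_rows[0].species == "Chinook salmon"

    def test_idempotent(self):
        rec = _record(agency="USACE", work_type="water way")
        once = pcts_io.harmonize_names(rec)
        assert pcts_io.harmonize_names(once) == once

    def test_does_not_mutate_input(self):
        rec = _record(agency="USACE")
        pcts_io.harmonize_names(rec)
        assert rec.agency == "USACE"


@pytest.mark.parametrize(
    "raw, expected",
    [
        ("Formal Programmatic", ("formal", "programmatic")),
        ("Informal", ("informal", "standard")),
        ("Combined Conference", ("combined", "conference")),
        ("informal early", ("informal", "early")),
        ("", ("missing", "missing")),
        ("Technical Assistance", ("missing", "missing")),
    ],
)
def test_split_consultation_type(raw, expected):
    split = pcts_io.split_consultation_type(raw)
    assert (split.type, split.complexity) == expected


def test_split_flags_defaulted_complexity():
    assert pcts_io.split_consultation_type("Informal").defaulted
    assert not pcts_io.split_consultation_type("Informal Standard").defaulted


@pytest.mark.parametrize(
    "raw, role, expected",
    [
        ("not likely to adversely affect", "expert", "NLAA"),
        ("not likely to adversely affect", "agency", "NLAA"),
        ("jeopardy", "expert", "jeopardy"),
        ("jeopardy", "agency", "proposed jeopardy"),
        ("LAA", "agency", "LAA"),
        ("LAA", "expert", "missing"),  # LAA is never a final expert category
        ("gibberish", "expert", "missing"),
        ("", "expert", "missing"),
    ],
)
def test_recode_species_determination(raw, role, expected):
    assert pcts_io.recode_species_determination(raw, role) == expected


@pytest.mark.parametrize(
    "raw, designated, expected",
    [
        ("adverse modification", True, "adverse modification"),
        ("adverse modification", False, "no critical habitat"),
        ("anything at all", False, "no critical habitat"),
        ("", True, "missing"),
        ("nonsense", True, "missing"),
    ],
)
def test_recode_critical_habitat(raw, designated, expected):
    assert pcts_io.recode_critical_habitat(raw, designated) == expected


class TestAggregations:
    def test_dps_rows_collapse_to_one_species_row(self):
        rows = tuple(
            SpeciesDetermination("Coho salmon", d, "LAA", e, "missing")
            for d, e in [
                ("Oregon Coast ESU", "no jeopardy"),
                ("Central California ESU", "jeopardy"),
                ("Lower Columbia ESU", "no jeopardy"),
            ]
        )
        rec = _record(species_rows=rows)
        out = pcts_io.aggregate_dps([rec])[0]
        assert len(out.species_rows) == 1
        assert out.species_rows[0].species == "Coho salmon"
        # most severe category survives the collapse
        assert out.species_rows[0].expert_final == "jeopardy"
        # original record untouched: determination-level tally still 3
        assert len(rec.species_rows) == 3

    def test_distinct_species_stay_distinct(self):
        rows = (
            SpeciesDetermination("Coho salmon", "Oregon Coast ESU", "LAA", "no jeopardy", "missing"),
            SpeciesDetermination("Chinook salmon", "Snake River ESU", "LAA", "no jeopardy", "missing"),
        )
        out = pcts_io.aggregate_dps([_record(species_rows=rows)])[0]
        assert {d.species for d in out.species_rows} == {"Coho salmon", "Chinook salmon"}

    @pytest.mark.parametrize(
        "region, expected",
        [("Northwest", "West Coast"), ("Southwest", "West Coast"), ("Alaska", "Alaska")],
    )
    def test_region_merge(self, region, expected):
        out = pcts_io.aggregate_regions([_record(region=region)])[0]
        assert out.region == expected

    def test_region_merge_idempotent(self):
        recs = [_record(region="Northwest")]
        once = pcts_io.aggregate_regions(recs)
        assert pcts_io.aggregate_regions(once) == once


class TestFilterPeriod:
    @pytest.mark.parametrize(
        "start, kept",
        [
            (date(1999, 12, 31), False),
            (date(2000, 1, 1), True),
            (date(2017, 6, 30), True),
            (date(2017, 7, 1), False),
        ],
    )
    def test_window_boundaries(self, start, kept):
        rec = _record(start_date=start, end_date=start)
        assert (len(pcts_io.filter_period([rec])) == 1) is kept

    def test_missing_start_excluded(self):
        assert pcts_io.filter_period([_record(start_date=None)]) == []

    def test_integer_bounds_are_whole_years(self):
        rec = _record(start_date=date(2016, 12, 31), end_date=date(2017, 1, 5))
        assert len(pcts_io.filter_period([rec], 2000, 2016)) == 1
        assert len(pcts_io.filter_period([rec], 2000, 2015)) == 0
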