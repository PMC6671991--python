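"""Parsing, cleaning and recoding of consultation-record extracts.

Administrative consultation databases accumulate entry errors over decades
of use: reversed dates, inconsistent species/agency/work-type spellings, a
free-text consultation-type field mixing formality with complexity, and a
zoo of raw determination strings.  This module turns a tabular extract into
validated :class:`~concord7.records.ConsultationRecord` values while keeping
a complete audit trail: every input row is either attached to a record or
reported in an issues log with a reason — never silently dropped — and all
cleaning operations are idempotent and non-mutating.

Vocabulary maps (name aliases, determination synonyms) are shipped as CSV
data rather than code so that new raw vocabularies can be accommodated
without a release.
"""

from __future__ import annotations

import csv
import dataclasses
from dataclasses import dataclass, field
from datetime import date
from importlib import resources
from pathlib import Path
from typing import Iterable, NamedTuple, Optional, Sequence

import pandas as pd

from .records import (
    AGENCY_CATEGORIES,
    COMPLEXITIES,
    CONSULTATION_TYPES,
    CRITICAL_HABITAT_CATEGORIES,
    EXPERT_CATEGORIES,
    MISSING,
    ConsultationRecord,
    SpeciesDetermination,
)

__all__ = [
    "SchemaError",
    "ParseResult",
    "aggregate_dps",
    "aggregate_regions",
    "clean_dates",
    "clean_records",
    "default_alias_map",
    "default_synonyms",
    "filter_period",
    "harmonize_names",
    "parse_records",
    "recode_critical_habitat",
    "recode_species_determination",
    "split_consultation_type",
]

MANDATORY_COLUMNS = [
    "consultation_id",
    "agency",
    "region",
    "work_type",
    "consultation_type",
    "start_date",
    "end_date",
    "species",
    "dps_esu",
    "agency_determination",
    "expert_determination",
    "critical_habitat_determination",
]


class SchemaError(ValueError):
    """The input file is missing mandatory columns."""


# ---------------------------------------------------------------------------
# Shipped vocabulary maps


def _load_map_csv(name: str) -> dict[tuple[str, str], str]:
    out: dict[tuple[str, str], str] = {}
    with resources.files("concord7").joinpath("data", name).open("r", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            out[(row["field"], row["raw"].strip().lower())] = row["canonical"]
    return out


def default_alias_map() -> dict[tuple[str, str], str]:
    """(field, lowercased raw) -> canonical for species/agency/work-type names."""
    return _load_map_csv("aliases.csv")


def default_synonyms() -> dict[tuple[str, str], str]:
    """(role, lowercased raw) -> canonical determination category."""
    return _load_map_csv("determination_synonyms.csv")


def load_two_column_map(path: str | Path, field_name: str) -> dict[tuple[str, str], str]:
    """Load a user (raw, canonical) CSV as an alias map for one field."""
    out = {}
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            out[(field_name, row["raw"].strip().lower())] = row["canonical"]
    return out


# ---------------------------------------------------------------------------
# Field-level recoding


class TypeSplit(NamedTuple):
    type: str
    complexity: str
    defaulted: bool  # complexity defaulted to "standard"
    recognized: bool


def split_consultation_type(raw: str) -> TypeSplit:
    """Split a raw consultation-type string into (type, complexity).

    The type is formal/informal/combined and the complexity is
    standard/programmatic/conference/early.  A bare type with no qualifier
    defaults to standard complexity (flagged via ``defaulted``); anything
    unrecognized maps to (missing, missing).
    """
    tokens = raw.strip().lower().split()
    if not tokens:
        return TypeSplit(MISSING, MISSING, False, False)
    ctype = tokens[0] if tokens[0] in CONSULTATION_TYPES else None
    rest = tokens[1:]
    if ctype is None:
        return TypeSplit(MISSING, MISSING, False, False)
    if not rest:
        return TypeSplit(ctype, "standard", True, True)
    complexity = " ".join(rest)
    if complexity in COMPLEXITIES:
        return TypeSplit(ctype, complexity, False, True)
    return TypeSplit(MISSING, MISSING, False, False)


def recode_species_determination(
    raw: str,
    role: str = "expert",
    synonyms: Optional[dict[tuple[str, str], str]] = None,
) -> str:
    """Recode a raw determination string into its category vocabulary.

    ``role`` is "agency" (five proposal categories) or "expert" (four final
    categories).  An LAA string in the expert role maps to missing: LAA is
    never a final category because formal review must conclude with a
    jeopardy or no-jeopardy finding.  Empty or unmapped strings map to
    missing; callers log them.
    """
    if role not in ("agency", "expert"):
        raise ValueError(f"role must be 'agency' or 'expert', got {role!r}")
    key = raw.strip().lower()
    if key in ("", MISSING, "na", "n/a", "none recorded"):
        return MISSING
    table = default_synonyms() if synonyms is None else synonyms
    cat = table.get((role, key), None)
    if cat is None:
        return MISSING
    valid = AGENCY_CATEGORIES if role == "agency" else EXPERT_CATEGORIES
    return cat if cat in valid else MISSING


def recode_critical_habitat(
    raw: str,
    had_designated_ch: bool,
    synonyms: Optional[dict[tuple[str, str], str]] = None,
) -> str:
    """Recode a critical-habitat determination string.

    Species without designated critical habitat at consultation time are
    coded 'no critical habitat' regardless of the raw string.
    """
    if not had_designated_ch:
        return "no critical habitat"
    key = raw.strip().lower()
    if key in ("", MISSING, "na", "n/a"):
        return MISSING
    table = default_synonyms() if synonyms is None else synonyms
    cat = table.get(("critical_habitat", key), None)
    if cat is None or cat not in CRITICAL_HABITAT_CATEGORIES:
        return MISSING
    return cat


# ---------------------------------------------------------------------------
# Parsing


@dataclass
class ParseResult:
    """Records plus a complete row-level audit log.

    ``issues`` has columns (row, reason, disposition); disposition is
    "rejected" for rows not attached to any record and "kept" for rows
    attached with a recoding fallback.  Conservation always holds:
    ``n_rows == n_attached + n_rejected``.
    """

    records: list[ConsultationRecord]
    issues: pd.DataFrame
    n_rows: int
    n_attached: int
    n_rejected: int

    def rejects(self) -> pd.DataFrame:
        return self.issues[self.issues["disposition"] == "rejected"]


def _parse_date(raw: str) -> Optional[date]:
    raw = raw.strip()
    if not raw:
        return None
    try:
        return date.fromisoformat(raw)
    except ValueError:
        return None


def parse_records(
    source: str | Path,
    synonyms: Optional[dict[tuple[str, str], str]] = None,
    column_map: Optional[dict[str, str]] = None,
) -> ParseResult:
    """Parse a CSV extract into consultation records.

    ``column_map`` renames raw-extract columns to the fixture dialect
    (raw name -> canonical name) for non-fixture exports.  Every row is
    accounted for in the returned :class:`ParseResult`.
    """
    df = pd.read_csv(source, dtype=str, keep_default_na=False)
    if column_map:
        df = df.rename(columns=column_map)
    missing_cols = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"missing mandatory columns: {missing_cols}")

    issues: list[dict] = []
    groups: dict[str, dict] = {}
    n_rejected = 0
    for pos, row in enumerate(df.itertuples(index=False), start=1):
        cid = row.consultation_id.strip()
        species = row.species.strip()
        if not cid or not species:
            issues.append({"row": pos, "reason": "missing consultation_id or species",
                           "disposition": "rejected"})
            n_rejected += 1
            continue
        agency_det = recode_species_determination(row.agency_determination, "agency", synonyms)
        expert_det = recode_species_determination(row.expert_determination, "expert", synonyms)
        if agency_det == MISSING and row.agency_determination.strip().lower() not in ("", MISSING):
            issues.append({"row": pos, "reason":
                           f"unknown agency determination {row.agency_determination!r}",
                           "disposition": "kept"})
        if expert_det == MISSING and row.expert_determination.strip().lower() not in ("", MISSING):
            issues.append({"row": pos, "reason":
                           f"unknown expert determination {row.expert_determination!r}",
                           "disposition": "kept"})
        raw_ch = row.critical_habitat_determination.strip().lower()
        if raw_ch == "no critical habitat":
            ch = "no critical habitat"
        else:
            ch = recode_critical_habitat(row.critical_habitat_determination, True, synonyms)
            if ch == MISSING and raw_ch not in ("", MISSING):
                issues.append({"row": pos, "reason":
                               f"unknown critical-habitat determination {row.critical_habitat_determination!r}",
                               "disposition": "kept"})
        det = SpeciesDetermination(
            species=species,
            dps_esu=row.dps_esu.strip() or None,
            agency_proposed=agency_det,
            expert_final=expert_det,
            critical_habitat=ch,
        )
        g = groups.setdefault(cid, {"first": row, "rows": [], "flags": set()})
        g["rows"].append(det)

    records = []
    for cid, g in groups.items():
        first = g["first"]
        split = split_consultation_type(first.consultation_type)
        flags = set(g["flags"])
        if split.defaulted:
            flags.add("complexity_defaulted")
        if not split.recognized and first.consultation_type.strip():
            flags.add("unrecognized_consultation_type")
        start = _parse_date(first.start_date)
        end = _parse_date(first.end_date)
        if first.start_date.strip() and start is None:
            flags.add("unparseable_start_date")
        if first.end_date.strip() and end is None:
            flags.add("unparseable_end_date")
        records.append(
            ConsultationRecord(
                consultation_id=cid,
                agency=first.agency.strip(),
                region=first.region.strip(),
                work_type=first.work_type.strip(),
                type=split.type,
                complexity=split.complexity,
                start_date=start,
                end_date=end,
                species_rows=tuple(g["rows"]),
                flags=tuple(sorted(flags)),
            )
        )

    n_attached = sum(len(r.species_rows) for r in records)
    issues_df = pd.DataFrame(issues, columns=["row", "reason", "disposition"])
    return ParseResult(
        records=records,
        issues=issues_df,
        n_rows=len(df),
        n_attached=n_attached,
        n_rejected=n_rejected,
    )


# ---------------------------------------------------------------------------
# Record-level cleaning (all idempotent, all return new values)


def clean_dates(record: ConsultationRecord) -> ConsultationRecord:
    """Swap reversed start/end dates and flag the correction.

    Swapping (rather than dropping) preserves sample size and leaves an
    audit trail via the "date_corrected" flag.
    """
    if record.start_date and record.end_date and record.end_date < record.start_date:
        return dataclasses.replace(
            record, start_date=record.end_date, end_date=record.start_date
        ).with_flag("date_corrected")
    return record


def harmonize_names(
    record: ConsultationRecord,
    alias_map: Optional[dict[tuple[str, str], str]] = None,
) -> ConsultationRecord:
    """Map species/agency/work-type strings to canonical names.

    A string already canonical (it appears as a canonical value of the map)
    passes through untouched; a known raw alias is replaced; anything else
    passes through with an "unmapped:<field>" flag.  Idempotent.
    """
    amap = default_alias_map() if alias_map is None else alias_map
    canonical: dict[str, set[str]] = {}
    for (fld, _), canon in amap.items():
        canonical.setdefault(fld, set()).add(canon)

    flags: list[str] = []

    def fix(fld: str, value: str) -> str:
        if value in canonical.get(fld, set()):
            return value
        mapped = amap.get((fld, value.strip().lower()))
        if mapped is not None:
            return mapped
        flags.append(f"unmapped:{fld}")
        return value

    agency = fix("agency", record.agency)
    work_type = fix("work_type", record.work_type)
    rows = tuple(
        dataclasses.replace(det, species=fix("species", det.species))
        for det in record.species_rows
    )
    out = dataclasses.replace(record, agency=agency, work_type=work_type, species_rows=rows)
    for f in sorted(set(flags)):
        out = out.with_flag(f)
    return out


_SEVERITY = {
    "expert": {MISSING: -1, "no effect": 0, "NLAA": 1, "no jeopardy": 2, "jeopardy": 3},
    "agency": {MISSING: -1, "no effect": 0, "NLAA": 1, "LAA": 2,
               "proposed no jeopardy": 3, "proposed jeopardy": 4},
    "critical_habitat": {MISSING: -1, "no critical habitat": 0, "no effect": 1, "NLAA": 2,
                         "no adverse modification": 3, "adverse modification": 4},
}


def aggregate_dps(records: Iterable[ConsultationRecord]) -> list[ConsultationRecord]:
    """Collapse DPS/ESU rows to one species-level row per consultation.

    Within a consultation, all listed units of one species become a single
    row (``dps_esu = None``) carrying the most severe category observed in
    each determination field, so "any unit jeopardized" survives the
    collapse.  Use the original records wherever the unit of analysis is
    the individual determination.
    """
    out = []
    for rec in records:
        by_species: dict[str, list[SpeciesDetermination]] = {}
        order: list[str] = []
        for det in rec.species_rows:
            if det.species not in by_species:
                order.append(det.species)
            by_species.setdefault(det.species, []).append(det)
        rows = []
        for sp in order:
            dets = by_species[sp]
            rows.append(
                SpeciesDetermination(
                    species=sp,
                    dps_esu=None,
                    agency_proposed=max(dets, key=lambda d: _SEVERITY["agency"][d.agency_proposed]).agency_proposed,
                    expert_final=max(dets, key=lambda d: _SEVERITY["expert"][d.expert_final]).expert_final,
                    critical_habitat=max(dets, key=lambda d: _SEVERITY["critical_habitat"][d.critical_habitat]).critical_habitat,
                )
            )
        out.append(dataclasses.replace(rec, species_rows=tuple(rows)))
    return out


_REGION_MERGE = {"Southwest": "West Coast", "Northwest": "West Coast"}


def aggregate_regions(records: Iterable[ConsultationRecord]) -> list[ConsultationRecord]:
    """Fold the historical Southwest and Northwest regions into West Coast."""
    return [
        dataclasses.replace(rec, region=_REGION_MERGE.get(rec.region, rec.region))
        for rec in records
    ]


def _as_date(value: date | int, end_of_year: bool) -> date:
    if isinstance(value, date):
        return value
    return date(value, 12, 31) if end_of_year else date(value, 1, 1)


def filter_period(
    records: Iterable[ConsultationRecord],
    start: date | int = date(2000, 1, 1),
    end: date | int = date(2017, 6, 30),
) -> list[ConsultationRecord]:
    """Keep records whose start date falls in the closed analysis window.

    Integer bounds mean whole years.  Records with no parseable start date
    are excluded (they cannot be placed in time).
    """
    lo = _as_date(start, end_of_year=False)
    hi = _as_date(end, end_of_year=True)
    if lo > hi:
        raise ValueError("analysis window start is after its end")
    return [r for r in records if r.start_date is not None and lo <= r.start_date <= hi]


def clean_records(
    records: Iterable[ConsultationRecord],
    alias_map: Optional[dict[tuple[str, str], str]] = None,
) -> list[ConsultationRecord]:
    """Standard cleaning pipeline: harmonize names, fix dates, merge regions."""
    out = [clean_dates(harmonize_names(r, alias_map)) for r in records]
    return aggregate_regions(out)
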