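"""Core domain types for section 7 consultation records.

A *consultation* is one administrative review of a proposed federal action.
Each consultation carries one or more per-species rows, and each row pairs
the determination the action agency proposed with the final determination
made by the expert wildlife agency (here generically "the expert").

Category vocabularies
---------------------
Agency-proposed determinations come in five levels, ordered by the severity
of effect they imply::

    no effect < NLAA < LAA            (plus the rare direct proposals
                                       "proposed no jeopardy" and
                                       "proposed jeopardy")

Expert final determinations come in four levels::

    no effect < NLAA < no jeopardy < jeopardy

An LAA proposal is never a *final* expert category: once the expert finds
"likely to adversely affect", formal review must end in either "no jeopardy"
or "jeopardy".
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date
from typing import Optional

# Agency-proposed determination categories, in severity order for the first
# three; the two "proposed" categories are direct jeopardy-range proposals.
AGENCY_CATEGORIES: tuple[str, ...] = (
    "no effect",
    "NLAA",
    "LAA",
    "proposed no jeopardy",
    "proposed jeopardy",
)

# Expert final determination categories, in severity order.
EXPERT_CATEGORIES: tuple[str, ...] = (
    "no effect",
    "NLAA",
    "no jeopardy",
    "jeopardy",
)

CRITICAL_HABITAT_CATEGORIES: tuple[str, ...] = (
    "no effect",
    "NLAA",
    "no adverse modification",
    "adverse modification",
    "no critical habitat",
)

MISSING = "missing"

RAW_REGIONS: tuple[str, ...] = (
    "Northeast",
    "Southeast",
    "Alaska",
    "Pacific Island",
    "West Coast",
    "Southwest",
    "Northwest",
)

CONSULTATION_TYPES: tuple[str, ...] = ("formal", "informal", "combined")
COMPLEXITIES: tuple[str, ...] = ("standard", "programmatic", "conference", "early")


@dataclass(frozen=True)
class SpeciesDetermination:
    """One per-species row of a consultation.

    ``dps_esu`` is the Distinct Population Segment / Evolutionarily
    Significant Unit label when the listed unit is below the species level,
    else ``None``.
    """

    species: str
    dps_esu: Optional[str]
    agency_proposed: str  # AGENCY_CATEGORIES or MISSING
    expert_final: str  # EXPERT_CATEGORIES or MISSING
    critical_habitat: str = MISSING  # CRITICAL_HABITAT_CATEGORIES or MISSING

    def __post_init__(self) -> None:
        if self.agency_proposed not in AGENCY_CATEGORIES + (MISSING,):
            raise ValueError(f"unknown agency determination {self.agency_proposed!r}")
        if self.expert_final not in EXPERT_CATEGORIES + (MISSING,):
            raise ValueError(f"unknown expert determination {self.expert_final!r}")
        if self.critical_habitat not in CRITICAL_HABITAT_CATEGORIES + (MISSING,):
            raise ValueError(f"unknown critical-habitat determination {self.critical_habitat!r}")


@dataclass(frozen=True)
class ConsultationRecord:
    """One consultation with its per-species determination rows.

    ``type`` is formal/informal/combined; ``complexity`` is
    standard/programmatic/conference/early. ``flags`` collects audit markers
    added by cleaning steps ("date_corrected", "unmapped:...", ...); they are
    metadata and take no part in any statistic.
    """

    consultation_id: str
    agency: str
    region: str
    work_type: str
    type: str  # CONSULTATION_TYPES or MISSING
    complexity: str  # COMPLEXITIES or MISSING
    start_date: Optional[date]
    end_date: Optional[date]
    species_rows: tuple[SpeciesDetermination, ...] = ()
    flags: tuple[str, ...] = ()

    def with_flag(self, flag: str) -> "ConsultationRecord":
        if flag in self.flags:
            return self
        return replace(self, flags=self.flags + (flag,))

    @property
    def year(self) -> Optional[int]:
        return self.start_date.year if self.start_date is not None else None


@dataclass(frozen=True)
class DeterminationPair:
    """An (agency-proposed, expert-final) category pair with context."""

    consultation_id: str
    agency: str
    work_type: str
    species: str
    dps_esu: Optional[str]
    agency_proposed: str
    expert_final: str
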