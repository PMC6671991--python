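"""Synthetic consultation-record generator.

Emulates the statistical regime of an expert wildlife agency's consultation
tracking database so that every downstream stage (cleaning, concordance,
outcome trends, enrichment, co-jeopardization) is testable without access to
the real administrative extract.  The generator reproduces, at configurable
strength:

* a species pool in which several species carry multiple DPS/ESU listed
  units, so unit-vs-species aggregation matters;
* heavily skewed agency and work-type frequencies (one dominant permitting
  agency, one dominant work type);
* a latent-variable determination process: the expert final category is
  drawn first, then the agency proposal is drawn conditionally through an
  ordinal shift kernel with per-agency bias (sign of typical deviation) and
  a global noise rate (probability of any deviation);
* rare jeopardy outcomes (on the order of 1.5% of formal consultations),
  optionally enriched in planted species x work-type cells;
* correlated multi-species jeopardy within single consultations through
  shared "shock" groups.

Determinism: one RNG stream per record, keyed by (seed, record index), so
output is byte-identical for a given config regardless of evaluation order.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .concordance import ConcordanceTable
from .records import (
    AGENCY_CATEGORIES,
    EXPERT_CATEGORIES,
    MISSING,
    ConsultationRecord,
    SpeciesDetermination,
)

__all__ = [
    "ConfigError",
    "SyntheticConfig",
    "cojeopardy_power_config",
    "default_config",
    "enrichment_power_config",
    "generate_consultations",
    "records_to_frame",
    "table1_fixture",
    "table1_pairs",
    "write_fixture",
]


class ConfigError(ValueError):
    """A generator configuration field violates its contract."""


# Default pools.  Weights are relative frequencies; agency bias is the
# signed tendency of that agency's proposals to sit below (negative) or
# above (positive) the expert category when they deviate at all.
DEFAULT_SPECIES_POOL: list[tuple[str, list[str]]] = [
    ("Chinook salmon", ["Puget Sound ESU", "Snake River ESU", "Central Valley ESU", "Lower Columbia ESU"]),
    ("Steelhead", ["Puget Sound DPS", "Snake River DPS", "Central California DPS", "Middle Columbia DPS", "Southern California DPS"]),
    ("Coho salmon", ["Oregon Coast ESU", "Central California ESU", "Lower Columbia ESU"]),
    ("Sockeye salmon", ["Snake River ESU", "Ozette Lake ESU"]),
    ("Chum salmon", ["Hood Canal ESU", "Columbia River ESU"]),
    ("Green sea turtle", []),
    ("Loggerhead sea turtle", []),
    ("Leatherback sea turtle", []),
    ("Killer whale", ["Southern Resident DPS"]),
    ("North Atlantic right whale", []),
    ("Green sturgeon", ["Southern DPS"]),
    ("Eulachon", ["Southern DPS"]),
]

DEFAULT_AGENCY_POOL: list[tuple[str, float, float]] = [
    ("Army Corps of Engineers", 6.0, 0.25),
    ("Forest Service", 1.0, 0.05),
    ("National Marine Fisheries Service", 0.8, 0.0),
    ("Federal Emergency Management Agency", 0.6, 0.2),
    ("Bureau of Land Management", 0.4, 0.0),
    ("Environmental Protection Agency", 0.3, -0.7),
    ("Federal Energy Regulatory Commission", 0.3, 0.35),
    ("Coast Guard", 0.25, -0.1),
    ("National Park Service", 0.2, -0.4),
    ("Navy", 0.2, 0.1),
]

DEFAULT_WORKTYPE_POOL: list[tuple[str, float]] = [
    ("waterway", 6.0),
    ("fishery", 1.5),
    ("transportation", 1.2),
    ("agriculture", 1.0),
    ("development", 1.0),
    ("forestry", 0.9),
    ("utility", 0.8),
    ("ocean", 0.7),
    ("research", 0.5),
    ("military", 0.4),
]

DEFAULT_REGION_POOL: list[tuple[str, float]] = [
    ("West Coast", 3.0),
    ("Northwest", 1.5),
    ("Southwest", 1.0),
    ("Southeast", 0.9),
    ("Alaska", 0.8),
    ("Northeast", 0.7),
    ("Pacific Island", 0.4),
]

# Unconditional expert-category distribution over determinations
# (no effect, NLAA, no jeopardy, jeopardy).  The jeopardy-range mass is
# realised only inside formal consultations; dividing it by p_formal keeps
# the unconditional rates at these values.  The jeopardy mass of 0.0012,
# together with the default planted enrichment and co-jeopardy shocks of
# the study regime, puts roughly 1.5% of formal consultations at one or
# more jeopardy determinations.
DEFAULT_DETERMINATION_PROBS = (0.134, 0.685, 0.1798, 0.0012)


@dataclass(frozen=True)
class SyntheticConfig:
    """All generative parameters of the synthetic consultation process."""

    n_consultations: int = 2000
    year_range: tuple[int, int] = (2000, 2016)
    species_pool: list[tuple[str, list[str]]] = field(
        default_factory=lambda: [(s, list(d)) for s, d in DEFAULT_SPECIES_POOL]
    )
    agency_pool: list[tuple[str, float, float]] = field(
        default_factory=lambda: list(DEFAULT_AGENCY_POOL)
    )
    worktype_pool: list[tuple[str, float]] = field(
        default_factory=lambda: list(DEFAULT_WORKTYPE_POOL)
    )
    region_pool: list[tuple[str, float]] = field(
        default_factory=lambda: list(DEFAULT_REGION_POOL)
    )
    p_formal: float = 0.199
    base_determination_probs: tuple[float, float, float, float] = DEFAULT_DETERMINATION_PROBS
    noise: float = 0.20
    jeopardy_enrichment: list[tuple[str, str, float]] = field(default_factory=list)
    cojeopardy_groups: list[frozenset[str]] = field(default_factory=list)
    cojeopardy_shock_prob: float = 0.005
    cojeopardy_boost: float = 30.0
    p_proposed_jeopardy: float = 3e-4
    mean_species_per_consultation: float = 2.0
    max_species_per_consultation: int = 25
    p_extra_dps: float = 0.25
    seed: int = 0

    def validate(self) -> None:
        if self.n_consultations < 0:
            raise ConfigError("n_consultations must be non-negative")
        lo, hi = self.year_range
        if lo > hi:
            raise ConfigError("year_range must be an inclusive (low, high) pair")
        for name, pool in (
            ("species_pool", self.species_pool),
            ("agency_pool", self.agency_pool),
            ("worktype_pool", self.worktype_pool),
            ("region_pool", self.region_pool),
        ):
            if not pool:
                raise ConfigError(f"{name} must not be empty")
        for agency, weight, bias in self.agency_pool:
            if weight < 0:
                raise ConfigError(f"agency_pool weight for {agency!r} must be non-negative")
            if not -1.0 <= bias <= 1.0:
                raise ConfigError(f"agency_pool bias for {agency!r} must lie in [-1, 1]")
        if not any(w > 0 for _, w, _ in self.agency_pool):
            raise ConfigError("agency_pool must contain a positive weight")
        for wt, weight in self.worktype_pool:
            if weight < 0:
                raise ConfigError(f"worktype_pool weight for {wt!r} must be non-negative")
        probs = np.asarray(self.base_determination_probs, dtype=float)
        if probs.shape != (4,) or (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-9:
            raise ConfigError(
                "base_determination_probs must be 4 non-negative values summing to 1"
            )
        for name, p in (
            ("p_formal", self.p_formal),
            ("noise", self.noise),
            ("p_proposed_jeopardy", self.p_proposed_jeopardy),
            ("cojeopardy_shock_prob", self.cojeopardy_shock_prob),
            ("p_extra_dps", self.p_extra_dps),
        ):
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]")
        for sp, wt, mult in self.jeopardy_enrichment:
            if mult < 0:
                raise ConfigError(f"jeopardy_enrichment multiplier for ({sp!r}, {wt!r}) must be >= 0")
        if self.cojeopardy_boost < 0:
            raise ConfigError("cojeopardy_boost must be non-negative")
        if self.mean_species_per_consultation < 1:
            raise ConfigError("mean_species_per_consultation must be >= 1")
        if self.max_species_per_consultation < 1:
            raise ConfigError("max_species_per_consultation must be >= 1")
        if self.p_formal > 0 and sum(probs[2:]) > self.p_formal + 1e-12:
            raise ConfigError(
                "jeopardy-range mass of base_determination_probs exceeds p_formal; "
                "the unconditional rates cannot be realised"
            )
        if self.p_formal == 0 and sum(probs[2:]) > 0:
            raise ConfigError("p_formal = 0 but base_determination_probs has jeopardy-range mass")


def default_config(**overrides) -> SyntheticConfig:
    """Study-regime configuration: skewed pools, planted enrichment in the
    agriculture work type for Pacific salmonids, and one salmonid + killer
    whale co-jeopardization group."""
    cfg = SyntheticConfig(
        jeopardy_enrichment=[
            ("Chinook salmon", "agriculture", 8.0),
            ("Coho salmon", "agriculture", 8.0),
            ("Steelhead", "agriculture", 8.0),
        ],
        cojeopardy_groups=[
            frozenset(
                {"Chinook salmon", "Steelhead", "Coho salmon", "Sockeye salmon",
                 "Chum salmon", "Killer whale"}
            )
        ],
    )
    return dataclasses.replace(cfg, **overrides)


def enrichment_power_config(
    n_consultations: int = 2000,
    multiplier: float = 10.0,
    seed: int = 0,
) -> SyntheticConfig:
    """Planted-enrichment experiment: one species x work-type cell at
    ``multiplier`` times the background jeopardy rate.

    A focused design for detection-power studies: a six-species pool, five
    work types with mild skew, and a determination-level jeopardy mass of
    0.015, large enough that the jeopardy matrix at n = 2000 carries a
    substantial background (roughly 100+ determinations spread over the
    grid) so the planted (Chinook salmon, agriculture) cell inflates its
    own count without dominating its row and column margins — the
    fixed-margin null absorbs a planted signal that IS its margins.  ``multiplier = 1`` gives the
    matched null (no planted cell) for false-positive calibration.
    """
    enrich = [] if multiplier == 1.0 else [("Chinook salmon", "agriculture", multiplier)]
    return SyntheticConfig(
        n_consultations=n_consultations,
        species_pool=[
            ("Chinook salmon", ["Puget Sound ESU", "Snake River ESU"]),
            ("Steelhead", ["Puget Sound DPS", "Snake River DPS"]),
            ("Coho salmon", ["Oregon Coast ESU"]),
            ("Green sea turtle", []),
            ("Killer whale", ["Southern Resident DPS"]),
            ("Leatherback sea turtle", []),
        ],
        worktype_pool=[
            ("waterway", 3.0),
            ("agriculture", 2.0),
            ("fishery", 2.0),
            ("utility", 1.5),
            ("transportation", 1.5),
        ],
        base_determination_probs=(0.134, 0.685, 0.166, 0.015),
        jeopardy_enrichment=enrich,
        cojeopardy_groups=[],
        mean_species_per_consultation=3.0,
        seed=seed,
    )


def cojeopardy_power_config(
    n_consultations: int = 2000,
    boost: float = 60.0,
    seed: int = 0,
) -> SyntheticConfig:
    """Planted co-jeopardization experiment: one shocked species pair.

    Chinook salmon and steelhead share per-consultation shocks (5% of
    consultations) that put both species into the consultation and multiply
    their jeopardy probability by ``boost``; the remaining species provide
    an uncorrelated jeopardy background (determination-level mass 0.01)
    that spreads the consultation universe so the pair's joint clustering
    is visible against the fixed-margins null.  ``boost = 1`` with shock
    probability 0 would reduce to the independent background.
    """
    return SyntheticConfig(
        n_consultations=n_consultations,
        base_determination_probs=(0.134, 0.685, 0.171, 0.010),
        jeopardy_enrichment=[],
        cojeopardy_groups=[frozenset({"Chinook salmon", "Steelhead"})],
        cojeopardy_shock_prob=0.05,
        cojeopardy_boost=boost,
        seed=seed,
    )


_SEVERITY_TO_AGENCY = ("no effect", "NLAA", "LAA")
# Agreement severity of each expert category: both jeopardy-range expert
# outcomes agree with an LAA proposal.
_AGREEMENT_SEVERITY = {"no effect": 0, "NLAA": 1, "no jeopardy": 2, "jeopardy": 2}


def _truncated_geometric(rng: np.random.Generator, mean: float, cap: int) -> int:
    k = int(rng.geometric(1.0 / mean)) if mean > 1 else 1
    return min(k, cap)


def _weighted_choice(rng: np.random.Generator, items: Sequence, weights: np.ndarray):
    idx = rng.choice(len(items), p=weights)
    return items[idx]


def _expert_probs(
    base: np.ndarray,
    formal: bool,
    p_formal: float,
    jeopardy_multiplier: float,
) -> np.ndarray:
    ne, nlaa, nj, j = base
    if not formal:
        # jeopardy-range outcomes require formal review; mass folds into NLAA
        v = np.array([ne, nlaa + nj + j, 0.0, 0.0])
        return v / v.sum()
    nj_f = nj / p_formal
    j_f = (j / p_formal) * jeopardy_multiplier
    informal_mass = max(1.0 - nj / p_formal - j / p_formal, 0.0)
    scale = informal_mass / (ne + nlaa) if ne + nlaa > 0 else 0.0
    v = np.array([ne * scale, nlaa * scale, nj_f, j_f])
    return v / v.sum()


def _propose(
    rng: np.random.Generator,
    expert: str,
    bias: float,
    noise: float,
    p_proposed_jeopardy: float,
) -> str:
    if rng.random() < p_proposed_jeopardy:
        return "proposed no jeopardy" if rng.random() < 0.75 else "proposed jeopardy"
    s = _AGREEMENT_SEVERITY[expert]
    if rng.random() < noise:
        sign = -1 if rng.random() < (1.0 - bias) / 2.0 else +1
        mag = 1 if rng.random() < 0.8 else 2
        s = int(np.clip(s + sign * mag, 0, 2))
    return _SEVERITY_TO_AGENCY[s]


def _critical_habitat(rng: np.random.Generator, expert: str) -> str:
    if rng.random() < 0.5:
        return "no critical habitat"
    if expert == "jeopardy":
        return "adverse modification" if rng.random() < 0.65 else "no adverse modification"
    if expert == "no jeopardy":
        return "adverse modification" if rng.random() < 0.002 else "no adverse modification"
    return expert  # no effect / NLAA mirror the species determination


def _generate_one(i: int, cfg: SyntheticConfig, pools: dict) -> ConsultationRecord:
    rng = np.random.default_rng((cfg.seed, i))
    cid = f"C{i + 1:06d}"

    agency, _, bias = _weighted_choice(rng, cfg.agency_pool, pools["agency_w"])
    work_type = _weighted_choice(rng, cfg.worktype_pool, pools["worktype_w"])[0]
    region = _weighted_choice(rng, cfg.region_pool, pools["region_w"])[0]

    lo, hi = cfg.year_range
    year = int(rng.integers(lo, hi + 1))
    start = date(year, 1, 1) + timedelta(days=int(rng.integers(0, 365)))
    end = start + timedelta(days=int(rng.integers(30, 301)))

    formal = bool(rng.random() < cfg.p_formal)

    n_species = _truncated_geometric(
        rng, cfg.mean_species_per_consultation,
        min(cfg.max_species_per_consultation, len(cfg.species_pool)),
    )
    chosen = rng.choice(len(cfg.species_pool), size=n_species, replace=False)

    # A firing shock pulls its whole group into the consultation (shared
    # exposure implies co-presence) and boosts their jeopardy probability.
    shocked: set[str] = set()
    for group in cfg.cojeopardy_groups:
        if rng.random() < cfg.cojeopardy_shock_prob:
            shocked |= set(group)
    name_to_idx = {name: k for k, (name, _) in enumerate(cfg.species_pool)}
    chosen = set(int(k) for k in chosen)
    chosen |= {name_to_idx[s] for s in shocked if s in name_to_idx}

    base = np.asarray(cfg.base_determination_probs, dtype=float)
    rows: list[SpeciesDetermination] = []
    for sp_idx in sorted(chosen):
        species, dps_labels = cfg.species_pool[sp_idx]
        mult = pools["enrichment"].get((species, work_type), 1.0)
        if species in shocked:
            mult *= cfg.cojeopardy_boost
        probs = _expert_probs(base, formal, cfg.p_formal, mult)
        expert = EXPERT_CATEGORIES[int(rng.choice(4, p=probs))]
        proposal = _propose(rng, expert, bias, cfg.noise, cfg.p_proposed_jeopardy)
        ch = _critical_habitat(rng, expert)

        units: list[Optional[str]]
        if dps_labels:
            k = 1
            if len(dps_labels) > 1 and rng.random() < cfg.p_extra_dps:
                k = 2
            picked = rng.choice(len(dps_labels), size=k, replace=False)
            units = [dps_labels[int(u)] for u in sorted(int(u) for u in picked)]
        else:
            units = [None]
        for unit in units:
            rows.append(
                SpeciesDetermination(
                    species=species,
                    dps_esu=unit,
                    agency_proposed=proposal,
                    expert_final=expert,
                    critical_habitat=ch,
                )
            )

    return ConsultationRecord(
        consultation_id=cid,
        agency=agency,
        region=region,
        work_type=work_type,
        type="formal" if formal else "informal",
        complexity="programmatic" if rng.random() < 0.05 else "standard",
        start_date=start,
        end_date=end,
        species_rows=tuple(rows),
    )


def generate_consultations(config: SyntheticConfig) -> list[ConsultationRecord]:
    """Generate ``config.n_consultations`` consultation records.

    Deterministic in the config (including the seed); each record draws from
    its own RNG stream keyed by (seed, index).  With ``noise = 0``, all
    agency biases 0 and ``p_proposed_jeopardy = 0`` every proposal agrees
    with the expert category (discrepancy score 0 throughout).
    """
    config.validate()
    pools = {
        "agency_w": _normalise([w for _, w, _ in config.agency_pool], "agency_pool"),
        "worktype_w": _normalise([w for _, w in config.worktype_pool], "worktype_pool"),
        "region_w": _normalise([w for _, w in config.region_pool], "region_pool"),
        "enrichment": {(sp, wt): m for sp, wt, m in config.jeopardy_enrichment},
    }
    return [_generate_one(i, config, pools) for i in range(config.n_consultations)]


def _normalise(weights: Sequence[float], name: str) -> np.ndarray:
    w = np.asarray(weights, dtype=float)
    total = w.sum()
    if total <= 0:
        raise ConfigError(f"{name} weights must sum to a positive value")
    return w / total


# ---------------------------------------------------------------------------
# Fixture I/O

FIXTURE_COLUMNS = [
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


def _raw_type_string(rec: ConsultationRecord) -> str:
    if rec.type == MISSING or rec.complexity == MISSING:
        return ""
    return f"{rec.type.capitalize()} {rec.complexity.capitalize()}"


def records_to_frame(records: Iterable[ConsultationRecord]) -> pd.DataFrame:
    """One row per (consultation, species determination) pair."""
    rows = []
    for rec in records:
        for det in rec.species_rows:
            rows.append(
                {
                    "consultation_id": rec.consultation_id,
                    "agency": rec.agency,
                    "region": rec.region,
                    "work_type": rec.work_type,
                    "consultation_type": _raw_type_string(rec),
                    "start_date": rec.start_date.isoformat() if rec.start_date else "",
                    "end_date": rec.end_date.isoformat() if rec.end_date else "",
                    "species": det.species,
                    "dps_esu": det.dps_esu or "",
                    "agency_determination": det.agency_proposed,
                    "expert_determination": det.expert_final,
                    "critical_habitat_determination": det.critical_habitat,
                }
            )
    return pd.DataFrame(rows, columns=FIXTURE_COLUMNS)


def write_fixture(
    records: Sequence[ConsultationRecord],
    destination: str | Path,
    allow_empty: bool = False,
) -> Path:
    """Write records as the UTF-8 CSV fixture dialect (ISO-8601 dates).

    The output round-trips losslessly through ``pcts_io.parse_records``.
    """
    records = list(records)
    if not records and not allow_empty:
        raise ValueError("refusing to write an empty fixture without allow_empty=True")
    dest = Path(destination)
    records_to_frame(records).to_csv(dest, index=False)
    return dest


# ---------------------------------------------------------------------------
# Published cross-tabulation fixture

# 4x5 frequencies of agency-proposed (columns) vs expert final (rows)
# determinations across the full 2000-2017 administrative extract, used as
# a deterministic worked example and regression fixture.
_TABLE1_COUNTS = np.array(
    [
        [3671, 7215, 1377, 6, 3],
        [853, 59258, 2509, 5, 0],
        [163, 2246, 13454, 17, 0],
        [55, 164, 439, 0, 0],
    ],
    dtype=np.int64,
)


def table1_fixture() -> ConcordanceTable:
    """The published 4x5 concordance table (grand total 91,435 pairs)."""
    return ConcordanceTable(counts=_TABLE1_COUNTS.copy())


def table1_pairs() -> list[tuple[str, str]]:
    """The fixture expanded to (agency, expert) category pairs."""
    pairs = []
    for i, expert in enumerate(EXPERT_CATEGORIES):
        for j, agency in enumerate(AGENCY_CATEGORIES):
            pairs.extend([(agency, expert)] * int(_TABLE1_COUNTS[i, j]))
    return pairs
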