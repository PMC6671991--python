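"""Frequency, rate and trend analyses of consultation outcomes.

Covers the descriptive layer of the pipeline: how consultations distribute
over species, agencies, work types and regions; how yearly counts of formal
and informal consultations move over time (generalized linear models with a
Poisson/log or Gaussian/identity family); how rare jeopardy and
adverse-modification findings are relative to formal and to all
consultations; and whether the jeopardy rate itself trends over years.

Species-level frequencies count each consultation once per species no
matter how many of its DPS/ESU listed units appear in it; determination-level
tallies (used elsewhere) keep the unit rows distinct.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .records import ConsultationRecord

__all__ = [
    "FrequencyTable",
    "GofResult",
    "OutcomeSummary",
    "TrendFit",
    "chisq_gof",
    "consultation_outcome_summary",
    "fit_jeopardy_trend",
    "fit_yearly_counts",
    "frequency_table",
    "jeopardy_rate",
    "round_half_up",
]


@dataclass(frozen=True)
class FrequencyTable:
    """Counts per level of one grouping dimension, sorted descending."""

    key: str
    counts: pd.Series

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def top(self, k: int = 10) -> pd.Series:
        return self.counts.head(k)


_KEYS = ("species", "agency", "work_type", "region")


def frequency_table(records: Iterable[ConsultationRecord], key: str) -> FrequencyTable:
    """Consultation frequencies by species, agency, work type or region.

    For ``key="species"`` a consultation contributes one count to every
    distinct species it involves (DPS/ESU units of one species collapse to
    a single count); for the other keys each consultation counts once.
    """
    if key not in _KEYS:
        raise ValueError(f"unknown grouping key {key!r}; expected one of {_KEYS}")
    values: list[str] = []
    for rec in records:
        if key == "species":
            values.extend(sorted({det.species for det in rec.species_rows}))
        else:
            values.append(getattr(rec, key))
    counts = pd.Series(values, dtype=object).value_counts().sort_values(ascending=False)
    counts.index.name = key
    return FrequencyTable(key=key, counts=counts.astype(np.int64))


@dataclass(frozen=True)
class GofResult:
    """Chi-square goodness-of-fit against uniform (or supplied) expectation."""

    chi2: float
    df: int
    p: float


def chisq_gof(
    counts: Sequence[int] | pd.Series,
    expected: Optional[Sequence[float]] = None,
) -> GofResult:
    """X^2 = sum (O-E)^2 / E with df = k - 1 and an upper-tail p-value.

    ``expected`` defaults to uniform over the observed levels; any zero
    expectation is an error.
    """
    obs = np.asarray(pd.Series(counts), dtype=float)
    if obs.size < 2:
        raise ValueError("need at least two levels for a goodness-of-fit test")
    total = obs.sum()
    if total <= 0:
        raise ValueError("total count must be positive")
    if expected is None:
        exp = np.full_like(obs, total / obs.size)
    else:
        exp = np.asarray(expected, dtype=float)
        if exp.shape != obs.shape:
            raise ValueError("expected vector length mismatch")
        exp = exp * (total / exp.sum())
    if np.any(exp <= 0):
        raise ValueError("expected counts must all be positive")
    chi2, p = stats.chisquare(obs, exp)
    return GofResult(chi2=float(chi2), df=obs.size - 1, p=float(p))


@dataclass(frozen=True)
class TrendFit:
    """Yearly-trend GLM fit: slope per year with its SE, test statistic, p."""

    slope_per_year: float
    se: float
    statistic: float
    p: float
    family: str
    n_years: int
    converged: bool = True


_FAMILIES = {
    "poisson-log": lambda: sm.families.Poisson(sm.families.links.Log()),
    "gaussian-identity": lambda: sm.families.Gaussian(sm.families.links.Identity()),
}


def _fit_glm(years: np.ndarray, y: np.ndarray, family: str) -> TrendFit:
    if family not in _FAMILIES:
        raise ValueError(f"unknown family {family!r}; expected one of {tuple(_FAMILIES)}")
    if np.unique(years).size < 3:
        raise ValueError("need at least 3 distinct years to fit a trend")
    # centring the year covariate keeps the slope identical while avoiding
    # exp(intercept + slope*2000) overflow in the Poisson/log fit
    exog = sm.add_constant(years.astype(float) - years.mean())
    y = y.astype(float)
    if np.ptp(y) == 0:
        # perfectly constant response: slope exactly 0; the Gaussian scale
        # estimate degenerates (zero residual variance), so short-circuit
        return TrendFit(slope_per_year=0.0, se=0.0, statistic=0.0, p=1.0,
                        family=family, n_years=int(np.unique(years).size))
    model = sm.GLM(y, exog, family=_FAMILIES[family]())
    try:
        res = model.fit()
    except ValueError:
        return TrendFit(slope_per_year=float("nan"), se=float("nan"),
                        statistic=float("nan"), p=float("nan"), family=family,
                        n_years=int(np.unique(years).size), converged=False)
    return TrendFit(
        slope_per_year=float(res.params[1]),
        se=float(res.bse[1]),
        statistic=float(res.tvalues[1]),
        p=float(res.pvalues[1]),
        family=family,
        n_years=int(np.unique(years).size),
        converged=bool(getattr(res, "converged", True)),
    )


def fit_yearly_counts(
    series: Mapping[int, int] | pd.Series, family: str = "poisson-log"
) -> TrendFit:
    """Fit count ~ year by maximum likelihood for the chosen GLM family."""
    s = pd.Series(dict(series)).sort_index()
    return _fit_glm(s.index.to_numpy(), s.to_numpy(), family)


def fit_jeopardy_trend(
    series: Mapping[int, tuple[int, int]],
) -> TrendFit:
    """Trend in the yearly share of formal consultations ending in jeopardy.

    ``series`` maps year -> (jeopardy consultations, formal consultations);
    the proportion is modelled as proportion ~ year with a Gaussian family
    and identity link.
    """
    years, props = [], []
    for year, (jeop, formal) in sorted(series.items()):
        if formal < 0 or jeop < 0 or jeop > formal:
            raise ValueError(f"inconsistent counts for year {year}: ({jeop}, {formal})")
        if formal == 0:
            continue
        years.append(year)
        props.append(jeop / formal)
    return _fit_glm(np.asarray(years), np.asarray(props), "gaussian-identity")


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal rounding with ties away from zero (printed-table convention)."""
    factor = 10**ndigits
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


@dataclass(frozen=True)
class JeopardyRate:
    raw: float  # percentage
    rounded: float  # half-up to one decimal


def jeopardy_rate(jeopardy: int, all_determinations: int) -> JeopardyRate:
    """Jeopardy determinations as a percentage of all determinations."""
    if all_determinations <= 0:
        raise ValueError("all_determinations must be positive")
    if not 0 <= jeopardy <= all_determinations:
        raise ValueError("jeopardy count must lie in [0, all_determinations]")
    pct = 100.0 * jeopardy / all_determinations
    return JeopardyRate(raw=pct, rounded=round_half_up(pct, 1))


@dataclass(frozen=True)
class OutcomeSummary:
    """Counts and percentages of consultation outcomes.

    Jeopardy / adverse-modification percentages are reported against both
    the formal-consultation and the all-consultation denominators; they are
    NaN (and ``jeopardy_defined`` False) when no formal consultations exist.
    """

    n_total: int
    n_formal: int
    n_informal: int
    n_combined: int
    n_jeopardy_consultations: int
    n_adverse_mod_consultations: int
    n_jeopardy_without_am: int
    n_am_without_jeopardy: int
    n_jeopardy_determinations: int
    n_adverse_mod_determinations: int
    formal_pct: float
    jeopardy_pct_of_formal: float
    jeopardy_pct_of_all: float
    adverse_mod_pct_of_formal: float
    adverse_mod_pct_of_all: float
    jeopardy_defined: bool

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def consultation_outcome_summary(records: Iterable[ConsultationRecord]) -> OutcomeSummary:
    """Summarise formality and jeopardy/adverse-modification outcomes."""
    records = list(records)
    n_total = len(records)
    n_formal = sum(r.type == "formal" for r in records)
    n_informal = sum(r.type == "informal" for r in records)
    n_combined = sum(r.type == "combined" for r in records)
    jeop_ids, am_ids = set(), set()
    n_jeop_det = n_am_det = 0
    for rec in records:
        for det in rec.species_rows:
            if det.expert_final == "jeopardy":
                jeop_ids.add(rec.consultation_id)
                n_jeop_det += 1
            if det.critical_habitat == "adverse modification":
                am_ids.add(rec.consultation_id)
                n_am_det += 1
    n_jeop = len(jeop_ids)
    n_am = len(am_ids)
    defined = n_formal > 0
    pct = lambda num, den: 100.0 * num / den if den else float("nan")
    return OutcomeSummary(
        n_total=n_total,
        n_formal=n_formal,
        n_informal=n_informal,
        n_combined=n_combined,
        n_jeopardy_consultations=n_jeop,
        n_adverse_mod_consultations=n_am,
        n_jeopardy_without_am=len(jeop_ids - am_ids),
        n_am_without_jeopardy=len(am_ids - jeop_ids),
        n_jeopardy_determinations=n_jeop_det,
        n_adverse_mod_determinations=n_am_det,
        formal_pct=pct(n_formal, n_total),
        jeopardy_pct_of_formal=pct(n_jeop, n_formal),
        jeopardy_pct_of_all=pct(n_jeop, n_total),
        adverse_mod_pct_of_formal=pct(n_am, n_formal),
        adverse_mod_pct_of_all=pct(n_am, n_total),
        jeopardy_defined=defined,
    )
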