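"""Pairwise co-jeopardization analysis.

Two species are *co-jeopardized* when the same consultation carries a
jeopardy determination for both.  On a binary species x consultation
matrix (1 = jeopardized in that consultation), each unordered species pair
is tested against the fixed-margins null: holding each species' number of
jeopardy consultations (N1, N2) fixed among the N consultations, the
co-occurrence count j is hypergeometric,

    P(j) = C(N1, j) C(N - N1, N2 - j) / C(N, N2),

so expected co-jeopardization is N1*N2/N, the effect is observed - expected,
and the tail probabilities are exact (p_gt = P(j >= observed),
p_lt = P(j <= observed)).  The analytic null is the probabilistic
co-occurrence model; a Monte-Carlo shuffle of one species' consultations
converges to the same tail probabilities and serves as a cross-check in the
test-suite, not as the implementation.

Because no single convention defines "probability of being jeopardized by
the same action", each pair reports observed/N alongside observed/N1,
observed/N2 and observed/|union| so any convention can be read off.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .records import ConsultationRecord

__all__ = [
    "BinaryMatrix",
    "PairResult",
    "all_pairs",
    "build_binary_matrix",
    "cooccur_test",
]


@dataclass(frozen=True)
class BinaryMatrix:
    """Binary species (rows) x consultation (columns) jeopardy matrix."""

    values: np.ndarray  # dtype bool
    species: tuple[str, ...]
    consultations: tuple[str, ...]

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=bool)
        if vals.shape != (len(self.species), len(self.consultations)):
            raise ValueError("label lengths do not match matrix shape")
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "species", tuple(self.species))
        object.__setattr__(self, "consultations", tuple(self.consultations))

    @property
    def is_empty(self) -> bool:
        return self.values.size == 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values.astype(int), index=list(self.species), columns=list(self.consultations)
        )


def build_binary_matrix(
    records: Iterable[ConsultationRecord], universe: str = "jeopardy"
) -> BinaryMatrix:
    """Binary jeopardy matrix over species with >= 1 jeopardy determination.

    ``universe`` selects the column set: "jeopardy" (default) keeps only
    consultations with at least one jeopardy determination; "formal" widens
    to every formal consultation.  DPS/ESU rows collapse to the species
    level: several jeopardized units of one species in one consultation
    yield a single 1.
    """
    if universe not in ("jeopardy", "formal"):
        raise ValueError(f"unknown universe {universe!r}; expected 'jeopardy' or 'formal'")
    jeop: dict[str, set[str]] = {}
    formal_ids: list[str] = []
    jeop_ids: list[str] = []
    for rec in records:
        if rec.type == "formal":
            formal_ids.append(rec.consultation_id)
        hit = False
        for det in rec.species_rows:
            if det.expert_final == "jeopardy":
                jeop.setdefault(det.species, set()).add(rec.consultation_id)
                hit = True
        if hit:
            jeop_ids.append(rec.consultation_id)
    if not jeop:
        return BinaryMatrix(values=np.zeros((0, 0), dtype=bool), species=(), consultations=())
    cols = tuple(jeop_ids if universe == "jeopardy" else formal_ids)
    col_index = {c: k for k, c in enumerate(cols)}
    species = tuple(sorted(jeop))
    values = np.zeros((len(species), len(cols)), dtype=bool)
    for i, sp in enumerate(species):
        for cid in jeop[sp]:
            if cid in col_index:
                values[i, col_index[cid]] = True
    return BinaryMatrix(values=values, species=species, consultations=cols)


@dataclass(frozen=True)
class PairResult:
    """Exact fixed-margins co-occurrence test for one species pair."""

    species_a: str
    species_b: str
    N: int
    N1: int
    N2: int
    observed: int
    expected: float
    effect: float
    p_gt: float
    p_lt: float
    prob_obs: float  # observed / N
    prob_obs_n1: float
    prob_obs_n2: float
    prob_obs_union: float
    low_support: bool = False


def cooccur_test(
    N: int, N1: int, N2: int, observed: int, species_a: str = "A", species_b: str = "B"
) -> PairResult:
    """Exact hypergeometric co-occurrence test for one pair.

    Under the null that species 2's N2 jeopardy consultations are a uniform
    draw from the N consultations, the overlap with species 1's N1 is
    hypergeometric; both tail probabilities are exact.
    """
    if not (0 <= N1 <= N and 0 <= N2 <= N):
        raise ValueError("N1 and N2 must lie in [0, N]")
    lo = max(0, N1 + N2 - N)
    hi = min(N1, N2)
    if not lo <= observed <= hi:
        raise ValueError(f"observed={observed} outside feasible range [{lo}, {hi}]")
    dist = stats.hypergeom(M=N, n=N1, N=N2)
    p_gt = float(dist.sf(observed - 1))  # P(j >= observed)
    p_lt = float(dist.cdf(observed))  # P(j <= observed)
    expected = N1 * N2 / N if N else 0.0
    union = N1 + N2 - observed
    return PairResult(
        species_a=species_a,
        species_b=species_b,
        N=N,
        N1=N1,
        N2=N2,
        observed=observed,
        expected=float(expected),
        effect=float(observed - expected),
        p_gt=min(p_gt, 1.0),
        p_lt=min(p_lt, 1.0),
        prob_obs=observed / N if N else 0.0,
        prob_obs_n1=observed / N1 if N1 else float("nan"),
        prob_obs_n2=observed / N2 if N2 else float("nan"),
        prob_obs_union=observed / union if union else float("nan"),
    )


def all_pairs(matrix: BinaryMatrix, min_support: int = 1) -> pd.DataFrame:
    """Exact co-occurrence test for every unordered species pair.

    One row per pair, symmetric in the pair and invariant to input row
    order.  Pairs where either species falls below ``min_support`` jeopardy
    consultations are reported with ``low_support = True``.  The result's
    ``attrs`` carry the maximum observed pair probability (observed/N) and
    the pair attaining it.
    """
    if len(matrix.species) < 2:
        raise ValueError("need at least two species rows for pairwise analysis")
    N = len(matrix.consultations)
    row_sums = matrix.values.sum(axis=1)
    rows = []
    for i, j in itertools.combinations(range(len(matrix.species)), 2):
        a, b = sorted((matrix.species[i], matrix.species[j]))
        if a != matrix.species[i]:
            i, j = j, i
        observed = int(np.logical_and(matrix.values[i], matrix.values[j]).sum())
        res = cooccur_test(N, int(row_sums[i]), int(row_sums[j]), observed, a, b)
        low = row_sums[i] < min_support or row_sums[j] < min_support
        d = dict(res.__dict__)
        d["low_support"] = bool(low)
        rows.append(d)
    df = pd.DataFrame(rows).sort_values(["species_a", "species_b"]).reset_index(drop=True)
    best = df.loc[df["prob_obs"].idxmax()]
    df.attrs["max_prob_obs"] = float(best["prob_obs"])
    df.attrs["max_prob_pair"] = (best["species_a"], best["species_b"])
    return df
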