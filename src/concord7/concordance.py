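"""Agreement analysis between agency-proposed and expert determinations.

The central object is the 4x5 cross-tabulation of expert final categories
(rows: no effect, NLAA, no jeopardy, jeopardy) against agency-proposed
categories (columns: no effect, NLAA, LAA, proposed no jeopardy, proposed
jeopardy).  Each cell carries an ordinal *discrepancy score* in {-3..+3}:
positive when the agency overestimated the effect relative to the expert,
negative when it underestimated, and 0 on agreement.  Agreement includes the
asymmetric jeopardy-range cells: an LAA proposal agrees with either expert
jeopardy outcome, because LAA is the proposal that correctly routes the
action into formal review.

Overall agreement is summarised by a disagreement-weighted Cohen's kappa

    K_w = 1 - (sum_ij w_ij O_ij / N) / (sum_ij w_ij r_i c_j / N^2)

with weights w_ij = |score_ij| / 4 by default (0 on agreement, 0.25 per
ordinal step, drawn from the set {0, 0.25, 0.5, 0.75, 1}).  Per-agency
departure from the pooled discrepancy distribution is tested with two-sample
two-tailed Kolmogorov-Smirnov tests.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .records import (
    AGENCY_CATEGORIES,
    EXPERT_CATEGORIES,
    ConsultationRecord,
    MISSING,
)

__all__ = [
    "SCORE_MATRIX",
    "ConcordanceTable",
    "KappaResult",
    "KSResult",
    "build_concordance_table",
    "default_weights",
    "determination_pairs",
    "discrepancy_score",
    "ks_agency_test",
    "ks_all_agencies",
    "orientation_report",
    "score_distribution",
    "underestimation_share",
    "weighted_kappa",
]

# Rows: expert categories; columns: agency categories.  Zeros mark the six
# agreement cells, including (expert no jeopardy, LAA), (expert jeopardy,
# LAA), (expert no jeopardy, proposed no jeopardy) and (expert jeopardy,
# proposed jeopardy); (expert jeopardy, proposed no jeopardy) scores -1.
SCORE_MATRIX = np.array(
    [
        [0, +1, +2, +2, +3],
        [-1, 0, +1, +1, +2],
        [-2, -1, 0, 0, +1],
        [-3, -2, 0, -1, 0],
    ],
    dtype=int,
)

SCORE_SUPPORT = tuple(range(-3, 4))

_EXPERT_INDEX = {c: i for i, c in enumerate(EXPERT_CATEGORIES)}
_AGENCY_INDEX = {c: j for j, c in enumerate(AGENCY_CATEGORIES)}


class UndefinedKappaError(ValueError):
    """Raised when the expected weighted disagreement is zero."""


class UndefinedShareError(ValueError):
    """Raised when a disagreement share is requested but no disagreements exist."""


def discrepancy_score(agency_category: str, expert_category: str) -> int:
    """Ordinal discrepancy of an agency proposal relative to the expert final.

    Positive: the agency overestimated the effect. Negative: underestimated.
    Raises ``ValueError`` for missing/unknown categories; callers must filter
    incomplete pairs first.
    """
    try:
        i = _EXPERT_INDEX[expert_category]
        j = _AGENCY_INDEX[agency_category]
    except KeyError as exc:
        raise ValueError(f"cannot score category {exc.args[0]!r}") from None
    return int(SCORE_MATRIX[i, j])


def default_weights() -> np.ndarray:
    """Disagreement weights: 0.25 per ordinal step of |score|, 0 on agreement."""
    return np.abs(SCORE_MATRIX) / 4.0


def validate_weights(weights: np.ndarray) -> np.ndarray:
    """Check a 4x5 weight matrix against the weighting contract.

    Weights must come from {0, 0.25, 0.5, 0.75, 1}, be 0 exactly on
    agreement cells, and assign equal weight to cells of equal |score|.
    """
    w = np.asarray(weights, dtype=float)
    if w.shape != SCORE_MATRIX.shape:
        raise ValueError(f"weight matrix must be {SCORE_MATRIX.shape}, got {w.shape}")
    allowed = {0.0, 0.25, 0.5, 0.75, 1.0}
    if not set(np.unique(w)) <= allowed:
        raise ValueError("weights must be drawn from {0, 0.25, 0.5, 0.75, 1}")
    if np.any(w[SCORE_MATRIX == 0] != 0):
        raise ValueError("agreement cells must have weight 0")
    for mag in (1, 2, 3):
        vals = np.unique(w[np.abs(SCORE_MATRIX) == mag])
        if len(vals) > 1:
            raise ValueError(f"cells with |score| = {mag} carry unequal weights {vals}")
    return w


@dataclass(frozen=True)
class ConcordanceTable:
    """4x5 cross-tabulation of expert (rows) vs agency (columns) categories."""

    counts: np.ndarray
    n_excluded: int = 0

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.shape != (len(EXPERT_CATEGORIES), len(AGENCY_CATEGORIES)):
            raise ValueError(f"counts must be 4x5, got {counts.shape}")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def N(self) -> int:
        return int(self.counts.sum())

    @property
    def row_margins(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_margins(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def cell(self, expert: str, agency: str) -> int:
        return int(self.counts[_EXPERT_INDEX[expert], _AGENCY_INDEX[agency]])

    def to_frame(self, margins: bool = False) -> pd.DataFrame:
        df = pd.DataFrame(
            self.counts,
            index=pd.Index(EXPERT_CATEGORIES, name="expert"),
            columns=pd.Index(AGENCY_CATEGORIES, name="agency"),
        )
        if margins:
            df["total"] = df.sum(axis=1)
            df.loc["total"] = df.sum(axis=0)
        return df

    def score_counts(self) -> pd.Series:
        """Counts of determination pairs at each discrepancy score -3..+3."""
        out = pd.Series(0, index=pd.Index(SCORE_SUPPORT, name="score"), dtype=np.int64)
        for s in SCORE_SUPPORT:
            out.loc[s] = int(self.counts[SCORE_MATRIX == s].sum())
        return out


def determination_pairs(
    records: Iterable[ConsultationRecord], drop_missing: bool = False
) -> pd.DataFrame:
    """Flatten records into one row per (consultation, species row) pair.

    Columns: consultation_id, agency, work_type, species, dps_esu,
    agency_proposed, expert_final, and score (NaN where either category is
    missing).  With ``drop_missing`` the incomplete rows are dropped.
    """
    rows = []
    for rec in records:
        for det in rec.species_rows:
            scoreable = (
                det.agency_proposed in _AGENCY_INDEX and det.expert_final in _EXPERT_INDEX
            )
            rows.append(
                {
                    "consultation_id": rec.consultation_id,
                    "agency": rec.agency,
                    "work_type": rec.work_type,
                    "species": det.species,
                    "dps_esu": det.dps_esu,
                    "agency_proposed": det.agency_proposed,
                    "expert_final": det.expert_final,
                    "score": (
                        discrepancy_score(det.agency_proposed, det.expert_final)
                        if scoreable
                        else np.nan
                    ),
                }
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "consultation_id",
            "agency",
            "work_type",
            "species",
            "dps_esu",
            "agency_proposed",
            "expert_final",
            "score",
        ],
    )
    if drop_missing:
        df = df.dropna(subset=["score"]).reset_index(drop=True)
    return df


def build_concordance_table(pairs: pd.DataFrame | Iterable[tuple[str, str]]) -> ConcordanceTable:
    """Cross-tabulate (agency_proposed, expert_final) category pairs.

    ``pairs`` is either the frame from :func:`determination_pairs` or an
    iterable of ``(agency_proposed, expert_final)`` tuples.  Pairs with a
    missing category are excluded and counted in ``n_excluded``; input order
    never affects the result.
    """
    if isinstance(pairs, pd.DataFrame):
        agency = pairs["agency_proposed"]
        expert = pairs["expert_final"]
    else:
        tup = list(pairs)
        agency = pd.Series([a for a, _ in tup], dtype=object)
        expert = pd.Series([e for _, e in tup], dtype=object)
    counts = np.zeros((len(EXPERT_CATEGORIES), len(AGENCY_CATEGORIES)), dtype=np.int64)
    ok = agency.isin(_AGENCY_INDEX) & expert.isin(_EXPERT_INDEX)
    for (a, e), n in pd.crosstab(agency[ok], expert[ok]).stack().items():
        counts[_EXPERT_INDEX[e], _AGENCY_INDEX[a]] = n
    return ConcordanceTable(counts=counts, n_excluded=int((~ok).sum()))


@dataclass(frozen=True)
class KappaResult:
    """Weighted kappa with its observed/expected weighted disagreement."""

    kappa: float
    observed_disagreement: float
    expected_disagreement: float
    n: int


def weighted_kappa(
    table: ConcordanceTable, weights: Optional[np.ndarray] = None
) -> KappaResult:
    """Disagreement-weighted Cohen's kappa of a concordance table.

    K_w = 1 - observed/expected, where observed = sum(w*O)/N and
    expected = sum(w * outer(row margins, column margins))/N^2.  K_w is 1
    when all mass sits on zero-weight cells and 0 when the table equals the
    independence product of its margins.
    """
    if table.N == 0:
        raise UndefinedKappaError("empty table: kappa undefined")
    w = default_weights() if weights is None else validate_weights(weights)
    n = table.N
    observed = float((w * table.counts).sum() / n)
    expected = float((w * np.outer(table.row_margins, table.col_margins)).sum() / n**2)
    if expected == 0:
        raise UndefinedKappaError("degenerate margins: expected weighted disagreement is 0")
    return KappaResult(
        kappa=1.0 - observed / expected,
        observed_disagreement=observed,
        expected_disagreement=expected,
        n=n,
    )


def score_distribution(pairs: pd.DataFrame, by: str = "agency") -> pd.DataFrame:
    """Per-group empirical distribution of discrepancy scores.

    Returns one row per group with count columns ``n_-3..n_3``, matching
    percentage columns ``pct_-3..pct_3`` (summing to 100), and ``N``.
    Pairs with missing score are ignored.
    """
    df = pairs.dropna(subset=["score"])
    out = {}
    for group, sub in df.groupby(by, sort=True):
        scores = sub["score"].astype(int)
        counts = scores.value_counts().reindex(SCORE_SUPPORT, fill_value=0)
        row = {f"n_{s}": int(counts.loc[s]) for s in SCORE_SUPPORT}
        n = int(counts.sum())
        for s in SCORE_SUPPORT:
            row[f"pct_{s}"] = 100.0 * counts.loc[s] / n if n else np.nan
        row["N"] = n
        out[group] = row
    res = pd.DataFrame.from_dict(out, orient="index")
    res.index.name = by
    return res


def underestimation_share(scores: Sequence[int] | pd.Series) -> float:
    """Fraction of disagreements in which the agency underestimated effects.

    count(score < 0) / count(score != 0); raises ``UndefinedShareError``
    when every score is 0.
    """
    s = np.asarray(pd.Series(scores).dropna(), dtype=float)
    disagreements = s[s != 0]
    if disagreements.size == 0:
        raise UndefinedShareError("no disagreements: underestimation share undefined")
    return float((disagreements < 0).sum() / disagreements.size)


def orientation_report(table: ConcordanceTable) -> dict[str, float]:
    """Agreement and disagreement-direction shares, both sign orientations.

    The zero-score share of the table does not depend on orientation, but
    which disagreements count as underestimation does: the canonical
    orientation scores the agency's departure from the expert final, while
    the transposed orientation flips every sign.  Both are reported because
    published summary percentages for this kind of table are sensitive to
    the (often unstated) choice.
    """
    sc = table.score_counts()
    n = int(sc.sum())
    neg = int(sc.loc[[-3, -2, -1]].sum())
    pos = int(sc.loc[[1, 2, 3]].sum())
    disagree = neg + pos
    return {
        "agreement_pct": 100.0 * sc.loc[0] / n if n else float("nan"),
        "underestimation_pct": 100.0 * neg / disagree if disagree else float("nan"),
        "overestimation_pct": 100.0 * pos / disagree if disagree else float("nan"),
        "underestimation_pct_transposed": 100.0 * pos / disagree if disagree else float("nan"),
        "n_pairs": float(n),
        "n_disagreements": float(disagree),
    }


@dataclass(frozen=True)
class KSResult:
    """Two-sample Kolmogorov-Smirnov comparison of score distributions."""

    D: float
    p: float
    n_agency: int
    n_reference: int


def _ks_statistic(x: np.ndarray, y: np.ndarray) -> float:
    grid = np.union1d(x, y)
    cdf_x = np.searchsorted(np.sort(x), grid, side="right") / x.size
    cdf_y = np.searchsorted(np.sort(y), grid, side="right") / y.size
    return float(np.max(np.abs(cdf_x - cdf_y)))


def _ks_exact_p(x: np.ndarray, y: np.ndarray) -> float:
    """Exact permutation p-value for the two-sample KS statistic.

    Enumerates all labelings of the pooled multiset (uniform under the
    null); valid with ties.  Feasible only for small samples (n, m <= 10).
    """
    n, m = x.size, y.size
    pooled = np.sort(np.concatenate([x, y]))
    d_obs = _ks_statistic(x, y)
    total = 0
    hits = 0
    idx = np.arange(n + m)
    for comb in itertools.combinations(idx, n):
        xs = pooled[list(comb)]
        ys = np.delete(pooled, list(comb))
        total += 1
        if _ks_statistic(xs, ys) >= d_obs - 1e-12:
            hits += 1
    return hits / total


def ks_agency_test(
    agency_scores: Sequence[int] | pd.Series,
    reference_scores: Sequence[int] | pd.Series,
    min_n: int = 20,
    method: str = "asymp",
) -> Optional[KSResult]:
    """Two-tailed two-sample KS test of one agency's scores vs the pool.

    Returns ``None`` (skipped) when the agency has fewer than ``min_n``
    scores.  ``method`` is "asymp" (default) or "exact"; the exact method
    enumerates pooled relabelings and requires both samples to have at most
    10 observations.
    """
    x = np.asarray(pd.Series(agency_scores).dropna(), dtype=float)
    y = np.asarray(pd.Series(reference_scores).dropna(), dtype=float)
    if y.size == 0:
        raise ValueError("reference score set is empty")
    if x.size < min_n:
        return None
    d = _ks_statistic(x, y)
    if method == "exact":
        if x.size > 10 or y.size > 10:
            raise ValueError("exact KS enumeration is limited to samples of size <= 10")
        p = _ks_exact_p(x, y)
    elif method == "asymp":
        p = float(stats.ks_2samp(x, y, alternative="two-sided", method="asymp").pvalue)
        p = min(p, 1.0)
    else:
        raise ValueError(f"unknown method {method!r}")
    return KSResult(D=d, p=p, n_agency=int(x.size), n_reference=int(y.size))


def ks_all_agencies(
    pairs: pd.DataFrame,
    min_n: int = 20,
    include_self: bool = True,
    method: str = "asymp",
) -> pd.DataFrame:
    """KS departure test for every agency against the pooled distribution.

    With ``include_self`` (default) the focal agency's scores remain in the
    pooled reference; otherwise the reference is leave-one-out.  Agencies
    below ``min_n`` get ``skipped = True`` and NaN statistics.
    """
    df = pairs.dropna(subset=["score"])
    all_scores = df["score"].to_numpy(dtype=float)
    rows = []
    for agency, sub in df.groupby("agency", sort=True):
        x = sub["score"].to_numpy(dtype=float)
        ref = all_scores if include_self else df.loc[df["agency"] != agency, "score"].to_numpy(dtype=float)
        res = ks_agency_test(x, ref, min_n=min_n, method=method)
        if res is None:
            rows.append(
                {"agency": agency, "n": int(x.size), "D": np.nan, "p": np.nan,
                 "significant": False, "skipped": True}
            )
        else:
            rows.append(
                {"agency": agency, "n": res.n_agency, "D": res.D, "p": res.p,
                 "significant": bool(res.p < 0.05), "skipped": False}
            )
    return pd.DataFrame(rows).set_index("agency")
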