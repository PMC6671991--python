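"""Fixed-margin permutation test for jeopardy enrichment.

Do particular species x work-type combinations accumulate jeopardy
determinations out of proportion to their margins?  The observed count
matrix (rows: species, columns: work types, cells: jeopardy determinations)
is compared against tables drawn from the fixed-margins conditional
distribution — every simulated table has exactly the observed row sums,
column sums and grand total (Patefield-style sampling).  For each cell the
test reports:

* ``effect`` = observed - mean(simulated), the excess over the null mean;
* ``sd`` = standard deviation of simulated cell counts;
* ``p_gt`` = proportion of simulated counts strictly greater than the
  observed (the literal permutation rule; a +1-smoothed variant that never
  returns exactly 0 is available), and ``p_lt`` mirrored for deficits.

No multiple-testing correction is applied by default; Benjamini-Hochberg
adjusted columns are emitted alongside as a clearly supplementary aid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .records import ConsultationRecord

__all__ = [
    "CellStats",
    "CountMatrix",
    "build_jeopardy_matrix",
    "permutation_enrichment",
    "sample_fixed_margins",
]


@dataclass(frozen=True)
class CountMatrix:
    """Non-negative integer count matrix with row/column labels."""

    values: np.ndarray
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=np.int64)
        if vals.ndim != 2:
            raise ValueError("count matrix must be two-dimensional")
        if vals.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("label lengths do not match matrix shape")
        if (vals < 0).any():
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "row_labels", tuple(self.row_labels))
        object.__setattr__(self, "col_labels", tuple(self.col_labels))

    @property
    def is_empty(self) -> bool:
        return self.values.size == 0 or self.values.sum() == 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.row_labels), columns=list(self.col_labels))

    def drop_zero_margins(self) -> tuple["CountMatrix", list[str], list[str]]:
        """Remove all-zero rows/columns; returns (matrix, dropped rows, dropped cols)."""
        rm = self.values.sum(axis=1) > 0
        cm = self.values.sum(axis=0) > 0
        dropped_rows = [r for r, keep in zip(self.row_labels, rm) if not keep]
        dropped_cols = [c for c, keep in zip(self.col_labels, cm) if not keep]
        sub = CountMatrix(
            values=self.values[np.ix_(rm, cm)],
            row_labels=tuple(r for r, keep in zip(self.row_labels, rm) if keep),
            col_labels=tuple(c for c, keep in zip(self.col_labels, cm) if keep),
        )
        return sub, dropped_rows, dropped_cols


def build_jeopardy_matrix(records: Iterable[ConsultationRecord]) -> CountMatrix:
    """Count jeopardy determinations for every (species, work type) cell.

    DPS/ESU rows are aggregated to the species level for the row labels but
    each determination row counts individually, so the matrix total equals
    the total number of jeopardy determinations.
    """
    cells: dict[tuple[str, str], int] = {}
    for rec in records:
        for det in rec.species_rows:
            if det.expert_final == "jeopardy":
                key = (det.species, rec.work_type)
                cells[key] = cells.get(key, 0) + 1
    if not cells:
        return CountMatrix(values=np.zeros((0, 0), dtype=np.int64), row_labels=(), col_labels=())
    species = tuple(sorted({s for s, _ in cells}))
    worktypes = tuple(sorted({w for _, w in cells}))
    values = np.zeros((len(species), len(worktypes)), dtype=np.int64)
    for (s, w), n in cells.items():
        values[species.index(s), worktypes.index(w)] = n
    return CountMatrix(values=values, row_labels=species, col_labels=worktypes)


def sample_fixed_margins(
    matrix: CountMatrix, rng: np.random.Generator, size: int = 1
) -> np.ndarray:
    """Draw tables from the fixed-margins conditional distribution.

    Returns an array of shape (size, rows, cols); every draw has exactly
    the row sums, column sums, and grand total of ``matrix``.
    """
    r = matrix.values.sum(axis=1)
    c = matrix.values.sum(axis=0)
    if r.sum() == 0:
        raise ValueError("degenerate matrix: no positive margin")
    if min(matrix.values.shape) == 1:
        # a single row or column is fully determined by its margins
        return np.tile(matrix.values, (size, 1, 1)).astype(np.int64)
    dist = stats.random_table(r, c)
    out = dist.rvs(size, method="patefield", random_state=rng)
    return np.asarray(out, dtype=np.int64).reshape(size, len(r), len(c))


@dataclass(frozen=True)
class CellStats:
    """Permutation-test summary for one matrix cell."""

    row: str
    col: str
    observed: int
    effect: float
    sd: float
    p_gt: float
    p_lt: float


def permutation_enrichment(
    matrix: CountMatrix,
    n_perm: int = 1000,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    smoothed: bool = False,
) -> pd.DataFrame:
    """Fixed-margin permutation test for every cell of a count matrix.

    Long-format result with one row per (species, work type) cell:
    observed, effect, sd, p_gt, p_lt, plus supplementary Benjamini-Hochberg
    columns ``q_gt``/``q_lt`` (no correction is applied to p_gt/p_lt
    themselves).  All-zero rows/columns are dropped before permutation and
    reported in the ``dropped`` DataFrame attribute.

    With ``smoothed`` the p-values use (#{sim >= obs} + 1) / (n_perm + 1)
    (and the mirror for p_lt), which can never return exactly 0.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if matrix.is_empty:
        raise ValueError("degenerate matrix: nothing to permute")
    sub, dropped_rows, dropped_cols = matrix.drop_zero_margins()
    if rng is None:
        rng = np.random.default_rng(seed)
    sims = sample_fixed_margins(sub, rng, size=n_perm)  # (n_perm, R, C)
    obs = sub.values
    mean_sim = sims.mean(axis=0)
    sd_sim = sims.std(axis=0, ddof=0)
    n_greater = (sims > obs).sum(axis=0)
    n_less = (sims < obs).sum(axis=0)
    n_geq = (sims >= obs).sum(axis=0)
    n_leq = (sims <= obs).sum(axis=0)
    if smoothed:
        p_gt = (n_geq + 1) / (n_perm + 1)
        p_lt = (n_leq + 1) / (n_perm + 1)
    else:
        p_gt = n_greater / n_perm
        p_lt = n_less / n_perm

    rows = []
    for i, r_lab in enumerate(sub.row_labels):
        for j, c_lab in enumerate(sub.col_labels):
            rows.append(
                {
                    "species": r_lab,
                    "work_type": c_lab,
                    "observed": int(obs[i, j]),
                    "effect": float(obs[i, j] - mean_sim[i, j]),
                    "sd": float(sd_sim[i, j]),
                    "p_gt": float(p_gt[i, j]),
                    "p_lt": float(p_lt[i, j]),
                }
            )
    df = pd.DataFrame(rows)
    # Supplementary FDR columns (not part of the core permutation protocol).
    for tail in ("p_gt", "p_lt"):
        df[tail.replace("p", "q")] = multipletests(df[tail].clip(lower=1.0 / (n_perm + 1)),
                                                   method="fdr_bh")[1]
    df.attrs["dropped_rows"] = dropped_rows
    df.attrs["dropped_cols"] = dropped_cols
    df.attrs["n_perm"] = n_perm
    df.attrs["smoothed"] = smoothed
    return df
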