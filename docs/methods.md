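# Methods

## Data model

A consultation record carries one row per (species, DPS/ESU listed unit)
with an agency-proposed determination (`no effect` < `NLAA` < `LAA`, plus
the rare direct proposals `proposed no jeopardy` / `proposed jeopardy`) and
an expert final determination (`no effect` < `NLAA` < `no jeopardy` <
`jeopardy`), together with an optional critical-habitat determination.
`LAA` is never a final category: a final in the jeopardy range implies the
expert treated the action as likely to adversely affect the species.

Two units of analysis coexist and are never mixed implicitly:

* **determination level** — every (species, unit) row counts; used for the
  concordance table, kappa, KS tests, and the enrichment matrix;
* **species-consultation level** — all units of one species within one
  consultation collapse to a single entry (`aggregate_dps`, keeping the
  most severe category per field so "any unit jeopardized" survives);
  used for frequency tables and the co-jeopardization matrix.

## Cleaning

Cleaning is conservative and auditable: reversed date pairs are swapped and
flagged (`date_corrected`) rather than dropped; name variants are mapped
through a shipped CSV alias table, with unmapped strings passed through and
flagged; the free-text consultation-type field is split into type
(formal/informal/combined) and complexity
(standard/programmatic/conference/early), a bare type defaulting to
standard complexity with a flag; unknown determination strings become
`missing` and are logged, never silently dropped. Parsing conserves rows
exactly: rows in = rows attached + rows rejected. All cleaning operations
are idempotent and return new values. The analysis window filters on the
consultation start date; the default window is 2000-01-01 through
2017-06-30 and is configurable.

## Concordance statistics

The 4x5 expert-by-agency cross-tabulation carries a fixed ordinal score
matrix with zeros on the six agreement cells — including the asymmetric
jeopardy-range cells ((no jeopardy, proposed no jeopardy) scores 0 while
(jeopardy, proposed no jeopardy) scores −1). The weighted kappa uses
disagreement weights: K_w = 1 − observed/expected weighted disagreement,
which is 1 under perfect agreement, 0 at exact independence of the margins,
and invariant to scaling all counts. The weight set is {0, 0.25, 0.5,
0.75, 1}; since no canonical assignment of those weights to score
magnitudes exists, the default is w = |score|/4 (monotone in |score|,
agreement = 0) and any assignment satisfying the same constraints can be
supplied. On the published fixture table the default weights give
K_w = 0.62829 (pinned by a regression test). The summary statistic of 0.38
published alongside that table is not reproducible without knowing the
weight assignment used there, and is deliberately not asserted anywhere.

The same ambiguity affects direction-of-disagreement shares: on the printed
fixture, zero-score cells are 84.0% of pairs and negative scores are 23.8%
of disagreements under the orientation defined here (76.2% transposed),
whereas the published prose reports 79% agreement and 71%
underestimation. `orientation_report` returns both orientations so either
convention can be read off; the package forces neither number.

Per-agency KS tests compare an agency's score distribution against the
pooled distribution of all agencies (the focal agency included by default;
a leave-one-out flag exists). The statistic D is the sup-distance between
step CDFs, correct under ties; p-values are asymptotic, with an exact
enumeration of pooled relabelings available for samples of at most 10
(the asymptotic p is approximate for heavily tied discrete scores, which
is why the exact option and the brute-force oracle in the test-suite
exist). Agencies under 20 determinations are reported as skipped.

## Trend and frequency analyses

Yearly counts are fitted by GLM — Poisson/log or Gaussian/identity — with
the year covariate centred (the slope is unchanged; uncentred calendar
years overflow the log-link's implied exp(intercept)). A perfectly constant
series short-circuits to slope 0 with a perfect fit, since the Gaussian
scale estimate degenerates at zero residual variance. Chi-square
goodness-of-fit uses k − 1 degrees of freedom against a uniform (or
supplied) expectation. Rates are reported raw and half-up-rounded to one
decimal where a printed-table comparison is intended.

## Enrichment permutation test

The species x work-type jeopardy count matrix is compared against tables
drawn from the fixed-margins conditional (Fisher/Patefield) distribution;
all-zero rows and columns are dropped first and reported. Per cell:
effect = observed − mean(simulated), sd(simulated), and two tail
probabilities. The default tail rule is the literal permutation
proportion #{sim > obs}/n_perm; a +1-smoothed variant
(#{sim ≥ obs}+1)/(n_perm+1) is available and is what the calibration and
power test-suites use, because it is the variant with the finite-sample
guarantee P(p ≤ α) ≤ α — the literal strict-inequality rule is
anti-conservative on sparse discrete cells. No multiple-testing correction
is applied to the reported p-values; Benjamini–Hochberg adjusted columns
(`q_gt`, `q_lt`) are emitted alongside as a clearly supplementary aid.
Single-row or single-column matrices are margin-forced and returned
unchanged by the sampler (the scipy Patefield path mishandles this edge,
so it is short-circuited exactly).

## Co-jeopardization

On the binary species x consultation matrix (columns default to
consultations with ≥ 1 jeopardy determination; a flag widens to all formal
consultations), the overlap count for a pair follows the hypergeometric
law under the fixed-margins null, giving exact tails and
expected = N1·N2/N. A Monte-Carlo column-shuffle oracle cross-checks the
analytic tails in the test-suite but never substitutes for them. Because
no single convention defines "probability of co-jeopardization by the same
action", each pair reports observed/N together with observed/N1,
observed/N2 and observed/|union|.

## Synthetic generator

The generator is the package's stand-in for the administrative extract.
The expert category is drawn first from a four-category probability vector
(defaults (0.134, 0.685, 0.1798, 0.0012)); jeopardy-range outcomes are
realised only in formal consultations (drawn with p_formal = 0.199), with
their unconditional mass preserved by inflating the conditional
probability by 1/p_formal. The agency proposal is then drawn through an
ordinal shift kernel: with probability `noise` (default 0.20) the proposal
deviates from the agreement category, moving down with probability
(1 − bias)/2 and up with (1 + bias)/2 (per-agency bias in [−1, 1]), by one
step (80%) or two, clipped to the valid range — so a deviation at a
boundary can land back on agreement. Direct jeopardy-range proposals are
emitted with probability 3 x 10⁻⁴. Species pools include multi-unit
species (a second DPS row joins with probability 0.25); agencies and work
types follow configured skewed weights; each record has its own RNG stream
keyed by (seed, record index), making output order-independent and
byte-reproducible.

Defaults were set once from the regime the analysis targets: formal share
~20%, zero-score share of the concordance table ~84%, and — including the
default planted enrichment (salmonids x agriculture at 8x) and co-jeopardy
shocks — roughly 1.5% of formal consultations carrying a jeopardy
determination. A co-jeopardy shock (per consultation, per group) pulls the
whole group into the consultation and multiplies its jeopardy probability:
co-presence is essential, since a pure probability boost applied to
independently present species inflates margins without creating pairwise
excess over a margins-conditioned null.

Two focused experiment configs exist for operating-characteristic studies,
designed by Monte-Carlo power analysis before the corresponding checks
were frozen: `enrichment_power_config` (six species, five work types,
jeopardy mass 0.015, one planted cell at 10x; detection power 0.92–0.98
over disjoint 50-seed sets at n = 2000 and 1000 permutations, measured
null false-positive rate 2.1% at α = 0.05 over 200 seeds) and
`cojeopardy_power_config` (one shocked pair at shock rate 0.05 and boost
60; pair detection power 0.86–0.96).

What the generator does **not** emulate: real PCTS vocabulary chaos beyond
the shipped alias tables, the extreme within-consultation clustering of
jeopardy determinations seen in the real extract (hundreds of
determinations across a handful of programmatic consultations), spatial
structure, species biology, and any dependence between agency identity and
work type. Passing tests therefore demonstrate that the statistical
machinery recovers known structure under a faithful-but-simplified data
process, not that the real extract satisfies the generator's independence
assumptions.

## Problem sizes

The test-suite and acceptance script size their simulations for a
single-CPU run: 2000-consultation datasets for the detection-power studies
(50 seeds), 800-consultation datasets for null calibration (200 seeds,
500 permutations), 5000-consultation datasets for bias-direction recovery,
and 4000 consultations for the end-to-end synthetic study run. These sizes
give each check stable operating characteristics (binomial SEs a few
percent) at a total runtime of roughly two minutes.

## Known limitations

* The published 79% / 71% / K_w = 0.38 summary statistics are not
  recomputable from the printed cross-tabulation under any orientation or
  weight assignment tried; the package documents the discrepancy and
  reports both orientations instead of forcing agreement.
* Permutation p-values of exactly 0 are an artefact of the literal tail
  rule; use the smoothed variant when calibrated p-values matter.
* The KS asymptotic p-value is approximate under heavy ties; the exact
  enumeration is exponential and limited to tiny samples.
* The hypergeometric co-occurrence null conditions on row margins and
  column count only; it does not model heterogeneous per-consultation
  inclusion probabilities.
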