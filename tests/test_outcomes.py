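"""Frequencies, chi-square GOF, GLM trends, outcome summaries."""

import itertools

import numpy as np
import pytest
from scipy import stats

from concord7 import outcomes, pcts_io, synthetic_data as sd
from concord7.records import ConsultationRecord, SpeciesDetermination


def _rec(cid, species_list, ctype="formal", agency="Army Corps of Engineers"):
    from datetime import date

    rows = tuple(
        SpeciesDetermination(sp, dps, "LAA", final, ch)
        for sp, dps, final, ch in species_list
    )
    return ConsultationRecord(
        consultation_id=cid,
        agency=agency,
        region="West Coast",
        work_type="waterway",
        type=ctype,
        complexity="standard",
        start_date=date(2005, 1, 1),
        end_date=date(2005, 6, 1),
        species_rows=rows,
    )


class TestFrequencyTable:
    def test_single_agency(self):
        recs = [_rec(f"C{i}", [("Chinook salmon", None, "no jeopardy", "missing")]) for i in range(10)]
        ft = outcomes.frequency_table(recs, "agency")
        assert ft.counts.to_dict() == {"Army Corps of Engineers": 10}

    def test_species_counts_collapse_dps(self):
        rec = _rec(
            "C1",
            [
                ("Steelhead", "Puget Sound DPS", "no jeopardy", "missing"),
                ("Steelhead", "Snake River DPS", "no jeopardy", "missing"),
                ("Steelhead", "Southern California DPS", "no jeopardy", "missing"),
            ],
        )
        ft = outcomes.frequency_table([rec], "species")
        assert ft.counts.to_dict() == {"Steelhead": 1}

    def test_totals_conserved(self, small_records):
        n = len(small_records)
        for key in ("agency", "work_type", "region"):
            assert outcomes.frequency_table(small_records, key).total == n

    def test_unknown_key_errors(self):
        with pytest.raises(ValueError):
            outcomes.frequency_table([], "color")


class TestChisqGof:
    def test_uniform_counts_zero(self):
        res = outcomes.chisq_gof([25, 25, 25, 25])
        assert res.chi2 == pytest.approx(0.0)
        assert res.df == 3
        assert res.p == pytest.approx(1.0)

    def test_hand_value_two_levels(self):
        res = outcomes.chisq_gof([10, 20])
        assert res.chi2 == pytest.approx(10 / 3)
        assert res.df == 1

    def test_p_decreases_with_skew(self):
        ps = [outcomes.chisq_gof(c).p for c in ([30, 30], [40, 20], [50, 10], [58, 2])]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_brute_force_formula_equivalence(self):
        """Match a direct evaluation of sum (O-E)^2/E on small vectors."""
        rng = np.random.default_rng(0)
        for k in (2, 3, 4, 5, 6):
            for _ in range(20):
                counts = rng.integers(1, 12, size=k)
                if counts.sum() > 50:
                    continue
                res = outcomes.chisq_gof(counts)
                e = counts.sum() / k
                assert res.chi2 == pytest.approx(((counts - e) ** 2 / e).sum())
                assert res.p == pytest.approx(stats.chi2.sf(res.chi2, k - 1))

    def test_zero_expected_errors(self):
        with pytest.raises(ValueError):
            outcomes.chisq_gof([5, 5], expected=[1.0, 0.0])


class TestTrendFits:
    def test_constant_series_zero_slope(self):
        series = {y: 40 for y in range(2000, 2010)}
        for fam in ("poisson-log", "gaussian-identity"):
            fit = outcomes.fit_yearly_counts(series, fam)
            assert fit.slope_per_year == pytest.approx(0.0, abs=1e-8)
            assert fit.p > 0.9

    def test_poisson_log_recovers_exact_exponential(self):
        b = 0.07
        years = np.arange(2000, 2015)
        series = {int(y): float(np.exp(-135.0 + b * y)) for y in years}
        fit = outcomes.fit_yearly_counts(series, "poisson-log")
        assert fit.slope_per_year == pytest.approx(b, abs=1e-6)

    def test_gaussian_identity_equals_least_squares_oracle(self):
        rng = np.random.default_rng(1)
        years = np.arange(2000, 2012)
        y = 100 + 3.5 * (years - 2000) + rng.normal(0, 5, size=years.size)
        series = dict(zip((int(v) for v in years), y))
        fit = outcomes.fit_yearly_counts(series, "gaussian-identity")
        # normal equations
        X = np.column_stack([np.ones_like(years, dtype=float), years.astype(float)])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert fit.slope_per_year == pytest.approx(beta[1], rel=1e-8)

    def test_fewer_than_three_years_errors(self):
        with pytest.raises(ValueError):
            outcomes.fit_yearly_counts({2000: 5, 2001: 6}, "poisson-log")

    def test_slope_recovery_within_2se(self):
        """Planted slopes land within 2 SE of the estimate at near-nominal rates.

        The 2-SE Wald interval has nominal coverage 95.45%; over 100 seeds
        the binomial SD of the hit count is ~2, so the assertion uses a
        bound ~2.6 SD below nominal — loose enough not to fail a calibrated
        fit by chance, tight enough to catch genuinely miscalibrated SEs.
        """
        years = np.arange(2000, 2017)
        hits = {"poisson-log": 0, "gaussian-identity": 0}
        n_seeds = 100
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            lam = np.exp(3.0 + 0.05 * (years - 2000))
            counts = rng.poisson(lam)
            fit = outcomes.fit_yearly_counts(dict(zip(map(int, years), counts)), "poisson-log")
            if abs(fit.slope_per_year - 0.05) <= 2 * fit.se:
                hits["poisson-log"] += 1
            y = 50 + 2.0 * (years - 2000) + rng.normal(0, 8, size=years.size)
            fit = outcomes.fit_yearly_counts(dict(zip(map(int, years), y)), "gaussian-identity")
            if abs(fit.slope_per_year - 2.0) <= 2 * fit.se:
                hits["gaussian-identity"] += 1
        assert hits["poisson-log"] >= 90
        assert hits["gaussian-identity"] >= 90

    def test_jeopardy_trend_constant_and_linear(self):
        const = {y: (2, 100) for y in range(2000, 2010)}
        fit = outcomes.fit_jeopardy_trend(const)
        assert fit.slope_per_year == pytest.approx(0.0, abs=1e-10)
        linear = {y: (y - 2000, 100) for y in range(2000, 2011)}
        fit = outcomes.fit_jeopardy_trend(linear)
        assert fit.slope_per_year == pytest.approx(0.01, abs=1e-10)
        with pytest.raises(ValueError):
            outcomes.fit_jeopardy_trend({2000: (1, 10)})


class TestJeopardyRate:
    @pytest.mark.parametrize(
        "j, n, pct", [(60, 3012, 2.0), (9, 186, 4.8), (0, 55, 0.0), (10, 176, 5.7), (24, 675, 3.6)]
    )
    def test_published_style_rounding(self, j, n, pct):
        assert outcomes.jeopardy_rate(j, n).rounded == pytest.approx(pct)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            outcomes.jeopardy_rate(1, 0)
        with pytest.raises(ValueError):
            outcomes.jeopardy_rate(5, 4)

    def test_round_half_up_ties(self):
        assert outcomes.round_half_up(0.25, 1) == 0.3
        assert outcomes.round_half_up(0.35, 1) == 0.4
        assert outcomes.round_half_up(-0.25, 1) == -0.3


class TestOutcomeSummary:
    def test_counting_example(self):
        recs = [
            _rec(f"F{i}", [("Chinook salmon", None, "no jeopardy", "missing")], "formal")
            for i in range(3)
        ]
        recs.append(_rec("F3", [("Chinook salmon", None, "jeopardy", "missing")], "formal"))
        recs += [
            _rec(f"I{i}", [("Chinook salmon", None, "NLAA", "missing")], "informal")
            for i in range(16)
        ]
        s = outcomes.consultation_outcome_summary(recs)
        assert s.n_total == 20 and s.n_formal == 4
        assert s.formal_pct == pytest.approx(20.0)
        assert s.jeopardy_pct_of_formal == pytest.approx(25.0)
        assert s.jeopardy_pct_of_all == pytest.approx(5.0)

    def test_no_formal_flagged_undefined(self):
        recs = [_rec("I0", [("Chinook salmon", None, "NLAA", "missing")], "informal")]
        s = outcomes.consultation_outcome_summary(recs)
        assert not s.jeopardy_defined
        assert np.isnan(s.jeopardy_pct_of_formal)

    def test_disjoint_partition_of_am_and_jeopardy(self):
        recs = [
            _rec("C0", [("Chinook salmon", None, "no jeopardy", "adverse modification")], "formal"),
            _rec("C1", [("Chinook salmon", None, "jeopardy", "no adverse modification")], "formal"),
            _rec("C2", [("Chinook salmon", None, "jeopardy", "adverse modification")], "formal"),
        ]
        s = outcomes.consultation_outcome_summary(recs)
        assert s.n_am_without_jeopardy == 1
        assert s.n_jeopardy_without_am == 1
        assert s.n_jeopardy_consultations == 2
        assert s.n_adverse_mod_consultations == 2

    def test_percentage_consistency(self, medium_records):
        s = outcomes.consultation_outcome_summary(medium_records)
        assert s.jeopardy_pct_of_all <= s.jeopardy_pct_of_formal
        assert s.n_total == s.n_formal + s.n_informal + s.n_combined
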