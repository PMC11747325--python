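"""The four disproportionality estimators, verdicts and screening."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from faerspv.cohort import ONASEMNOGENE_LEXICON, build_cases
from faerspv.dispro import (ContingencyTable, DEFAULT_THRESHOLDS,
                            SignalMetrics, Thresholds, apply_exclusion,
                            build_background, build_table, compute_metrics,
                            ebgm_stat, evaluate_signal, ic_stat, prr_chi2_stat,
                            ror_stat, screen)
from faerspv.io import deduplicate
from faerspv import mgps
from faerspv.synthetic import screen_generated

cells = st.integers(min_value=1, max_value=2000)


def table(a, b, c, d):
    return ContingencyTable(a, b, c, d)


class TestRor:
    def test_reference_example(self):
        ror, low, high, corrected = ror_stat(table(10, 90, 100, 9800))
        assert ror == pytest.approx(10.8889, abs=1e-3)
        assert low == pytest.approx(5.503, abs=2e-3)
        assert high == pytest.approx(21.545, abs=2e-3)
        assert not corrected

    def test_unit_table_symmetric_about_one(self):
        ror, low, high, _ = ror_stat(table(1, 1, 1, 1))
        assert ror == pytest.approx(1.0)
        assert low * high == pytest.approx(1.0)

    def test_zero_cell_policy(self):
        assert ror_stat(table(0, 10, 10, 100), zero_policy="none")[0] is None
        ror, low, high, corrected = ror_stat(table(0, 10, 10, 100))
        assert corrected and low < ror < high

    @settings(max_examples=200, deadline=None)
    @given(cells, cells, cells, cells)
    def test_geometric_mean_identity(self, a, b, c, d):
        ror, low, high, _ = ror_stat(table(a, b, c, d))
        assert math.sqrt(low * high) == pytest.approx(ror, rel=1e-6)


class TestPrrChi2:
    def test_reference_example(self):
        prr, chi2 = prr_chi2_stat(table(10, 90, 100, 9800))
        assert prr == pytest.approx(9.9, abs=1e-9)
        assert chi2 == pytest.approx(73.5455, abs=1e-3)

    def test_null_table(self):
        # equal reporting proportions: PRR = 1, chi2 = 0
        prr, chi2 = prr_chi2_stat(table(10, 90, 100, 900))
        assert prr == pytest.approx(1.0)
        assert chi2 == pytest.approx(0.0)

    @settings(max_examples=100, deadline=None)
    @given(cells, cells, cells, cells)
    def test_chi2_invariant_under_transpose(self, a, b, c, d):
        _, chi2 = prr_chi2_stat(table(a, b, c, d))
        _, chi2_t = prr_chi2_stat(table(a, c, b, d))
        assert chi2 == pytest.approx(chi2_t, rel=1e-12)


class TestEbgmIc:
    def test_simplified_reference_example(self):
        ebgm, ebgm05 = ebgm_stat(table(10, 90, 100, 9800))
        assert ebgm == pytest.approx(9.0909, abs=1e-3)
        assert ebgm05 == pytest.approx(5.127, abs=2e-3)

    def test_observed_equals_expected(self):
        # a = E exactly: shrunk ratio 1, canonical IC 0
        t = table(50, 50, 450, 450)
        assert t.expected_a == pytest.approx(50.0)
        assert ebgm_stat(t)[0] == pytest.approx(1.0)
        ic, ic025 = ic_stat(t)
        assert ic == pytest.approx(0.0)
        assert ic025 < 0

    def test_fixed_offset_dialect_is_log2_of_ebgm(self):
        t = table(10, 90, 100, 9800)
        ebgm = ebgm_stat(t)[0]
        ic, ic025 = ic_stat(t, "fixed_offset", ebgm=ebgm)
        assert ic == pytest.approx(math.log2(9.0909), abs=1e-3)
        assert ic == pytest.approx(3.184, abs=1e-3)
        assert ic - ic025 == pytest.approx(1.67, abs=0)

    def test_undefined_markers(self):
        t = table(0, 10, 50, 1000)
        assert ebgm_stat(t) == (None, None)
        assert ic_stat(t, "fixed_offset", ebgm=None) == (None, None)

    @settings(max_examples=100, deadline=None)
    @given(cells, cells, cells, cells)
    def test_monotone_in_observed_count(self, a, b, c, d):
        """More target-event reports, everything else fixed, can only
        strengthen every statistic."""
        t0, t1 = table(a, b, c, d), table(a + 1, b, c, d)
        assert ror_stat(t1)[0] > ror_stat(t0)[0]
        assert prr_chi2_stat(t1)[0] > prr_chi2_stat(t0)[0]
        # EBGM/IC expectations move with a too (E depends on a); the ratio
        # can even dip on degenerate tiny tables, so assert growth only on
        # the screening-shaped domain where the event is rare in both arms
        if min(b, c) > a:
            assert ebgm_stat(t1)[0] > ebgm_stat(t0)[0]
            assert ic_stat(t1)[0] >= ic_stat(t0)[0]


class TestVerdicts:
    def passing_metrics(self):
        return compute_metrics("x", table(201, 1750, 900, 55000))

    def test_all_four_pass_on_strong_signal(self):
        verdicts = evaluate_signal(self.passing_metrics())
        assert verdicts == {"ror": True, "prr": True, "bcpnn": True,
                            "mgps": True, "joint": True}

    def test_ror_ci_low_below_one_fails_joint(self):
        m = self.passing_metrics()
        m.ror_low = 0.99
        assert not evaluate_signal(m)["joint"]

    def test_min_case_count_gates_huge_ror(self):
        m = compute_metrics("x", table(2, 1, 1, 10000))
        assert m.ror > 100
        assert not evaluate_signal(m)["joint"]

    def test_undefined_metric_fails_quietly(self):
        m = SignalMetrics(term="x", a=10)
        assert evaluate_signal(m)["joint"] is False


class TestBuildTable:
    def test_counts_by_definition(self, small_synth_parsed):
        quarter, dedup, truth = small_synth_parsed
        cohort = build_cases(quarter, dedup.retained_primaryids,
                             ONASEMNOGENE_LEXICON)
        ps = cohort.ps_cases
        background = build_background(quarter, dedup.retained_primaryids,
                                      [c.primaryid for c in ps])
        assert background.n_reports == truth.n_background
        # planted and null PTs alike match the generator's event ledger
        for pt, a_true in list(truth.target_case_counts.items())[::10]:
            t = build_table(ps, background, pt)
            assert t.a == a_true
            assert t.c == truth.background_case_counts[pt]
            assert t.a + t.b == truth.n_target_ps

    def test_absent_term_gives_empty_cells(self, small_synth_parsed):
        quarter, dedup, _ = small_synth_parsed
        cohort = build_cases(quarter, dedup.retained_primaryids,
                             ONASEMNOGENE_LEXICON)
        background = build_background(quarter, dedup.retained_primaryids,
                                      [c.primaryid for c in cohort.ps_cases])
        t = build_table(cohort.ps_cases, background, "No such reaction")
        assert t.a == 0 and t.c == 0

    def test_manual_example(self):
        # 10 target cases, 3 with the PT; 990 background reports, 50 with it
        from collections import Counter

        from faerspv.dispro import Background
        from tests.conftest import make_case

        cases = [make_case(i, pts=("X",) if i < 3 else ("Y",))
                 for i in range(10)]
        bg = Background(n_reports=990, n_pairs=1200,
                        pt_counts=Counter({"X": 50, "Y": 700}))
        t = build_table(cases, bg, "X")
        assert (t.a, t.b, t.c, t.d) == (3, 7, 50, 940)


class TestScreen:
    def test_planted_recovered_and_exclusion_identity(self, small_synth):
        outdir, truth = small_synth
        result, _, _ = screen_generated(outdir)
        flagged = set(result.table.loc[result.table["signal"], "term"])
        assert flagged >= set(truth.planted_signals)
        # empty exclusion list: output count equals input count
        assert result.n_signals_after_exclusion == \
            result.n_signals_before_exclusion
        # exclusion bookkeeping: removing named PTs after screening
        one_planted = sorted(truth.planted_signals)[:1]
        excluded = apply_exclusion(result, one_planted)
        assert excluded.n_signals_after_exclusion == \
            excluded.n_signals_before_exclusion - 1

    def test_soc_level_units(self, small_synth):
        outdir, truth = small_synth
        report, _, _ = screen_generated(outdir, level="SOC", unit="report")
        occurrence, _, _ = screen_generated(outdir, level="SOC",
                                            unit="occurrence")
        merged = report.table.merge(occurrence.table, on="term",
                                    suffixes=("_rep", "_occ"))
        # occurrence counting can only raise SOC case numbers
        assert (merged["case_count_occ"] >= merged["case_count_rep"]).all()
        assert occurrence.table["case_count"].sum() > truth.n_target_ps

    def test_empty_cohort_status(self):
        result = screen([], None, {}, frozenset())
        assert result.status == "empty cohort"
        assert result.table.empty

    def test_ranking_by_count_then_term(self, small_synth):
        outdir, _ = small_synth
        result, _, _ = screen_generated(outdir)
        counts = result.table["case_count"].tolist()
        assert counts == sorted(counts, reverse=True)


class TestMgpsShrinkage:
    def test_null_terms_shrink_more_than_simplified(self):
        """EM-fitted shrinkage pulls null-term EBGMs toward 1 harder than
        the raw observed/expected ratio on the same tables."""
        truth = mgps.GammaMixture(5.0, 5.0, 3.0, 0.3, 0.8)
        rng = np.random.default_rng(11)
        a, E, comp1 = mgps.simulate_counts(2000, truth, rng, e_low=2,
                                           e_high=50)
        prior, converged, _ = mgps.fit_gamma_mixture_em(a, E)
        assert converged
        keep = comp1 & (a > 0)
        shrunk = np.abs(np.log(mgps.posterior_ebgm(a[keep], E[keep], prior)))
        raw = np.abs(np.log(a[keep] / E[keep]))
        assert shrunk.mean() < raw.mean()

    def test_posterior_quantile_matches_monte_carlo(self):
        """EB05 on five hand-built tables agrees with sampling from the
        posterior gamma mixture."""
        prior = mgps.GammaMixture(2.0, 2.0, 2.0, 0.4, 0.6)
        tables = [(3, 2.0), (10, 2.5), (50, 10.0), (7, 7.0), (120, 20.0)]
        a = np.array([t[0] for t in tables], dtype=float)
        E = np.array([t[1] for t in tables])
        eb05 = mgps.posterior_quantile(a, E, prior, 0.05)
        rng = np.random.default_rng(5)
        l1, l2 = mgps._component_logliks(a, E, prior)
        q1 = np.exp(l1 - np.logaddexp(l1, l2))
        for i in range(len(tables)):
            comp = rng.random(200_000) < q1[i]
            draws = np.where(
                comp, rng.gamma(prior.alpha1 + a[i],
                                1 / (prior.beta1 + E[i]), 200_000),
                rng.gamma(prior.alpha2 + a[i],
                          1 / (prior.beta2 + E[i]), 200_000))
            assert eb05[i] == pytest.approx(np.quantile(draws, 0.05),
                                            rel=2e-2)
        ebgm = mgps.posterior_ebgm(a, E, prior)
        assert (eb05 < ebgm).all()

    def test_em_fallback_via_screen(self, small_synth):
        outdir, truth = small_synth
        result, _, _ = screen_generated(outdir, ebgm_method="mgps_em")
        tab = result.table.set_index("term")
        planted = sorted(truth.planted_signals)
        nulls = [t for t in tab.index if t not in truth.planted_signals]
        assert (tab.loc[planted, "ebgm"] > 2).all()
        # shrinkage: null terms sit nearer 1 than their raw ratios would
        simple, _, _ = screen_generated(outdir, ebgm_method="simplified_oe")
        stab = simple.table.set_index("term")
        log_m = np.abs(np.log(tab.loc[nulls, "ebgm"].astype(float)))
        log_s = np.abs(np.log(stab.loc[nulls, "ebgm"].astype(float)))
        assert log_m.mean() < log_s.mean()
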