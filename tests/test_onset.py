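"""Time-to-onset intervals, exclusion accounting and profiles."""

from __future__ import annotations

import pytest

from faerspv.cohort import ONASEMNOGENE_LEXICON, build_cases
from faerspv.onset import (OnsetRecord, bin_profile, compute_onsets,
                           first_window_share, late_soc_composition)
from tests.conftest import TINY_SOC_MAP, make_case


def rec(days, pt="Pyrexia", pid="1"):
    return OnsetRecord(pid, pt, days)


class TestComputeOnsets:
    def test_simple_interval(self):
        case = make_case(1, pts=("Pyrexia",), event_dt="20200310",
                         start_dt="20200301")
        result = compute_onsets([case])
        assert [r.days for r in result.records] == [9]

    def test_exclusion_reasons(self):
        cases = [
            make_case(1, event_dt="20200210", start_dt="20200301"),  # negative
            make_case(2, event_dt="202003", start_dt="20200301"),    # partial
            make_case(3, event_dt=None, start_dt="20200301"),        # missing
            make_case(4, event_dt="20200310", start_dt=None),        # missing
            make_case(5, event_dt="20200310", start_dt="20200301"),
        ]
        result = compute_onsets(cases)
        assert result.exclusions == {"negative": 1, "partial": 1, "missing": 2}
        assert len(result.records) == 1

    def test_report_pt_expansion_and_conservation(self):
        cases = [make_case(1, pts=("A", "B", "C"), event_dt="20200305",
                           start_dt="20200301"),
                 make_case(2, pts=("A", "B"), event_dt="202003",
                           start_dt="20200301")]
        result = compute_onsets(cases)
        # one event date, three PTs -> three onset records
        assert len(result.records) == 3
        assert result.exclusions["partial"] == 2
        assert result.n_candidates == 5

    def test_generated_quarter_conservation(self, small_synth_parsed):
        quarter, dedup, _ = small_synth_parsed
        cohort = build_cases(quarter, dedup.retained_primaryids,
                             ONASEMNOGENE_LEXICON)
        result = compute_onsets(cohort.ps_cases)
        candidates = sum(len(c.reaction_pts) for c in cohort.ps_cases)
        assert result.n_candidates == candidates
        assert all(r.days >= 0 for r in result.records)


class TestBinProfile:
    def test_monthly_bins(self):
        profile = bin_profile([rec(2), rec(2), rec(9), rec(40)])
        assert profile["count"].tolist() == [3, 1]
        assert profile["bin_start"].tolist() == [0, 30]

    def test_empty_input(self):
        assert bin_profile([]).empty
        assert bin_profile([], "daily_first_month").empty

    def test_daily_scheme_conserves_total(self):
        records = [rec(d) for d in (0, 0, 1, 7, 30, 31, 400)]
        profile = bin_profile(records, "daily_first_month")
        assert profile["count"].sum() == len(records)
        assert profile.loc[profile["day"] == ">30", "count"].item() == 2

    def test_totals_conserved_both_schemes(self, small_synth_parsed):
        quarter, dedup, _ = small_synth_parsed
        cohort = build_cases(quarter, dedup.retained_primaryids,
                             ONASEMNOGENE_LEXICON)
        records = compute_onsets(cohort.ps_cases).records
        for scheme in ("monthly_30d", "daily_first_month"):
            assert bin_profile(records, scheme)["count"].sum() == len(records)

    def test_first_month_share_tracks_generator_mixture(self,
                                                        small_synth_parsed):
        """The early-decay + uniform-tail mixture share within 30 days is
        recovered within binomial sampling error."""
        quarter, dedup, truth = small_synth_parsed
        cohort = build_cases(quarter, dedup.retained_primaryids,
                             ONASEMNOGENE_LEXICON)
        records = compute_onsets(cohort.ps_cases).records
        observed = first_window_share(records, 30)
        expected = truth.onset_first_month_share
        n = len(records)
        # (report, PT) records share report-level dates, so allow for the
        # clustering on top of the binomial error
        assert observed == pytest.approx(expected, abs=5 * (0.25 / n) ** 0.5 + 0.02)


class TestLateComposition:
    def test_single_soc_share(self):
        records = [rec(400, "Pyrexia"), rec(500, "Pyrexia"), rec(12, "Vomiting")]
        result = late_soc_composition(records, TINY_SOC_MAP)
        assert result.n_late == 2
        assert result.table["share"].tolist() == [1.0]
        assert result.table["soc"].tolist() == ["General disorders"]

    def test_cutoff_beyond_max_days(self):
        result = late_soc_composition([rec(10)], TINY_SOC_MAP, cutoff_days=365)
        assert result.status == "no late events"
        assert result.table.empty

    def test_shares_sum_to_one(self, small_synth_parsed):
        quarter, dedup, _ = small_synth_parsed
        cohort = build_cases(quarter, dedup.retained_primaryids,
                             ONASEMNOGENE_LEXICON)
        records = compute_onsets(cohort.ps_cases).records
        from faerspv.cohort import load_soc_map
        result = late_soc_composition(
            records, {r.pt: "SOC A" if hash(r.pt) % 2 else "SOC B"
                      for r in records}, cutoff_days=365)
        if result.n_late:
            assert result.table["share"].sum() == pytest.approx(1.0)
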