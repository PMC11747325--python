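"""Subgroup screens, sex contrasts and threshold contrasts."""

from __future__ import annotations

import dataclasses
import math

import pytest
from scipy import stats

from faerspv.cohort import ONASEMNOGENE_LEXICON, build_cases
from faerspv.dispro import build_background
from faerspv.strata import (DEFAULT_AGE_BANDS, StratumSpec, age_band_months,
                            exclusive_pt_sets, partition, sex_contrast,
                            stratified_screen, threshold_contrast,
                            weight_band, _contrast_row)
from faerspv.synthetic import (GeneratorConfig, StratumPlant, generate,
                               screen_generated)
from tests.conftest import make_case


def _cohort_and_background(quarter, dedup):
    cohort = build_cases(quarter, dedup.retained_primaryids,
                         ONASEMNOGENE_LEXICON)
    ps = cohort.ps_cases
    background = build_background(quarter, dedup.retained_primaryids,
                                  [c.primaryid for c in ps])
    return ps, background


def test_partition_sums_to_total(small_synth_parsed):
    quarter, dedup, _ = small_synth_parsed
    ps, _ = _cohort_and_background(quarter, dedup)
    split = partition(ps, DEFAULT_AGE_BANDS)
    assert sum(len(v) for v in split.values()) == len(ps)
    assert not split["other"]          # the three bands cover [0, inf)
    assert split["missing"]            # the generator leaves ages blank


def test_all_case_stratum_reproduces_unstratified_screen(small_synth,
                                                         small_synth_parsed):
    outdir, _ = small_synth
    quarter, dedup, _ = small_synth_parsed
    ps, background = _cohort_and_background(quarter, dedup)
    from faerspv.cohort import load_ime_list, load_soc_map
    soc_map = load_soc_map(outdir / "soc_map.csv")
    ime = load_ime_list(outdir / "ime_list.csv")
    everyone = StratumSpec("all", lambda c: True, lambda v: True)
    strat = stratified_screen(ps, everyone, background, soc_map, ime)
    full, _, _ = screen_generated(outdir)
    assert strat.table.equals(full.table)


def test_stratum_specific_planted_signal_localizes(tmp_path):
    """A PT planted only in the oldest age band is flagged there and stays
    unflagged in the youngest band."""
    pt = "Synthetic reaction 030"
    config = dataclasses.replace(
        GeneratorConfig(n_reports=30_000, seed=13),
        planted_signals={}, combo_planted={},
        age_missing_rate=0.1,
        stratum_planted=(StratumPlant(pt, 10.0, "age", low=18.0),))
    outdir = tmp_path / "q"
    generate(config, outdir)
    from faerspv import io as fio
    quarter = fio.parse_quarter(fio.quarter_paths(outdir))
    dedup = fio.deduplicate(quarter.demo.records)
    ps, background = _cohort_and_background(quarter, dedup)
    from faerspv.cohort import load_ime_list, load_soc_map
    soc_map = load_soc_map(outdir / "soc_map.csv")
    ime = load_ime_list(outdir / "ime_list.csv")
    old = stratified_screen(ps, age_band_months(18), background, soc_map, ime)
    young = stratified_screen(ps, age_band_months(0, 6), background, soc_map,
                              ime)
    old_signals = set(old.table.loc[old.table["signal"], "term"])
    young_signals = set(young.table.loc[young.table["signal"], "term"])
    assert pt in old_signals
    assert pt not in young_signals


class TestExclusiveSets:
    def test_partition_of_union(self):
        a = [make_case(1, pts=("X", "Z")), make_case(2, pts=("Z",))]
        b = [make_case(3, pts=("Y", "Z"))]
        only_a, only_b, shared = exclusive_pt_sets(a, b)
        assert (only_a, only_b, shared) == ({"X"}, {"Y"}, {"Z"})

    def test_identical_strata_have_empty_exclusives(self):
        cases = [make_case(1, pts=("X",)), make_case(2, pts=("Y",))]
        only_a, only_b, shared = exclusive_pt_sets(cases, cases)
        assert not only_a and not only_b and shared == {"X", "Y"}


class TestSexContrast:
    def test_reference_counts(self):
        row = _contrast_row(20, 380, 10, 390)
        assert row["ror"] == pytest.approx(2.0526, abs=1e-3)
        se = math.sqrt(1 / 20 + 1 / 380 + 1 / 10 + 1 / 390)
        z = math.log(row["ror"]) / se
        assert row["p_value"] == pytest.approx(2 * stats.norm.sf(abs(z)))
        # agreement in kind with an exact-test oracle on the same table
        odds, p_exact = stats.fisher_exact([[20, 380], [10, 390]])
        assert row["ror"] == pytest.approx(odds)
        assert abs(row["p_value"] - p_exact) < 0.03

    def test_null_table(self):
        row = _contrast_row(20, 380, 20, 380)
        assert row["log2_ror"] == pytest.approx(0.0)
        assert row["p_value"] == pytest.approx(1.0)
        assert not row["significant"]

    def test_antisymmetry(self):
        fwd = _contrast_row(17, 283, 41, 559)
        rev = _contrast_row(41, 559, 17, 283)
        assert fwd["ror"] == pytest.approx(1 / rev["ror"], rel=1e-12)
        assert fwd["p_value"] == pytest.approx(rev["p_value"], rel=1e-12)

    def test_volcano_coordinates_are_pure_functions(self):
        row = _contrast_row(25, 175, 12, 188)
        assert row["log2_ror"] == pytest.approx(
            math.log2(row["ror"]), rel=1e-12)
        assert row["neg_log10_p"] == pytest.approx(
            -math.log10(row["p_value"]), rel=1e-12)

    def test_female_bias_direction_and_shared_pts_only(self):
        females = [make_case(i, sex="F", pts=("FemPT", "Shared"))
                   for i in range(20)] + \
                  [make_case(100 + i, sex="F", pts=("Shared",))
                   for i in range(20)]
        males = [make_case(200 + i, sex="M", pts=("Shared",))
                 for i in range(40)] + \
                [make_case(300, sex="M", pts=("MalePT", "Shared"))]
        table = sex_contrast(females + males)
        assert set(table["pt"]) == {"Shared"}
        shared = table.set_index("pt").loc["Shared"]
        assert shared["ror"] == pytest.approx(1.0, rel=0.2)

    def test_requires_both_sexes(self):
        with pytest.raises(ValueError):
            sex_contrast([make_case(1, sex="F")])


class TestThresholdContrast:
    def test_cut_below_all_weights_is_degenerate(self):
        cases = [make_case(i, weight_kg=8.0 + i) for i in range(5)]
        result = threshold_contrast(cases, "weight", 1.0)
        assert result.status == "degenerate stratum"
        assert result.table.empty

    def test_identical_rates_give_null_ror(self):
        heavy = [make_case(i, weight_kg=10.0,
                           pts=("X",) if i % 2 else ("Y",))
                 for i in range(40)]
        light = [make_case(100 + i, weight_kg=5.0,
                           pts=("X",) if i % 2 else ("Y",))
                 for i in range(40)]
        result = threshold_contrast(heavy + light, "weight", 8.5)
        assert result.n_above == result.n_below == 40
        for _, row in result.table.iterrows():
            assert row["ror"] == pytest.approx(1.0)

    def test_missing_values_counted(self):
        cases = [make_case(1, weight_kg=None), make_case(2, weight_kg=9.0),
                 make_case(3, weight_kg=5.0)]
        result = threshold_contrast(cases, "weight", 8.5)
        assert result.n_missing == 1

    def test_planted_weight_effect_detected(self, tmp_path):
        """Heavier patients given an elevated PT rate: the above-cut ROR
        excludes 1 at the generator's sample size."""
        pt = "Synthetic reaction 090"
        config = dataclasses.replace(
            GeneratorConfig(n_reports=30_000, seed=29),
            planted_signals={}, combo_planted={},
            weight_missing_rate=0.1,
            stratum_planted=(StratumPlant(pt, 2.5, "weight", low=8.5),))
        outdir = tmp_path / "q"
        generate(config, outdir)
        from faerspv import io as fio
        quarter = fio.parse_quarter(fio.quarter_paths(outdir))
        dedup = fio.deduplicate(quarter.demo.records)
        ps, _ = _cohort_and_background(quarter, dedup)
        result = threshold_contrast(ps, "weight", 8.5, pts=[pt])
        row = result.table.iloc[0]
        assert row["ror"] > 1.5
        assert row["ror_low"] > 1.0

    def test_weight_band_and_age_band_specs(self):
        case = make_case(1, weight_kg=9.0, age_months=20.0)
        assert weight_band(8.5).status(case) == "in"
        assert age_band_months(0, 6).status(case) == "out"
        assert age_band_months(0, 6).status(make_case(2, age_months=None)) \
            == "missing"
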