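"""End-to-end orchestration: parse -> dedup -> cohort -> screens -> strata ->
onset -> combination analysis -> demographics, with a run manifest.

Every output table is written deterministically (stable sort orders, fixed
float formatting, no timestamps), so a rerun with the same inputs and seed
is byte-identical. The manifest records the config snapshot, input file
checksums, per-stage attrition counts, software version and the MedDRA map
version string supplied by the user, making each reported number
re-derivable from manifest + inputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from . import combo as combo_mod
from . import io as fio
from . import onset as onset_mod
from . import strata as strata_mod
from .cohort import (DrugLexicon, ONASEMNOGENE_LEXICON, NUSINERSEN_LEXICON,
                     build_cases, load_ime_list, load_lexicon, load_soc_map)
from .dispro import Thresholds, build_background, screen

FLOAT_FORMAT = "%.6g"

OUTCOME_PRIORITY = ("DE", "LT", "DS", "HO", "CA", "RI", "OT")
OUTCOME_LABELS = {"DE": "Death", "LT": "Life-threatening", "DS": "Disability",
                  "HO": "Hospitalization", "CA": "Congenital anomaly",
                  "RI": "Required intervention", "OT": "Other serious events"}
OCCUPATION_LABELS = {"CN": "Consumer", "HP": "Health professional",
                     "MD": "Physician", "OT": "Other healthcare professional",
                     "PH": "Pharmacist", "UNK": "Missing"}
AGE_BANDS_MONTHS = (("0-6 months", 0.0, 6.0), ("6-18 months", 6.0, 18.0),
                    ("1.5-10 years", 18.0, 120.0), ("10-18 years", 120.0, 216.0),
                    ("18+ years", 216.0, float("inf")))


def percentage(count: int, denominator: int, decimals: int = 2) -> float:
    """count/denominator as a percentage, rounded for table display."""
    if denominator == 0:
        return float("nan")
    return round(100.0 * count / denominator, decimals)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    quarter_dir: str
    outdir: str
    soc_map: Optional[str] = None        # defaults to quarter_dir/soc_map.csv
    ime_list: Optional[str] = None       # defaults to quarter_dir/ime_list.csv
    lexicon: Optional[dict] = None       # defaults to the onasemnogene synonyms
    partner_lexicon: Optional[dict] = None   # defaults to nusinersen synonyms
    match_mode: str = "word"
    unit: str = "report"
    ic_dialect: str = "canonical"
    ebgm_method: str = "simplified_oe"
    zero_policy: str = "haldane"
    thresholds: dict = field(default_factory=dict)
    exclusion_pts: list = field(default_factory=list)
    weight_cut_kg: float = 8.5
    age_cut_months: float = 8.0
    conmed_min_count: int = 20
    quorum: int = 3
    onset_cutoff_days: int = 365
    country_top_k: int = 5
    seed: int = 0
    meddra_version: str = "user-supplied (unversioned)"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def resolve_lexicon(self) -> DrugLexicon:
        return (load_lexicon(self.lexicon) if self.lexicon
                else ONASEMNOGENE_LEXICON)

    def resolve_partner(self) -> DrugLexicon:
        return (load_lexicon(self.partner_lexicon) if self.partner_lexicon
                else NUSINERSEN_LEXICON)

    def resolve_thresholds(self) -> Thresholds:
        return Thresholds(**self.thresholds)


# ---------------------------------------------------------------------------
# demographics (Table-1-shaped summary)


def _age_band(age_months: Optional[float]) -> str:
    if age_months is None:
        return "Missing"
    for label, low, high in AGE_BANDS_MONTHS:
        if low <= age_months < high:
            return label
    return "Missing"


def _primary_outcome(outcomes: frozenset) -> str:
    for code in OUTCOME_PRIORITY:
        if code in outcomes:
            return OUTCOME_LABELS[code]
    return "Missing"


def demographics_summary(cases, ime_pts, country_top_k: int = 5) -> pd.DataFrame:
    """Counts and percentages by sex, age band, outcome, reporter occupation,
    country and year, for the full cohort and its IME subset.

    Percentages use the block's stated denominator: the cohort size for the
    count columns and the IME-case total for the IME columns. Each case
    contributes one category per block (outcomes by severity priority), so
    category counts including Missing sum to the total in every block.
    """
    ime_pts = frozenset(ime_pts)
    ime_cases = [c for c in cases if c.reaction_pts & ime_pts]
    n_all, n_ime = len(cases), len(ime_cases)

    def block(name, labeller, categories):
        tall = pd.Series([labeller(c) for c in cases]).value_counts()
        time = pd.Series([labeller(c) for c in ime_cases]).value_counts() \
            if ime_cases else pd.Series(dtype=int)
        rows = []
        for cat in categories:
            ae = int(tall.get(cat, 0))
            im = int(time.get(cat, 0))
            rows.append({"block": name, "category": cat,
                         "ae_count": ae, "ae_pct": percentage(ae, n_all),
                         "ime_count": im, "ime_pct": percentage(im, n_ime)})
        return rows

    rows = [{"block": "Total", "category": "Total", "ae_count": n_all,
             "ae_pct": 100.0, "ime_count": n_ime,
             "ime_pct": 100.0 if n_ime else float("nan")}]
    rows += block("Sex", lambda c: {"F": "Female", "M": "Male"}.get(c.sex, "Missing"),
                  ["Female", "Male", "Missing"])
    rows += block("Age", lambda c: _age_band(c.age_months),
                  [b[0] for b in AGE_BANDS_MONTHS] + ["Missing"])
    rows += block("Outcome", lambda c: _primary_outcome(c.outcomes),
                  [OUTCOME_LABELS[c] for c in OUTCOME_PRIORITY] + ["Missing"])
    rows += block("Occupation", lambda c: OCCUPATION_LABELS.get(c.occupation,
                                                                "Missing"),
                  sorted(set(OCCUPATION_LABELS.values())))
    top = pd.Series([c.reporter_country or "Missing" for c in cases]) \
        .value_counts().index.tolist()
    keep = [c for c in top if c != "Missing"][:country_top_k]
    rows += block("Country",
                  lambda c: (c.reporter_country
                             if c.reporter_country in keep
                             else ("Missing" if not c.reporter_country else "Other")),
                  keep + ["Other", "Missing"])
    years = sorted({c.fda_dt.year for c in cases})
    rows += block("Year", lambda c: str(c.fda_dt.year), [str(y) for y in years])
    return pd.DataFrame(rows, columns=["block", "category", "ae_count",
                                       "ae_pct", "ime_count", "ime_pct"])


# ---------------------------------------------------------------------------
# run-all


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _write_csv(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False, float_format=FLOAT_FORMAT,
                 lineterminator="\n")


def _write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_all(config: RunConfig) -> dict:
    """Run every stage on one quarter directory; returns the manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "software": {"name": "faerspv", "version": __version__},
        "seed": config.seed,
        "meddra_version": config.meddra_version,
        "config": dataclasses.asdict(config),
        "stages": {},
    }
    stage = "parse"
    try:
        paths = fio.quarter_paths(config.quarter_dir)
        quarter = fio.parse_quarter(paths)
        manifest["inputs"] = {name: {"path": str(p), "sha256": _sha256(p)}
                              for name, p in sorted(paths.items())}
        fio.write_parse_report(quarter, outdir / "parse_report.json")
        manifest["stages"]["parse"] = quarter.parse_report()

        stage = "dedup"
        dedup = fio.deduplicate(quarter.demo.records)
        manifest["stages"]["dedup"] = {
            "input_reports": len(quarter.demo.records),
            "retained_reports": len(dedup.retained),
            "attrition": dedup.attrition,
        }

        stage = "cohort"
        lexicon = config.resolve_lexicon()
        cohort = build_cases(quarter, dedup.retained_primaryids, lexicon,
                             config.match_mode)
        ps = cohort.ps_cases
        manifest["stages"]["cohort"] = cohort.attrition()
        soc_path = config.soc_map or Path(config.quarter_dir) / "soc_map.csv"
        ime_path = config.ime_list or Path(config.quarter_dir) / "ime_list.csv"
        soc_map = load_soc_map(soc_path)
        ime = load_ime_list(ime_path)
        background = build_background(quarter, dedup.retained_primaryids,
                                      [c.primaryid for c in ps])

        stage = "screen"
        thresholds = config.resolve_thresholds()
        common = dict(thresholds=thresholds, ic_dialect=config.ic_dialect,
                      ebgm_method=config.ebgm_method,
                      zero_policy=config.zero_policy)
        pt_screen = screen(ps, background, soc_map, ime, level="PT",
                           unit=config.unit,
                           exclusion_list=config.exclusion_pts, **common)
        soc_screen = screen(ps, background, soc_map, ime, level="SOC",
                            unit=config.unit, **common)
        _write_csv(pt_screen.table, outdir / "signals_pt.csv")
        _write_csv(soc_screen.table, outdir / "signals_soc.csv")
        manifest["stages"]["screen"] = {
            "pt_signals_before_exclusion": pt_screen.n_signals_before_exclusion,
            "pt_signals_after_exclusion": pt_screen.n_signals_after_exclusion,
            "pt_excluded_terms": pt_screen.excluded_terms,
            "soc_signals": soc_screen.n_signals_before_exclusion,
        }

        stage = "strata"
        strata_info = {}
        for spec in strata_mod.DEFAULT_AGE_BANDS:
            sub = strata_mod.stratified_screen(ps, spec, background, soc_map,
                                               ime, unit=config.unit, **common)
            _write_csv(sub.table, outdir / f"signals_{spec.name}.csv")
            strata_info[spec.name] = len(spec.members(ps))
        females = strata_mod.sex_stratum("F").members(ps)
        males = strata_mod.sex_stratum("M").members(ps)
        strata_info["sex_F"] = len(females)
        strata_info["sex_M"] = len(males)
        if females and males:
            contrast = strata_mod.sex_contrast(ps, soc_map=soc_map)
            _write_csv(contrast, outdir / "sex_contrast.csv")
            volcano = contrast[["pt", "log2_ror", "neg_log10_p",
                                "significant"]]
            _write_json(volcano.to_dict(orient="records"),
                        outdir / "sex_volcano.json")
            only_f, only_m, shared = strata_mod.exclusive_pt_sets(females, males)
            _write_json({"only_female": sorted(only_f),
                         "only_male": sorted(only_m),
                         "shared": sorted(shared)},
                        outdir / "sex_exclusive_pts.json")
            strata_info["sex_shared_pts"] = len(shared)
        for variable, cut, fname in (("weight", config.weight_cut_kg,
                                      "weight_contrast.csv"),
                                     ("age", config.age_cut_months,
                                      "age_contrast.csv")):
            tc = strata_mod.threshold_contrast(ps, variable, cut,
                                               soc_map=soc_map)
            _write_csv(tc.table, outdir / fname)
            strata_info[f"{variable}_contrast"] = {
                "cut": cut, "n_above": tc.n_above, "n_below": tc.n_below,
                "n_missing": tc.n_missing, "status": tc.status}
        manifest["stages"]["strata"] = strata_info

        stage = "onset"
        onsets = onset_mod.compute_onsets(ps)
        _write_csv(pd.DataFrame([{"primaryid": r.primaryid, "pt": r.pt,
                                  "days": r.days} for r in onsets.records]),
                   outdir / "onset_records.csv")
        _write_csv(onset_mod.bin_profile(onsets.records, "monthly_30d"),
                   outdir / "onset_monthly.csv")
        _write_csv(onset_mod.bin_profile(onsets.records, "daily_first_month"),
                   outdir / "onset_daily.csv")
        late = onset_mod.late_soc_composition(onsets.records, soc_map,
                                              config.onset_cutoff_days)
        _write_csv(late.table, outdir / "onset_late_soc.csv")
        manifest["stages"]["onset"] = {
            "records": len(onsets.records),
            "exclusions": dict(sorted(onsets.exclusions.items())),
            "late_events": late.n_late, "late_status": late.status,
            "unit_note": onsets.note,
        }

        stage = "combo"
        partner = config.resolve_partner()
        cohorts = combo_mod.build_combo_cohorts(quarter,
                                                dedup.retained_primaryids,
                                                lexicon, partner,
                                                target_cohort=cohort,
                                                mode=config.match_mode)
        census = combo_mod.conmed_census(ps, config.conmed_min_count)
        _write_csv(census, outdir / "combo_census.csv")
        sizes = cohorts.sizes()
        if min(sizes.values()) > 0:
            interaction = combo_mod.interaction_screen(
                cohorts, background, thresholds=thresholds,
                quorum=config.quorum)
            combo_status = "ok"
        else:
            interaction = pd.DataFrame(columns=combo_mod._INTERACTION_COLUMNS)
            combo_status = f"degenerate cohorts: {sizes}"
        _write_csv(interaction, outdir / "combo_interaction.csv")
        manifest["stages"]["combo"] = {"cohort_sizes": sizes,
                                       "status": combo_status}

        stage = "demographics"
        demo = demographics_summary(ps, ime, config.country_top_k)
        _write_csv(demo, outdir / "demographics.csv")
        manifest["stages"]["demographics"] = {
            "cases": len(ps),
            "ime_cases": int(demo.loc[0, "ime_count"]),
        }
    except Exception as exc:  # noqa: BLE001 - abort with stage context
        manifest["failed_stage"] = stage
        _write_json(manifest, outdir / "manifest.json")
        raise PipelineError(stage, exc) from exc

    _write_json(manifest, outdir / "manifest.json")
    return manifest
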