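"""Synthetic FAERS-style quarters with known ground truth.

The generator emits the exact dollar-delimited dialect :mod:`faerspv.io`
reads (DEMO/DRUG/REAC/THER/OUTC/INDI plus a PT->SOC map and IME list), with
a JSON truth manifest recording everything needed for parameter-recovery
tests: configured and realized per-PT rates in the target and background
cohorts, the injected duplicate pairs, planted signal multipliers, and the
onset-mixture parameters.

Reporting structure emulated: per-report demographics, one-to-many drug
entries with role codes, one-to-many reaction PTs (independent Bernoulli
per vocabulary term, with at least one PT enforced by row resampling),
therapy dates with configurable corruption (missing/partial/negative
intervals), outcome codes, duplicate CASEIDs, a partner drug for
combination-therapy screening, and planted disproportionality signals of
known strength. Same seed, same bytes.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import io as fio
from .cohort import build_cases, load_soc_map, load_ime_list, DrugLexicon, \
    ONASEMNOGENE_LEXICON, NUSINERSEN_LEXICON
from .dispro import ScreenResult, build_background, screen


SOC_NAMES = (
    "Investigations",
    "Blood and lymphatic system disorders",
    "Gastrointestinal disorders",
    "Hepatobiliary disorders",
    "Infections and infestations",
    "Respiratory, thoracic and mediastinal disorders",
    "Nervous system disorders",
    "General disorders and administration site conditions",
)

CONMED_POOL = (
    ("PREDNISOLONE", 0.30), ("NUSINERSEN", 0.0), ("CHOLECALCIFEROL", 0.15),
    ("FAMOTIDINE", 0.14), ("SALBUTAMOL", 0.10), ("ONDANSETRON", 0.09),
    ("OMEPRAZOLE", 0.08), ("PARACETAMOL", 0.08), ("IBUPROFEN", 0.06),
)

BACKGROUND_DRUGS = tuple(f"BACKGROUND DRUG {i:02d}" for i in range(1, 31))

TARGET_NAME_VARIANTS = ("ZOLGENSMA", "ONASEMNOGENE ABEPARVOVEC-XIOI",
                        "AVXS-101", "ZOLGENSMA 2E13 VG")
PARTNER_NAME_VARIANTS = ("SPINRAZA", "NUSINERSEN")

COUNTRIES = (("US", 0.56), ("RU", 0.04), ("GB", 0.03), ("JP", 0.03),
             ("DE", 0.03), ("FR", 0.02), ("IT", 0.02), ("OTHER", 0.27))
OCCUPATIONS = (("CN", 0.44), ("MD", 0.40), ("HP", 0.12), ("PH", 0.01),
               ("OT", 0.01), ("UNK", 0.02))
OUTCOME_PROBS = (("HO", 0.25), ("OT", 0.22), ("DE", 0.055), ("LT", 0.025),
                 ("RI", 0.01), ("DS", 0.002), ("CA", 0.001))


@dataclass(frozen=True)
class PtSpec:
    pt: str
    soc: str
    is_ime: bool
    background_rate: float


@dataclass(frozen=True)
class StratumPlant:
    """Extra multiplier for one PT inside a demographic stratum of the
    target cohort; ``field`` is ``age`` (months), ``weight`` (kg) or ``sex``."""

    pt: str
    multiplier: float
    field: str
    low: float = 0.0
    high: float = float("inf")
    sex: str = "F"


def default_vocabulary(n_terms: int = 100) -> tuple:
    """Deterministic vocabulary: rates log-spaced over 0.005–0.05/report."""
    rates = 0.005 * (10.0 ** (np.arange(n_terms) / (n_terms - 1)))
    specs = []
    for i in range(n_terms):
        specs.append(PtSpec(pt=f"Synthetic reaction {i:03d}",
                            soc=SOC_NAMES[i % len(SOC_NAMES)],
                            is_ime=(i % 7 == 0),
                            background_rate=round(float(rates[i]), 6)))
    return tuple(specs)


_VOCAB = default_vocabulary()

DEFAULT_PLANTED = {
    _VOCAB[20].pt: 5.0,
    _VOCAB[35].pt: 6.0,
    _VOCAB[50].pt: 8.0,
    _VOCAB[65].pt: 10.0,
    _VOCAB[80].pt: 12.0,
}

DEFAULT_COMBO_PLANTED = {_VOCAB[60].pt: 3.0, _VOCAB[62].pt: 3.0}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic quarter.

    Defaults give 50,000 reports with a 5% target-drug share, a 100-term
    vocabulary with five planted signals (multipliers 5–12) and 95 null
    terms, 5% duplicated caseids, realistic date corruption, and an onset
    mixture of an early geometric decay plus a uniform long tail.
    """

    n_reports: int = 50_000
    target_share: float = 0.05
    target_ps_share: float = 0.90
    pt_vocabulary: tuple = _VOCAB
    planted_signals: dict = field(default_factory=lambda: dict(DEFAULT_PLANTED))
    stratum_planted: tuple = ()
    duplicate_rate: float = 0.05
    missing_date_rate: float = 0.10
    partial_date_rate: float = 0.05
    negative_onset_rate: float = 0.02
    sex_probs: tuple = (("F", 0.45), ("M", 0.40), ("UNK", 0.15))
    age_mean_months: float = 12.0
    age_sd_months: float = 8.0
    age_missing_rate: float = 0.30
    weight_mean_kg: float = 8.5
    weight_sd_kg: float = 2.5
    weight_missing_rate: float = 0.30
    partner_share: float = 0.10
    partner_background_share: float = 0.02
    combo_planted: dict = field(default_factory=lambda: dict(DEFAULT_COMBO_PLANTED))
    onset_early_weight: float = 0.8
    onset_geometric_p: float = 0.2
    onset_tail_max_days: int = 730
    quarter_start: _dt.date = _dt.date(2023, 1, 1)
    quarter_end: _dt.date = _dt.date(2023, 3, 31)
    seed: int = 0

    def validate(self) -> None:
        for name in ("target_share", "duplicate_rate", "missing_date_rate",
                     "partial_date_rate", "negative_onset_rate",
                     "partner_share", "partner_background_share",
                     "onset_early_weight"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name}={value} outside [0, 1]")
        if len({s.soc for s in self.pt_vocabulary}) < 2:
            raise ValueError("vocabulary must span at least 2 SOCs")
        rates = {s.pt: s.background_rate for s in self.pt_vocabulary}
        for source in (self.planted_signals, self.combo_planted):
            for pt, mult in source.items():
                if pt not in rates:
                    raise ValueError(f"planted PT {pt!r} not in vocabulary")
                if mult <= 0:
                    raise ValueError(f"multiplier for {pt!r} must be > 0")
                if rates[pt] * mult > 1.0:
                    raise ValueError(
                        f"infeasible config: rate {rates[pt]} x multiplier "
                        f"{mult} exceeds 1 for {pt!r}")
        for plant in self.stratum_planted:
            if plant.pt not in rates:
                raise ValueError(f"stratum-planted PT {plant.pt!r} not in vocabulary")
            if rates[plant.pt] * plant.multiplier > 1.0:
                raise ValueError(f"infeasible stratum multiplier for {plant.pt!r}")


@dataclass
class SyntheticTruth:
    """Ground-truth manifest recorded at emission (not re-simulated)."""

    seed: int
    n_reports: int
    n_emitted_demo_rows: int
    duplicate_pairs: list            # [dropped_primaryid, retained_primaryid]
    planted_signals: dict
    combo_planted: dict
    stratum_planted: list
    background_rates: dict           # configured per-PT rate
    target_case_counts: dict         # realized a per PT over target-PS reports
    background_case_counts: dict     # realized c per PT over comparator reports
    n_target: int
    n_target_ps: int
    n_background: int
    n_combo: int
    n_mono_partner: int
    onset_params: dict
    onset_first_month_share: float   # realized share of uncorrupted intervals
    stratum_sizes: dict

    def null_pts(self) -> list:
        planted = set(self.planted_signals)
        return [pt for pt in self.background_rates if pt not in planted]

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2,
                                         sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        return cls(**json.loads(Path(path).read_text()))


def _categorical(rng, n, pairs):
    labels = [p[0] for p in pairs]
    probs = np.array([p[1] for p in pairs], dtype=float)
    probs = probs / probs.sum()
    return np.array(labels, dtype=object)[rng.choice(len(labels), n, p=probs)]


def _date_tokens(dates: Sequence[_dt.date]) -> list:
    return [d.strftime("%Y%m%d") for d in dates]


def generate(config: GeneratorConfig, outdir) -> tuple:
    """Emit one synthetic quarter into ``outdir``.

    Returns ``(paths, truth)`` where ``paths`` maps table names to the
    emitted files (plus ``soc_map``, ``ime_list`` and ``truth``).
    Deterministic: the same config (including seed) yields identical bytes.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_reports
    vocab = config.pt_vocabulary
    n_terms = len(vocab)
    pts = [s.pt for s in vocab]
    rates = np.array([s.background_rate for s in vocab])

    case_numbers = np.arange(1, n + 1)
    primaryids = case_numbers * 10 + 2
    caseids = np.array([f"C{i:07d}" for i in case_numbers], dtype=object)

    target = rng.random(n) < config.target_share
    role = np.full(n, "", dtype=object)
    u_role = rng.random(n)
    role[target] = "PS"
    role[target & (u_role >= config.target_ps_share)] = "SS"
    role[target & (u_role >= config.target_ps_share
                   + 0.6 * (1 - config.target_ps_share))] = "C"

    partner = target & (rng.random(n) < config.partner_share)
    partner_bg = (~target) & (rng.random(n) < config.partner_background_share)

    sex = _categorical(rng, n, config.sex_probs)
    age = np.maximum(rng.normal(config.age_mean_months, config.age_sd_months, n),
                     0.25)
    age_missing = rng.random(n) < config.age_missing_rate
    weight = np.maximum(rng.normal(config.weight_mean_kg, config.weight_sd_kg, n),
                        1.5)
    weight_missing = rng.random(n) < config.weight_missing_rate
    country = _categorical(rng, n, COUNTRIES)
    occupation = _categorical(rng, n, OCCUPATIONS)

    # per-report x per-term reaction probabilities
    prob = np.tile(rates, (n, 1))
    pt_index = {pt: j for j, pt in enumerate(pts)}
    for pt, mult in sorted(config.planted_signals.items()):
        prob[target, pt_index[pt]] *= mult
    for plant in config.stratum_planted:
        if plant.field == "age":
            member = (~age_missing) & (age >= plant.low) & (age < plant.high)
        elif plant.field == "weight":
            member = (~weight_missing) & (weight >= plant.low) & (weight < plant.high)
        elif plant.field == "sex":
            member = sex == plant.sex
        else:
            raise ValueError(f"unknown stratum field {plant.field!r}")
        prob[target & member, pt_index[plant.pt]] *= plant.multiplier
    combo = target & partner
    for pt, mult in sorted(config.combo_planted.items()):
        prob[combo, pt_index[pt]] *= mult
    if prob.max() > 1.0:
        raise ValueError("infeasible config: some reaction probability > 1")

    reactions = rng.random((n, n_terms)) < prob
    empty = ~reactions.any(axis=1)
    while empty.any():  # every report must carry at least one reaction
        idx = np.flatnonzero(empty)
        reactions[idx] = rng.random((len(idx), n_terms)) < prob[idx]
        empty = ~reactions.any(axis=1)

    # dates: FDA receipt within the quarter; therapy start before it
    span = (config.quarter_end - config.quarter_start).days + 1
    fda_offset = rng.integers(0, span, n)
    fda_dates = [config.quarter_start + _dt.timedelta(int(o)) for o in fda_offset]

    early = rng.random(n) < config.onset_early_weight
    onset_days = np.where(
        early, rng.geometric(config.onset_geometric_p, n) - 1,
        rng.integers(0, config.onset_tail_max_days + 1, n))
    extra_lag = rng.integers(0, 60, n)
    start_dates = [f - _dt.timedelta(int(o) + int(l))
                   for f, o, l in zip(fda_dates, onset_days, extra_lag)]
    event_dates = [s + _dt.timedelta(int(o))
                   for s, o in zip(start_dates, onset_days)]
    negative = rng.random(n) < config.negative_onset_rate
    neg_shift = rng.integers(1, 30, n)
    event_dates = [s - _dt.timedelta(int(k)) if isneg else e
                   for s, e, isneg, k in zip(start_dates, event_dates,
                                             negative, neg_shift)]
    event_missing = rng.random(n) < config.missing_date_rate
    event_partial = (~event_missing) & (rng.random(n) < config.partial_date_rate)
    start_missing = rng.random(n) < config.missing_date_rate / 2
    start_partial = (~start_missing) & (rng.random(n) < config.partial_date_rate / 2)

    event_tokens = np.array(_date_tokens(event_dates), dtype=object)
    event_tokens[event_partial] = [t[:6] for t in event_tokens[event_partial]]
    event_tokens[event_missing] = ""
    start_tokens = np.array(_date_tokens(start_dates), dtype=object)
    start_tokens[start_partial] = [t[:6] for t in start_tokens[start_partial]]
    start_tokens[start_missing] = ""

    # realized onset distribution among clean, non-negative target intervals
    clean = (target & ~negative & ~event_missing & ~event_partial
             & ~start_missing & ~start_partial)
    onset_first_month = (float(np.mean(onset_days[clean] < 30))
                         if clean.any() else float("nan"))

    outcome_draw = rng.random(n)
    outcome = np.full(n, "", dtype=object)
    has_outcome = outcome_draw < 0.56
    outcome[has_outcome] = _categorical(rng, int(has_outcome.sum()),
                                        OUTCOME_PROBS)

    # ---- assemble DEMO (original rows, then duplicate early versions) ----
    age_unit = np.where(rng.random(n) < 0.2, "YR", "MON")
    age_value = np.where(age_unit == "YR", np.round(age / 12.0, 2),
                         np.round(age, 1))
    demo = pd.DataFrame({
        "primaryid": primaryids.astype(str),
        "caseid": caseids,
        "fda_dt": _date_tokens(fda_dates),
        "event_dt": event_tokens,
        "sex": np.where(sex == "UNK", "", sex),
        "age": np.where(age_missing, "", age_value.astype(str)),
        "age_cod": np.where(age_missing, "", age_unit),
        "wt": np.where(weight_missing, "", np.round(weight, 1).astype(str)),
        "wt_cod": np.where(weight_missing, "", "KG"),
        "reporter_country": country,
        "occp_cod": np.where(occupation == "UNK", "", occupation),
    })

    n_dups = int(round(config.duplicate_rate * n))
    dup_idx = np.sort(rng.choice(n, size=n_dups, replace=False))
    same_day = rng.random(n_dups) < 0.2
    dup_lag = rng.integers(1, 21, n_dups)
    dup_rows = demo.iloc[dup_idx].copy()
    dup_rows["primaryid"] = (case_numbers[dup_idx] * 10 + 1).astype(str)
    dup_fda = [f if same else f - _dt.timedelta(int(l))
               for f, same, l in zip([fda_dates[i] for i in dup_idx],
                                     same_day, dup_lag)]
    dup_rows["fda_dt"] = _date_tokens(dup_fda)
    duplicate_pairs = [[d, o] for d, o in zip(dup_rows["primaryid"],
                                              demo["primaryid"].iloc[dup_idx])]
    demo_all = pd.concat([demo, dup_rows], ignore_index=True)

    # ---- DRUG / THER / REAC / OUTC / INDI rows ----
    drug_rows, ther_rows, indi_rows = [], [], []
    variant_target = rng.integers(0, len(TARGET_NAME_VARIANTS), n)
    variant_partner = rng.integers(0, len(PARTNER_NAME_VARIANTS), n)
    bg_drug = rng.integers(0, len(BACKGROUND_DRUGS), n)
    n_conmed = rng.poisson(1.2, n)
    conmed_names = [p[0] for p in CONMED_POOL if p[1] > 0]
    conmed_probs = np.array([p[1] for p in CONMED_POOL if p[1] > 0])
    conmed_probs = conmed_probs / conmed_probs.sum()
    conmed_choice = rng.choice(len(conmed_names), size=(n, 4), p=conmed_probs)

    for i in range(n):
        pid = str(primaryids[i])
        seq = 1
        if target[i]:
            drug_rows.append((pid, seq, role[i],
                              TARGET_NAME_VARIANTS[variant_target[i]],
                              "ONASEMNOGENE ABEPARVOVEC"))
            ther_rows.append((pid, seq, start_tokens[i], ""))
            indi_rows.append((pid, seq, "Spinal muscular atrophy"))
            if partner[i]:
                seq += 1
                drug_rows.append((pid, seq, "C",
                                  PARTNER_NAME_VARIANTS[variant_partner[i]],
                                  "NUSINERSEN"))
        elif partner_bg[i]:
            drug_rows.append((pid, seq, "PS",
                              PARTNER_NAME_VARIANTS[variant_partner[i]],
                              "NUSINERSEN"))
            ther_rows.append((pid, seq, start_tokens[i], ""))
            indi_rows.append((pid, seq, "Spinal muscular atrophy"))
        else:
            drug_rows.append((pid, seq, "PS", BACKGROUND_DRUGS[bg_drug[i]], ""))
            ther_rows.append((pid, seq, start_tokens[i], ""))
        for k in range(min(n_conmed[i], 4)):
            seq += 1
            drug_rows.append((pid, seq, "C",
                              conmed_names[conmed_choice[i, k]], ""))

    reac_pid, reac_pt = [], []
    rows_idx, cols_idx = np.nonzero(reactions)
    for i, j in zip(rows_idx, cols_idx):
        reac_pid.append(str(primaryids[i]))
        reac_pt.append(pts[j])

    outc_rows = [(str(primaryids[i]), outcome[i]) for i in range(n)
                 if outcome[i]]

    # duplicate versions copy their original's content rows
    dup_of = {str(case_numbers[i] * 10 + 2): str(case_numbers[i] * 10 + 1)
              for i in dup_idx}
    for source in (drug_rows, ther_rows, indi_rows, outc_rows):
        extra = [(dup_of[r[0]],) + tuple(r[1:]) for r in list(source)
                 if r[0] in dup_of]
        source.extend(extra)
    reac_extra_pid = [dup_of[p] for p in reac_pid if p in dup_of]
    reac_extra_pt = [t for p, t in zip(reac_pid, reac_pt) if p in dup_of]

    frames = {
        "demo": demo_all,
        "drug": pd.DataFrame(drug_rows, columns=["primaryid", "drug_seq",
                                                 "role_cod", "drugname",
                                                 "prod_ai"]),
        "reac": pd.DataFrame({"primaryid": reac_pid + reac_extra_pid,
                              "pt": reac_pt + reac_extra_pt}),
        "ther": pd.DataFrame(ther_rows, columns=["primaryid", "drug_seq",
                                                 "start_dt", "end_dt"]),
        "outc": pd.DataFrame(outc_rows, columns=["primaryid", "outc_cod"]),
        "indi": pd.DataFrame(indi_rows, columns=["primaryid", "indi_drug_seq",
                                                 "indi_pt"]),
    }
    outdir = Path(outdir)
    paths = fio.write_tables(frames, outdir)

    soc_frame = pd.DataFrame({"pt": pts, "soc": [s.soc for s in vocab]})
    soc_frame.to_csv(outdir / "soc_map.csv", index=False, lineterminator="\n")
    ime_frame = pd.DataFrame({"pt": [s.pt for s in vocab if s.is_ime]})
    ime_frame.to_csv(outdir / "ime_list.csv", index=False, lineterminator="\n")
    paths["soc_map"] = outdir / "soc_map.csv"
    paths["ime_list"] = outdir / "ime_list.csv"

    # ---- truth, recorded from the emission-time arrays ----
    target_ps = target & (role == "PS")
    comparator = ~target_ps
    a_counts = reactions[target_ps].sum(axis=0)
    c_counts = reactions[comparator].sum(axis=0)
    age_bands = {"age_0_6mo": int(((~age_missing) & (age < 6)).sum()),
                 "age_6_18mo": int(((~age_missing) & (age >= 6) & (age < 18)).sum()),
                 "age_ge_18mo": int(((~age_missing) & (age >= 18)).sum()),
                 "age_missing": int(age_missing.sum())}
    truth = SyntheticTruth(
        seed=config.seed,
        n_reports=n,
        n_emitted_demo_rows=len(demo_all),
        duplicate_pairs=duplicate_pairs,
        planted_signals=dict(sorted(config.planted_signals.items())),
        combo_planted=dict(sorted(config.combo_planted.items())),
        stratum_planted=[dataclasses.asdict(p) for p in config.stratum_planted],
        background_rates={s.pt: s.background_rate for s in vocab},
        target_case_counts={pt: int(a_counts[j]) for j, pt in enumerate(pts)},
        background_case_counts={pt: int(c_counts[j]) for j, pt in enumerate(pts)},
        n_target=int(target.sum()),
        n_target_ps=int(target_ps.sum()),
        n_background=int(comparator.sum()),
        n_combo=int((combo & (role == "PS")).sum()),
        n_mono_partner=int(partner_bg.sum()),
        onset_params={"early_weight": config.onset_early_weight,
                      "geometric_p": config.onset_geometric_p,
                      "tail_max_days": config.onset_tail_max_days},
        onset_first_month_share=onset_first_month,
        stratum_sizes=age_bands,
    )
    truth.to_json(outdir / "truth.json")
    paths["truth"] = outdir / "truth.json"
    return paths, truth


# ---------------------------------------------------------------------------
# recovery scoring


@dataclass
class RecoveryReport:
    sensitivity: float
    false_flag_rate: float
    n_planted: int
    n_null_screened: int
    rate_ratios: pd.DataFrame   # per planted PT: estimated vs true ratio


def truth_compare(result: ScreenResult, truth: SyntheticTruth) -> RecoveryReport:
    """Score a PT-level screen against the generator's truth manifest."""
    table = result.table
    unknown = set(table["term"]) - set(truth.background_rates)
    if unknown:
        raise ValueError(f"screened terms not in generator vocabulary: "
                         f"{sorted(unknown)[:5]}")
    flagged = set(table.loc[table["signal"] & ~table["excluded"], "term"])
    planted = set(truth.planted_signals)
    nulls = [pt for pt in table["term"] if pt not in planted]
    sensitivity = (len(flagged & planted) / len(planted)) if planted else float("nan")
    false_rate = (sum(1 for pt in nulls if pt in flagged) / len(nulls)
                  if nulls else 0.0)
    rows = []
    for pt in sorted(planted):
        a = truth.target_case_counts[pt]
        c = truth.background_case_counts[pt]
        est = ((a / truth.n_target_ps) / (c / truth.n_background)
               if a and c else float("nan"))
        rows.append({"pt": pt, "true_multiplier": truth.planted_signals[pt],
                     "estimated_rate_ratio": est, "flagged": pt in flagged})
    return RecoveryReport(sensitivity, false_rate, len(planted), len(nulls),
                          pd.DataFrame(rows))


def screen_generated(quarter_dir, thresholds=None, **screen_kwargs):
    """Parse an emitted quarter, deduplicate, build the PS cohort, screen."""
    quarter = fio.parse_quarter(fio.quarter_paths(quarter_dir))
    dedup = fio.deduplicate(quarter.demo.records)
    cohort = build_cases(quarter, dedup.retained_primaryids,
                         ONASEMNOGENE_LEXICON)
    ps = cohort.ps_cases
    background = build_background(quarter, dedup.retained_primaryids,
                                  [c.primaryid for c in ps])
    soc_map = load_soc_map(Path(quarter_dir) / "soc_map.csv")
    ime = load_ime_list(Path(quarter_dir) / "ime_list.csv")
    kwargs = dict(screen_kwargs)
    kwargs.setdefault("level", "PT")
    if thresholds is not None:
        kwargs["thresholds"] = thresholds
    return screen(ps, background, soc_map, ime, **kwargs), dedup, cohort


def run_recovery(seeds: Sequence[int], workdir,
                 config: Optional[GeneratorConfig] = None) -> pd.DataFrame:
    """Generate/screen/score one quarter per seed; one summary row each."""
    workdir = Path(workdir)
    rows = []
    for seed in seeds:
        cfg = dataclasses.replace(config or GeneratorConfig(), seed=int(seed))
        qdir = workdir / f"seed{seed}"
        _, truth = generate(cfg, qdir)
        result, _, _ = screen_generated(qdir)
        report = truth_compare(result, truth)
        rows.append({"seed": seed, "sensitivity": report.sensitivity,
                     "false_flag_rate": report.false_flag_rate,
                     "n_null_screened": report.n_null_screened})
    return pd.DataFrame(rows)
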