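"""Target-drug cohort assembly and PT annotation.

A report is one statistical unit. Reports naming the target drug are
collected into :class:`ReportCase` objects carrying demographics, the
report-level set of reaction PTs, outcomes, the target-drug therapy start
date and the set of co-reported drug names. Only cases where the target is
the primary suspect (PS) enter disproportionality screening; cases with the
target in a less suspect role are counted but excluded.

PT annotation maps each preferred term to its primary System Organ Class and
flags membership in an Important Medical Event (IME) list. Both maps are
user-supplied delimited files: MedDRA is licensed and is not bundled.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd

from .dates import ParsedDate
from .io import ParsedQuarter, TherRecord

logger = logging.getLogger(__name__)

# most-suspect-first ordering of drug role codes
ROLE_PRIORITY = {"PS": 0, "SS": 1, "C": 2, "I": 3}


def normalize_drugname(name: str) -> str:
    """Uppercase and collapse whitespace (FAERS drug names are free text)."""
    return " ".join(str(name).upper().split())


@dataclass(frozen=True)
class DrugLexicon:
    """Synonym sets identifying one drug: generic, trade and R&D code names."""

    generic_names: frozenset
    trade_names: frozenset
    rnd_codes: frozenset

    def __post_init__(self):
        for attr in ("generic_names", "trade_names", "rnd_codes"):
            object.__setattr__(self, attr, frozenset(
                normalize_drugname(n) for n in getattr(self, attr) if str(n).strip()))
        if not self.all_terms:
            raise ValueError("lexicon must contain at least one name")

    @property
    def all_terms(self) -> frozenset:
        return self.generic_names | self.trade_names | self.rnd_codes

    def matcher(self, mode: str = "word"):
        """Compile a predicate over normalized drug names.

        ``word``: any lexicon entry as a whole token inside the name (FAERS
        names carry dose/formulation suffixes); ``exact``: full-string match.
        """
        terms = sorted(self.all_terms, key=len, reverse=True)
        if mode == "exact":
            pool = frozenset(terms)
            return pool.__contains__
        if mode != "word":
            raise ValueError(f"unknown match mode {mode!r}")
        pattern = re.compile(
            "|".join(rf"(?<![A-Z0-9]){re.escape(t)}(?![A-Z0-9])" for t in terms))
        return lambda name: pattern.search(name) is not None


ONASEMNOGENE_LEXICON = DrugLexicon(
    generic_names=frozenset({"ONASEMNOGENE ABEPARVOVEC-XIOI",
                             "ONASEMNOGENE ABEPARVOVEC"}),
    trade_names=frozenset({"ZOLGENSMA"}),
    rnd_codes=frozenset({"AVXS-101", "OAV-101"}),
)

NUSINERSEN_LEXICON = DrugLexicon(
    generic_names=frozenset({"NUSINERSEN", "NUSINERSEN SODIUM"}),
    trade_names=frozenset({"SPINRAZA"}),
    rnd_codes=frozenset({"IONIS-SMNRX", "ISIS-SMNRX"}),
)


def match_target(drugname: str, lexicon: DrugLexicon, mode: str = "word") -> bool:
    """True iff the (normalized) drug name matches the lexicon."""
    return lexicon.matcher(mode)(normalize_drugname(drugname))


@dataclass(frozen=True)
class ReportCase:
    """One deduplicated safety report carrying the target drug."""

    primaryid: str
    caseid: str
    sex: str
    age_months: Optional[float]
    weight_kg: Optional[float]
    reporter_country: str
    occupation: str
    fda_dt: ParsedDate
    event_dt: Optional[ParsedDate]
    target_role: str
    reaction_pts: frozenset
    outcomes: frozenset
    therapy_start: Optional[ParsedDate]
    multiple_therapy: bool
    concomitant_drugnames: frozenset


@dataclass
class CohortResult:
    cases: list                 # all target-drug cases with >=1 reaction PT
    n_retained: int             # deduplicated reports scanned
    n_target: int               # reports naming the target in any role
    n_target_no_reaction: int   # target reports dropped for lacking REAC rows
    role_counts: dict = field(default_factory=dict)

    @property
    def ps_cases(self) -> list:
        return [c for c in self.cases if c.target_role == "PS"]

    def attrition(self) -> dict:
        return {
            "retained_reports": self.n_retained,
            "target_reports": self.n_target,
            "target_without_reactions": self.n_target_no_reaction,
            "target_cases": len(self.cases),
            "ps_cases": len(self.ps_cases),
            "target_role_counts": dict(sorted(self.role_counts.items())),
        }


def _earliest_full_start(ther_rows: Iterable[TherRecord]):
    starts = [t.start_dt for t in ther_rows
              if t.start_dt is not None and t.start_dt.is_full]
    if not starts:
        # fall back to a partial token so downstream exclusion can say "partial"
        partial = [t.start_dt for t in ther_rows if t.start_dt is not None]
        return (partial[0] if partial else None)
    return min(starts, key=lambda d: d.date)


def build_cases(quarter: ParsedQuarter, retained_ids: Iterable[str],
                lexicon: DrugLexicon, mode: str = "word") -> CohortResult:
    """Assemble one :class:`ReportCase` per retained target-drug report.

    ``target_role`` is the most suspect role the target carries in the report
    (PS > SS > C > I). Reports with the target drug but no reaction rows are
    excluded and counted.
    """
    retained = set(retained_ids)
    matches = lexicon.matcher(mode)

    drug_rows: dict[str, list] = {}
    for r in quarter.drug.records:
        if r.primaryid in retained:
            drug_rows.setdefault(r.primaryid, []).append(r)
    reac_rows: dict[str, set] = {}
    for r in quarter.reac.records:
        if r.primaryid in retained:
            reac_rows.setdefault(r.primaryid, set()).add(r.pt)
    ther_rows: dict[str, list] = {}
    for t in quarter.ther.records:
        ther_rows.setdefault(t.primaryid, []).append(t)
    outc_rows: dict[str, set] = {}
    for o in quarter.outc.records:
        outc_rows.setdefault(o.primaryid, set()).add(o.outcome)

    cases: list[ReportCase] = []
    n_target = 0
    n_no_reac = 0
    role_counts: dict[str, int] = {}
    for demo in quarter.demo.records:
        pid = demo.primaryid
        if pid not in retained:
            continue
        rows = drug_rows.get(pid, [])
        target_rows = []
        conmeds = set()
        for row in rows:
            name = normalize_drugname(row.drugname)
            if matches(name):
                target_rows.append(row)
            else:
                conmeds.add(name)
        if not target_rows:
            continue
        n_target += 1
        role = min((r.role for r in target_rows), key=ROLE_PRIORITY.__getitem__)
        role_counts[role] = role_counts.get(role, 0) + 1
        pts = reac_rows.get(pid, set())
        if not pts:
            n_no_reac += 1
            logger.debug("target report %s has no reaction rows; excluded", pid)
            continue
        target_seqs = {r.drug_seq for r in target_rows}
        target_ther = [t for t in ther_rows.get(pid, []) if t.drug_seq in target_seqs]
        start = _earliest_full_start(target_ther)
        n_full_starts = sum(1 for t in target_ther
                            if t.start_dt is not None and t.start_dt.is_full)
        cases.append(ReportCase(
            primaryid=pid, caseid=demo.caseid, sex=demo.sex,
            age_months=demo.age_months, weight_kg=demo.weight_kg,
            reporter_country=demo.reporter_country, occupation=demo.occupation,
            fda_dt=demo.fda_dt, event_dt=demo.event_dt, target_role=role,
            reaction_pts=frozenset(pts),
            outcomes=frozenset(outc_rows.get(pid, set())),
            therapy_start=start, multiple_therapy=n_full_starts > 1,
            concomitant_drugnames=frozenset(conmeds)))
    return CohortResult(cases, len(retained), n_target, n_no_reac, role_counts)


# ---------------------------------------------------------------------------
# PT -> SOC / IME annotation


@dataclass(frozen=True, slots=True)
class PtAnnotation:
    pt: str
    soc: str
    is_ime: bool


UNMAPPED_SOC = "UNMAPPED"
_warned_unmapped: set = set()


def annotate_pt(pt: str, soc_map: Mapping[str, str], ime_list) -> PtAnnotation:
    """Map a PT to its primary SOC and flag IME membership.

    Unmapped PTs get the explicit ``UNMAPPED`` SOC with a one-time warning.
    """
    soc = soc_map.get(pt)
    if soc is None:
        if pt not in _warned_unmapped:
            logger.warning("PT %r missing from the SOC map", pt)
            _warned_unmapped.add(pt)
        soc = UNMAPPED_SOC
    return PtAnnotation(pt, soc, pt in ime_list)


def load_soc_map(path) -> dict:
    """Load a two-column (pt, soc) delimited file into a dict."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    frame.columns = [c.strip().lower() for c in frame.columns]
    if not {"pt", "soc"} <= set(frame.columns):
        raise ValueError(f"{path}: SOC map needs 'pt' and 'soc' columns")
    return {" ".join(p.split()): " ".join(s.split())
            for p, s in zip(frame["pt"], frame["soc"]) if p.strip()}


def load_ime_list(path) -> frozenset:
    """Load a one-column (pt) delimited file of IME preferred terms."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    frame.columns = [c.strip().lower() for c in frame.columns]
    if "pt" not in frame.columns:
        raise ValueError(f"{path}: IME list needs a 'pt' column")
    return frozenset(" ".join(p.split()) for p in frame["pt"] if p.strip())


def load_lexicon(entries: Mapping[str, Iterable[str]]) -> DrugLexicon:
    return DrugLexicon(
        generic_names=frozenset(entries.get("generic_names", ())),
        trade_names=frozenset(entries.get("trade_names", ())),
        rnd_codes=frozenset(entries.get("rnd_codes", ())),
    )
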