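"""Reading and writing of FAERS-style quarterly ASCII tables.

FAERS quarters ship as dollar-delimited text files with one header row:
DEMO (demographics/administrative), DRUG (one row per drug per report, with
role codes PS/SS/C/I), REAC (one row per reported MedDRA preferred term),
THER (therapy start/end dates), OUTC (outcome codes), INDI (indications) and
RPSR (report sources, parsed but unused downstream).

Every well-formed row becomes one typed record; malformed rows are counted
per reason and logged, never silently dropped. Duplicate case versions are
collapsed by :func:`deduplicate`: keep the report with the latest FDA receipt
date per CASEID, breaking ties by the higher (numeric) PRIMARYID.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .dates import ParsedDate, parse_date

logger = logging.getLogger(__name__)

DELIMITER = "$"

SEXES = frozenset({"F", "M", "UNK"})
AGE_UNITS = frozenset({"DEC", "YR", "MON", "WK", "DY", "HR", "UNK"})
ROLE_CODES = frozenset({"PS", "SS", "C", "I"})
OUTCOME_CODES = frozenset({"DE", "LT", "HO", "DS", "CA", "RI", "OT"})

# months per unit of age (DEC = decade, HR uses 8766 h per mean year)
AGE_UNIT_TO_MONTHS = {
    "DEC": 120.0,
    "YR": 12.0,
    "MON": 1.0,
    "WK": 12.0 / 52.1429,
    "DY": 12.0 / 365.25,
    "HR": 12.0 / 8766.0,
}

_WEIGHT_TO_KG = {"KG": 1.0, "KGS": 1.0, "LBS": 0.45359237, "GMS": 0.001}


class FaersParseError(RuntimeError):
    """Unreadable file or missing mandatory column."""


@dataclass(frozen=True, slots=True)
class DemoRecord:
    primaryid: str
    caseid: str
    fda_dt: ParsedDate
    event_dt: Optional[ParsedDate]
    sex: str
    age_value: Optional[float]
    age_unit: str
    weight_kg: Optional[float]
    reporter_country: str
    occupation: str

    @property
    def age_months(self) -> Optional[float]:
        if self.age_value is None:
            return None
        factor = AGE_UNIT_TO_MONTHS.get(self.age_unit)
        return None if factor is None else self.age_value * factor


@dataclass(frozen=True, slots=True)
class DrugRecord:
    primaryid: str
    drug_seq: int
    role: str
    drugname: str
    active_ingredient: Optional[str] = None


@dataclass(frozen=True, slots=True)
class ReacRecord:
    primaryid: str
    pt: str


@dataclass(frozen=True, slots=True)
class TherRecord:
    primaryid: str
    drug_seq: int
    start_dt: Optional[ParsedDate]
    end_dt: Optional[ParsedDate]
    inconsistent: bool = False


@dataclass(frozen=True, slots=True)
class OutcRecord:
    primaryid: str
    outcome: str


@dataclass(frozen=True, slots=True)
class IndiRecord:
    primaryid: str
    drug_seq: Optional[int]
    indication_pt: str


@dataclass(slots=True)
class TableParse:
    """Parsed records of one table plus the acceptance/rejection ledger."""

    name: str
    records: list
    n_rows: int
    rejections: Counter = field(default_factory=Counter)

    @property
    def n_rejected(self) -> int:
        return sum(self.rejections.values())

    def check_conservation(self) -> bool:
        return len(self.records) + self.n_rejected == self.n_rows


@dataclass(slots=True)
class ParsedQuarter:
    demo: TableParse
    drug: TableParse
    reac: TableParse
    ther: TableParse
    outc: TableParse
    indi: TableParse
    rpsr: Optional[TableParse] = None

    def tables(self) -> list[TableParse]:
        out = [self.demo, self.drug, self.reac, self.ther, self.outc, self.indi]
        if self.rpsr is not None:
            out.append(self.rpsr)
        return out

    def parse_report(self) -> dict:
        """Per-table row/acceptance/rejection counts (JSON-serializable)."""
        return {
            t.name: {
                "rows": t.n_rows,
                "accepted": len(t.records),
                "rejected": t.n_rejected,
                "rejection_reasons": dict(sorted(t.rejections.items())),
            }
            for t in self.tables()
        }


def _normalize_ws(text: str) -> str:
    return " ".join(str(text).split())


def _read_table(path, mandatory: Sequence[str], aliases: Mapping[str, str]) -> pd.DataFrame:
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep=DELIMITER, dtype=str, keep_default_na=False,
                            engine="python")
    except OSError as exc:
        raise FaersParseError(f"cannot read {path}: {exc}") from exc
    except pd.errors.EmptyDataError as exc:
        raise FaersParseError(f"{path} has no header row") from exc
    frame.columns = [aliases.get(c.strip().lower(), c.strip().lower())
                     for c in frame.columns]
    for col in mandatory:
        if col not in frame.columns:
            raise FaersParseError(f"{path}: missing mandatory column {col!r}")
    return frame


def _opt_float(token: str) -> Optional[float]:
    token = token.strip()
    if not token:
        return None
    try:
        return float(token)
    except ValueError:
        return None


def _opt_int(token: str) -> Optional[int]:
    value = _opt_float(token)
    if value is None or value != int(value):
        return None
    return int(value)


def _parse_demo(path) -> TableParse:
    aliases = {"age": "age_value", "age_cod": "age_unit", "wt": "weight",
               "wt_cod": "weight_unit", "occp_cod": "occupation"}
    frame = _read_table(path, ["primaryid", "caseid", "fda_dt"], aliases)
    table = TableParse("demo", [], len(frame))
    seen: set[str] = set()
    get = frame.columns.__contains__
    for row in frame.itertuples(index=False):
        d = row._asdict()
        primaryid = d["primaryid"].strip()
        caseid = d["caseid"].strip()
        if not primaryid or not caseid:
            table.rejections["missing_identifier"] += 1
            continue
        if primaryid in seen:
            table.rejections["duplicate_primaryid"] += 1
            continue
        fda = parse_date(d["fda_dt"])
        if not fda.is_full:
            table.rejections["invalid_fda_dt"] += 1
            continue
        event_raw = d.get("event_dt", "").strip() if get("event_dt") else ""
        event = parse_date(event_raw) if event_raw else None
        sex = d.get("sex", "").strip().upper() if get("sex") else ""
        sex = sex if sex in SEXES else "UNK"
        age_value = _opt_float(d.get("age_value", "")) if get("age_value") else None
        if age_value is not None and age_value < 0:
            age_value = None
        age_unit = d.get("age_unit", "").strip().upper() if get("age_unit") else ""
        age_unit = age_unit if age_unit in AGE_UNITS else "UNK"
        weight = _opt_float(d.get("weight", "")) if get("weight") else None
        if weight is not None:
            unit = d.get("weight_unit", "KG").strip().upper() or "KG"
            weight = weight * _WEIGHT_TO_KG.get(unit, 1.0)
            if weight <= 0:
                weight = None
        country = _normalize_ws(d.get("reporter_country", "")) if get("reporter_country") else ""
        occupation = d.get("occupation", "").strip().upper() if get("occupation") else ""
        occupation = occupation if occupation in {"MD", "PH", "OT", "CN", "HP"} else "UNK"
        seen.add(primaryid)
        table.records.append(DemoRecord(primaryid, caseid, fda, event, sex,
                                        age_value, age_unit, weight, country,
                                        occupation))
    return table


def _parse_drug(path) -> TableParse:
    aliases = {"role_cod": "role", "prod_ai": "active_ingredient"}
    frame = _read_table(path, ["primaryid", "drug_seq", "role", "drugname"], aliases)
    table = TableParse("drug", [], len(frame))
    has_ai = "active_ingredient" in frame.columns
    for row in frame.itertuples(index=False):
        d = row._asdict()
        primaryid = d["primaryid"].strip()
        seq = _opt_int(d["drug_seq"])
        role = d["role"].strip().upper()
        name = _normalize_ws(d["drugname"])
        if not primaryid:
            table.rejections["missing_identifier"] += 1
        elif seq is None or seq <= 0:
            table.rejections["invalid_drug_seq"] += 1
        elif role not in ROLE_CODES:
            table.rejections["invalid_role"] += 1
        elif not name:
            table.rejections["empty_drugname"] += 1
        else:
            ai = _normalize_ws(d.get("active_ingredient", "")) or None if has_ai else None
            table.records.append(DrugRecord(primaryid, seq, role, name, ai))
    return table


def _parse_reac(path) -> TableParse:
    frame = _read_table(path, ["primaryid", "pt"], {})
    table = TableParse("reac", [], len(frame))
    for row in frame.itertuples(index=False):
        d = row._asdict()
        primaryid = d["primaryid"].strip()
        pt = _normalize_ws(d["pt"])
        if not primaryid:
            table.rejections["missing_identifier"] += 1
        elif not pt:
            table.rejections["empty_pt"] += 1
        else:
            table.records.append(ReacRecord(primaryid, pt))
    return table


def _parse_ther(path) -> TableParse:
    aliases = {"dsg_drug_seq": "drug_seq"}
    frame = _read_table(path, ["primaryid", "drug_seq"], aliases)
    table = TableParse("ther", [], len(frame))
    for row in frame.itertuples(index=False):
        d = row._asdict()
        primaryid = d["primaryid"].strip()
        seq = _opt_int(d["drug_seq"])
        if not primaryid:
            table.rejections["missing_identifier"] += 1
            continue
        if seq is None or seq <= 0:
            table.rejections["invalid_drug_seq"] += 1
            continue
        start_raw = d.get("start_dt", "").strip()
        end_raw = d.get("end_dt", "").strip()
        start = parse_date(start_raw) if start_raw else None
        end = parse_date(end_raw) if end_raw else None
        inconsistent = (start is not None and end is not None
                        and start.is_full and end.is_full
                        and end.date < start.date)
        table.records.append(TherRecord(primaryid, seq, start, end, inconsistent))
    return table


def _parse_outc(path) -> TableParse:
    aliases = {"outc_cod": "outcome", "outc_code": "outcome"}
    frame = _read_table(path, ["primaryid", "outcome"], aliases)
    table = TableParse("outc", [], len(frame))
    for row in frame.itertuples(index=False):
        d = row._asdict()
        primaryid = d["primaryid"].strip()
        outcome = d["outcome"].strip().upper()
        if not primaryid:
            table.rejections["missing_identifier"] += 1
        elif outcome not in OUTCOME_CODES:
            table.rejections["invalid_outcome"] += 1
        else:
            table.records.append(OutcRecord(primaryid, outcome))
    return table


def _parse_indi(path) -> TableParse:
    aliases = {"indi_drug_seq": "drug_seq", "indi_pt": "indication_pt"}
    frame = _read_table(path, ["primaryid"], aliases)
    table = TableParse("indi", [], len(frame))
    has_seq = "drug_seq" in frame.columns
    has_pt = "indication_pt" in frame.columns
    for row in frame.itertuples(index=False):
        d = row._asdict()
        primaryid = d["primaryid"].strip()
        if not primaryid:
            table.rejections["missing_identifier"] += 1
            continue
        seq = _opt_int(d.get("drug_seq", "")) if has_seq else None
        pt = _normalize_ws(d.get("indication_pt", "")) if has_pt else ""
        table.records.append(IndiRecord(primaryid, seq, pt))
    return table


def _parse_rpsr(path) -> TableParse:
    frame = _read_table(path, ["primaryid"], {})
    table = TableParse("rpsr", [], len(frame))
    for row in frame.itertuples(index=False):
        d = row._asdict()
        primaryid = d["primaryid"].strip()
        if not primaryid:
            table.rejections["missing_identifier"] += 1
        else:
            table.records.append(dict(d))
    return table


_PARSERS = {"demo": _parse_demo, "drug": _parse_drug, "reac": _parse_reac,
            "ther": _parse_ther, "outc": _parse_outc, "indi": _parse_indi,
            "rpsr": _parse_rpsr}


def parse_quarter(paths: Mapping[str, object]) -> ParsedQuarter:
    """Parse one quarter's tables from ``{table_name: path}``.

    The six analysis tables (demo, drug, reac, ther, outc, indi) are
    required; ``rpsr`` is parsed when supplied but unused downstream.
    """
    parsed = {}
    for name in ("demo", "drug", "reac", "ther", "outc", "indi"):
        if name not in paths:
            raise FaersParseError(f"missing table {name!r} in paths")
        parsed[name] = _PARSERS[name](paths[name])
    if "rpsr" in paths:
        parsed["rpsr"] = _parse_rpsr(paths["rpsr"])
    quarter = ParsedQuarter(**parsed)
    for t in quarter.tables():
        if t.n_rejected:
            logger.warning("%s: rejected %d/%d rows (%s)", t.name,
                           t.n_rejected, t.n_rows, dict(t.rejections))
    return quarter


def quarter_paths(directory, suffix: str = ".txt") -> dict:
    """Locate table files in ``directory`` by conventional name prefixes."""
    directory = Path(directory)
    out = {}
    for name in ("demo", "drug", "reac", "ther", "outc", "indi", "rpsr"):
        hits = sorted(directory.glob(f"{name.upper()}*{suffix}"))
        if hits:
            out[name] = hits[0]
    return out


# ---------------------------------------------------------------------------
# deduplication


@dataclass(slots=True)
class DedupResult:
    retained: list          # retained DemoRecords, input order
    dropped_primaryids: set
    attrition: int

    @property
    def retained_primaryids(self) -> set:
        return {r.primaryid for r in self.retained}


def _primaryid_sort_keys(group: Sequence[DemoRecord]):
    try:
        return {r.primaryid: int(r.primaryid) for r in group}
    except ValueError:
        logger.warning("non-numeric primaryid among %s; falling back to "
                       "lexicographic tie-break",
                       [r.primaryid for r in group][:5])
        return {r.primaryid: r.primaryid for r in group}


def deduplicate(demo: Iterable[DemoRecord]) -> DedupResult:
    """Keep one report per CASEID: latest FDA_DT, then higher PRIMARYID.

    Idempotent; output size equals the number of distinct caseids.
    """
    demo = list(demo)
    by_case: dict[str, list[DemoRecord]] = {}
    for record in demo:
        by_case.setdefault(record.caseid, []).append(record)
    keep: set[str] = set()
    for group in by_case.values():
        if len(group) == 1:
            keep.add(group[0].primaryid)
            continue
        keys = _primaryid_sort_keys(group)
        best = max(group, key=lambda r: (r.fda_dt.date, keys[r.primaryid]))
        keep.add(best.primaryid)
    retained = [r for r in demo if r.primaryid in keep]
    dropped = {r.primaryid for r in demo} - keep
    return DedupResult(retained, dropped, len(demo) - len(retained))


# ---------------------------------------------------------------------------
# writing (round-trips through parse_quarter; also used by the generator)


def write_tables(frames: Mapping[str, pd.DataFrame], directory,
                 suffix: str = ".txt") -> dict:
    """Write ``{table_name: DataFrame}`` in the dollar-delimited dialect."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, frame in frames.items():
        path = directory / f"{name.upper()}{suffix}"
        frame.to_csv(path, sep=DELIMITER, index=False, lineterminator="\n")
        paths[name] = path
    return paths


def _date_token(d: Optional[ParsedDate]) -> str:
    return "" if d is None else d.to_token()


def records_to_frames(quarter: ParsedQuarter) -> dict:
    """Render parsed records back into writable tables (field-faithful)."""
    demo = pd.DataFrame(
        [{"primaryid": r.primaryid, "caseid": r.caseid,
          "fda_dt": r.fda_dt.to_token(), "event_dt": _date_token(r.event_dt),
          "sex": "" if r.sex == "UNK" else r.sex,
          "age": "" if r.age_value is None else repr(r.age_value),
          "age_cod": "" if r.age_unit == "UNK" else r.age_unit,
          "wt": "" if r.weight_kg is None else repr(r.weight_kg),
          "wt_cod": "" if r.weight_kg is None else "KG",
          "reporter_country": r.reporter_country,
          "occp_cod": "" if r.occupation == "UNK" else r.occupation}
         for r in quarter.demo.records])
    drug = pd.DataFrame(
        [{"primaryid": r.primaryid, "drug_seq": r.drug_seq, "role_cod": r.role,
          "drugname": r.drugname, "prod_ai": r.active_ingredient or ""}
         for r in quarter.drug.records])
    reac = pd.DataFrame([{"primaryid": r.primaryid, "pt": r.pt}
                         for r in quarter.reac.records])
    ther = pd.DataFrame(
        [{"primaryid": r.primaryid, "drug_seq": r.drug_seq,
          "start_dt": _date_token(r.start_dt), "end_dt": _date_token(r.end_dt)}
         for r in quarter.ther.records])
    outc = pd.DataFrame([{"primaryid": r.primaryid, "outc_cod": r.outcome}
                         for r in quarter.outc.records])
    indi = pd.DataFrame(
        [{"primaryid": r.primaryid,
          "indi_drug_seq": "" if r.drug_seq is None else r.drug_seq,
          "indi_pt": r.indication_pt}
         for r in quarter.indi.records])
    return {"demo": demo, "drug": drug, "reac": reac, "ther": ther,
            "outc": outc, "indi": indi}


def write_parse_report(quarter: ParsedQuarter, path) -> None:
    Path(path).write_text(json.dumps(quarter.parse_report(), indent=2,
                                     sort_keys=True) + "\n")
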