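"""Stratified re-screening and between-stratum contrasts.

Subgroup screens re-run the full four-algorithm screen on a stratum of the
target cohort against the unchanged background. Between-stratum contrasts
compare PT reporting *within* the target cohort via a 2x2 of
(stratum x PT presence): the sex contrast (with volcano-plot coordinates)
and threshold contrasts for weight (e.g. the 8.5 kg cut) and age in months
(e.g. the 8-month cut), which feed forest plots.

p-values are two-sided Wald z on ln ROR, matching the ROR-CI framework; a
Fisher exact alternative is available for small cells. A Benjamini–Hochberg
column is emitted for reference but never gates output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import ReportCase, annotate_pt
from .dispro import (Background, ScreenResult, Thresholds, DEFAULT_THRESHOLDS,
                     Z95, screen)

MISSING_STRATUM = "missing"


@dataclass(frozen=True)
class StratumSpec:
    """A reusable subset definition over report cases.

    ``getter`` extracts the stratifying value (may be None = missing);
    ``predicate`` decides membership given a non-missing value.
    """

    name: str
    getter: Callable[[ReportCase], object]
    predicate: Callable[[object], bool]

    def status(self, case: ReportCase) -> str:
        value = self.getter(case)
        if value is None:
            return MISSING_STRATUM
        return "in" if self.predicate(value) else "out"

    def members(self, cases: Sequence[ReportCase]) -> list:
        return [c for c in cases if self.status(c) == "in"]


def sex_stratum(sex: str) -> StratumSpec:
    return StratumSpec(f"sex_{sex}",
                       lambda c: None if c.sex == "UNK" else c.sex,
                       lambda v: v == sex)


def age_band_months(low: float, high: float = math.inf,
                    name: Optional[str] = None) -> StratumSpec:
    """Closed-open age band [low, high) in months."""
    label = name or (f"age_{low:g}_{high:g}mo" if math.isfinite(high)
                     else f"age_ge_{low:g}mo")
    return StratumSpec(label, lambda c: c.age_months,
                       lambda v: low <= v < high)


def weight_band(low: float, high: float = math.inf,
                name: Optional[str] = None) -> StratumSpec:
    label = name or (f"wt_{low:g}_{high:g}kg" if math.isfinite(high)
                     else f"wt_ge_{low:g}kg")
    return StratumSpec(label, lambda c: c.weight_kg,
                       lambda v: low <= v < high)


def occupation_stratum(code: str) -> StratumSpec:
    return StratumSpec(f"reporter_{code}",
                       lambda c: None if c.occupation == "UNK" else c.occupation,
                       lambda v: v == code)


DEFAULT_AGE_BANDS = (age_band_months(0, 6), age_band_months(6, 18),
                     age_band_months(18))


def partition(cases: Sequence[ReportCase],
              specs: Sequence[StratumSpec]) -> dict:
    """Split cases over disjoint strata plus an explicit missing stratum.

    Cases matching none of the specs (and not missing) land in ``"other"``.
    Stratum sizes, including missing/other, always sum to the input size.
    """
    out: dict[str, list] = {spec.name: [] for spec in specs}
    out[MISSING_STRATUM] = []
    out["other"] = []
    for case in cases:
        statuses = [spec.status(case) for spec in specs]
        hits = [spec.name for spec, s in zip(specs, statuses) if s == "in"]
        if hits:
            out[hits[0]].append(case)
        elif all(s == MISSING_STRATUM for s in statuses):
            out[MISSING_STRATUM].append(case)
        else:
            out["other"].append(case)
    return out


def stratified_screen(cases: Sequence[ReportCase], spec: StratumSpec,
                      background: Background, soc_map: Mapping[str, str],
                      ime_list, **screen_kwargs) -> ScreenResult:
    """Run the standard screen on one stratum against the full background."""
    return screen(spec.members(cases), background, soc_map, ime_list,
                  **screen_kwargs)


def exclusive_pt_sets(cases_a: Sequence[ReportCase],
                      cases_b: Sequence[ReportCase],
                      signal_tables: Optional[tuple] = None):
    """Partition reported PTs into (only in A, only in B, shared).

    Presence-based by default; pass two screen tables as ``signal_tables``
    to restrict each side to its joint-criteria signals instead.
    """
    if signal_tables is None:
        pts_a = {pt for c in cases_a for pt in c.reaction_pts}
        pts_b = {pt for c in cases_b for pt in c.reaction_pts}
    else:
        ta, tb = signal_tables
        pts_a = set(ta.table.loc[ta.table["signal"], "term"])
        pts_b = set(tb.table.loc[tb.table["signal"], "term"])
    return pts_a - pts_b, pts_b - pts_a, pts_a & pts_b


# ---------------------------------------------------------------------------
# contrasts


_CONTRAST_COLUMNS = ["pt", "soc", "a1", "b1", "a2", "b2", "ror", "ror_low",
                     "ror_high", "p_value", "p_bh", "log2_ror",
                     "neg_log10_p", "significant", "zero_corrected", "status"]


def _contrast_row(a1: int, b1: int, a2: int, b2: int,
                  method: str = "wald") -> dict:
    """2x2 stratum-vs-stratum ROR, Wald CI and p (or Fisher exact p)."""
    corrected = 0 in (a1, b1, a2, b2)
    aa, bb, cc, dd = ((x + 0.5 for x in (a1, b1, a2, b2)) if corrected
                      else (float(a1), float(b1), float(a2), float(b2)))
    aa, bb, cc, dd = float(aa), float(bb), float(cc), float(dd)
    log_ror = math.log(aa * dd / (bb * cc))
    se = math.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    if method == "wald":
        z = log_ror / se
        p = 2.0 * stats.norm.sf(abs(z))
    elif method == "fisher":
        p = float(stats.fisher_exact([[a1, b1], [a2, b2]])[1])
    else:
        raise ValueError(f"unknown p-value method {method!r}")
    ror = math.exp(log_ror)
    p = min(p, 1.0)
    return {"a1": a1, "b1": b1, "a2": a2, "b2": b2, "ror": ror,
            "ror_low": math.exp(log_ror - Z95 * se),
            "ror_high": math.exp(log_ror + Z95 * se),
            "p_value": p, "log2_ror": log_ror / math.log(2),
            "neg_log10_p": -math.log10(p) if p > 0 else math.inf,
            "significant": p < 0.05, "zero_corrected": corrected,
            "status": "ok"}


def _bh_adjust(p: pd.Series) -> pd.Series:
    p = p.to_numpy(dtype=float)
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank in range(n - 1, -1, -1):
        idx = order[rank]
        running = min(running, p[idx] * n / (rank + 1))
        adj[idx] = running
    return pd.Series(adj)


def _pt_counts(cases: Sequence[ReportCase], pts: Iterable[str]) -> dict:
    counts = {pt: 0 for pt in pts}
    for case in cases:
        for pt in case.reaction_pts:
            if pt in counts:
                counts[pt] += 1
    return counts


def contrast_table(cases_1: Sequence[ReportCase],
                   cases_2: Sequence[ReportCase],
                   pts: Iterable[str],
                   soc_map: Optional[Mapping[str, str]] = None,
                   method: str = "wald") -> pd.DataFrame:
    """Per-PT 2x2 contrast of group 1 vs group 2 within the target cohort."""
    pts = sorted(set(pts))
    n1, n2 = len(cases_1), len(cases_2)
    c1 = _pt_counts(cases_1, pts)
    c2 = _pt_counts(cases_2, pts)
    rows = []
    for pt in pts:
        row = _contrast_row(c1[pt], n1 - c1[pt], c2[pt], n2 - c2[pt], method)
        row["pt"] = pt
        row["soc"] = (annotate_pt(pt, soc_map, frozenset()).soc
                      if soc_map is not None else "")
        rows.append(row)
    frame = pd.DataFrame(rows)
    frame["p_bh"] = _bh_adjust(frame["p_value"]) if len(frame) else []
    frame = frame[_CONTRAST_COLUMNS]
    if soc_map is not None:
        frame = frame.sort_values(["soc", "pt"], kind="mergesort")
    else:
        frame = frame.sort_values("pt", kind="mergesort")
    return frame.reset_index(drop=True)


def sex_contrast(cases: Sequence[ReportCase],
                 pts: Optional[Iterable[str]] = None,
                 soc_map: Optional[Mapping[str, str]] = None,
                 method: str = "wald") -> pd.DataFrame:
    """Female-vs-male contrast over PTs shared by both sexes.

    ROR > 1 marks female-biased reporting, < 1 male-biased. Columns include
    volcano coordinates (log2 ROR, −log10 p) and a p < 0.05 significance
    mark; they are pure functions of the count columns.
    """
    females = [c for c in cases if c.sex == "F"]
    males = [c for c in cases if c.sex == "M"]
    if not females or not males:
        raise ValueError("both sexes must have non-zero cohort sizes")
    if pts is None:
        _, _, pts = exclusive_pt_sets(females, males)
    return contrast_table(females, males, pts, soc_map, method)


@dataclass
class ThresholdContrast:
    table: pd.DataFrame
    variable: str
    cut: float
    n_above: int
    n_below: int
    n_missing: int
    status: str = "ok"


def threshold_contrast(cases: Sequence[ReportCase], variable: str, cut: float,
                       pts: Optional[Iterable[str]] = None,
                       soc_map: Optional[Mapping[str, str]] = None,
                       method: str = "wald") -> ThresholdContrast:
    """Above-vs-below-cut contrast (e.g. weight 8.5 kg, age 8 months).

    Cases missing the stratifying variable are excluded and counted. If all
    cases fall on one side of the cut the result carries a degenerate
    status and no statistics.
    """
    getter = {"weight": lambda c: c.weight_kg,
              "age": lambda c: c.age_months}.get(variable)
    if getter is None:
        raise ValueError(f"unknown contrast variable {variable!r}")
    above, below, missing = [], [], 0
    for case in cases:
        value = getter(case)
        if value is None:
            missing += 1
        elif value >= cut:
            above.append(case)
        else:
            below.append(case)
    if not above or not below:
        return ThresholdContrast(pd.DataFrame(columns=_CONTRAST_COLUMNS),
                                 variable, cut, len(above), len(below),
                                 missing, status="degenerate stratum")
    if pts is None:
        _, _, pts = exclusive_pt_sets(above, below)
    table = contrast_table(above, below, pts, soc_map, method)
    return ThresholdContrast(table, variable, cut, len(above), len(below),
                             missing)
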