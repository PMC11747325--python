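"""Disproportionality statistics over 2x2 contingency tables.

For each term (MedDRA PT, or SOC grouping), reports are cross-classified as

    ==============  ============  ============
                    term present  term absent
    target drug         a             b
    all other drugs     c             d
    ==============  ============  ============

and four conventional algorithms are evaluated:

* ROR  = ad/bc with a Wald 95% CI on the log scale;
* PRR  = [a/(a+b)] / [c/(c+d)] with a Pearson chi-square (no continuity
  correction);
* BCPNN information component, IC = log2 of the shrunk observed/expected
  ratio with an approximate 2.5th-percentile lower bound (IC025);
* MGPS empirical-Bayes geometric mean (EBGM) with its 5th-percentile lower
  bound (EB05), either as the simplified observed/expected form or via a
  two-component gamma-mixture prior fitted by EM (see :mod:`faerspv.mgps`).

A term is a signal only when all four criteria pass jointly. Zero cells are
handled by the Haldane–Anscombe correction (+0.5 to every cell, applied only
when some cell is zero and only to ROR/PRR and their intervals); affected
rows are flagged. Statistics that remain undefined (e.g. a = 0) are reported
as ``None`` and fail their criterion rather than erroring.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .cohort import PtAnnotation, ReportCase, annotate_pt
from .io import ParsedQuarter
from . import mgps

logger = logging.getLogger(__name__)

Z95 = 1.959963984540054   # two-sided 95% normal quantile
Z90 = 1.6448536269514722  # one-sided 95% (EB05 log-normal approximation)
FIXED_IC_OFFSET = 1.67    # fixed IC - IC025 gap of the fixed_offset dialect


@dataclass(frozen=True, slots=True)
class ContingencyTable:
    a: int  # target drug, target event
    b: int  # target drug, other events
    c: int  # other drugs, target event
    d: int  # other drugs, other events

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")
        if self.N == 0:
            raise ValueError("empty contingency table")

    @property
    def N(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def has_zero_cell(self) -> bool:
        return min(self.a, self.b, self.c, self.d) == 0

    @property
    def expected_a(self) -> float:
        """Expected target-event count under independence, (a+b)(a+c)/N."""
        return (self.a + self.b) * (self.a + self.c) / self.N

    def corrected(self) -> tuple[float, float, float, float]:
        """Cells after the Haldane–Anscombe +0.5 (only if some cell is 0)."""
        if self.has_zero_cell:
            return (self.a + 0.5, self.b + 0.5, self.c + 0.5, self.d + 0.5)
        return (float(self.a), float(self.b), float(self.c), float(self.d))


@dataclass
class SignalMetrics:
    term: str
    a: int
    ror: Optional[float] = None
    ror_low: Optional[float] = None
    ror_high: Optional[float] = None
    prr: Optional[float] = None
    chi2: Optional[float] = None
    ic: Optional[float] = None
    ic025: Optional[float] = None
    ebgm: Optional[float] = None
    ebgm05: Optional[float] = None
    zero_corrected: bool = False

    @property
    def case_count(self) -> int:
        return self.a


@dataclass(frozen=True)
class Thresholds:
    """Joint signal criteria (the conventional four-algorithm standards)."""

    min_a: int = 3
    ror_low_gt: float = 1.0
    prr_min: float = 2.0
    chi2_min: float = 4.0
    ic025_gt: float = 0.0
    ebgm05_gt: float = 2.0


DEFAULT_THRESHOLDS = Thresholds()


# ---------------------------------------------------------------------------
# the four estimators


def ror_stat(t: ContingencyTable, zero_policy: str = "haldane"):
    """ROR = ad/bc with Wald 95% CI exp(ln ROR ± 1.96·√(Σ 1/cell)).

    Returns ``(ror, low, high, corrected_flag)``; all ``None`` when a cell is
    zero and ``zero_policy`` is ``"none"``.
    """
    if t.has_zero_cell and zero_policy == "none":
        return None, None, None, False
    a, b, c, d = t.corrected()
    log_ror = math.log(a) + math.log(d) - math.log(b) - math.log(c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return (math.exp(log_ror), math.exp(log_ror - Z95 * se),
            math.exp(log_ror + Z95 * se), t.has_zero_cell)


def prr_chi2_stat(t: ContingencyTable, zero_policy: str = "haldane"):
    """PRR on (optionally corrected) cells; Pearson chi2 on the raw cells.

    chi2 = N(ad−bc)² / [(a+b)(c+d)(a+c)(b+d)], without Yates correction;
    it is ``None`` when any margin of the raw table is zero.
    """
    if t.has_zero_cell and zero_policy == "none":
        prr = None
    else:
        a, b, c, d = t.corrected()
        prr = (a / (a + b)) / (c / (c + d))
    margins = ((t.a + t.b), (t.c + t.d), (t.a + t.c), (t.b + t.d))
    if min(margins) == 0:
        chi2 = None
    else:
        num = t.N * (t.a * t.d - t.b * t.c) ** 2
        chi2 = num / (margins[0] * margins[1] * margins[2] * margins[3])
    return prr, chi2


def ic_stat(t: ContingencyTable, dialect: str = "canonical",
            ebgm: Optional[float] = None):
    """BCPNN information component and its lower credibility bound.

    ``canonical``: IC = log2[(a+0.5)/(E+0.5)] with E = (a+b)(a+c)/N, and
    IC025 = IC − 3.3(a+0.5)^(−1/2) − 2(a+0.5)^(−3/2) (shrinkage
    observed/expected form with the standard credibility approximation).

    ``fixed_offset``: IC = log2(EBGM) and IC025 = IC − 1.67, the
    dialect matching published screening tables where the IC column is the
    base-2 log of the EBGM column and the interval gap is constant.
    """
    if dialect == "canonical":
        shrunk = (t.a + 0.5) / (t.expected_a + 0.5)
        ic = math.log2(shrunk)
        ic025 = ic - 3.3 * (t.a + 0.5) ** -0.5 - 2.0 * (t.a + 0.5) ** -1.5
        return ic, ic025
    if dialect == "fixed_offset":
        if t.a == 0 or ebgm is None or ebgm <= 0:
            return None, None
        ic = math.log2(ebgm)
        return ic, ic - FIXED_IC_OFFSET
    raise ValueError(f"unknown IC dialect {dialect!r}")


def ebgm_stat(t: ContingencyTable, method: str = "simplified_oe",
              prior: Optional[mgps.GammaMixture] = None):
    """Empirical-Bayes geometric mean and 5th-percentile lower bound.

    ``simplified_oe``: EBGM = a/E with EB05 = EBGM·exp(−1.645·√(Σ 1/cell))
    (log-normal approximation on the observed/expected ratio).

    ``mgps_em`` requires a gamma-mixture ``prior`` fitted over all screened
    terms (:func:`faerspv.mgps.fit_gamma_mixture_em`); EBGM is the posterior
    geometric mean of the shrunk ratio and EB05 the posterior 5th percentile
    by numerical quantile inversion.
    """
    expected = t.expected_a
    if expected <= 0 or t.a == 0:
        return None, None
    if method == "simplified_oe":
        ebgm = t.a / expected
        a, b, c, d = t.corrected()
        se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        return ebgm, ebgm * math.exp(-Z90 * se)
    if method == "mgps_em":
        if prior is None:
            raise ValueError("mgps_em needs a fitted gamma-mixture prior")
        ebgm = mgps.posterior_ebgm([t.a], [expected], prior)[0]
        eb05 = mgps.posterior_quantile([t.a], [expected], prior, 0.05)[0]
        return float(ebgm), float(eb05)
    raise ValueError(f"unknown EBGM method {method!r}")


def compute_metrics(term: str, t: ContingencyTable,
                    ic_dialect: str = "canonical",
                    ebgm_method: str = "simplified_oe",
                    prior: Optional[mgps.GammaMixture] = None,
                    zero_policy: str = "haldane") -> SignalMetrics:
    ror, low, high, corrected = ror_stat(t, zero_policy)
    prr, chi2 = prr_chi2_stat(t, zero_policy)
    ebgm, ebgm05 = ebgm_stat(t, ebgm_method, prior)
    # in the fixed-offset dialect the IC column is log2 of the EBGM column
    ic, ic025 = ic_stat(t, ic_dialect, ebgm=ebgm)
    return SignalMetrics(term=term, a=t.a, ror=ror, ror_low=low, ror_high=high,
                         prr=prr, chi2=chi2, ic=ic, ic025=ic025, ebgm=ebgm,
                         ebgm05=ebgm05, zero_corrected=corrected)


def evaluate_signal(m: SignalMetrics,
                    th: Thresholds = DEFAULT_THRESHOLDS) -> dict:
    """Per-algorithm verdicts plus the joint all-four verdict.

    An undefined (``None``) statistic fails its criterion, never errors.
    """
    def ok(value, bound, strict=False):
        if value is None:
            return False
        return value > bound if strict else value >= bound

    enough = m.a >= th.min_a
    verdicts = {
        "ror": enough and ok(m.ror_low, th.ror_low_gt, strict=True),
        "prr": enough and ok(m.prr, th.prr_min) and ok(m.chi2, th.chi2_min),
        "bcpnn": ok(m.ic025, th.ic025_gt, strict=True),
        "mgps": ok(m.ebgm05, th.ebgm05_gt, strict=True),
    }
    verdicts["joint"] = all(verdicts.values())
    return verdicts


# ---------------------------------------------------------------------------
# background index and table construction


@dataclass
class Background:
    """Event-count index over the comparator reports (non-target universe)."""

    n_reports: int
    n_pairs: int                       # total (report, PT) pairs
    pt_counts: Counter                 # PT -> number of reports mentioning it
    report_pt_sets: list = field(default_factory=list)

    def soc_report_count(self, soc_pts: frozenset) -> int:
        return sum(1 for pts in self.report_pt_sets if pts & soc_pts)

    def soc_pair_count(self, soc_pts: frozenset) -> int:
        return sum(n for pt, n in self.pt_counts.items() if pt in soc_pts)


def build_background(quarter: ParsedQuarter, retained_ids: Iterable[str],
                     exclude_primaryids: Iterable[str]) -> Background:
    """Index all retained reports except the target cohort.

    The comparator universe is "all other reports in the loaded quarters";
    target-PS reports are excluded via ``exclude_primaryids``.
    """
    retained = set(retained_ids)
    excluded = set(exclude_primaryids)
    per_report: dict[str, set] = {}
    for r in quarter.reac.records:
        pid = r.primaryid
        if pid in retained and pid not in excluded:
            per_report.setdefault(pid, set()).add(r.pt)
    # reports with no reactions still belong to the universe denominator
    n_reports = len(retained - excluded)
    counts: Counter = Counter()
    sets = []
    for pts in per_report.values():
        fs = frozenset(pts)
        sets.append(fs)
        counts.update(fs)
    return Background(n_reports=n_reports, n_pairs=sum(counts.values()),
                      pt_counts=counts, report_pt_sets=sets)


def build_table(cases: Sequence[ReportCase], background: Background,
                term: str, level: str = "PT", unit: str = "report",
                soc_map: Optional[Mapping[str, str]] = None) -> ContingencyTable:
    """Cross-classify the cohort and background for one PT or SOC.

    ``unit="report"`` counts reports (presence/absence); ``unit="occurrence"``
    counts distinct (report, PT) pairs, which at SOC level reproduces tables
    whose SOC case numbers exceed the report total.
    """
    if level not in {"PT", "SOC"}:
        raise ValueError(f"unknown level {level!r}")
    if unit not in {"report", "occurrence"}:
        raise ValueError(f"unknown unit {unit!r}")
    if level == "SOC":
        if soc_map is None:
            raise ValueError("SOC-level tables need a soc_map")
        soc_pts = frozenset(pt for pt, soc in soc_map.items() if soc == term)
        member = lambda pts: pts & soc_pts
        a_units = (sum(1 for case in cases if member(case.reaction_pts))
                   if unit == "report"
                   else sum(len(member(case.reaction_pts)) for case in cases))
        c_units = (background.soc_report_count(soc_pts) if unit == "report"
                   else background.soc_pair_count(soc_pts))
        if not soc_pts:
            logger.warning("SOC %r has no mapped PTs; empty table", term)
    else:
        a_units = sum(1 for case in cases if term in case.reaction_pts)
        c_units = background.pt_counts.get(term, 0)
        if a_units == 0 and c_units == 0:
            logger.warning("term %r unknown in cohort and background", term)
    target_total = (len(cases) if unit == "report"
                    else sum(len(case.reaction_pts) for case in cases))
    background_total = (background.n_reports if unit == "report"
                        else background.n_pairs)
    return ContingencyTable(a=a_units, b=target_total - a_units,
                            c=c_units, d=background_total - c_units)


# ---------------------------------------------------------------------------
# screening


@dataclass
class ScreenResult:
    table: pd.DataFrame
    level: str
    unit: str
    n_signals_before_exclusion: int
    n_signals_after_exclusion: int
    excluded_terms: list
    status: str = "ok"


_COLUMNS = ["term", "soc", "case_count", "ror", "ror_low", "ror_high", "prr",
            "chi2", "ic", "ic025", "ebgm", "ebgm05", "ime",
            "ror_signal", "prr_signal", "bcpnn_signal", "mgps_signal",
            "signal", "zero_corrected", "excluded"]


def screen(cases: Sequence[ReportCase], background: Background,
           soc_map: Mapping[str, str], ime_list,
           level: str = "PT", unit: str = "report",
           exclusion_list: Optional[Iterable[str]] = None,
           thresholds: Thresholds = DEFAULT_THRESHOLDS,
           ic_dialect: str = "canonical", ebgm_method: str = "simplified_oe",
           zero_policy: str = "haldane") -> ScreenResult:
    """Screen every term observed in the cohort; apply the exclusion list.

    One output row per term: counts, the four statistics, per-algorithm and
    joint verdicts, IME flag and SOC. Named terms on the exclusion list are
    dropped from the signal set *after* screening, and the before/after
    signal counts are reported. Ranking: case count descending, then term.
    """
    if not cases:
        return ScreenResult(pd.DataFrame(columns=_COLUMNS), level, unit, 0, 0,
                            [], status="empty cohort")
    if level == "PT":
        terms = sorted({pt for case in cases for pt in case.reaction_pts})
        annotations = {pt: annotate_pt(pt, soc_map, ime_list) for pt in terms}
    else:
        annotations = {pt: annotate_pt(pt, soc_map, ime_list)
                       for case in cases for pt in case.reaction_pts}
        terms = sorted({ann.soc for ann in annotations.values()})

    tables = {term: build_table(cases, background, term, level=level,
                                unit=unit, soc_map=soc_map) for term in terms}
    prior = None
    if ebgm_method == "mgps_em":
        prior, converged, _ = mgps.fit_gamma_mixture_em(
            [tables[t].a for t in terms],
            [tables[t].expected_a for t in terms])
        if not converged:
            logger.warning("MGPS EM did not converge; falling back to "
                           "simplified observed/expected EBGM")
            ebgm_method, prior = "simplified_oe", None

    excluded = {str(t) for t in (exclusion_list or ())}
    rows = []
    for term in terms:
        t = tables[term]
        m = compute_metrics(term, t, ic_dialect=ic_dialect,
                            ebgm_method=ebgm_method, prior=prior,
                            zero_policy=zero_policy)
        v = evaluate_signal(m, thresholds)
        if level == "PT":
            ann = annotations[term]
            soc, ime = ann.soc, ann.is_ime
        else:
            soc, ime = term, False
        rows.append({"term": term, "soc": soc, "case_count": m.a,
                     "ror": m.ror, "ror_low": m.ror_low, "ror_high": m.ror_high,
                     "prr": m.prr, "chi2": m.chi2, "ic": m.ic, "ic025": m.ic025,
                     "ebgm": m.ebgm, "ebgm05": m.ebgm05, "ime": ime,
                     "ror_signal": v["ror"], "prr_signal": v["prr"],
                     "bcpnn_signal": v["bcpnn"], "mgps_signal": v["mgps"],
                     "signal": v["joint"], "zero_corrected": m.zero_corrected,
                     "excluded": term in excluded})
    frame = pd.DataFrame(rows, columns=_COLUMNS)
    frame = frame.sort_values(["case_count", "term"],
                              ascending=[False, True], kind="mergesort")
    frame = frame.reset_index(drop=True)
    n_before = int(frame["signal"].sum())
    n_after = int((frame["signal"] & ~frame["excluded"]).sum())
    return ScreenResult(frame, level, unit, n_before, n_after,
                        sorted(excluded & set(terms)))


def apply_exclusion(result: ScreenResult, exclusion_list: Iterable[str]) -> ScreenResult:
    """Re-apply an exclusion list to an existing screen result."""
    excluded = {str(t) for t in exclusion_list}
    frame = result.table.copy()
    frame["excluded"] = frame["term"].isin(excluded)
    n_before = int(frame["signal"].sum())
    n_after = int((frame["signal"] & ~frame["excluded"]).sum())
    return ScreenResult(frame, result.level, result.unit, n_before, n_after,
                        sorted(excluded & set(frame["term"])), result.status)
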