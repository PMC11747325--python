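"""Time-to-onset of adverse events.

The onset interval is the number of days between the report's event date
(EVENT_DT, report-level in the DEMO table) and the start of target-drug
therapy (START_DT in THER). FAERS carries no per-PT event dates, so one
report with k reaction PTs and a valid date pair contributes k onset
records — the (report, PT) expansion noted in each output's metadata.

Rows are excluded, and tallied by reason, when either date is missing
(``missing``), reported to year/month precision only (``partial``),
unparseable (``invalid``), or when the event precedes therapy start
(``negative``).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import pandas as pd

from .cohort import ReportCase, annotate_pt

EXPANSION_NOTE = ("onset unit is (report, PT): the event date is "
                  "report-level, so every reaction PT of a report shares it")


@dataclass(frozen=True, slots=True)
class OnsetRecord:
    primaryid: str
    pt: str
    days: int


@dataclass
class OnsetResult:
    records: list
    exclusions: Counter
    note: str = EXPANSION_NOTE

    @property
    def n_candidates(self) -> int:
        return len(self.records) + sum(self.exclusions.values())


def _date_reason(parsed) -> Optional[str]:
    if parsed is None or not parsed.raw:
        return "missing"
    if parsed.is_partial:
        return "partial"
    if parsed.is_invalid:
        return "invalid"
    return None


def compute_onsets(cases: Sequence[ReportCase]) -> OnsetResult:
    """One onset record per (report, PT) with a valid non-negative interval.

    Candidate rows are every (report, PT) pair; records + exclusion tallies
    add up to the candidate count exactly. Reports with several target
    therapy rows use the earliest full start date (flagged on the case).
    """
    records: list[OnsetRecord] = []
    exclusions: Counter = Counter()
    for case in cases:
        n_pts = len(case.reaction_pts)
        reason = _date_reason(case.event_dt) or _date_reason(case.therapy_start)
        if reason is not None:
            exclusions[reason] += n_pts
            continue
        days = (case.event_dt.date - case.therapy_start.date).days
        if days < 0:
            exclusions["negative"] += n_pts
            continue
        for pt in sorted(case.reaction_pts):
            records.append(OnsetRecord(case.primaryid, pt, days))
    return OnsetResult(records, exclusions)


def bin_profile(onsets: Sequence[OnsetRecord],
                scheme: str = "monthly_30d") -> pd.DataFrame:
    """Histogram of onset days.

    ``monthly_30d``: 30-day bins [0,30), [30,60), ... covering the maximum
    observed interval. ``daily_first_month``: day-resolution counts for days
    0–30 plus a terminal ``>30`` bin, so every scheme conserves the record
    count.
    """
    days = [r.days for r in onsets]
    if scheme == "monthly_30d":
        if not days:
            return pd.DataFrame(columns=["bin_start", "bin_end", "count"])
        n_bins = max(days) // 30 + 1
        counts = [0] * n_bins
        for d in days:
            counts[d // 30] += 1
        return pd.DataFrame({"bin_start": [30 * i for i in range(n_bins)],
                             "bin_end": [30 * (i + 1) for i in range(n_bins)],
                             "count": counts})
    if scheme == "daily_first_month":
        if not days:
            return pd.DataFrame(columns=["day", "count"])
        counts = [0] * 32  # index 31 collects >30
        for d in days:
            counts[min(d, 31)] += 1
        labels = [str(i) for i in range(31)] + [">30"]
        return pd.DataFrame({"day": labels, "count": counts})
    raise ValueError(f"unknown binning scheme {scheme!r}")


def first_window_share(onsets: Sequence[OnsetRecord], days: int = 30) -> float:
    """Fraction of onset records within the first ``days`` days (0-based)."""
    if not onsets:
        return float("nan")
    return sum(1 for r in onsets if r.days < days) / len(onsets)


@dataclass
class SocComposition:
    table: pd.DataFrame
    cutoff_days: int
    n_late: int
    status: str = "ok"


def late_soc_composition(onsets: Sequence[OnsetRecord],
                         soc_map: Mapping[str, str],
                         cutoff_days: int = 365) -> SocComposition:
    """SOC shares among events with onset beyond ``cutoff_days``.

    Shares sum to 1 over the late events; no late events yields an empty
    table with an explanatory status.
    """
    late = [r for r in onsets if r.days > cutoff_days]
    if not late:
        return SocComposition(pd.DataFrame(columns=["soc", "count", "share"]),
                              cutoff_days, 0, status="no late events")
    counts: Counter = Counter(
        annotate_pt(r.pt, soc_map, frozenset()).soc for r in late)
    frame = pd.DataFrame(sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])),
                         columns=["soc", "count"])
    frame["share"] = frame["count"] / len(late)
    return SocComposition(frame, cutoff_days, len(late))
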