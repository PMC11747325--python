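"""Concomitant-medication census and combination-therapy screening.

The census ranks drugs co-reported with the target (frequency over target
cases, filtered at a minimum count). Interaction screening contrasts three
disjoint cohorts — target+partner combination, target-only, partner-only —
per PT: reporting proportions, combination-vs-each-monotherapy RORs with
Wald CIs and p-values, an "elevated in combination" flag (both RORs > 1
with CI lower bounds > 1), and the count of four-algorithm criteria the PT
passes on the combination cohort against the full background, so a
quorum filter (default >= 3 of 4) can be applied.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .cohort import (CohortResult, DrugLexicon, ReportCase, build_cases)
from .dispro import (Background, Thresholds, DEFAULT_THRESHOLDS, build_table,
                     compute_metrics, evaluate_signal)
from .io import ParsedQuarter
from .strata import _contrast_row


@dataclass
class ComboCohorts:
    combo: list          # target PS cases also naming the partner (any role)
    mono_target: list    # target PS cases without the partner
    mono_partner: list   # partner-suspect (PS/SS) cases without the target

    def sizes(self) -> dict:
        return {"combo": len(self.combo), "mono_target": len(self.mono_target),
                "mono_partner": len(self.mono_partner)}


def _names_match(case: ReportCase, matcher) -> bool:
    return any(matcher(name) for name in case.concomitant_drugnames)


def build_combo_cohorts(quarter: ParsedQuarter, retained_ids,
                        target_lexicon: DrugLexicon,
                        partner_lexicon: DrugLexicon,
                        target_cohort: Optional[CohortResult] = None,
                        mode: str = "word") -> ComboCohorts:
    """Partition target/partner suspect cases into the three cohorts.

    Partner presence in a target case means the partner appears with any
    role among the case's drugs; the partner-monotherapy cohort requires a
    suspect role (PS or SS) for the partner and no target drug at all.
    """
    if target_cohort is None:
        target_cohort = build_cases(quarter, retained_ids, target_lexicon, mode)
    partner_matches = partner_lexicon.matcher(mode)
    combo, mono_target = [], []
    for case in target_cohort.ps_cases:
        (combo if _names_match(case, partner_matches) else mono_target).append(case)
    target_matches = target_lexicon.matcher(mode)
    partner_cohort = build_cases(quarter, retained_ids, partner_lexicon, mode)
    mono_partner = [case for case in partner_cohort.cases
                    if case.target_role in {"PS", "SS"}
                    and not _names_match(case, target_matches)]
    return ComboCohorts(combo, mono_target, mono_partner)


def conmed_census(cases: Sequence[ReportCase],
                  min_count: int = 20) -> pd.DataFrame:
    """Ranked frequency of co-reported drug names across target cases.

    Names are already whitespace/case normalized, so spelling variants that
    normalize identically merge into one row. Report-level presence: a drug
    listed twice in one report counts once.
    """
    counts: Counter = Counter()
    for case in cases:
        counts.update(case.concomitant_drugnames)
    rows = [(name, n) for name, n in counts.items() if n >= min_count]
    rows.sort(key=lambda kv: (-kv[1], kv[0]))
    frame = pd.DataFrame(rows, columns=["drugname", "count"])
    frame.insert(0, "rank", range(1, len(frame) + 1))
    return frame


_INTERACTION_COLUMNS = [
    "pt", "combo_count", "combo_prop", "mono_target_count",
    "mono_target_prop", "mono_partner_count", "mono_partner_prop",
    "ror_vs_target", "ror_vs_target_low", "ror_vs_target_high",
    "p_vs_target", "ror_vs_partner", "ror_vs_partner_low",
    "ror_vs_partner_high", "p_vs_partner", "elevated_in_combo",
    "criteria_count", "meets_quorum", "zero_corrected"]


def interaction_screen(cohorts: ComboCohorts,
                       background: Optional[Background] = None,
                       thresholds: Thresholds = DEFAULT_THRESHOLDS,
                       quorum: int = 3,
                       min_combo_count: int = 1) -> pd.DataFrame:
    """Per-PT comparison of the combination cohort against both monotherapies.

    ``criteria_count`` is how many of the four disproportionality criteria
    the PT passes when the combination cohort is screened against the full
    background (0 when no background is supplied); ``meets_quorum`` applies
    the configured >= ``quorum`` filter to it.
    """
    sizes = cohorts.sizes()
    if min(sizes.values()) == 0:
        raise ValueError(f"all three cohorts must be non-empty, got {sizes}")
    pts = sorted({pt for case in cohorts.combo for pt in case.reaction_pts})
    counts = {}
    for label, group in (("combo", cohorts.combo),
                         ("mono_target", cohorts.mono_target),
                         ("mono_partner", cohorts.mono_partner)):
        tally = Counter()
        for case in group:
            tally.update(case.reaction_pts)
        counts[label] = tally
    n_combo = sizes["combo"]
    rows = []
    for pt in pts:
        a = counts["combo"][pt]
        if a < min_combo_count:
            continue
        row = {"pt": pt, "combo_count": a, "combo_prop": a / n_combo}
        corrected = False
        for label, key in (("mono_target", "target"), ("mono_partner", "partner")):
            c = counts[label][pt]
            n = sizes[label]
            contrast = _contrast_row(a, n_combo - a, c, n - c)
            corrected = corrected or contrast["zero_corrected"]
            row[f"{label}_count"] = c
            row[f"{label}_prop"] = c / n
            row[f"ror_vs_{key}"] = contrast["ror"]
            row[f"ror_vs_{key}_low"] = contrast["ror_low"]
            row[f"ror_vs_{key}_high"] = contrast["ror_high"]
            row[f"p_vs_{key}"] = contrast["p_value"]
        row["elevated_in_combo"] = (row["ror_vs_target_low"] > 1.0
                                    and row["ror_vs_partner_low"] > 1.0)
        if background is not None:
            table = build_table(cohorts.combo, background, pt)
            verdicts = evaluate_signal(compute_metrics(pt, table), thresholds)
            row["criteria_count"] = sum(verdicts[k] for k in
                                        ("ror", "prr", "bcpnn", "mgps"))
        else:
            row["criteria_count"] = 0
        row["meets_quorum"] = row["criteria_count"] >= quorum
        row["zero_corrected"] = corrected
        rows.append(row)
    frame = pd.DataFrame(rows, columns=_INTERACTION_COLUMNS)
    return frame.sort_values(["combo_count", "pt"], ascending=[False, True],
                             kind="mergesort").reset_index(drop=True)
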