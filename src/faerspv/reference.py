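"""Published reference values for the onasemnogene abeparvovec screening.

Bundled, as plain CSV, are the SOC- and PT-level disproportionality tables
and the demographic summary from a published FAERS screening of
onasemnogene abeparvovec (Zolgensma; FAERS 2019Q2–2024Q1, MedDRA v26.1).
They serve as *inputs* to internal-consistency checks: the printed ROR must
equal the geometric mean of its printed CI bounds, the printed IC must be
log2 of the printed EBGM with a constant IC − IC025 offset, and every
demographic percentage must recompute from its count and denominator.

One demographic row (reporting year 2020) prints 25.27% where its count
recomputes to 22.50%; it is flagged ``printed_inconsistent`` so consumers
can assert the recomputation instead of the typo.
"""

from __future__ import annotations

import math
from importlib import resources

import pandas as pd

# headline counts of the reference screening
REFERENCE_SUMMARY = {
    "total_reports": 1951,
    "ime_reports": 778,
    "signals_screened": 295,
    "signals_excluded": 14,
    "signals_retained": 281,
    "soc_count_retained": 20,
    "onset_cases": 5597,
    "first_3day_onset_pct": 50.54,
    "conmed_records": 3951,
    "combo_with_partner_cases": 194,
    "weight_contrast": {"pt": "Platelet count decreased", "cut_kg": 8.5,
                        "ror": 1.45, "ror_low": 1.05, "ror_high": 2.0},
    "meddra_version": "26.1",
}


def _load(name: str) -> pd.DataFrame:
    with resources.files("faerspv.data").joinpath(name).open() as handle:
        return pd.read_csv(handle)


def load_reference_soc_table() -> pd.DataFrame:
    return _load("reference_soc_signals.csv")


def load_reference_pt_table() -> pd.DataFrame:
    return _load("reference_pt_signals.csv")


def load_reference_demographics() -> pd.DataFrame:
    frame = _load("reference_demographics.csv")
    frame["printed_inconsistent"] = frame["printed_inconsistent"] == "yes"
    return frame


def _half_ulp(printed: float) -> float:
    """Half of the last printed decimal place (e.g. 12.66 -> 0.005)."""
    text = f"{printed}"
    decimals = len(text.split(".")[1]) if "." in text else 0
    return 0.5 * 10.0 ** (-decimals)


def ror_geometric_mean_identity(row) -> tuple:
    """(recomputed sqrt(low*high), printed ROR, rounding tolerance).

    The tolerance propagates the half-ulp rounding of both printed bounds
    onto the geometric mean and adds the half-ulp of the printed ROR.
    Bounds printed as 0 cannot be inverted and yield (nan, ror, nan).
    """
    low, high, ror = row["ror_low"], row["ror_high"], row["ror"]
    if low <= 0 or high <= 0:
        return float("nan"), ror, float("nan")
    gm = math.sqrt(low * high)
    tol = gm * (_half_ulp(low) / (2 * low) + _half_ulp(high) / (2 * high)) \
        + _half_ulp(ror)
    return gm, ror, tol


def ic_log2_ebgm_identity(row) -> tuple:
    """(log2 of printed EBGM, printed IC, rounding tolerance)."""
    ebgm, ic = row["ebgm"], row["ic"]
    if ebgm <= 0:
        return float("nan"), ic, float("nan")
    value = math.log2(ebgm)
    tol = _half_ulp(ebgm) / (ebgm * math.log(2)) + _half_ulp(ic)
    return value, ic, tol
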