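"""Parsing of FAERS date tokens.

FAERS dates are plain digit strings: ``YYYYMMDD`` (full), ``YYYYMM`` or
``YYYY`` (partial, reported to month or year precision only). Anything else —
including impossible calendar dates — is invalid. Partial dates are kept for
non-temporal analyses but are never used in interval arithmetic (time to
onset), where they count as "inaccurate" and are excluded.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from typing import Optional

__all__ = ["ParsedDate", "parse_date", "FULL", "PARTIAL", "INVALID"]

FULL = "full"
PARTIAL = "partial"
INVALID = "invalid"


@dataclass(frozen=True, slots=True)
class ParsedDate:
    """Outcome of parsing one date token.

    ``kind`` is ``"full"``, ``"partial"`` or ``"invalid"``. ``date`` is set
    only for full dates; partial dates expose ``year``/``month`` and a
    ``precision`` of ``"year"`` or ``"month"``.
    """

    kind: str
    raw: str
    date: Optional[_dt.date] = None
    year: Optional[int] = None
    month: Optional[int] = None
    precision: Optional[str] = None

    @property
    def is_full(self) -> bool:
        return self.kind == FULL

    @property
    def is_partial(self) -> bool:
        return self.kind == PARTIAL

    @property
    def is_invalid(self) -> bool:
        return self.kind == INVALID

    def to_token(self) -> str:
        """Render back to the FAERS digit-string dialect."""
        if self.kind == FULL:
            return self.date.strftime("%Y%m%d")
        if self.kind == PARTIAL and self.precision == "month":
            return f"{self.year:04d}{self.month:02d}"
        if self.kind == PARTIAL:
            return f"{self.year:04d}"
        return self.raw


def parse_date(token: object) -> ParsedDate:
    """Parse a FAERS date token. Total: never raises.

    8 valid digits -> full date; 6 digits with a real month -> month-precision
    partial; 4 digits -> year-precision partial; everything else -> invalid.
    """
    if token is None:
        return ParsedDate(INVALID, "")
    text = str(token).strip()
    if text.endswith(".0"):  # float round-trip from loosely typed tables
        text = text[:-2]
    if not text.isdigit():
        return ParsedDate(INVALID, text)
    if len(text) == 8:
        try:
            d = _dt.date(int(text[:4]), int(text[4:6]), int(text[6:8]))
        except ValueError:
            return ParsedDate(INVALID, text)
        return ParsedDate(FULL, text, date=d, year=d.year, month=d.month,
                          precision="day")
    if len(text) == 6:
        year, month = int(text[:4]), int(text[4:6])
        if not 1 <= month <= 12:
            return ParsedDate(INVALID, text)
        return ParsedDate(PARTIAL, text, year=year, month=month,
                          precision="month")
    if len(text) == 4:
        return ParsedDate(PARTIAL, text, year=int(text), precision="year")
    return ParsedDate(INVALID, text)
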