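"""Calendar dates at year, month or day precision.

FAERS date fields (``fda_dt``, ``event_dt``, ``start_dt``) are recorded as
YYYYMMDD digit strings, but a sizeable fraction of reports carry only YYYY
or YYYYMM. Rather than dropping those rows at parse time, dates are kept
with an explicit precision so each analysis can decide whether it needs day
resolution: time-to-onset does, deduplication and quarter assignment do not.
"""

from __future__ import annotations

import datetime as _dt
import re
from dataclasses import dataclass
from typing import Optional, Tuple

_DATE_RE = re.compile(r"^(\d{4})(\d{2})?(\d{2})?$")


@dataclass(frozen=True)
class PartialDate:
    """A calendar date whose month and day may be unknown."""

    year: int
    month: Optional[int] = None
    day: Optional[int] = None

    def __post_init__(self) -> None:
        if self.day is not None and self.month is None:
            raise ValueError("day precision requires a month")
        if self.month is not None and not (1 <= self.month <= 12):
            raise ValueError(f"month out of range: {self.month}")
        if self.day is not None and not (1 <= self.day <= 31):
            raise ValueError(f"day out of range: {self.day}")

    @property
    def precision(self) -> str:
        if self.day is not None:
            return "day"
        if self.month is not None:
            return "month"
        return "year"

    @property
    def is_day_precision(self) -> bool:
        return self.day is not None

    @property
    def quarter(self) -> Optional[Tuple[int, int]]:
        """(year, quarter) if the month is known, else None."""
        if self.month is None:
            return None
        return (self.year, (self.month - 1) // 3 + 1)

    def sort_key(self) -> Tuple[int, int, int]:
        """Total-order key; unknown components sort before any known value."""
        return (self.year, self.month or 0, self.day or 0)

    def to_date(self) -> _dt.date:
        if not self.is_day_precision:
            raise ValueError(f"not a day-precision date: {self}")
        return _dt.date(self.year, self.month, self.day)

    def __str__(self) -> str:
        if self.day is not None:
            return f"{self.year:04d}{self.month:02d}{self.day:02d}"
        if self.month is not None:
            return f"{self.year:04d}{self.month:02d}"
        return f"{self.year:04d}"

    @classmethod
    def from_date(cls, d: _dt.date) -> "PartialDate":
        return cls(d.year, d.month, d.day)

    @classmethod
    def parse(cls, raw: object) -> Optional["PartialDate"]:
        """Parse a FAERS date string; returns None for blank/unparseable.

        Accepts YYYY, YYYYMM and YYYYMMDD. A YYYYMMDD string naming an
        invalid calendar day (e.g. Feb 30) is demoted to month precision
        rather than discarded.
        """
        if raw is None:
            return None
        s = str(raw).strip()
        if not s or s.lower() in {"nan", "none"}:
            return None
        if s.endswith(".0"):  # numeric round-trip through spreadsheets
            s = s[:-2]
        m = _DATE_RE.match(s)
        if m is None:
            return None
        year = int(m.group(1))
        month = int(m.group(2)) if m.group(2) else None
        day = int(m.group(3)) if m.group(3) else None
        if month is not None and not (1 <= month <= 12):
            return cls(year)
        if day is not None:
            try:
                _dt.date(year, month, day)
            except ValueError:
                return cls(year, month)
        return cls(year, month, day)


def days_between(start: PartialDate, end: PartialDate) -> int:
    """Whole-day difference end - start; both must be day precision."""
    return (end.to_date() - start.to_date()).days


def quarter_le(q1: Tuple[int, int], q2: Tuple[int, int]) -> bool:
    return q1 <= q2
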