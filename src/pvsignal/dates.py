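"""Partial calendar dates as they occur in spontaneous-report data.

FAERS date fields are plain digit strings in ``YYYY``, ``YYYYMM`` or
``YYYYMMDD`` form, and any component may be missing or malformed.  A
:class:`PartialDate` stores the three components independently so that a
year-only date is representable without inventing a month or day.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass
from typing import Optional

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PartialDate:
    """A calendar date whose month and day may be absent.

    Ordering is lexicographic on (year, month, day) with absent components
    sorting before present ones; this makes "later receipt date" tie-breaks
    well defined even for partial dates.
    """

    year: Optional[int] = None
    month: Optional[int] = None
    day: Optional[int] = None

    def sort_key(self):
        return (
            self.year if self.year is not None else -1,
            self.month if self.month is not None else -1,
            self.day if self.day is not None else -1,
        )

    def __lt__(self, other: "PartialDate") -> bool:  # absent sorts first
        return self.sort_key() < other.sort_key()

    def __le__(self, other: "PartialDate") -> bool:
        return self.sort_key() <= other.sort_key()

    @property
    def is_absent(self) -> bool:
        return self.year is None

    @property
    def is_complete(self) -> bool:
        return self.year is not None and self.month is not None and self.day is not None

    def to_date(self) -> Optional[_dt.date]:
        """Return a ``datetime.date`` when all three components are present."""
        if not self.is_complete:
            return None
        return _dt.date(self.year, self.month, self.day)

    def to_faers(self) -> str:
        """Serialize back to the digit-string dialect ('' when absent)."""
        if self.year is None:
            return ""
        if self.month is None:
            return f"{self.year:04d}"
        if self.day is None:
            return f"{self.year:04d}{self.month:02d}"
        return f"{self.year:04d}{self.month:02d}{self.day:02d}"


ABSENT_DATE = PartialDate()


def parse_partial_date(text: str) -> PartialDate:
    """Parse a FAERS date string into a :class:`PartialDate`.

    Total function: empty or unparseable input yields an absent date, and an
    invalid month or day drops that component (keeping the valid prefix) with
    a logged warning — rows are never discarded over a bad date.
    """
    text = (text or "").strip()
    if not text:
        return ABSENT_DATE
    if not text.isdigit() or len(text) not in (4, 6, 8):
        logger.warning("unparseable date %r treated as absent", text)
        return ABSENT_DATE
    year = int(text[:4])
    if year == 0:
        logger.warning("zero year in date %r treated as absent", text)
        return ABSENT_DATE
    month: Optional[int] = None
    day: Optional[int] = None
    if len(text) >= 6:
        m = int(text[4:6])
        if 1 <= m <= 12:
            month = m
        else:
            logger.warning("invalid month in date %r; month/day dropped", text)
            return PartialDate(year=year)
    if len(text) == 8:
        d = int(text[6:8])
        if month is not None and _valid_day(year, month, d):
            day = d
        else:
            logger.warning("invalid day in date %r; day dropped", text)
    return PartialDate(year=year, month=month, day=day)


def _valid_day(year: int, month: int, day: int) -> bool:
    try:
        _dt.date(year, month, day)
        return True
    except ValueError:
        return False


def days_between(start: PartialDate, end: PartialDate) -> Optional[int]:
    """Day difference ``end - start`` when both dates are complete, else None."""
    s, e = start.to_date(), end.to_date()
    if s is None or e is None:
        return None
    return (e - s).days
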