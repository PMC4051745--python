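"""Calendar-month arithmetic on ISO "YYYY-MM" strings.

All time indexing in the package is monthly; dates finer than a month are
truncated on input. Months are kept as plain strings at every interface and
converted to a linear integer index only for arithmetic.
"""

from __future__ import annotations

import re

_MONTH_RE = re.compile(r"^(\d{4})-(\d{2})$")
_DATE_RE = re.compile(r"^(\d{4})-(\d{2})(?:-\d{2})?(?:[T ].*)?$")


def parse_month(value: str) -> str:
    """Normalize a date or month string to "YYYY-MM".

    Accepts "2010-05", "2010-05-14", or an ISO datetime; anything finer than
    the month is discarded.
    """
    m = _DATE_RE.match(value.strip())
    if not m:
        raise ValueError(f"cannot parse month from {value!r}")
    year, month = int(m.group(1)), int(m.group(2))
    if not 1 <= month <= 12:
        raise ValueError(f"invalid month number in {value!r}")
    return f"{year:04d}-{month:02d}"


def month_index(month: str) -> int:
    """Linear index (year*12 + month-1) of a "YYYY-MM" string."""
    m = _MONTH_RE.match(month)
    if not m or not 1 <= int(m.group(2)) <= 12:
        raise ValueError(f"invalid month {month!r}")
    return int(m.group(1)) * 12 + int(m.group(2)) - 1


def index_month(idx: int) -> str:
    return f"{idx // 12:04d}-{idx % 12 + 1:02d}"


def month_add(month: str, delta: int) -> str:
    return index_month(month_index(month) + delta)


def month_range(start: str, end: str) -> list[str]:
    """Inclusive list of months from start to end."""
    lo, hi = month_index(start), month_index(end)
    if lo > hi:
        raise ValueError(f"month range start {start!r} after end {end!r}")
    return [index_month(i) for i in range(lo, hi + 1)]
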