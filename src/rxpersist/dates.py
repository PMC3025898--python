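"""Calendar-month arithmetic used throughout the pipeline.

All study windows (6-month pre-period, 3/6/12-month assessment horizons,
15-month post-period) are calendar months anchored at the patient's index
date, with end-of-month clamping: Jan 31 + 1 month = Feb 28 (or Feb 29 in a
leap year).  Windows are half-open, [start, end), unless stated otherwise.
"""

from __future__ import annotations

import datetime as dt

from dateutil.relativedelta import relativedelta

__all__ = ["add_months", "month_boundary", "parse_date"]


def add_months(d: dt.date, months: int) -> dt.date:
    """Advance ``d`` by ``months`` calendar months, clamping the day-of-month.

    ``add_months(date(2003, 1, 31), 1) == date(2003, 2, 28)``.
    Negative ``months`` moves backwards with the same clamping rule.
    """
    return d + relativedelta(months=months)


def month_boundary(index_date: dt.date, m: int) -> dt.date:
    """End of the m-th month of follow-up for a patient indexed on ``index_date``.

    Month ``m`` of follow-up spans ``[month_boundary(index, m - 1),
    month_boundary(index, m))``; ``month_boundary(d, 0) == d``.
    """
    if m < 0:
        raise ValueError("month count must be non-negative")
    return add_months(index_date, m)


def parse_date(value) -> dt.date:
    """Coerce an ISO-8601 string / datetime / date to ``datetime.date``."""
    if isinstance(value, dt.datetime):
        return value.date()
    if isinstance(value, dt.date):
        return value
    return dt.date.fromisoformat(str(value))
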