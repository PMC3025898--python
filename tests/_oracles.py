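"""Independent brute-force oracles the implementation is checked against."""

from __future__ import annotations

import calendar
import datetime as dt

import numpy as np
from scipy import stats as sps


def add_months_oracle(d: dt.date, months: int) -> dt.date:
    """Calendar-table month shift with day-of-month clamping."""
    total = d.year * 12 + (d.month - 1) + months
    year, month0 = divmod(total, 12)
    last_day = calendar.monthrange(year, month0 + 1)[1]
    return dt.date(year, month0 + 1, min(d.day, last_day))


def brute_force_gaps(fill_dates, index_date, threshold_days, observation_end):
    """O(n^2) gap scan: for each in-window fill, find the next later fill by
    testing every date pair; the terminal residue is checked separately.

    Returns (gap_start, gap_end_or_None, length) tuples in date order.
    """
    days = sorted({d for d in fill_dates if index_date <= d <= observation_end})
    gaps = []
    for a in days:
        nxt = None
        for b in days:
            if b > a and (nxt is None or b < nxt):
                nxt = b
        if nxt is None:
            if (observation_end - a).days > threshold_days:
                gaps.append((a, None, (observation_end - a).days))
        elif (nxt - a).days > threshold_days:
            gaps.append((a, nxt, (nxt - a).days))
    return gaps


def chi2_closed_form(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square by the definition sum (O-E)^2 / E, plus its p-value."""
    table = np.asarray(table, dtype=float)
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row @ col / table.sum()
    stat = float(((table - expected) ** 2 / expected).sum())
    dof = (table.shape[0] - 1) * (table.shape[1] - 1)
    return stat, float(sps.chi2.sf(stat, dof))


def random_claim_days(rng: np.random.Generator, max_day: int = 470,
                      max_extra_claims: int = 12) -> list[int]:
    """A random fill-day set always containing day 0 (the index fill)."""
    n = int(rng.integers(0, max_extra_claims + 1))
    extra = rng.integers(1, max_day + 1, size=n).tolist()
    return [0] + sorted(extra)
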