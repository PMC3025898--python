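"""Persistence classification at 3, 6 and 12 months.

Two classifiers, applied to each cohort patient's mealtime fills:

* **Measure 1 (refill-gap rule).** A patient is persistent at horizon ``h``
  months iff no refill gap longer than 90 days *starts* strictly before the
  end of month ``h``.  Gaps include the terminal residue to the end of the
  15-month observation window, and a disqualifying gap dates the patient's
  discontinuation at the last fill before the gap.  Example: index fill
  Jan 1 with refills Mar 15, May 1, Jul 15 and nothing after is persistent
  at 6 months (no gap starts before Jul 1) but not at 12 (the terminal gap
  starts Jul 15).

* **Measure 2 (quarterly-refill rule).** A deliberately more lenient count
  rule.  Persistent at 3 months: >=2 mealtime claims in the first 4 months.
  At 6 months: >=3 claims in the first 7 months, with >=1 in months 1-3 and
  >=1 in months 4-6.  At 12 months: >=4 claims in the first 12 months with
  >=1 in each index-anchored quarter.  Counts include the index claim.
  Measure 2 is *not* monotone over horizons: one claim per quarter can
  satisfy the 12-month rule while failing the 6-month rule.

Months and quarters are calendar months anchored at the index date (month
``m`` spans ``[month_boundary(index, m-1), month_boundary(index, m))``).
Non-persistence is not discontinuation: patients keep all downstream
metrics, since a gap is often followed by further fills (intermittent use).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .dates import month_boundary
from .exposure import DEFAULT_GAP_DAYS, DEFAULT_POST_MONTHS, detect_gaps

__all__ = [
    "PersistenceStatus",
    "month_boundary",
    "classify_measure1",
    "classify_measure2",
    "classify_all",
    "persistence_summary",
]

MEASURES = ("m1", "m2")
HORIZONS = (3, 6, 12)


@dataclass(frozen=True)
class PersistenceStatus:
    measure: str  # m1 | m2
    horizon_months: int
    persistent: bool
    discontinuation_date: dt.date | None = None  # m1 non-persistent only

    def __post_init__(self) -> None:
        if (self.discontinuation_date is not None) and (
            self.measure != "m1" or self.persistent
        ):
            raise ValueError(
                "discontinuation_date only applies to non-persistent measure 1"
            )


def _window_fills(
    fill_dates: Iterable[dt.date], index_date: dt.date, observation_end: dt.date
) -> list[dt.date]:
    """Fills inside the closed observation window; everything else is ignored."""
    return [d for d in fill_dates if index_date <= d <= observation_end]


def classify_measure1(
    fill_dates: Iterable[dt.date],
    index_date: dt.date,
    horizon_months: int,
    threshold_days: int = DEFAULT_GAP_DAYS,
    post_months: int = DEFAULT_POST_MONTHS,
) -> PersistenceStatus:
    """Gap rule: persistent iff no gap starts strictly before the horizon end.

    A gap starting exactly on the horizon boundary does not disqualify
    (the rule reads "started prior to the end" of the period).
    """
    observation_end = month_boundary(index_date, post_months)
    fills = _window_fills(fill_dates, index_date, observation_end)
    analysis = detect_gaps(fills, index_date, threshold_days, observation_end)
    boundary = month_boundary(index_date, horizon_months)
    disqualifying = [g for g in analysis.gaps if g.gap_start < boundary]
    if disqualifying:
        return PersistenceStatus(
            "m1", horizon_months, False, min(g.gap_start for g in disqualifying)
        )
    return PersistenceStatus("m1", horizon_months, True)


#: Measure-2 requirements per horizon: (total window months, minimum claims,
#: list of (start month, end month) sub-windows each needing >=1 claim).
_M2_RULES = {
    3: (4, 2, []),
    6: (7, 3, [(0, 3), (3, 6)]),
    12: (12, 4, [(0, 3), (3, 6), (6, 9), (9, 12)]),
}


def classify_measure2(
    fill_dates: Iterable[dt.date],
    index_date: dt.date,
    horizon_months: int,
    post_months: int = DEFAULT_POST_MONTHS,
) -> PersistenceStatus:
    """Quarterly-refill rule (counts include the index claim and same-day
    duplicate fills, which are distinct claims)."""
    try:
        total_months, min_claims, quarters = _M2_RULES[horizon_months]
    except KeyError:
        raise ValueError(f"unsupported horizon: {horizon_months}") from None
    observation_end = month_boundary(index_date, post_months)
    fills = _window_fills(fill_dates, index_date, observation_end)

    def n_in(m_from: int, m_to: int) -> int:
        lo = month_boundary(index_date, m_from)
        hi = month_boundary(index_date, m_to)
        return sum(1 for d in fills if lo <= d < hi)

    ok = n_in(0, total_months) >= min_claims and all(
        n_in(a, b) >= 1 for a, b in quarters
    )
    return PersistenceStatus("m2", horizon_months, ok)


def classify_all(
    fill_dates: Iterable[dt.date],
    index_date: dt.date,
    horizons: Sequence[int] = HORIZONS,
    threshold_days: int = DEFAULT_GAP_DAYS,
    post_months: int = DEFAULT_POST_MONTHS,
) -> list[PersistenceStatus]:
    """Both measures at every horizon (6 statuses by default)."""
    out: list[PersistenceStatus] = []
    for h in horizons:
        out.append(
            classify_measure1(fill_dates, index_date, h, threshold_days, post_months)
        )
        out.append(classify_measure2(fill_dates, index_date, h, post_months))
    return out


def persistence_summary(per_patient: pd.DataFrame) -> pd.DataFrame:
    """Cohort-level persistence proportions from a per-patient boolean frame.

    Expects columns ``persistent_{measure}_{h}m``; returns one row per
    measure x horizon with n, n_persistent and pct_persistent.
    """
    rows = []
    for measure in MEASURES:
        for h in HORIZONS:
            col = f"persistent_{measure}_{h}m"
            if col not in per_patient.columns:
                continue
            vals = per_patient[col].astype(bool)
            rows.append(
                {
                    "measure": measure,
                    "horizon_months": h,
                    "n": int(len(vals)),
                    "n_persistent": int(vals.sum()),
                    "pct_persistent": 100.0 * float(vals.mean()) if len(vals) else 0.0,
                }
            )
    return pd.DataFrame(rows)
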