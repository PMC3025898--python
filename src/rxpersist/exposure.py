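"""Insulin-use metrics: claim counts, daily supply, refill intervals, gaps, switches.

All windows are calendar-month windows anchored at the index date and
half-open: a horizon of ``h`` months covers fills with
``index <= fill_date < month_boundary(index, h)``.

Two tie rules apply to same-day fills (e.g. several packages dispensed at
once): they count *individually* for claim counts and mL totals, but
collapse to a single time point for refill intervals and gap detection — in
time, they are one refill event.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from statistics import mean as _mean, median as _median
from typing import Iterable, Sequence

import pandas as pd

from .dates import month_boundary

__all__ = [
    "GapRecord",
    "GapAnalysis",
    "RefillIntervals",
    "SwitchRecord",
    "count_claims",
    "quantity_per_day",
    "refill_intervals",
    "detect_gaps",
    "detect_switch",
    "usage_summary",
    "HORIZONS",
]

HORIZONS = (3, 6, 12)

DEFAULT_GAP_DAYS = 90
DEFAULT_POST_MONTHS = 15


def _window(index_date: dt.date, horizon_months: int) -> tuple[dt.date, dt.date]:
    return index_date, month_boundary(index_date, horizon_months)


def _select(
    claims: pd.DataFrame, insulin_class: str, start: dt.date, end: dt.date
) -> pd.DataFrame:
    """Rows of ``claims`` in [start, end) belonging to ``insulin_class``.

    ``insulin_class='total'`` pools basal and mealtime (mixtures are excluded
    from the cohort post-index by design, so 'total' is their sum).
    """
    dates = claims["fill_date"]
    in_window = (dates >= start) & (dates < end)
    if insulin_class == "total":
        cls_ok = claims["insulin_class"].isin(("basal", "mealtime"))
    else:
        cls_ok = claims["insulin_class"] == insulin_class
    return claims[in_window & cls_ok]


def count_claims(
    claims: pd.DataFrame,
    insulin_class: str,
    index_date: dt.date,
    horizon_months: int,
) -> int:
    """Number of fills of ``insulin_class`` in the half-open horizon window."""
    start, end = _window(index_date, horizon_months)
    return int(len(_select(claims, insulin_class, start, end)))


def quantity_per_day(
    claims: pd.DataFrame,
    insulin_class: str,
    index_date: dt.date,
    horizon_months: int,
) -> float:
    """Total mL dispensed in the window divided by its exact day count."""
    start, end = _window(index_date, horizon_months)
    n_days = (end - start).days
    total_ml = float(_select(claims, insulin_class, start, end)["quantity_ml"].sum())
    return total_ml / n_days


@dataclass
class RefillIntervals:
    """Day gaps between consecutive distinct fill dates within a horizon."""

    intervals: list[int]
    mean: float | None
    median: float | None

    @property
    def sufficient(self) -> bool:
        """False when fewer than two distinct fill dates fell in the window."""
        return bool(self.intervals)


def _distinct_sorted_days(dates: Iterable[dt.date]) -> list[dt.date]:
    return sorted(set(dates))


def refill_intervals(
    fill_dates: Iterable[dt.date],
    index_date: dt.date,
    horizon_months: int,
) -> RefillIntervals:
    """Intervals between consecutive distinct mealtime fill dates in the window.

    With fewer than two distinct dates the result is empty and flagged via
    :attr:`RefillIntervals.sufficient` rather than raising.
    """
    start, end = _window(index_date, horizon_months)
    days = [d for d in _distinct_sorted_days(fill_dates) if start <= d < end]
    ivals = [(b - a).days for a, b in zip(days, days[1:])]
    if not ivals:
        return RefillIntervals([], None, None)
    return RefillIntervals(ivals, float(_mean(ivals)), float(_median(ivals)))


@dataclass
class GapRecord:
    """One detected refill gap.

    ``gap_start`` is the date of the last fill before the gap (or the index
    date itself when the first interval is already a gap); non-persistence
    under the gap rule is effective on this date.  A terminal gap — no
    further fill before the end of observation — has ``gap_end`` None and
    its length measured to the observation end.
    """

    gap_start: dt.date
    gap_end: dt.date | None
    gap_length_days: int
    days_from_index_to_gap_start: int

    @property
    def terminal(self) -> bool:
        return self.gap_end is None


@dataclass
class GapAnalysis:
    """All gaps for one patient plus the summary spans the study reports."""

    gaps: list[GapRecord] = field(default_factory=list)
    days_index_to_first_gap: int | None = None
    days_first_gap_to_next_claim: int | None = None

    @property
    def any_gap(self) -> bool:
        return bool(self.gaps)


def detect_gaps(
    fill_dates: Iterable[dt.date],
    index_date: dt.date,
    threshold_days: int = DEFAULT_GAP_DAYS,
    observation_end: dt.date | None = None,
) -> GapAnalysis:
    """Find every refill gap strictly exceeding ``threshold_days``.

    ``fill_dates`` are the patient's mealtime fills (the index fill should be
    among them); fills outside ``[index_date, observation_end]`` are ignored.
    A gap is an interval between consecutive distinct fill dates strictly
    greater than the threshold, plus a terminal gap when the residue from the
    last fill to ``observation_end`` (default index + 15 months) strictly
    exceeds it.
    """
    if observation_end is None:
        observation_end = month_boundary(index_date, DEFAULT_POST_MONTHS)
    days = [
        d
        for d in _distinct_sorted_days(fill_dates)
        if index_date <= d <= observation_end
    ]
    if not days:
        raise ValueError("at least one fill (the index fill) is required")

    analysis = GapAnalysis()
    for a, b in zip(days, days[1:]):
        length = (b - a).days
        if length > threshold_days:
            analysis.gaps.append(
                GapRecord(a, b, length, (a - index_date).days)
            )
    residue = (observation_end - days[-1]).days
    if residue > threshold_days:
        analysis.gaps.append(
            GapRecord(days[-1], None, residue, (days[-1] - index_date).days)
        )
    if analysis.gaps:
        first = analysis.gaps[0]
        analysis.days_index_to_first_gap = first.days_from_index_to_gap_start
        if first.gap_end is not None:
            analysis.days_first_gap_to_next_claim = (
                first.gap_end - first.gap_start
            ).days
    return analysis


@dataclass
class SwitchRecord:
    """Change away from the index product's type (human/analog) or form."""

    type_changed: bool
    days_to_type_change: int | None
    form_changed: bool
    days_to_form_change: int | None


def detect_switch(
    claims: pd.DataFrame,
    index_date: dt.date,
    index_type: str,
    index_form: str,
    observation_end: dt.date | None = None,
) -> SwitchRecord:
    """First post-index mealtime fill differing from the index type / form.

    A differing fill on the index date itself (a second, same-day claim)
    counts as a change at day 0.
    """
    if observation_end is None:
        observation_end = month_boundary(index_date, DEFAULT_POST_MONTHS)
    mt = claims[
        (claims["insulin_class"] == "mealtime")
        & (claims["fill_date"] >= index_date)
        & (claims["fill_date"] <= observation_end)
    ].sort_values("fill_date", kind="stable")

    def first_change(column: str, reference: str) -> int | None:
        changed = mt[mt[column].notna() & (mt[column] != reference)]
        if changed.empty:
            return None
        return int((changed["fill_date"].iloc[0] - index_date).days)

    d_type = first_change("insulin_type", index_type)
    d_form = first_change("form", index_form)
    return SwitchRecord(d_type is not None, d_type, d_form is not None, d_form)


def usage_summary(
    claims: pd.DataFrame,
    index_date: dt.date,
    horizons: Sequence[int] = HORIZONS,
) -> dict[str, float]:
    """One flat row of the per-patient use metrics at each horizon.

    ``claims`` must carry ``fill_date`` (datetime.date), ``insulin_class``
    and ``quantity_ml`` columns (see :func:`rxpersist.cohort.classify_claims`).
    """
    row: dict[str, float] = {}
    mealtime_dates = claims.loc[
        claims["insulin_class"] == "mealtime", "fill_date"
    ].tolist()
    for h in horizons:
        for cls in ("mealtime", "basal", "total"):
            row[f"n_claims_{cls}_{h}m"] = count_claims(claims, cls, index_date, h)
            row[f"ml_per_day_{cls}_{h}m"] = quantity_per_day(
                claims, cls, index_date, h
            )
        ri = refill_intervals(mealtime_dates, index_date, h)
        row[f"mean_refill_interval_days_{h}m"] = ri.mean
        row[f"median_refill_interval_days_{h}m"] = ri.median
    return row
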