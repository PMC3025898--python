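"""New-user cohort construction for mealtime-insulin initiators.

A patient enters the cohort at their *index event*: the earliest mealtime
insulin fill preceded, strictly within the prior 6 calendar months, by at
least two basal insulin fills (stable basal therapy).  Inclusion further
requires a type 2 diabetes diagnosis in the pre-period and continuous
enrollment over the 21-month window [index - 6 months, index + 15 months].
Exclusions: evidence of type 1 diabetes (ICD-9-CM 250.x1/250.x3 or DRG 295),
gestational diabetes (648.8x), inhaled-insulin or pump use anywhere in the
observation window, any insulin-mixture fill after index, and patients whose
index fill is their only mealtime fill in the first 12 months.

:func:`build_cohort` applies the steps in a fixed order and emits a stepwise
attrition table alongside the cohort.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field

import pandas as pd

from .catalog import InsulinCatalog, default_catalog
from .dates import add_months, parse_date

logger = logging.getLogger(__name__)

__all__ = [
    "CohortConfig",
    "IndexEvent",
    "EXCLUSION_REASONS",
    "ATTRITION_STEPS",
    "classify_claims",
    "find_index_event",
    "check_enrollment",
    "apply_exclusions",
    "build_cohort",
    "attrition_from_counts",
]


@dataclass(frozen=True)
class CohortConfig:
    """Study-window and rule parameters with their default calendar bounds.

    The index accrual window and overall data bounds are configuration, not
    hard-coded study facts, so re-analyses on other calendars only change
    the config.
    """

    pre_months: int = 6
    post_months: int = 15
    followup_months: int = 12
    min_basal_claims: int = 2
    min_mealtime_claims: int = 2
    enrollment_gap_days: int = 0
    index_start: dt.date = dt.date(2001, 7, 1)
    index_end: dt.date = dt.date(2006, 12, 31)
    data_start: dt.date = dt.date(2001, 1, 1)
    data_end: dt.date = dt.date(2008, 3, 31)


@dataclass(frozen=True)
class IndexEvent:
    patient_id: str
    index_date: dt.date
    index_type: str  # human | analog
    index_form: str  # pen | vial_syringe


#: Reason codes in the order the pipeline tests them.
EXCLUSION_REASONS = (
    "no_t2d_dx",
    "type1",
    "gestational",
    "inhaled_or_pump",
    "mixture_post_index",
    "single_mealtime_claim",
)

ATTRITION_STEPS = (
    "mealtime_claim",
    "t2d_and_enrollment",
    "basal_pre_period",
    "type1_exclusion",
    "gestational_inhaled_pump",
    "mixture_post_index",
    "min_two_mealtime_claims",
)


# ---------------------------------------------------------------------------
# ICD-9-CM code predicates (syntax-level only)
# ---------------------------------------------------------------------------
def _norm_code(code: str) -> str:
    return str(code).replace(".", "").strip()


def is_type1_dx(code: str) -> bool:
    """250.x1 or 250.x3 — type 1 diabetes fifth digits."""
    c = _norm_code(code)
    return c.startswith("250") and len(c) == 5 and c[4] in "13"


def is_t2d_dx(code: str) -> bool:
    """Type-2-compatible diabetes code: 250, 250.x, or 250.x0 / 250.x2."""
    c = _norm_code(code)
    if not c.startswith("250"):
        return False
    return len(c) <= 4 or c[4] in "02"


def is_gestational_dx(code: str) -> bool:
    """648.8x — abnormal glucose tolerance of pregnancy."""
    return _norm_code(code).startswith("6488")


TYPE1_DRG = 295


def _is_type1_drg(drg) -> bool:
    if drg is None or (isinstance(drg, float) and pd.isna(drg)):
        return False
    s = str(drg).strip()
    if not s:
        return False
    try:
        return int(float(s)) == TYPE1_DRG
    except ValueError:
        return False


# ---------------------------------------------------------------------------
# Claim classification
# ---------------------------------------------------------------------------
def classify_claims(
    claims: pd.DataFrame, catalog: InsulinCatalog | None = None
) -> tuple[pd.DataFrame, int]:
    """Attach ``insulin_class`` / ``insulin_type`` columns to pharmacy claims.

    Non-injectable rows (route inhaled/pump) are kept unclassified on
    purpose — they are exclusion evidence, not insulin exposure.  Unknown
    injectable products are left unclassified and *counted*; the count is
    returned so callers can log it rather than drop rows silently.
    """
    catalog = catalog or default_catalog()
    out = claims.copy()
    out["fill_date"] = out["fill_date"].map(parse_date)
    norm = out["product_name"].map(lambda s: " ".join(str(s).split()).upper())
    out["insulin_class"] = norm.map(catalog.class_map())
    out["insulin_type"] = norm.map(catalog.type_map())
    injectable = out.get("route", pd.Series("injectable", index=out.index))
    unknown = out["insulin_class"].isna() & (injectable == "injectable")
    n_unclassified = int(unknown.sum())
    if n_unclassified:
        logger.warning(
            "%d injectable claim rows with unclassified products", n_unclassified
        )
    return out, n_unclassified


# ---------------------------------------------------------------------------
# Index event
# ---------------------------------------------------------------------------
def find_index_event(
    claims: pd.DataFrame,
    catalog: InsulinCatalog | None = None,
    pre_months: int = 6,
    min_basal_claims: int = 2,
) -> IndexEvent | None:
    """Earliest mealtime fill with >= ``min_basal_claims`` basal fills in its
    own 6-month lookback.

    The lookback is half-open, ``[candidate - pre_months, candidate)``: a
    basal fill on the candidate date itself does not count.  A later
    mealtime fill may qualify when earlier ones do not.  Returns None when
    no mealtime fill qualifies (absence is a valid outcome).
    """
    if "insulin_class" not in claims.columns:
        claims, _ = classify_claims(claims, catalog)
    mealtime = claims[claims["insulin_class"] == "mealtime"].sort_values(
        "fill_date", kind="stable"
    )
    basal_dates = sorted(
        claims.loc[claims["insulin_class"] == "basal", "fill_date"].tolist()
    )
    for _, row in mealtime.iterrows():
        d = row["fill_date"]
        lo = add_months(d, -pre_months)
        n_basal = sum(1 for b in basal_dates if lo <= b < d)
        if n_basal >= min_basal_claims:
            return IndexEvent(
                patient_id=str(row["patient_id"]),
                index_date=d,
                index_type=row["insulin_type"],
                index_form=row.get("form", "vial_syringe"),
            )
    return None


# ---------------------------------------------------------------------------
# Enrollment
# ---------------------------------------------------------------------------
def _merge_spans(
    spans: list[tuple[dt.date, dt.date]], gap_tolerance_days: int
) -> list[tuple[dt.date, dt.date]]:
    merged: list[tuple[dt.date, dt.date]] = []
    for start, end in sorted(spans):
        if merged and (start - merged[-1][1]).days - 1 <= gap_tolerance_days:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def check_enrollment(
    spans: pd.DataFrame,
    index_date: dt.date,
    config: CohortConfig = CohortConfig(),
) -> bool:
    """True iff continuous enrollment covers the full 21-month study window.

    The window is ``[index - pre_months, index + post_months]`` (closed) and
    must also lie inside the configured data calendar bounds.  Adjacent
    spans separated by at most ``config.enrollment_gap_days`` days are
    merged before testing coverage (default 0: only abutting spans merge).
    """
    window_start = add_months(index_date, -config.pre_months)
    window_end = add_months(index_date, config.post_months)
    if window_start < config.data_start or window_end > config.data_end:
        return False
    pairs = [
        (parse_date(s), parse_date(e))
        for s, e in zip(spans["start_date"], spans["end_date"])
    ]
    for start, end in _merge_spans(pairs, config.enrollment_gap_days):
        if start <= window_start and end >= window_end:
            return True
    return False


# ---------------------------------------------------------------------------
# Exclusions
# ---------------------------------------------------------------------------
def _dx_iter(medical: pd.DataFrame):
    for _, row in medical.iterrows():
        date = parse_date(row["service_date"])
        codes = row.get("dx_codes")
        if codes is None or (isinstance(codes, float) and pd.isna(codes)):
            codes = []
        elif isinstance(codes, str):
            codes = [c for c in codes.split(";") if c]
        elif not isinstance(codes, (list, tuple)):
            codes = [str(codes)]
        drg = row.get("drg")
        yield date, codes, drg


def apply_exclusions(
    index: IndexEvent,
    claims: pd.DataFrame,
    medical: pd.DataFrame,
    config: CohortConfig = CohortConfig(),
) -> list[str]:
    """Every exclusion reason that fires for this indexed patient, in
    pipeline order (see :data:`EXCLUSION_REASONS`); empty means included.

    Windows: the T2D diagnosis must fall in the pre-period
    ``[index - 6 months, index)``; gestational / type 1 / inhaled / pump are
    tested over the whole observation period ``[index - 6, index + 15]``
    months; mixture fills over ``(index, index + 15 months]``; and
    ``single_mealtime_claim`` fires when fewer than two mealtime fills fall
    in ``[index, index + 12 months]``.
    """
    d = index.index_date
    pre_start = add_months(d, -config.pre_months)
    obs_end = add_months(d, config.post_months)
    followup_end = add_months(d, config.followup_months)

    has_t2d = has_type1 = has_gestational = False
    for date, codes, drg in _dx_iter(medical):
        if pre_start <= date <= obs_end:
            if any(is_type1_dx(c) for c in codes):
                has_type1 = True
            if any(is_gestational_dx(c) for c in codes):
                has_gestational = True
            if _is_type1_drg(drg):
                has_type1 = True
        if pre_start <= date < d and any(is_t2d_dx(c) for c in codes):
            has_t2d = True

    dates = claims["fill_date"]
    in_obs = (dates >= pre_start) & (dates <= obs_end)
    route = claims.get("route", pd.Series("injectable", index=claims.index))
    inhaled_or_pump = bool((in_obs & route.isin(("inhaled", "pump"))).any())
    mixture_post = bool(
        (
            (claims["insulin_class"] == "mixture") & (dates > d) & (dates <= obs_end)
        ).any()
    )
    n_mealtime_followup = int(
        (
            (claims["insulin_class"] == "mealtime")
            & (dates >= d)
            & (dates <= followup_end)
        ).sum()
    )

    reasons = []
    if not has_t2d:
        reasons.append("no_t2d_dx")
    if has_type1:
        reasons.append("type1")
    if has_gestational:
        reasons.append("gestational")
    if inhaled_or_pump:
        reasons.append("inhaled_or_pump")
    if mixture_post:
        reasons.append("mixture_post_index")
    if n_mealtime_followup < config.min_mealtime_claims:
        reasons.append("single_mealtime_claim")
    return reasons


# ---------------------------------------------------------------------------
# Cohort assembly + attrition
# ---------------------------------------------------------------------------
def attrition_from_counts(labels, remaining) -> pd.DataFrame:
    """Build an attrition table from step labels and remaining counts.

    ``removed`` at step k is ``remaining[k-1] - remaining[k]``; remaining
    counts must be non-increasing.  ``pct_removed_of_prev`` expresses each
    removal against the count entering that step, and
    ``pct_remaining_of_first`` tracks overall retention.
    """
    remaining = [int(r) for r in remaining]
    if any(b > a for a, b in zip(remaining, remaining[1:])):
        raise ValueError("remaining counts must be non-increasing")
    removed = [0] + [a - b for a, b in zip(remaining, remaining[1:])]
    first = remaining[0] if remaining else 0
    prev = [first] + remaining[:-1]
    return pd.DataFrame(
        {
            "step": list(labels),
            "remaining": remaining,
            "removed": removed,
            "pct_removed_of_prev": [
                100.0 * r / p if p else 0.0 for r, p in zip(removed, prev)
            ],
            "pct_remaining_of_first": [
                100.0 * r / first if first else 0.0 for r in remaining
            ],
        }
    )


def build_cohort(
    pharmacy: pd.DataFrame,
    medical: pd.DataFrame,
    enrollment: pd.DataFrame,
    catalog: InsulinCatalog | None = None,
    config: CohortConfig = CohortConfig(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply every inclusion / exclusion step and return (cohort, attrition).

    Step order: mealtime claim -> T2D dx + continuous enrollment (+ index
    inside the accrual window) -> >=2 basal fills in the pre-period ->
    type 1 exclusion -> gestational / inhaled / pump -> mixture post-index
    -> >=2 mealtime claims in follow-up.  For the enrollment/diagnosis step
    the patient is evaluated at their qualifying index event when one
    exists, else at their first mealtime fill (so the attrition steps can
    keep the study's reporting order even though the index definition
    couples the mealtime and basal rules).

    The cohort frame has one row per included patient: patient_id,
    index_date, index_type, index_form.
    """
    claims, n_unclassified = classify_claims(pharmacy, catalog)
    medical = medical.copy()
    if not medical.empty:
        medical["service_date"] = medical["service_date"].map(parse_date)
    enrollment = enrollment.copy()

    counts = {step: 0 for step in ATTRITION_STEPS}
    survivors: dict[str, IndexEvent] = {}

    for patient_id, pclaims in claims.groupby("patient_id", sort=True):
        mealtime = pclaims[pclaims["insulin_class"] == "mealtime"]
        if mealtime.empty:
            continue
        counts["mealtime_claim"] += 1

        index = find_index_event(
            pclaims, pre_months=config.pre_months,
            min_basal_claims=config.min_basal_claims,
        )
        if index is None:
            first = mealtime.sort_values("fill_date", kind="stable").iloc[0]
            eval_index = IndexEvent(
                str(patient_id), first["fill_date"],
                first["insulin_type"], first.get("form", "vial_syringe"),
            )
        else:
            eval_index = index

        if not (config.index_start <= eval_index.index_date <= config.index_end):
            continue
        pmed = medical[medical["patient_id"] == patient_id]
        pre_start = add_months(eval_index.index_date, -config.pre_months)
        has_t2d = any(
            pre_start <= date < eval_index.index_date and any(
                is_t2d_dx(c) for c in codes
            )
            for date, codes, _ in _dx_iter(pmed)
        )
        spans = enrollment[enrollment["patient_id"] == patient_id]
        if not has_t2d or spans.empty or not check_enrollment(
            spans, eval_index.index_date, config
        ):
            continue
        counts["t2d_and_enrollment"] += 1

        if index is None:
            continue
        counts["basal_pre_period"] += 1

        reasons = apply_exclusions(index, pclaims, pmed, config)
        if "type1" in reasons:
            continue
        counts["type1_exclusion"] += 1
        if "gestational" in reasons or "inhaled_or_pump" in reasons:
            continue
        counts["gestational_inhaled_pump"] += 1
        if "mixture_post_index" in reasons:
            continue
        counts["mixture_post_index"] += 1
        if "single_mealtime_claim" in reasons:
            continue
        counts["min_two_mealtime_claims"] += 1
        survivors[str(patient_id)] = index

    attrition = attrition_from_counts(
        ATTRITION_STEPS, [counts[s] for s in ATTRITION_STEPS]
    )
    attrition.attrs["n_unclassified_product_rows"] = n_unclassified
    cohort = pd.DataFrame(
        [
            {
                "patient_id": ev.patient_id,
                "index_date": ev.index_date,
                "index_type": ev.index_type,
                "index_form": ev.index_form,
            }
            for ev in survivors.values()
        ],
        columns=["patient_id", "index_date", "index_type", "index_form"],
    )
    logger.info(
        "cohort: %d included of %d with a mealtime claim",
        len(cohort), counts["mealtime_claim"],
    )
    return cohort, attrition
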