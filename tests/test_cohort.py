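import datetime as dt

import numpy as np
import pandas as pd
import pytest

from rxpersist.cohort import (
    CohortConfig,
    IndexEvent,
    apply_exclusions,
    attrition_from_counts,
    build_cohort,
    check_enrollment,
    find_index_event,
    is_gestational_dx,
    is_t2d_dx,
    is_type1_dx,
)
from rxpersist.synth import SimulationConfig, generate_cohort_dataset

ORIGIN = dt.date(2003, 6, 1)


def medical(rows, patient_id="P1"):
    return pd.DataFrame(
        [
            {
                "patient_id": patient_id,
                "service_date": ORIGIN + dt.timedelta(days=int(day)),
                "dx_codes": codes,
                "drg": drg,
            }
            for day, codes, drg in rows
        ],
        columns=["patient_id", "service_date", "dx_codes", "drg"],
    )


def spans(pairs, patient_id="P1"):
    return pd.DataFrame(
        [
            {
                "patient_id": patient_id,
                "start_date": ORIGIN + dt.timedelta(days=int(a)),
                "end_date": ORIGIN + dt.timedelta(days=int(b)),
            }
            for a, b in pairs
        ]
    )


# ---------------------------------------------------------------------------
# index event
# ---------------------------------------------------------------------------
class TestFindIndexEvent:
    def test_straightforward_qualification(self, claim_builder):
        claims = claim_builder(
            [(-120, "LANTUS"), (-60, "LANTUS"), (0, "HUMALOG")]
        )
        index = find_index_event(claims)
        assert index is not None
        assert index.index_date == ORIGIN
        assert (index.index_type, index.index_form) == ("analog", "vial_syringe")

    def test_later_mealtime_claim_rescues_patient(self, claim_builder):
        # first mealtime fill has only one basal fill in its lookback; the
        # second mealtime fill sees two and becomes the index
        claims = claim_builder(
            [(-60, "LANTUS"), (0, "HUMALOG"), (10, "LANTUS"), (40, "HUMALOG")]
        )
        index = find_index_event(claims)
        assert index is not None
        assert index.index_date == ORIGIN + dt.timedelta(days=40)

    def test_no_basal_claims_means_no_index(self, claim_builder):
        assert find_index_event(claim_builder([(0, "HUMALOG"), (30, "NOVOLOG")])) is None

    def test_basal_on_candidate_date_does_not_count(self, claim_builder):
        # lookback is half-open: [index - 6 months, index)
        claims = claim_builder([(-30, "LANTUS"), (0, "LANTUS"), (0, "HUMALOG")])
        assert find_index_event(claims) is None

    def test_basal_just_outside_six_months_does_not_count(self, claim_builder):
        # 6 calendar months before 2003-06-01 is 2002-12-01 (182 days)
        claims = claim_builder([(-183, "LANTUS"), (-30, "LANTUS"), (0, "HUMALOG")])
        assert find_index_event(claims) is None
        claims = claim_builder([(-182, "LANTUS"), (-30, "LANTUS"), (0, "HUMALOG")])
        assert find_index_event(claims).index_date == ORIGIN


# ---------------------------------------------------------------------------
# enrollment
# ---------------------------------------------------------------------------
class TestCheckEnrollment:
    def test_single_covering_span(self):
        assert check_enrollment(spans([(-7 * 31, 16 * 31)]), ORIGIN)

    def test_span_short_of_post_window_fails(self):
        # ends ~14 months after index, 15 required
        assert not check_enrollment(spans([(-7 * 31, 14 * 30)]), ORIGIN)

    def test_abutting_spans_merge(self):
        # end day of first = start day of second - 1
        assert check_enrollment(spans([(-220, 100), (101, 500)]), ORIGIN)

    def test_one_day_hole_needs_gap_tolerance(self):
        holed = spans([(-220, 100), (102, 500)])
        assert not check_enrollment(holed, ORIGIN)
        assert check_enrollment(
            holed, ORIGIN, CohortConfig(enrollment_gap_days=1)
        )

    def test_window_outside_data_bounds_fails(self):
        early = dt.date(2001, 4, 1)  # pre-period would reach before 2001-01-01
        assert not check_enrollment(
            spans([(-3000, 3000)], patient_id="P1"), early
        )


# ---------------------------------------------------------------------------
# diagnosis code predicates
# ---------------------------------------------------------------------------
@pytest.mark.parametrize("code,t1,t2,gest", [
    ("250.11", True, False, False),
    ("250.13", True, False, False),
    ("250.01", True, False, False),
    ("250.00", False, True, False),
    ("250.02", False, True, False),
    ("250.0", False, True, False),
    ("648.81", False, False, True),
    ("401.9", False, False, False),
])
def test_icd9_predicates(code, t1, t2, gest):
    assert is_type1_dx(code) is t1
    assert is_t2d_dx(code) is t2
    assert is_gestational_dx(code) is gest


# ---------------------------------------------------------------------------
# exclusions
# ---------------------------------------------------------------------------
class TestApplyExclusions:
    def index(self):
        return IndexEvent("P1", ORIGIN, "analog", "vial_syringe")

    def base_claims(self, claim_builder, extra=()):
        rows = [(-120, "LANTUS"), (-60, "LANTUS"), (0, "HUMALOG"),
                (45, "HUMALOG"), (120, "HUMALOG")]
        return claim_builder(rows + list(extra))

    def base_medical(self):
        return medical([(-90, "250.00", "")])

    def classify(self, claims):
        from rxpersist.cohort import classify_claims
        return classify_claims(claims)[0]

    def test_clean_patient_has_no_reasons(self, claim_builder):
        reasons = apply_exclusions(
            self.index(), self.classify(self.base_claims(claim_builder)),
            self.base_medical(),
        )
        assert reasons == []

    def test_type1_code_fires_anytime_in_observation(self, claim_builder):
        med = pd.concat([self.base_medical(), medical([(300, "250.11", "")])])
        reasons = apply_exclusions(
            self.index(), self.classify(self.base_claims(claim_builder)), med
        )
        assert reasons == ["type1"]

    def test_type1_drg_295_fires(self, claim_builder):
        med = pd.concat([self.base_medical(), medical([(10, "", "295")])])
        assert "type1" in apply_exclusions(
            self.index(), self.classify(self.base_claims(claim_builder)), med
        )

    def test_mixture_post_index_fires(self, claim_builder):
        claims = self.base_claims(claim_builder, [(30, "HUMULIN 70/30")])
        reasons = apply_exclusions(self.index(), self.classify(claims),
                                   self.base_medical())
        assert reasons == ["mixture_post_index"]

    def test_mixture_in_pre_period_does_not_fire(self, claim_builder):
        claims = self.base_claims(claim_builder, [(-30, "HUMULIN 70/30")])
        assert apply_exclusions(self.index(), self.classify(claims),
                                self.base_medical()) == []

    def test_single_mealtime_claim_fires(self, claim_builder):
        claims = claim_builder([(-120, "LANTUS"), (-60, "LANTUS"), (0, "HUMALOG")])
        reasons = apply_exclusions(self.index(), self.classify(claims),
                                   self.base_medical())
        assert reasons == ["single_mealtime_claim"]

    def test_second_mealtime_claim_after_followup_does_not_rescue(
        self, claim_builder
    ):
        # second fill 13 months out: outside the 12-month follow-up
        claims = claim_builder(
            [(-120, "LANTUS"), (-60, "LANTUS"), (0, "HUMALOG"), (400, "HUMALOG")]
        )
        assert "single_mealtime_claim" in apply_exclusions(
            self.index(), self.classify(claims), self.base_medical()
        )

    def test_inhaled_and_pump_routes_fire(self, claim_builder):
        claims = self.base_claims(
            claim_builder, [(90, "EXUBERA", "other", "inhaled")]
        )
        assert "inhaled_or_pump" in apply_exclusions(
            self.index(), self.classify(claims), self.base_medical()
        )

    def test_missing_t2d_dx_fires(self, claim_builder):
        reasons = apply_exclusions(
            self.index(), self.classify(self.base_claims(claim_builder)),
            medical([(30, "250.00", "")]),  # dx after index, not pre-period
        )
        assert reasons == ["no_t2d_dx"]

    def test_gestational_fires(self, claim_builder):
        med = pd.concat([self.base_medical(), medical([(-100, "648.83", "")])])
        assert "gestational" in apply_exclusions(
            self.index(), self.classify(self.base_claims(claim_builder)), med
        )


# ---------------------------------------------------------------------------
# build_cohort on generator scenarios with known truth
# ---------------------------------------------------------------------------
def clean_config(**kwargs):
    # tight ~30-day refills and zero hazard: no natural discontinuation or
    # single-claim patients, so planted contaminants are the only exclusions
    base = dict(
        n_patients=80,
        seed=42,
        discontinuation_hazard=0.0,
        refill_shape=900.0,
        refill_scale=1.0 / 30.0,
        refill_frailty_sigma=0.0,
        contaminant_rates={},
    )
    base.update(kwargs)
    return SimulationConfig(**base)


class TestBuildCohort:
    def test_clean_patients_all_included(self):
        ds = generate_cohort_dataset(clean_config())
        cohort, attrition = build_cohort(ds.pharmacy, ds.medical, ds.enrollment)
        assert len(cohort) == 80
        assert (attrition["removed"] == 0).all()
        assert attrition["remaining"].iloc[0] == 80

    def test_planted_contaminants_recovered_exactly(self):
        cfg = clean_config(
            n_patients=120,
            contaminant_counts={
                "type1": 10, "mixture_post_index": 5, "single_mealtime_claim": 20
            },
        )
        ds = generate_cohort_dataset(cfg)
        cohort, attrition = build_cohort(ds.pharmacy, ds.medical, ds.enrollment)
        removed = dict(zip(attrition["step"], attrition["removed"]))
        assert removed["type1_exclusion"] == 10
        assert removed["mixture_post_index"] == 5
        assert removed["min_two_mealtime_claims"] == 20
        assert len(cohort) == 120 - 35
        truth_clean = set(
            ds.truth.loc[ds.truth["planted_exclusion_reason"] == "", "patient_id"]
        )
        assert set(cohort["patient_id"]) == truth_clean

    def test_attrition_conservation_and_shuffle_invariance(self):
        cfg = clean_config(
            n_patients=60, contaminant_counts={"type1": 5, "gestational": 3}
        )
        ds = generate_cohort_dataset(cfg)
        cohort, attrition = build_cohort(ds.pharmacy, ds.medical, ds.enrollment)
        assert len(cohort) + attrition["removed"].sum() == attrition["remaining"].iloc[0]

        rng = np.random.default_rng(0)
        shuffled = ds.pharmacy.sample(frac=1.0, random_state=rng.integers(2**31))
        cohort2, attrition2 = build_cohort(shuffled, ds.medical, ds.enrollment)
        pd.testing.assert_frame_equal(
            cohort.reset_index(drop=True), cohort2.reset_index(drop=True)
        )
        pd.testing.assert_frame_equal(attrition, attrition2)

    def test_idempotent_on_own_output(self):
        ds = generate_cohort_dataset(clean_config(n_patients=40, seed=3))
        cohort, _ = build_cohort(ds.pharmacy, ds.medical, ds.enrollment)
        kept = set(cohort["patient_id"])
        cohort2, _ = build_cohort(
            ds.pharmacy[ds.pharmacy["patient_id"].isin(kept)],
            ds.medical[ds.medical["patient_id"].isin(kept)],
            ds.enrollment[ds.enrollment["patient_id"].isin(kept)],
        )
        assert set(cohort2["patient_id"]) == kept

    def test_empty_input_gives_empty_cohort(self):
        empty = pd.DataFrame(
            columns=["patient_id", "fill_date", "product_name", "quantity_ml",
                     "copay", "form", "route"]
        )
        med = pd.DataFrame(columns=["patient_id", "service_date", "dx_codes", "drg"])
        enr = pd.DataFrame(columns=["patient_id", "start_date", "end_date"])
        cohort, attrition = build_cohort(empty, med, enr)
        assert cohort.empty
        assert (attrition["remaining"] == 0).all()


# ---------------------------------------------------------------------------
# attrition arithmetic helper
# ---------------------------------------------------------------------------
def test_attrition_from_counts_arithmetic():
    table = attrition_from_counts(
        ["a", "b", "c"], [1000, 400, 300]
    )
    assert table["removed"].tolist() == [0, 600, 100]
    assert table["pct_removed_of_prev"].tolist() == [0.0, 60.0, 25.0]
    assert table["pct_remaining_of_first"].tolist() == [100.0, 40.0, 30.0]


def test_attrition_from_counts_rejects_increasing():
    with pytest.raises(ValueError):
        attrition_from_counts(["a", "b"], [10, 20])
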