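# Methods

This note records the modelling choices behind `rxpersist`: the cohort and
persistence rules as implemented, the synthetic-data model and its
calibration, the statistical machinery, and what the package's passing
tests do and do not establish about real claims data.

## Study design implemented

The pipeline reproduces a retrospective new-user design on pharmacy/medical
claims. Day 0 is the **index event**: the earliest mealtime-insulin fill
with ≥ 2 basal-insulin fills strictly inside its own 6-calendar-month
lookback `[index − 6 mo, index)`. A later mealtime fill may qualify when
earlier ones do not — the rule is "first *qualifying* fill", so a patient
whose first mealtime fill lacks the basal history can still enter at a
subsequent fill. A basal fill on the candidate date itself does not count
(the lookback is half-open).

Inclusion further requires a type-2-compatible diabetes code in the
pre-period and continuous enrollment over `[index − 6 mo, index + 15 mo]`
(closed), inside configurable calendar bounds (defaults: index accrual
2001-07-01 … 2006-12-31, data 2001-01-01 … 2008-03-31). Adjacent enrollment
spans merge when separated by at most `enrollment_gap_days` (default 0:
only abutting spans merge).

Exclusions, tested over the full 21-month observation window unless noted:
type 1 diabetes (ICD-9-CM 250.x1 / 250.x3, or DRG 295), gestational
diabetes (648.8x), inhaled-insulin or pump use (flagged by a claim-level
`route` attribute, since the product table contains no inhaled product),
any insulin-mixture fill in `(index, index + 15 mo]`, and fewer than two
mealtime fills in `[index, index + 12 mo]`. The attrition table applies the
steps in a fixed order (diagnosis/enrollment → basal history → type 1 →
gestational/inhaled/pump → mixture → second mealtime claim) and attributes
each removal to the first step that fires.

ICD-9-CM detail: only the type 1 and gestational code patterns are fixed by
the design; for the type 2 *inclusion* the package accepts 250, 250.x and
250.x0 / 250.x2 (the standard non-type-1 fifth digits). Codes are matched
on syntax only. The Deyo–Charlson comorbidity score is consumed as a
supplied integer covariate; its ICD mapping is out of scope.

## Date arithmetic

Everything is calendar months anchored at the index date, via
`dateutil.relativedelta`, with end-of-month clamping
(Jan 31 + 1 mo = Feb 28). Month *m* of follow-up is
`[boundary(m − 1), boundary(m))`; every analysis window is half-open except
the enrollment/observation window, which is closed. The refill-gap rule
uses **strictly greater than** 90 days (an exact 90-day refill cycle is not
a gap) and a gap starting exactly on a horizon boundary does not disqualify
that horizon ("started prior to the end" is strict).

## Persistence classifiers

**Measure 1 (gap rule).** Fill dates are deduplicated (same-day fills are
one refill event in time); gaps are intervals > `gap_threshold_days`
between consecutive fills, plus a terminal gap when the residue from the
last fill to `index + 15 mo` exceeds the threshold. The 15-month window
exists precisely so that the 12-month horizon has ≥ 90 assessable days
after month 12. Persistent at *h* iff no gap starts before `boundary(h)`;
otherwise the discontinuation date is the earliest such gap's start (the
last fill before the gap). Measure 1 is monotone over horizons by
construction.

**Measure 2 (quarterly rule).** Pure claim counting (same-day duplicates
count; the index claim counts): ≥ 2 claims in months 1–4 for the 3-month
horizon — deliberately one month longer than the horizon, exactly as the
rule is defined; ≥ 3 claims in months 1–7 with ≥ 1 in months 1–3 and ≥ 1 in
months 4–6 for the 6-month horizon; ≥ 4 claims in months 1–12 with ≥ 1 per
index-anchored quarter for 12 months. Measure 2 is *not* monotone over
horizons (one claim per quarter passes at 12 months but fails at 6) — the
suite asserts the witness rather than smoothing it away. An earlier variant
of this rule that additionally required ≥ 0.10 mL/day average supply is
deliberately not implemented.

Both classifiers see only fills inside `[index, index + 15 mo]`; injected
claims outside the window are ignored (tested). Non-persistence is not
discontinuation: non-persistent patients keep all downstream metrics, and
the gap analytics report the time from the first gap to the next fill
because most gaps are followed by further fills (intermittent use).

Property guarantees enforced by tests: measure-1 monotonicity over
horizons, measure-1 ⇒ measure-2 at every horizon (dominance — measure 2 is
the more lenient rule), and exact agreement of the gap detector with an
O(n²) all-pairs + terminal-residue brute-force oracle on thousands of
random sequences.

## Synthetic-data model

Each simulated patient has:

* **Covariates** drawn from marginal frequencies typical of a commercially
  insured T2D population intensifying insulin (49% female; age mode 55–64;
  ~40% human and ~13% pen at index; Charlson mean 2.2; mental-health 7.7%;
  per-claim copay lognormal with mean ≈ $18).
* **A latent discontinuation day** `T ~ Exponential(λ_i)` with
  `λ_i = λ₀ · exp(Σ β_k x_ik)`. Behaviour (stopping) is separated from
  observation (refills), which is what makes parameter-recovery experiments
  exact: the generator records `T` and every planted effect in a truth
  table. Default `λ₀ = 1/1500` per day.
* **Mealtime refills**: a renewal process with gamma(shape 1.5,
  scale 85 d) increments, scaled per patient by a lognormal **refill
  frailty** `exp(N(0, σ))`, σ = 1.4, median multiplier 1. The frailty is
  essential, not cosmetic: real cohorts mix fast refillers (~6-week cycles)
  with sporadic users, and without it gap-rule persistence at 12 months is
  a sub-1% event and the persistence outcome degenerates. Defaults put the
  cohort median of per-patient mean refill intervals near 72 days with a
  heavy right tail (cohort mean ≈ 94 days), 12-month gap-rule persistence
  in the mid-teens and quarterly-rule persistence near 40%.
* **A restart process**: after discontinuation, with probability 0.85 the
  patient fills again, 90 + Exponential(70) days after the last fill, and
  resumes the renewal process — reproducing the qualitative finding that
  the large majority of refill gaps are followed by further claims.
* **Pre-period structure** (2 basal fills, a T2D diagnosis, covering
  enrollment) and **post-index basal refills** (gamma, mean ≈ 55 d).
* **Planted contaminants**, mutually exclusive and recorded in the truth
  table: type 1 codes or DRG 295, gestational codes, inhaled/pump routes,
  post-index mixture fills, missing T2D diagnosis, or forced single-claim
  behaviour. Contaminants can be drawn at configured rates or planted at
  exact counts (used by the exact-recovery tests).

Everything is deterministic given `(config, seed)`; per-patient RNG streams
are spawned from a single seed sequence so datasets are byte-identical
across runs.

**What the generator does not emulate.** Within-patient autocorrelation of
refill timing beyond the frailty, seasonal/calendar effects, days-supply
fields (the design is deliberately date-based), dose titration, realistic
ICD-9 breadth, plan-design and pricing realism, and provider effects. The
generated cohort's persistence proportions are in the neighbourhood of, but
deliberately not fitted to, real published cohorts; passing tests establish
the *correctness of the algorithms and the recoverability of planted
effects*, not the real-world representativeness of any particular
percentage.

## Statistical analyses

Bivariate comparisons use Pearson χ² without continuity correction for
categorical covariates (checked against the closed form Σ(O−E)²/E), the
two-tailed pooled-variance *t* test for continuous covariates between two
groups, and one-way ANOVA for more. Degenerate cells (strata under 2
patients, zero-variance covariates) are flagged, not tested. No
multiple-testing correction is applied; α = 0.05 throughout.

The persistence models are maximum-likelihood logistic regressions
(statsmodels) of 12-month persistence on the covariate set, with
categorical covariates dummy-coded against fixed reference levels
(age 45–54, region NorthEast, non-capitated, male). Intervals are Wald:
`exp(β ± 1.96·SE)` — deterministic, fast, and standard for claims studies;
profile-likelihood intervals were deliberately not used. Continuous
covariates (Charlson, OAD-class count, average insulin copay) enter
linearly, giving per-unit odds ratios. Perfect separation is reported as a
fit diagnostic (with a small-ridge fallback for point estimates), never an
exception. The average insulin copay covariate is the mean copay across the
patient's basal/mealtime claims in the observation window.

## Experiment designs in the acceptance suite

* **Effect recovery.** A single planted log hazard ratio of 0.5 on
  `index_human` with baseline hazard 1/600 per day; at these settings the
  marginal 12-month persistence OR is ≈ 0.65, so the per-replicate log-OR
  SE (~0.075 at n = 5,000) makes the sign essentially deterministic and
  coverage is governed by the Wald interval. Ground truth is the marginal
  OR from one independent n = 150,000 simulation (Monte-Carlo error ~0.012
  on the log-OR scale, negligible against the per-replicate SE). The
  criterion is ≥ 90% of 50 replicates producing OR < 1 with the CI covering
  truth.
* **Null calibration.** 200 replicates of n = 1,000 with all covariate
  effects zero; for each covariate the count of p < 0.05 rejections must
  fall in [2, 20] — a ≈ 99.5% band for Binomial(200, 0.05).
* **Exact exclusion recovery.** n = 2,000 with contaminants planted at
  exact counts and a steady ~30-day refill model (zero hazard, zero
  frailty), so planted records are the *only* possible exclusions and
  attrition removals must equal truth counts exactly.

Problem sizes throughout (3,000-patient pipeline runs in the acceptance
script; 150k/50×5k/200×1k in the simulation experiments) were chosen as
the smallest sizes at which the Monte-Carlo error of each check is
comfortably below its decision threshold.

## Known limitations and open choices

* The attrition step "diagnosis + enrollment" is evaluated at the
  qualifying index when one exists, else at the first mealtime fill; this
  keeps the conventional reporting order even though the index definition
  couples the mealtime and basal rules.
* Gap analytics pool all mealtime-class products; switching is analyzed
  separately. Restricting gaps to the index product is a defensible
  alternative reading and can be obtained by filtering the claims before
  calling the exposure functions, but the pooled definition is the default.
* Proportion-of-days-covered metrics and days-supply-based gaps are
  intentionally out of scope: the design is fill-date-based.
* The index accrual end date and the exact T2D code list are configuration
  defaults, not facts the package can validate.
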