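"""Synthetic pharmacy-claims generator with known ground truth.

Emulates the structure of an administrative claims extract for patients with
type 2 diabetes who add mealtime insulin to a stable basal regimen:

* a 6-month pre-period with >=2 basal fills and a T2D diagnosis;
* mealtime refills whose inter-fill intervals follow a gamma model scaled
  per patient by a lognormal *refill frailty* with median 1 — fast
  refillers coexist with slow ones, which is what makes gap-based
  persistence a non-degenerate patient-level trait rather than pure
  interval noise.  Defaults (gamma shape 1.5, scale 85 days, frailty sigma
  1.4) put the cohort median of per-patient mean refill intervals near 72
  days with a heavy right tail (cohort mean ~94 days);
* a *latent discontinuation day* drawn from a covariate-linked exponential
  hazard — behaviour (stopping) is separated from observation (refills), so
  parameter-recovery experiments have an exact truth;
* a restart process after discontinuation (default: probability 0.85 of at
  least one later fill, delayed past the 90-day gap threshold), emulating
  the finding that most refill gaps are followed by further claims;
* planted contaminant records that trigger each cohort exclusion rule, with
  the planted reason recorded in a per-patient truth table.

Everything is deterministic given (config, seed).
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .dates import add_months, parse_date

__all__ = [
    "SimulationConfig",
    "SyntheticDataset",
    "generate_patient",
    "generate_cohort_dataset",
    "simulate_persistence_sample",
]

AGE_GROUPS = ("<18", "18-34", "35-44", "45-54", "55-64", "65-74", ">=75")
AGE_RANGES = {
    "<18": (10, 17), "18-34": (18, 34), "35-44": (35, 44), "45-54": (45, 54),
    "55-64": (55, 64), "65-74": (65, 74), ">=75": (75, 90),
}
REGIONS = ("NorthEast", "North Central", "South", "West", "Unknown")

MEALTIME_HUMAN = ("HUMULIN R", "NOVOLIN R")
MEALTIME_ANALOG = ("HUMALOG", "NOVOLOG", "APIDRA")
BASAL_HUMAN = ("HUMULIN N", "NOVOLIN N")
BASAL_ANALOG = ("LANTUS", "LEVEMIR")
MIXTURES = ("HUMULIN 70/30", "NOVOLOG MIX 70/30")
TYPE1_CODES = ("250.01", "250.03", "250.11", "250.13")
GESTATIONAL_CODES = ("648.81", "648.83")
T2D_CODES = ("250.00", "250.02")

CONTAMINANT_REASONS = (
    "no_t2d_dx",
    "type1",
    "gestational",
    "inhaled_or_pump",
    "mixture_post_index",
    "single_mealtime_claim",
)


def _default_effects() -> dict[str, float]:
    # log hazard ratios on the daily discontinuation hazard
    return {"index_human": 0.25, "mental_health": 0.25, "avg_insulin_copay": 0.004}


def _default_contaminants() -> dict[str, float]:
    return {
        "type1": 0.05,
        "gestational": 0.003,
        "inhaled_or_pump": 0.003,
        "mixture_post_index": 0.11,
        "single_mealtime_claim": 0.0,
        "no_t2d_dx": 0.0,
    }


def _default_prevalence() -> dict[str, Any]:
    # marginal covariate frequencies typical of a commercially insured
    # T2D population intensifying insulin therapy
    return {
        "p_female": 0.489,
        "age_group_probs": [0.0017, 0.0149, 0.0676, 0.2346, 0.3411, 0.1995, 0.1406],
        "region_probs": [0.20, 0.25, 0.35, 0.19, 0.01],
        "p_rural": 0.195,
        "p_capitated": 0.15,
        "charlson_mean": 2.2,
        "p_er": 0.03,
        "p_inpatient": 0.06,
        "p_diabetes_complications": 0.318,
        "p_macrovascular": 0.502,
        "p_mental_health": 0.077,
        "oad_mean": 1.03,
    }


@dataclass
class SimulationConfig:
    """All knobs of the generator, with defaults defining the study conditions.

    ``covariate_effects`` maps covariate names (boolean covariates contribute
    their indicator; ``avg_insulin_copay`` its dollar value) to log hazard
    ratios multiplying ``discontinuation_hazard``.
    """

    n_patients: int = 1000
    seed: int = 0
    # refill behaviour (days)
    refill_shape: float = 1.5
    refill_scale: float = 85.0
    refill_frailty_sigma: float = 1.4
    basal_refill_shape: float = 2.0
    basal_refill_scale: float = 27.5
    # latent discontinuation
    discontinuation_hazard: float = 1.0 / 1500.0  # per day
    covariate_effects: dict[str, float] = field(default_factory=_default_effects)
    restart_probability: float = 0.85
    restart_delay_scale: float = 70.0
    gap_threshold_days: int = 90
    # product mix at index
    p_human_index: float = 0.40
    p_pen_index: float = 0.13
    p_type_switch_per_fill: float = 0.065
    p_form_switch_per_fill: float = 0.008
    # contaminants
    contaminant_rates: dict[str, float] = field(default_factory=_default_contaminants)
    contaminant_counts: dict[str, int] | None = None
    # calendar
    index_start: dt.date = dt.date(2002, 1, 1)
    index_end: dt.date = dt.date(2006, 12, 31)
    pre_months: int = 6
    post_months: int = 15
    # quantities and costs
    quantity_ml: float = 10.0
    copay_mu: float = 2.56  # patient-level lognormal -> mean copay ~ $18/claim
    copay_sigma: float = 0.8
    covariate_prevalence: dict[str, Any] = field(default_factory=_default_prevalence)

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        for name in ("refill_shape", "refill_scale", "basal_refill_shape",
                     "basal_refill_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.discontinuation_hazard < 0:
            raise ValueError("discontinuation_hazard must be >= 0")
        if self.refill_frailty_sigma < 0:
            raise ValueError("refill_frailty_sigma must be >= 0")
        probs = [self.restart_probability, self.p_human_index, self.p_pen_index,
                 self.p_type_switch_per_fill, self.p_form_switch_per_fill,
                 *self.contaminant_rates.values()]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if sum(self.contaminant_rates.values()) > 1.0:
            raise ValueError("contaminant rates must sum to <= 1")
        unknown = set(self.contaminant_rates) - set(CONTAMINANT_REASONS)
        if unknown:
            raise ValueError(f"unknown contaminant reasons: {sorted(unknown)}")
        if self.index_start > self.index_end:
            raise ValueError("index_start must be <= index_end")

    # -- (de)serialization -------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["index_start"] = self.index_start.isoformat()
        data["index_end"] = self.index_end.isoformat()
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "SimulationConfig":
        kwargs = dict(data)
        for key in ("index_start", "index_end"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = parse_date(kwargs[key])
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    def replace(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# per-patient machinery
# ---------------------------------------------------------------------------
def _draw_covariates(rng: np.random.Generator, cfg: SimulationConfig) -> dict:
    p = cfg.covariate_prevalence
    age_group = AGE_GROUPS[rng.choice(len(AGE_GROUPS), p=np.asarray(
        p["age_group_probs"]) / np.sum(p["age_group_probs"]))]
    lo, hi = AGE_RANGES[age_group]
    region = REGIONS[rng.choice(len(REGIONS), p=np.asarray(
        p["region_probs"]) / np.sum(p["region_probs"]))]
    return {
        "gender": "F" if rng.random() < p["p_female"] else "M",
        "age": int(rng.integers(lo, hi + 1)),
        "age_group": age_group,
        "region": region,
        "rural": int(rng.random() < p["p_rural"]),
        "capitated": int(rng.random() < p["p_capitated"]),
        "charlson": int(min(rng.poisson(p["charlson_mean"]), 10)),
        "er_any": int(rng.random() < p["p_er"]),
        "inpatient_any": int(rng.random() < p["p_inpatient"]),
        "diabetes_complications": int(rng.random() < p["p_diabetes_complications"]),
        "macrovascular_complications": int(rng.random() < p["p_macrovascular"]),
        "mental_health": int(rng.random() < p["p_mental_health"]),
        "n_oad_classes": int(min(rng.poisson(p["oad_mean"]), 6)),
    }


def _patient_hazard(cfg: SimulationConfig, cov: dict, index_human: bool,
                    index_pen: bool, copay_mean: float) -> float:
    x = dict(cov)
    x["index_human"] = int(index_human)
    x["index_pen"] = int(index_pen)
    x["avg_insulin_copay"] = copay_mean
    lp = 0.0
    for name, beta in cfg.covariate_effects.items():
        if name not in x:
            raise KeyError(f"covariate_effects references unknown covariate {name!r}")
        lp += beta * float(x[name])
    return cfg.discontinuation_hazard * math.exp(lp)


def _simulate_mealtime_days(
    rng: np.random.Generator,
    cfg: SimulationConfig,
    hazard: float,
    obs_days: int,
    refill_scale: float | None = None,
) -> tuple[list[int], float | None]:
    """Day offsets of mealtime fills (index fill at day 0) and the latent
    discontinuation day (None when it falls beyond the observation window).

    ``refill_scale`` is the patient's frailty-adjusted gamma scale; default
    draws it as ``cfg.refill_scale * exp(N(0, cfg.refill_frailty_sigma))``.
    """
    if refill_scale is None:
        refill_scale = cfg.refill_scale * math.exp(
            rng.normal(0.0, cfg.refill_frailty_sigma)
        )
    disc = rng.exponential(1.0 / hazard) if hazard > 0 else math.inf
    stop = min(disc, obs_days)
    days = [0]
    t = 0.0
    while True:
        t += rng.gamma(cfg.refill_shape, refill_scale)
        if t >= stop:
            break
        days.append(int(round(t)))
    if disc < obs_days and rng.random() < cfg.restart_probability:
        t = days[-1] + cfg.gap_threshold_days + rng.exponential(
            cfg.restart_delay_scale
        )
        while t < obs_days:
            days.append(int(round(t)))
            t += rng.gamma(cfg.refill_shape, refill_scale)
    return days, (float(disc) if disc < obs_days else None)


def _choose_contaminants(
    rng: np.random.Generator, cfg: SimulationConfig
) -> list[str | None]:
    """Planted exclusion reason per patient (None = clean)."""
    n = cfg.n_patients
    if cfg.contaminant_counts is not None:
        reasons: list[str | None] = []
        for reason, count in cfg.contaminant_counts.items():
            if reason not in CONTAMINANT_REASONS:
                raise ValueError(f"unknown contaminant reason {reason!r}")
            reasons.extend([reason] * int(count))
        if len(reasons) > n:
            raise ValueError("contaminant_counts exceed n_patients")
        reasons.extend([None] * (n - len(reasons)))
        rng.shuffle(reasons)
        return reasons
    names = list(cfg.contaminant_rates)
    rates = np.array([cfg.contaminant_rates[r] for r in names], dtype=float)
    probs = np.append(rates, max(0.0, 1.0 - rates.sum()))
    draws = rng.choice(len(names) + 1, size=n, p=probs / probs.sum())
    return [names[i] if i < len(names) else None for i in draws]


def generate_patient(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    patient_id: str,
    planted_reason: str | None = None,
) -> dict[str, list[dict]]:
    """All table rows plus the truth row for one simulated patient."""
    cov = _draw_covariates(rng, cfg)
    index_human = rng.random() < cfg.p_human_index
    index_pen = rng.random() < cfg.p_pen_index
    copay_mean = float(rng.lognormal(cfg.copay_mu, cfg.copay_sigma))
    hazard = _patient_hazard(cfg, cov, index_human, index_pen, copay_mean)

    span_days = (cfg.index_end - cfg.index_start).days
    index_date = cfg.index_start + dt.timedelta(days=int(rng.integers(span_days + 1)))
    obs_end = add_months(index_date, cfg.post_months)
    obs_days = (obs_end - index_date).days

    def day(offset: int) -> dt.date:
        return index_date + dt.timedelta(days=int(offset))

    def fill(offset, product, form="vial_syringe", route="injectable", ml=None):
        q = float(ml if ml is not None else cfg.quantity_ml * rng.lognormal(0, 0.25))
        return {
            "patient_id": patient_id,
            "fill_date": day(offset),
            "product_name": product,
            "quantity_ml": round(q, 1),
            "copay": round(copay_mean * rng.lognormal(-0.045, 0.3), 2),
            "form": form,
            "route": route,
        }

    pharmacy: list[dict] = []
    medical: list[dict] = []

    # --- pre-period: stable basal therapy + T2D diagnosis -----------------
    basal_type = "human" if rng.random() < cfg.p_human_index else "analog"
    basal_products = BASAL_HUMAN if basal_type == "human" else BASAL_ANALOG
    basal_product = basal_products[rng.integers(len(basal_products))]
    for offset in (-int(rng.integers(95, 176)), -int(rng.integers(10, 91))):
        pharmacy.append(fill(offset, basal_product))
    if planted_reason != "no_t2d_dx":
        medical.append({
            "patient_id": patient_id,
            "service_date": day(-int(rng.integers(30, 171))),
            "dx_codes": T2D_CODES[rng.integers(len(T2D_CODES))],
            "drg": "",
        })

    # --- mealtime refills --------------------------------------------------
    if planted_reason == "single_mealtime_claim":
        mealtime_days, disc = [0], 1.0
    else:
        mealtime_days, disc = _simulate_mealtime_days(rng, cfg, hazard, obs_days)
    mt_type = "human" if index_human else "analog"
    form = "pen" if index_pen else "vial_syringe"
    products = {
        "human": MEALTIME_HUMAN[rng.integers(len(MEALTIME_HUMAN))],
        "analog": MEALTIME_ANALOG[rng.integers(len(MEALTIME_ANALOG))],
    }
    for i, offset in enumerate(mealtime_days):
        if i > 0 and rng.random() < cfg.p_type_switch_per_fill:
            mt_type = "analog" if mt_type == "human" else "human"
        if i > 0 and rng.random() < cfg.p_form_switch_per_fill:
            form = "vial_syringe" if form == "pen" else "pen"
        pharmacy.append(fill(offset, products[mt_type], form=form))

    # --- post-index basal refills ------------------------------------------
    t = float(rng.uniform(0, 40))
    while t < obs_days:
        pharmacy.append(fill(int(round(t)), basal_product))
        t += rng.gamma(cfg.basal_refill_shape, cfg.basal_refill_scale)

    # --- planted contaminant evidence ---------------------------------------
    if planted_reason == "type1":
        if rng.random() < 0.2:
            medical.append({
                "patient_id": patient_id,
                "service_date": day(int(rng.integers(-150, obs_days))),
                "dx_codes": "",
                "drg": "295",
            })
        else:
            medical.append({
                "patient_id": patient_id,
                "service_date": day(int(rng.integers(-150, obs_days))),
                "dx_codes": TYPE1_CODES[rng.integers(len(TYPE1_CODES))],
                "drg": "",
            })
    elif planted_reason == "gestational":
        medical.append({
            "patient_id": patient_id,
            "service_date": day(int(rng.integers(-150, obs_days))),
            "dx_codes": GESTATIONAL_CODES[rng.integers(len(GESTATIONAL_CODES))],
            "drg": "",
        })
    elif planted_reason == "inhaled_or_pump":
        if rng.random() < 0.5:
            pharmacy.append(fill(int(rng.integers(0, obs_days)), "EXUBERA",
                                 route="inhaled"))
        else:
            pharmacy.append(fill(int(rng.integers(0, obs_days)),
                                 products[mt_type], route="pump"))
    elif planted_reason == "mixture_post_index":
        pharmacy.append(fill(int(rng.integers(10, min(401, obs_days))),
                             MIXTURES[rng.integers(len(MIXTURES))]))

    # --- enrollment ---------------------------------------------------------
    enrollment = [{
        "patient_id": patient_id,
        "start_date": add_months(index_date, -cfg.pre_months)
        - dt.timedelta(days=int(rng.integers(0, 61))),
        "end_date": obs_end + dt.timedelta(days=int(rng.integers(0, 61))),
    }]

    demographics = [{"patient_id": patient_id, **cov}]
    truth = [{
        "patient_id": patient_id,
        "latent_discontinuation_day": (
            round(disc, 2) if disc is not None else ""
        ),
        "planted_exclusion_reason": planted_reason or "",
        "index_date": index_date,
        "index_human": int(index_human),
        "index_pen": int(index_pen),
        "copay_mean": round(copay_mean, 4),
        "hazard_per_day": hazard,
        **cov,
    }]
    return {
        "pharmacy": pharmacy,
        "medical": medical,
        "enrollment": enrollment,
        "demographics": demographics,
        "truth": truth,
    }


@dataclass
class SyntheticDataset:
    """The four claim tables plus the generator-side truth table."""

    pharmacy: pd.DataFrame
    medical: pd.DataFrame
    enrollment: pd.DataFrame
    demographics: pd.DataFrame
    truth: pd.DataFrame

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name in ("pharmacy", "medical", "enrollment", "demographics", "truth"):
            path = outdir / f"{'pharmacy_claims' if name == 'pharmacy' else 'medical_claims' if name == 'medical' else name}.csv"
            getattr(self, name).to_csv(path, index=False)
            paths[name] = path
        return paths


def generate_cohort_dataset(cfg: SimulationConfig) -> SyntheticDataset:
    """Simulate ``cfg.n_patients`` patients; deterministic given the config seed."""
    cfg.validate()
    root = np.random.default_rng(cfg.seed)
    reasons = _choose_contaminants(root, cfg)
    streams = [np.random.default_rng(s) for s in
               np.random.SeedSequence(cfg.seed).spawn(cfg.n_patients)]
    tables: dict[str, list[dict]] = {
        "pharmacy": [], "medical": [], "enrollment": [],
        "demographics": [], "truth": [],
    }
    width = len(str(cfg.n_patients))
    for i, (rng, reason) in enumerate(zip(streams, reasons)):
        rows = generate_patient(cfg, rng, f"P{i + 1:0{width}d}", reason)
        for name, chunk in rows.items():
            tables[name].extend(chunk)
    frames = {name: pd.DataFrame(rows) for name, rows in tables.items()}
    frames["pharmacy"] = frames["pharmacy"].sort_values(
        ["patient_id", "fill_date"], kind="stable"
    ).reset_index(drop=True)
    return SyntheticDataset(**frames)


# ---------------------------------------------------------------------------
# streamlined sampler for effect-recovery / calibration experiments
# ---------------------------------------------------------------------------
def simulate_persistence_sample(
    cfg: SimulationConfig,
    n: int | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Covariates plus 12-month persistence labels for ``n`` clean patients.

    Skips the claim-table plumbing (no contaminants, no basal fills) but
    classifies persistence with the real classifiers on the simulated fill
    dates, so recovery experiments exercise the actual persistence logic.
    """
    from .persistence import classify_measure1, classify_measure2

    n = n or cfg.n_patients
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    span_days = (cfg.index_end - cfg.index_start).days
    rows = []
    for _ in range(n):
        cov = _draw_covariates(rng, cfg)
        index_human = rng.random() < cfg.p_human_index
        index_pen = rng.random() < cfg.p_pen_index
        copay_mean = float(rng.lognormal(cfg.copay_mu, cfg.copay_sigma))
        hazard = _patient_hazard(cfg, cov, index_human, index_pen, copay_mean)
        index_date = cfg.index_start + dt.timedelta(
            days=int(rng.integers(span_days + 1))
        )
        obs_days = (add_months(index_date, cfg.post_months) - index_date).days
        days, disc = _simulate_mealtime_days(rng, cfg, hazard, obs_days)
        fills = [index_date + dt.timedelta(days=d) for d in days]
        m1 = classify_measure1(fills, index_date, 12,
                               cfg.gap_threshold_days, cfg.post_months)
        m2 = classify_measure2(fills, index_date, 12, cfg.post_months)
        rows.append({
            **cov,
            "index_human": int(index_human),
            "index_pen": int(index_pen),
            "avg_insulin_copay": copay_mean,
            "latent_discontinuation_day": disc,
            "persistent_m1_12m": m1.persistent,
            "persistent_m2_12m": m2.persistent,
        })
    return pd.DataFrame(rows)
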