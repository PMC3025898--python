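"""End-to-end orchestration: simulate/load -> cohort -> exposure -> persistence -> stats.

:func:`run_pipeline` reads (or simulates) the four claim tables, builds the
cohort with its attrition table, computes per-patient use metrics, gap and
switch records, persistence labels under both measures, the bivariate
comparison tables and the two 12-month logistic regressions, and writes
every artifact as plain CSV plus a JSON run manifest with artifact hashes.
Given a fixed simulation seed the whole bundle is byte-for-byte
reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .catalog import default_catalog
from .cohort import CohortConfig, build_cohort, classify_claims
from .dates import add_months
from .exposure import detect_gaps, detect_switch, usage_summary
from .io import load_tables
from .persistence import classify_measure1, classify_measure2, persistence_summary
from .stats import TABLE_COVARIATES, compare_groups, fit_persistence_model
from .synth import SimulationConfig, generate_cohort_dataset

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Either ``input_dir`` (directory with the four CSV tables) or
    ``simulation`` (a :class:`~rxpersist.synth.SimulationConfig`) must be
    set.  ``seed`` overrides the simulation seed when given.
    """

    outdir: Path
    input_dir: Path | None = None
    simulation: SimulationConfig | None = None
    gap_threshold_days: int = 90
    horizons: tuple[int, ...] = (3, 6, 12)
    post_months: int = 15
    cohort: CohortConfig = field(default_factory=CohortConfig)
    seed: int | None = None

    def validate(self) -> None:
        if (self.input_dir is None) == (self.simulation is None):
            raise ValueError("exactly one of input_dir / simulation must be set")
        if self.gap_threshold_days <= 0:
            raise ValueError("gap threshold must be positive")
        if list(self.horizons) != sorted(self.horizons):
            raise ValueError("horizons must be sorted ascending")
        if self.post_months < max(self.horizons) + 3:
            raise ValueError("post window must extend >=3 months past the "
                             "longest horizon")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write(df: pd.DataFrame, path: Path) -> Path:
    df.to_csv(path, index=False)
    return path


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return the manifest dict (also written to disk)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("rxpersist")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        return _run(config, outdir)
    finally:
        root.removeHandler(handler)
        handler.close()


def _run(config: RunConfig, outdir: Path) -> dict:
    catalog = default_catalog()

    if config.simulation is not None:
        sim = config.simulation
        if config.seed is not None:
            sim = sim.replace(seed=config.seed)
        logger.info("simulating %d patients (seed %d)", sim.n_patients, sim.seed)
        dataset = generate_cohort_dataset(sim)
        input_dir = outdir / "input"
        dataset.write(input_dir)
        tables = {
            "pharmacy_claims": dataset.pharmacy,
            "medical_claims": dataset.medical,
            "enrollment": dataset.enrollment,
            "demographics": dataset.demographics,
        }
    else:
        logger.info("loading tables from %s", config.input_dir)
        tables = load_tables(config.input_dir)

    for name, df in tables.items():
        logger.info("table %s: %d rows", name, len(df))

    cohort, attrition = build_cohort(
        tables["pharmacy_claims"], tables["medical_claims"],
        tables["enrollment"], catalog, config.cohort,
    )
    if cohort.empty:
        logger.warning("empty cohort: reports will have zero rows")

    claims, _ = classify_claims(tables["pharmacy_claims"], catalog)
    by_patient = dict(tuple(claims.groupby("patient_id", sort=True)))

    usage_rows, gap_rows, persistence_rows = [], [], []
    for _, patient in cohort.iterrows():
        pid, index_date = patient["patient_id"], patient["index_date"]
        pclaims = by_patient[pid]
        obs_end = add_months(index_date, config.post_months)
        mt_dates = pclaims.loc[
            pclaims["insulin_class"] == "mealtime", "fill_date"
        ].tolist()

        usage_rows.append({"patient_id": pid,
                           **usage_summary(pclaims, index_date, config.horizons)})

        analysis = detect_gaps(mt_dates, index_date,
                               config.gap_threshold_days, obs_end)
        switch = detect_switch(pclaims, index_date, patient["index_type"],
                               patient["index_form"], obs_end)
        gap_rows.append({
            "patient_id": pid,
            "n_gaps": len(analysis.gaps),
            "any_gap": analysis.any_gap,
            "days_index_to_first_gap": analysis.days_index_to_first_gap,
            "days_first_gap_to_next_claim": analysis.days_first_gap_to_next_claim,
            "first_gap_start": (analysis.gaps[0].gap_start
                                if analysis.gaps else None),
            "type_changed": switch.type_changed,
            "days_to_type_change": switch.days_to_type_change,
            "form_changed": switch.form_changed,
            "days_to_form_change": switch.days_to_form_change,
        })

        prow: dict = {"patient_id": pid}
        for h in config.horizons:
            m1 = classify_measure1(mt_dates, index_date, h,
                                   config.gap_threshold_days, config.post_months)
            m2 = classify_measure2(mt_dates, index_date, h, config.post_months)
            prow[f"persistent_m1_{h}m"] = m1.persistent
            prow[f"persistent_m2_{h}m"] = m2.persistent
            if h == max(config.horizons):
                prow["m1_discontinuation_date"] = m1.discontinuation_date
        persistence_rows.append(prow)

    persistence_cols = ["patient_id"] + [
        f"persistent_{m}_{h}m" for h in config.horizons for m in ("m1", "m2")
    ] + ["m1_discontinuation_date"]
    usage = pd.DataFrame(usage_rows) if usage_rows else pd.DataFrame(
        columns=["patient_id"])
    gaps = pd.DataFrame(gap_rows) if gap_rows else pd.DataFrame(
        columns=["patient_id", "n_gaps", "any_gap", "days_index_to_first_gap",
                 "days_first_gap_to_next_claim", "first_gap_start",
                 "type_changed", "days_to_type_change", "form_changed",
                 "days_to_form_change"])
    persistence = pd.DataFrame(persistence_rows) if persistence_rows else \
        pd.DataFrame(columns=persistence_cols)
    summary = persistence_summary(persistence) if not persistence.empty else \
        pd.DataFrame(columns=["measure", "horizon_months", "n",
                              "n_persistent", "pct_persistent"])

    # --- covariate assembly for the statistical analyses -------------------
    bivariate = pd.DataFrame()
    regression = pd.DataFrame()
    if not cohort.empty:
        demo = tables["demographics"]
        cov = cohort.merge(demo, on="patient_id", how="left")
        cov["index_human"] = (cov["index_type"] == "human").astype(int)
        cov["index_pen"] = (cov["index_form"] == "pen").astype(int)
        copay_means = []
        for _, patient in cohort.iterrows():
            pclaims = by_patient[patient["patient_id"]]
            window = pclaims[
                (pclaims["insulin_class"].isin(("basal", "mealtime")))
                & (pclaims["fill_date"] >= add_months(patient["index_date"],
                                                      -config.cohort.pre_months))
                & (pclaims["fill_date"] <= add_months(patient["index_date"],
                                                      config.post_months))
            ]
            copay_means.append(float(window["copay"].mean()))
        cov["avg_insulin_copay"] = copay_means
        cov = cov.merge(persistence, on="patient_id")

        cov_names = [c for c in TABLE_COVARIATES if c in cov.columns]
        biv_frames, reg_frames = [], []
        h_max = max(config.horizons)
        for measure in ("m1", "m2"):
            label_col = f"persistent_{measure}_{h_max}m"
            biv = compare_groups(cov, cov[label_col], cov_names)
            biv.insert(0, "measure", measure)
            biv_frames.append(biv)
            try:
                res = fit_persistence_model(cov, cov[label_col], measure, h_max)
                tab = res.table.copy()
                tab.insert(0, "measure", measure)
                tab["n"] = res.n
                tab["converged"] = res.converged
                tab["separation"] = res.separation
                reg_frames.append(tab)
            except Exception as exc:  # tiny cohorts: report, don't crash
                logger.warning("regression (%s) failed: %s", measure, exc)
        bivariate = pd.concat(biv_frames, ignore_index=True)
        if reg_frames:
            regression = pd.concat(reg_frames, ignore_index=True)

    artifacts = {
        "attrition": _write(attrition, outdir / "attrition.csv"),
        "usage": _write(usage, outdir / "usage.csv"),
        "gaps_switches": _write(gaps, outdir / "gaps_switches.csv"),
        "persistence": _write(persistence, outdir / "persistence.csv"),
        "persistence_summary": _write(summary, outdir / "persistence_summary.csv"),
        "bivariate": _write(bivariate, outdir / "bivariate.csv"),
        "regression": _write(regression, outdir / "regression.csv"),
    }
    config_echo = {
        "gap_threshold_days": config.gap_threshold_days,
        "horizons": list(config.horizons),
        "post_months": config.post_months,
        "seed": config.seed,
        "input_dir": str(config.input_dir) if config.input_dir else None,
        "cohort": {k: str(v) for k, v in
                   dataclasses.asdict(config.cohort).items()},
    }
    if config.simulation is not None:
        sim_echo = dataclasses.asdict(config.simulation)
        sim_echo["index_start"] = str(sim_echo["index_start"])
        sim_echo["index_end"] = str(sim_echo["index_end"])
        config_echo["simulation"] = sim_echo
    manifest = {
        "rxpersist_version": __version__,
        "config": config_echo,
        "row_counts": {
            **{name: int(len(df)) for name, df in tables.items()},
            "cohort": int(len(cohort)),
        },
        "artifacts": {name: {"path": path.name, "sha256": _sha256(path)}
                      for name, path in sorted(artifacts.items())},
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    logger.info("wrote %d artifacts to %s", len(artifacts), outdir)
    return manifest
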