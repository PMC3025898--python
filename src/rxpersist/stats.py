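"""Persistent-vs-non-persistent comparisons and logistic risk-factor models.

Bivariate machinery: chi-square tests for categorical covariates,
two-tailed t-tests for continuous ones (ANOVA when more than two groups are
compared).  Multivariate machinery: maximum-likelihood logistic regression
of 12-month persistence on the demographic / clinical / treatment covariate
set, reported as odds ratios with Wald 95% confidence intervals.  No
multiple-testing correction is applied; alpha = 0.05 throughout.

Reference levels for the categorical covariates: age group 45-54, region
NorthEast, non-capitated insurance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "TABLE_COVARIATES",
    "CONTINUOUS_COVARIATES",
    "RegressionResult",
    "compare_groups",
    "fit_persistence_model",
]

#: Default covariate set of the 12-month persistence models.
TABLE_COVARIATES = (
    "gender", "age_group", "region", "rural", "capitated",
    "index_human", "index_pen", "charlson", "er_any", "inpatient_any",
    "diabetes_complications", "n_oad_classes", "macrovascular_complications",
    "mental_health", "avg_insulin_copay",
)

#: Covariates entered linearly (per-unit odds ratios).
CONTINUOUS_COVARIATES = ("age", "charlson", "n_oad_classes", "avg_insulin_copay")

REFERENCE_LEVELS = {"age_group": "45-54", "region": "NorthEast", "gender": "M"}


def _is_continuous(series: pd.Series, name: str) -> bool:
    if name in CONTINUOUS_COVARIATES:
        return True
    if series.dtype == bool or series.dtype == object:
        return False
    # integer-coded indicators (0/1) are categorical
    return series.nunique() > 2


# ---------------------------------------------------------------------------
# bivariate comparisons
# ---------------------------------------------------------------------------
def compare_groups(
    covariates: pd.DataFrame,
    labels: pd.Series,
    covariate_names: list[str] | None = None,
) -> pd.DataFrame:
    """Compare covariates across the groups defined by ``labels``.

    Returns one row per covariate (plus one row per level for categorical
    covariates, carrying within-group percentages).  P-values: chi-square on
    the full contingency table for categorical covariates; two-tailed t-test
    for continuous covariates with two groups, one-way ANOVA otherwise.
    Degenerate cells are flagged instead of tested: zero-variance continuous
    covariates and strata with fewer than 2 patients.
    """
    labels = pd.Series(labels).reset_index(drop=True)
    covariates = covariates.reset_index(drop=True)
    groups = sorted(labels.unique(), reverse=True)
    names = covariate_names or [c for c in covariates.columns]
    rows: list[dict] = []
    for name in names:
        series = covariates[name]
        if _is_continuous(series, name):
            samples = [series[labels == g].astype(float) for g in groups]
            flag = ""
            if any(len(s) < 2 for s in samples):
                p = np.nan
                flag = "insufficient_n"
            elif all(s.std(ddof=1) == 0 for s in samples):
                p = np.nan
                flag = "zero_variance"
            elif len(samples) == 2:
                p = float(sps.ttest_ind(samples[0], samples[1]).pvalue)
            else:
                p = float(sps.f_oneway(*samples).pvalue)
            row = {"covariate": name, "level": "", "kind": "continuous",
                   "p_value": p, "test": "t" if len(samples) == 2 else "anova",
                   "flag": flag}
            for g, s in zip(groups, samples):
                row[f"mean[{g}]"] = float(s.mean()) if len(s) else np.nan
                row[f"sd[{g}]"] = float(s.std(ddof=1)) if len(s) > 1 else np.nan
            rows.append(row)
        else:
            table = pd.crosstab(series, labels)
            table = table.reindex(columns=groups, fill_value=0)
            flag = ""
            if table.shape[0] < 2 or (table.sum(axis=0) < 2).any():
                p = np.nan
                flag = "insufficient_n"
            else:
                p = float(
                    sps.chi2_contingency(table.to_numpy(), correction=False)[1]
                )
            rows.append({"covariate": name, "level": "", "kind": "categorical",
                         "p_value": p, "test": "chi2", "flag": flag})
            col_totals = table.sum(axis=0)
            for level in table.index:
                row = {"covariate": name, "level": str(level),
                       "kind": "categorical_level", "p_value": np.nan,
                       "test": "", "flag": flag}
                for g in groups:
                    denom = col_totals[g]
                    row[f"pct[{g}]"] = (
                        100.0 * table.loc[level, g] / denom if denom else np.nan
                    )
                rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# logistic regression
# ---------------------------------------------------------------------------
@dataclass
class RegressionResult:
    """Odds-ratio table plus fit diagnostics for one persistence model."""

    table: pd.DataFrame  # term, odds_ratio, ci_low, ci_high, p_value
    n: int
    measure: str
    horizon_months: int
    converged: bool
    separation: bool

    def odds_ratio(self, term: str) -> float:
        match = self.table[self.table["term"].str.contains(term, regex=False)]
        if len(match) != 1:
            raise KeyError(f"term {term!r} matches {len(match)} rows")
        return float(match["odds_ratio"].iloc[0])

    def row(self, term: str) -> pd.Series:
        match = self.table[self.table["term"].str.contains(term, regex=False)]
        if len(match) != 1:
            raise KeyError(f"term {term!r} matches {len(match)} rows")
        return match.iloc[0]


def _design_matrix(
    covariates: pd.DataFrame, names: list[str]
) -> pd.DataFrame:
    """Dummy-code categoricals against the fixed reference levels."""
    cols = {}
    for name in names:
        series = covariates[name]
        if _is_continuous(series, name):
            cols[name] = series.astype(float)
        elif series.dtype == object or str(series.dtype) == "category":
            levels = sorted(map(str, pd.unique(series.astype(str))))
            ref = str(REFERENCE_LEVELS.get(name, levels[0]))
            for lv in levels:
                if lv == ref:
                    continue
                cols[f"{name}[{lv}]"] = (series.astype(str) == lv).astype(float)
        else:
            cols[name] = series.astype(float)
    X = pd.DataFrame(cols, index=covariates.index)
    return sm.add_constant(X, has_constant="add")


def fit_persistence_model(
    covariates: pd.DataFrame,
    persistent: pd.Series,
    measure: str = "m1",
    horizon_months: int = 12,
    covariate_names: list[str] | None = None,
) -> RegressionResult:
    """ML logistic fit of 12-month persistence on the covariate set.

    Complete-case: rows with missing covariates are an error (the synthetic
    data has none).  Perfect separation is reported via the ``separation``
    flag with a ridge-stabilized fallback fit rather than raising.
    """
    names = list(covariate_names or [c for c in TABLE_COVARIATES
                                     if c in covariates.columns])
    missing = [c for c in names if c not in covariates.columns]
    if missing:
        raise KeyError(f"missing covariates: {missing}")
    if covariates[names].isna().any().any():
        raise ValueError("missing covariate values (complete-case analysis)")
    X = _design_matrix(covariates, names)
    y = pd.Series(persistent).astype(int).to_numpy()

    model = sm.Logit(y, X)
    separation = False
    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = model.fit(disp=0, maxiter=200)
        converged = bool(fit.mle_retvals.get("converged", True))
        params, bse, pvalues = fit.params, fit.bse, fit.pvalues
        if not np.isfinite(bse).all() or (np.abs(params) > 15).any():
            separation = True
    except Exception:  # LinAlgError, PerfectSeparationError, non-convergence
        separation = True
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = model.fit_regularized(alpha=1e-4, disp=0, maxiter=500)
        params = fit.params
        bse = pd.Series(np.nan, index=params.index)
        pvalues = pd.Series(np.nan, index=params.index)

    z = sps.norm.ppf(0.975)
    np_err = np.errstate(over="ignore")  # separated fits: CI bound -> inf
    with np_err:
        table = _or_table(params, bse, pvalues, z)
    table = table[table["term"] != "const"].reset_index(drop=True)
    return RegressionResult(
        table=table, n=int(len(y)), measure=measure,
        horizon_months=horizon_months, converged=converged,
        separation=separation,
    )


def _or_table(params, bse, pvalues, z) -> pd.DataFrame:
    return pd.DataFrame({
        "term": params.index,
        "coef": params.to_numpy(dtype=float),
        "se": np.asarray(bse, dtype=float),
        "odds_ratio": np.exp(params.to_numpy(dtype=float)),
        "ci_low": np.exp(params.to_numpy(dtype=float)
                         - z * np.asarray(bse, dtype=float)),
        "ci_high": np.exp(params.to_numpy(dtype=float)
                          + z * np.asarray(bse, dtype=float)),
        "p_value": np.asarray(pvalues, dtype=float),
    })
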