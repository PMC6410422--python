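"""Category-wise epidemiologic models and the baseline descriptive table.

Each AAM category (reference: 16 years) enters one adjusted model as a
dummy indicator:

* logistic regression for binary outcomes (MetS, each component flag),
  reported as OR = exp(beta) with normal-approximation 95% CIs;
* ordinary least squares for quantitative traits, reported as beta with
  95% CI and t-based p-values.

Default adjustment covariates are age, area, income, education and CRP;
area is binary (urban=1) and income/education enter as ordinal 0/1/2
scores. The baseline table gives per-category descriptives with
Kruskal-Wallis (continuous) and Pearson chi-square (categorical)
across-category tests.

The reference row is reported with estimate 0 (OR 1) and no CI: under
the fitted parameterisation the reference has no sampling variance of
its own, so a CI for it is not defined.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from . import constants as C

__all__ = [
    "fit_category_logistic",
    "fit_category_linear",
    "fit_early_linear",
    "baseline_table",
]

Z95 = 1.959964  # normal 97.5% quantile used for all 95% CIs

DEFAULT_CONTINUOUS = ("age", "sbp", "dbp", "fg", "fi", "wc", "tg", "hdl",
                      "crp", "alcohol", "obs_score")
DEFAULT_CATEGORICAL = ("area", "income", "education", "smoking", "mets")


def _category_design(cohort: pd.DataFrame, covariates) -> tuple[pd.DataFrame, list[str]]:
    cats = cohort["aam_category"]
    dummies = pd.get_dummies(cats, prefix="cat", dtype=float)
    keep = [f"cat_{c}" for c in C.AAM_CATEGORIES if c != C.REFERENCE_CATEGORY]
    # empty categories would contribute all-zero (collinear) columns
    present = [k for k in keep if k in dummies.columns and dummies[k].sum() > 0]
    X = dummies[present].copy()
    for cov in covariates:
        X[cov] = pd.to_numeric(cohort[cov], errors="raise")
    X = sm.add_constant(X, has_constant="add")
    return X, present


def _empty_effect(category: str, n: int, n_cases, pct_cases) -> dict:
    return {
        "category": category, "n": n, "n_cases": n_cases, "pct_cases": pct_cases,
        "estimate": np.nan, "se": np.nan, "or_or_beta": np.nan,
        "ci_low": np.nan, "ci_high": np.nan, "p_value": np.nan, "status": "empty",
    }


def fit_category_logistic(
    cohort: pd.DataFrame,
    outcome: str,
    covariates=C.DEFAULT_COVARIATES,
) -> pd.DataFrame:
    """Adjusted ORs of a binary outcome per AAM category vs reference 16.

    One logistic model with five category indicators plus covariates,
    maximum likelihood via IRLS (tol 1e-8, max 100 iterations).
    Separation or non-convergence flags the affected rows instead of
    raising. Empty categories are dropped with a warning.
    """
    y = pd.to_numeric(cohort[outcome], errors="raise")
    mask = y.notna()
    X_all, terms = _category_design(cohort, covariates)
    mask &= X_all.notna().all(axis=1)
    sub = cohort.loc[mask]
    y = y.loc[mask].astype(float)
    X = X_all.loc[mask]

    counts = sub.groupby("aam_category", observed=False).agg(
        n=("subject_id", "size")
    )
    cases = sub.loc[y == 1].groupby("aam_category", observed=False).size()

    status = "ok"
    params = ses = pvals = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = sm.GLM(y, X, family=sm.families.Binomial())
            fit = model.fit(maxiter=100, tol=1e-8)
            if not fit.converged:
                status = "nonconverged"
            params, ses, pvals = fit.params, fit.bse, fit.pvalues
            if np.any(np.abs(params[terms]) > 15):  # likely separation
                status = "separation"
        except Exception:
            status = "failed"

    rows = []
    for cat in C.AAM_CATEGORIES:
        n = int(counts["n"].get(cat, 0))
        n_cases = int(cases.get(cat, 0))
        pct = 100.0 * n_cases / n if n else np.nan
        if n == 0:
            warnings.warn(f"AAM category {cat} empty; dropped from model output")
            rows.append(_empty_effect(cat, n, n_cases, pct))
            continue
        if cat == C.REFERENCE_CATEGORY:
            rows.append({
                "category": cat, "n": n, "n_cases": n_cases, "pct_cases": pct,
                "estimate": 0.0, "se": np.nan, "or_or_beta": 1.0,
                "ci_low": np.nan, "ci_high": np.nan, "p_value": np.nan,
                "status": "reference",
            })
            continue
        key = f"cat_{cat}"
        if params is None or key not in params.index:
            rows.append({**_empty_effect(cat, n, n_cases, pct), "status": status})
            continue
        b, se = float(params[key]), float(ses[key])
        rows.append({
            "category": cat, "n": n, "n_cases": n_cases, "pct_cases": pct,
            "estimate": b, "se": se, "or_or_beta": float(np.exp(b)),
            "ci_low": float(np.exp(b - Z95 * se)),
            "ci_high": float(np.exp(b + Z95 * se)),
            "p_value": float(pvals[key]),
            "status": status,
        })
    return pd.DataFrame(rows)


def fit_category_linear(
    cohort: pd.DataFrame,
    trait: str,
    covariates=C.DEFAULT_COVARIATES,
) -> pd.DataFrame:
    """Adjusted per-category mean differences of a quantitative trait (OLS)."""
    y = pd.to_numeric(cohort[trait], errors="raise")
    X_all, terms = _category_design(cohort, covariates)
    mask = y.notna() & X_all.notna().all(axis=1)
    sub = cohort.loc[mask]
    y = y.loc[mask].astype(float)
    X = X_all.loc[mask]
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        corr = np.corrcoef(X.to_numpy().T)
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.nanargmax(np.abs(corr)), corr.shape)
        raise ValueError(
            f"rank-deficient design; collinear columns include "
            f"{X.columns[i]!r} and {X.columns[j]!r}"
        )

    fit = sm.OLS(y, X).fit()
    degenerate = float(fit.scale) < 1e-12  # constant trait: SEs are 0-degenerate
    counts = sub.groupby("aam_category", observed=False).size()

    rows = []
    for cat in C.AAM_CATEGORIES:
        n = int(counts.get(cat, 0))
        if n == 0:
            warnings.warn(f"AAM category {cat} empty; dropped from model output")
            rows.append(_empty_effect(cat, n, np.nan, np.nan))
            continue
        if cat == C.REFERENCE_CATEGORY:
            rows.append({
                "category": cat, "n": n, "n_cases": np.nan, "pct_cases": np.nan,
                "estimate": 0.0, "se": np.nan, "or_or_beta": 0.0,
                "ci_low": np.nan, "ci_high": np.nan, "p_value": np.nan,
                "status": "reference",
            })
            continue
        key = f"cat_{cat}"
        b, se = float(fit.params[key]), float(fit.bse[key])
        rows.append({
            "category": cat, "n": n, "n_cases": np.nan, "pct_cases": np.nan,
            "estimate": b, "se": se, "or_or_beta": b,
            "ci_low": b - Z95 * se, "ci_high": b + Z95 * se,
            "p_value": float(fit.pvalues[key]),
            "status": "degenerate_se" if degenerate else "ok",
        })
    return pd.DataFrame(rows)


def fit_early_linear(
    cohort: pd.DataFrame,
    trait: str,
    covariates=C.DEFAULT_COVARIATES,
) -> dict:
    """Single-dummy model: trait ~ early (AAM <= 12) + covariates.

    Returns the early-indicator effect with 95% CI and t-based p-value.
    """
    y = pd.to_numeric(cohort[trait], errors="raise")
    X = pd.DataFrame({"early": pd.to_numeric(cohort["early"], errors="raise")})
    for cov in covariates:
        X[cov] = pd.to_numeric(cohort[cov], errors="raise")
    X = sm.add_constant(X, has_constant="add")
    mask = y.notna() & X.notna().all(axis=1)
    fit = sm.OLS(y.loc[mask].astype(float), X.loc[mask]).fit()
    b, se = float(fit.params["early"]), float(fit.bse["early"])
    return {
        "estimate": b, "se": se,
        "ci_low": b - Z95 * se, "ci_high": b + Z95 * se,
        "p_value": float(fit.pvalues["early"]),
        "n": int(mask.sum()),
    }


def baseline_table(
    cohort: pd.DataFrame,
    continuous=DEFAULT_CONTINUOUS,
    categorical=DEFAULT_CATEGORICAL,
) -> pd.DataFrame:
    """Per-category descriptives with across-category tests.

    Continuous variables: mean +/- SD per category and a tie-corrected
    Kruskal-Wallis p; categorical: count (%) per level and a Pearson
    chi-square p without continuity correction. Categories with no
    subjects are omitted with a warning; with a single non-empty
    category no test p-values are emitted.
    """
    cats = [c for c in C.AAM_CATEGORIES if (cohort["aam_category"] == c).any()]
    for c in set(C.AAM_CATEGORIES) - set(cats):
        warnings.warn(f"AAM category {c} has n = 0; omitted from baseline table")
    groups = {c: cohort.loc[cohort["aam_category"] == c] for c in cats}
    total = len(cohort)
    do_tests = len(cats) > 1

    rows = []
    header = {"variable": "n (%)", "p_value": np.nan, "all": f"{total}"}
    for c in cats:
        n = len(groups[c])
        header[c] = f"{n} ({100.0 * n / total:.1f})"
    rows.append(header)

    for var in continuous:
        if var not in cohort.columns:
            continue
        vals = {c: pd.to_numeric(groups[c][var], errors="coerce").dropna() for c in cats}
        row = {"variable": var}
        for c in cats:
            v = vals[c]
            row[c] = f"{v.mean():.2f} +/- {v.std():.2f}" if len(v) else "."
        allv = pd.to_numeric(cohort[var], errors="coerce").dropna()
        row["all"] = f"{allv.mean():.2f} +/- {allv.std():.2f}"
        if do_tests:
            samples = [v for v in vals.values() if len(v)]
            try:
                row["p_value"] = stats.kruskal(*samples).pvalue if len(samples) > 1 else np.nan
            except ValueError:  # all values identical across groups
                row["p_value"] = np.nan
        else:
            row["p_value"] = np.nan
        rows.append(row)

    for var in categorical:
        if var not in cohort.columns:
            continue
        col = cohort[var]
        levels = sorted(col.dropna().unique(), key=str)
        table = np.array([
            [(groups[c][var] == lev).sum() for c in cats] for lev in levels
        ])
        row = {"variable": var}
        for k, c in enumerate(cats):
            n = len(groups[c])
            parts = [f"{lev}: {table[j, k]} ({100.0 * table[j, k] / n:.1f})"
                     for j, lev in enumerate(levels)] if n else ["."]
            row[c] = "; ".join(parts)
        row["all"] = "; ".join(
            f"{lev}: {int((col == lev).sum())}" for lev in levels
        )
        if do_tests and table.shape[0] > 1 and (table.sum(axis=0) > 0).all():
            row["p_value"] = stats.chi2_contingency(table, correction=False).pvalue
        else:
            row["p_value"] = np.nan
        rows.append(row)

    return pd.DataFrame(rows, columns=["variable", *cats, "all", "p_value"])
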