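"""Per-cohort linear models of epigenetic aging outcomes on risk factors.

Each three-level risk factor enters as treatment-coded dummies against a
fixed reference (education High, smoking Never, obesity NormalWeight,
alcohol Abstainer, physical-activity High). Model 1 ("M1") adjusts for age,
sex and any cohort-specific covariates; Model 2 ("M2") additionally adjusts
for all five risk factors simultaneously, so the focal factor's coefficient
is the mutually adjusted estimate. Outcomes are EAA in years (clock
outcomes) or log epimutation burden (SEM outcome); coefficients on clock
outcomes are therefore directly interpretable as years of epigenetic age
difference versus the reference group.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .io import FACTOR_LEVELS, FACTORS, REFERENCE_LEVELS, PhenotypeTable

logger = logging.getLogger("epiaging")

__all__ = ["AssocEstimate", "encode_design", "fit_cohort_models",
           "fit_interaction", "fit_sex_stratified", "Z975"]

#: two-sided 95% normal quantile used for all Wald intervals
Z975 = 1.959964


@dataclass
class AssocEstimate:
    """One per-cohort coefficient: a non-reference category of one factor."""

    cohort_id: str
    outcome: str
    factor: str
    category: str
    model: str
    beta: float
    se: float
    ci95: tuple[float, float]
    n: int
    p_value: float = float("nan")

    @classmethod
    def from_fit(cls, cohort_id: str, outcome: str, factor: str, category: str,
                 model: str, beta: float, se: float, n: int) -> "AssocEstimate":
        from scipy.stats import norm
        p = 2 * norm.sf(abs(beta / se)) if se > 0 else float("nan")
        return cls(cohort_id, outcome, factor, category, model, beta, se,
                   (beta - Z975 * se, beta + Z975 * se), n, p)


def _factor_dummies(pheno_df: pd.DataFrame, factor: str,
                    warn_missing: bool = True) -> pd.DataFrame:
    """Treatment-coded dummies for the non-reference levels present."""
    vals = pheno_df[factor]
    cols = {}
    for level in FACTOR_LEVELS[factor][1:]:
        col = (vals == level).astype(float)
        if col.sum() == 0:
            if warn_missing:
                logger.warning("factor %s: category %r absent; dummy dropped",
                               factor, level)
            continue
        cols[f"{factor}[{level}]"] = col
    return pd.DataFrame(cols, index=pheno_df.index)


def encode_design(phenotypes: PhenotypeTable, factor: str, model: str = "M1",
                  extra_covariates: list[str] | None = None) -> pd.DataFrame:
    """Design matrix (with intercept) for one focal factor and model.

    Columns: const, the focal factor's dummies, age, sex[male], any
    extra covariates, and under M2 the dummies of the other four factors.
    """
    if factor not in FACTORS:
        raise ValueError(f"unknown factor {factor!r}")
    if model not in ("M1", "M2"):
        raise ValueError(f"model must be 'M1' or 'M2', got {model!r}")
    df = phenotypes.df
    parts = [_factor_dummies(df, factor)]
    parts.append(pd.DataFrame({"age": df["age"].astype(float),
                               "sex[male]": (df["sex"] == "male").astype(float)},
                              index=df.index))
    for cov in extra_covariates or []:
        col = df[cov]
        if col.dtype == object:
            dummies = pd.get_dummies(col, prefix=cov, drop_first=True, dtype=float)
            parts.append(dummies)
        else:
            parts.append(col.astype(float).to_frame(cov))
    if model == "M2":
        for other in FACTORS:
            if other != factor:
                parts.append(_factor_dummies(df, other, warn_missing=False))
    X = pd.concat(parts, axis=1)
    X.insert(0, "const", 1.0)
    return X


def _check_full_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(float)
    if np.linalg.matrix_rank(arr) == arr.shape[1]:
        return
    aliased = []
    kept: list[int] = []
    for j in range(arr.shape[1]):
        trial = kept + [j]
        if np.linalg.matrix_rank(arr[:, trial]) == len(trial):
            kept.append(j)
        else:
            aliased.append(X.columns[j])
    raise ValueError(f"collinear design; aliased columns: {aliased}")


def _ols(y: pd.Series, X: pd.DataFrame, robust: bool = False):
    fit = sm.OLS(y.to_numpy(float), X.to_numpy(float)).fit(
        cov_type="HC1" if robust else "nonrobust")
    return fit


def fit_cohort_models(outcome: pd.Series, phenotypes: PhenotypeTable,
                      factor: str, model: str = "M1",
                      extra_covariates: list[str] | None = None,
                      robust: bool = False,
                      min_outcome_frac: float = 0.9) -> list[AssocEstimate]:
    """Fit one cohort's regression of ``outcome`` (Series indexed by
    sample_id, .name = outcome label) on one focal factor; returns one
    estimate per non-reference category present in the cohort.
    """
    cohorts = phenotypes.cohort_ids
    if len(cohorts) != 1:
        raise ValueError(f"fit_cohort_models expects one cohort, got {cohorts}")
    cid = cohorts[0]
    y = outcome.reindex(phenotypes.sample_ids).astype(float)
    frac = 1.0 - y.isna().mean()
    if frac < min_outcome_frac:
        raise ValueError(f"outcome {outcome.name!r} non-missing for only "
                         f"{frac:.0%} of samples in {cid}")
    X = encode_design(phenotypes, factor, model, extra_covariates)
    keep = ~(y.isna() | X.isna().any(axis=1))
    dropped = int((~keep).sum())
    if dropped:
        logger.info("cohort %s: listwise deletion of %d samples", cid, dropped)
    y, X = y[keep], X.loc[keep]
    if len(y) < X.shape[1] + 1:
        raise ValueError(f"cohort {cid}: n={len(y)} too small for "
                         f"{X.shape[1]} design columns")
    _check_full_rank(X)
    fit = _ols(y, X, robust)
    out = []
    focal = [c for c in X.columns if c.startswith(f"{factor}[")]
    for col in focal:
        j = list(X.columns).index(col)
        category = col[col.index("[") + 1:-1]
        out.append(AssocEstimate.from_fit(
            cid, str(outcome.name), factor, category, model,
            float(fit.params[j]), float(fit.bse[j]), int(len(y))))
    return out


def fit_interaction(outcome: pd.Series, phenotypes: PhenotypeTable,
                    factor: str, moderator: str,
                    extra_covariates: list[str] | None = None,
                    robust: bool = False) -> list[AssocEstimate]:
    """M1 plus focal-dummy x moderator product terms; returns the
    product-term coefficients (moderator in {'age', 'sex'})."""
    if moderator not in ("age", "sex"):
        raise ValueError("moderator must be 'age' or 'sex'")
    cohorts = phenotypes.cohort_ids
    if len(cohorts) != 1:
        raise ValueError(f"fit_interaction expects one cohort, got {cohorts}")
    cid = cohorts[0]
    X = encode_design(phenotypes, factor, "M1", extra_covariates)
    mod = (X["age"] if moderator == "age" else X["sex[male]"])
    if moderator == "age":
        mod = mod - mod.mean()  # centre age so main effects stay interpretable
    focal = [c for c in X.columns if c.startswith(f"{factor}[")]
    prod_cols = []
    for col in focal:
        name = f"{col}:{moderator}"
        X[name] = X[col] * mod
        prod_cols.append(name)
    y = outcome.reindex(phenotypes.sample_ids).astype(float)
    keep = ~(y.isna() | X.isna().any(axis=1))
    y, X = y[keep], X.loc[keep]
    _check_full_rank(X)
    fit = _ols(y, X, robust)
    out = []
    for col in prod_cols:
        j = list(X.columns).index(col)
        category = col.split("[")[1].split("]")[0]
        out.append(AssocEstimate.from_fit(
            cid, str(outcome.name), factor, f"{category}:{moderator}",
            f"M1+{moderator}-interaction",
            float(fit.params[j]), float(fit.bse[j]), int(len(y))))
    return out


def fit_sex_stratified(outcome: pd.Series, phenotypes: PhenotypeTable,
                       factor: str,
                       extra_covariates: list[str] | None = None) -> list[AssocEstimate]:
    """M1 fit separately in men and women (sex dropped from the design)."""
    out = []
    for sex in ("female", "male"):
        sub = phenotypes.df[phenotypes.df["sex"] == sex]
        if len(sub) < 10:
            logger.warning("sex stratum %s too small (n=%d); skipped", sex, len(sub))
            continue
        pt = PhenotypeTable(sub, phenotypes.wbc_columns)
        X = encode_design(pt, factor, "M1", extra_covariates).drop(columns="sex[male]")
        y = outcome.reindex(pt.sample_ids).astype(float)
        keep = ~(y.isna() | X.isna().any(axis=1))
        y, X = y[keep], X.loc[keep]
        _check_full_rank(X)
        fit = _ols(y, X)
        for col in [c for c in X.columns if c.startswith(f"{factor}[")]:
            j = list(X.columns).index(col)
            category = col[col.index("[") + 1:-1]
            out.append(AssocEstimate.from_fit(
                pt.cohort_ids[0], str(outcome.name), factor,
                f"{category}|{sex}", "M1+sex-stratified",
                float(fit.params[j]), float(fit.bse[j]), int(len(y))))
    return out
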