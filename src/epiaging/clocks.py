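"""Linear epigenetic clocks and age-acceleration measures.

A clock predicts DNAm age as an intercept plus a weighted sum of CpG betas,
optionally followed by the inverse of the piecewise log transform used for
pan-tissue clocks trained on subjects spanning childhood and adulthood.
From DNAm age we derive:

  AA   = DNAm age - chronological age
  EAA  = residual of AA on age (extrinsic acceleration; mean 0,
         uncorrelated with age by construction)
  IEAA = residual of AA on age plus WBC fractions (intrinsic acceleration,
         additionally orthogonal to blood cell composition)

Residualization is performed within cohort by default, matching a
per-cohort meta-analytic design.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import BetaMatrix, ClockModel, PhenotypeTable

__all__ = ["predict_dnam_age", "inverse_age_transform", "compute_acceleration"]


def inverse_age_transform(y: np.ndarray, adult_age: float = 20.0) -> np.ndarray:
    """Map the linear predictor back to years for log-adult clocks.

    The forward transform compresses childhood ages logarithmically; its
    inverse is (1 + A) * exp(y) - 1 for y < 0 and (1 + A) * y + A otherwise,
    with A the adult-age knot in years.
    """
    y = np.asarray(y, dtype=float)
    return np.where(y < 0, (1.0 + adult_age) * np.exp(y) - 1.0,
                    (1.0 + adult_age) * y + adult_age)


def predict_dnam_age(beta: BetaMatrix, model: ClockModel,
                     missing_policy: str = "impute_probe_mean",
                     min_coverage: float = 0.95) -> np.ndarray:
    """Apply a linear clock to a beta matrix; returns years per sample.

    At least ``min_coverage`` of the model's probes must be present in the
    matrix. Missing cells within present probes are handled per
    ``missing_policy``: 'impute_probe_mean' substitutes the cross-sample
    mean of that probe, 'error' refuses.
    """
    if missing_policy not in ("impute_probe_mean", "error"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    have = set(beta.probe_ids)
    present = [p for p in model.probe_ids if p in have]
    coverage = len(present) / len(model)
    if coverage < min_coverage:
        missing = [p for p in model.probe_ids if p not in have]
        raise ValueError(
            f"clock {model.name!r}: only {coverage:.1%} of probes present "
            f"(need {min_coverage:.0%}); missing e.g. {missing[:5]}"
        )
    sub = beta.subset_probes(present)
    vals = sub.values
    if np.isnan(vals).any():
        if missing_policy == "error":
            raise ValueError(f"missing beta values for clock {model.name!r} probes")
        col_means = np.nanmean(vals, axis=0)
        idx = np.where(np.isnan(vals))
        vals = vals.copy()
        vals[idx] = np.take(col_means, idx[1])
    w = np.array([model.coefficients[p] for p in present])
    y = model.intercept + vals @ w
    if model.age_transform == "horvath_logadult":
        return inverse_age_transform(y, model.adult_age)
    return y


def _residualize(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """OLS residuals of y on [1, X]."""
    design = np.column_stack([np.ones(len(y)), X]) if X.size else np.ones((len(y), 1))
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ coef


def compute_acceleration(dnam_age: np.ndarray, phenotypes: PhenotypeTable,
                         clock_name: str, use_wbc: bool = False,
                         within_cohort: bool = True, min_n: int = 10) -> pd.DataFrame:
    """Derive AA, EAA and (optionally) IEAA from predicted DNAm ages.

    ``dnam_age`` must align with ``phenotypes.sample_ids``. Returns a
    DataFrame with columns sample_id, cohort_id, age, dnam_age, aa, eaa and
    ieaa (NaN when WBC fractions are unavailable or use_wbc is False).
    """
    dnam_age = np.asarray(dnam_age, dtype=float)
    if len(dnam_age) != len(phenotypes):
        raise ValueError("dnam_age length does not match phenotype table")
    age = phenotypes.df["age"].to_numpy(float)
    aa = dnam_age - age
    out = pd.DataFrame({
        "sample_id": phenotypes.sample_ids,
        "cohort_id": phenotypes.df["cohort_id"].astype(str).to_numpy(),
        "age": age,
        "dnam_age": dnam_age,
        "aa": aa,
        "eaa": np.nan,
        "ieaa": np.nan,
        "clock_name": clock_name,
    })
    wbc = phenotypes.wbc_fractions() if use_wbc else None
    if use_wbc and wbc is None:
        raise ValueError("use_wbc=True but phenotype table carries no WBC fractions")
    groups = (out.groupby("cohort_id", sort=False).indices.values()
              if within_cohort else [np.arange(len(out))])
    eaa = np.empty(len(out))
    ieaa = np.full(len(out), np.nan)
    for idx in groups:
        idx = np.asarray(idx)
        if len(idx) < min_n:
            cid = out["cohort_id"].iloc[idx[0]]
            raise ValueError(f"cohort {cid!r} has n={len(idx)} < {min_n}; "
                             "cannot residualize acceleration")
        eaa[idx] = _residualize(aa[idx], age[idx, None])
        if wbc is not None:
            X = np.column_stack([age[idx], wbc[idx][:, :-1]])  # drop one fraction
            ieaa[idx] = _residualize(aa[idx], X)
    out["eaa"] = eaa
    out["ieaa"] = ieaa
    return out
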