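import dataclasses
import logging

import numpy as np
import pandas as pd
import pytest

from epiaging import (SimulationConfig, compute_acceleration, encode_design,
                      fit_cohort_models, fit_interaction, fit_sex_stratified,
                      predict_dnam_age, simulate_cohorts)
from epiaging.assoc import Z975
from epiaging.io import PhenotypeTable


def _pheno_frame(rng, n, cohort="c1"):
    return pd.DataFrame({
        "sample_id": [f"{cohort}_{i}" for i in range(n)],
        "age": rng.uniform(35, 75, n),
        "sex": rng.choice(["male", "female"], n),
        "cohort_id": cohort,
        "education": rng.choice(["High", "Medium", "Low"], n),
        "smoking": rng.choice(["Never", "Former", "Current"], n),
        "obesity": rng.choice(["NormalWeight", "Overweight", "Obese"], n),
        "alcohol": rng.choice(["Abstainer", "Occasional", "Habitual"], n),
        "physical_activity": rng.choice(["High", "Medium", "Low"], n),
    })


class TestEncodeDesign:
    def test_education_reference_high(self, rng):
        pt = PhenotypeTable(_pheno_frame(rng, 60))
        X = encode_design(pt, "education", "M1")
        assert "education[Medium]" in X.columns
        assert "education[Low]" in X.columns
        assert "education[High]" not in X.columns

    def test_smoking_reference_never(self, rng):
        pt = PhenotypeTable(_pheno_frame(rng, 60))
        X = encode_design(pt, "smoking", "M1")
        assert set(c for c in X.columns if c.startswith("smoking")) == \
            {"smoking[Former]", "smoking[Current]"}

    def test_degenerate_level_dropped_with_warning(self, rng, caplog):
        df = _pheno_frame(rng, 40)
        df["education"] = "High"
        pt = PhenotypeTable(df)
        with caplog.at_level(logging.WARNING, logger="epiaging"):
            X = encode_design(pt, "education", "M1")
        assert not [c for c in X.columns if c.startswith("education")]
        assert any("dummy dropped" in r.message for r in caplog.records)

    def test_m2_includes_all_factor_dummies(self, rng):
        pt = PhenotypeTable(_pheno_frame(rng, 80))
        X = encode_design(pt, "education", "M2")
        for prefix in ("smoking[", "obesity[", "alcohol[", "physical_activity["):
            assert any(c.startswith(prefix) for c in X.columns)


class TestFitCohortModels:
    def test_normal_equations_oracle(self, rng):
        """OLS coefficients match a hand-coded (X'X)^-1 X'y solve to 1e-8
        on a 40-sample fixture."""
        pt = PhenotypeTable(_pheno_frame(rng, 40))
        y = pd.Series(rng.normal(0, 1, 40), index=pt.sample_ids, name="out")
        ests = fit_cohort_models(y, pt, "education", "M1")
        X = encode_design(pt, "education", "M1").to_numpy(float)
        beta_hat = np.linalg.solve(X.T @ X, X.T @ y.to_numpy())
        resid = y.to_numpy() - X @ beta_hat
        sigma2 = resid @ resid / (40 - X.shape[1])
        cov = sigma2 * np.linalg.inv(X.T @ X)
        cols = list(encode_design(pt, "education", "M1").columns)
        for e in ests:
            j = cols.index(f"education[{e.category}]")
            assert e.beta == pytest.approx(beta_hat[j], abs=1e-8)
            assert e.se == pytest.approx(np.sqrt(cov[j, j]), abs=1e-8)
            lo, hi = e.ci95
            assert lo == pytest.approx(e.beta - Z975 * e.se, abs=1e-9)
            assert hi == pytest.approx(e.beta + Z975 * e.se, abs=1e-9)

    def test_planted_effect_recovered(self, rng):
        pt = PhenotypeTable(_pheno_frame(rng, 500))
        low = (pt.df["education"] == "Low").to_numpy(float)
        y = pd.Series(0.6 * low + rng.normal(0, 1, 500), index=pt.sample_ids,
                      name="out")
        est = next(e for e in fit_cohort_models(y, pt, "education", "M1")
                   if e.category == "Low")
        assert abs(est.beta - 0.6) < 3 * est.se

    def test_confounding_attenuation_m2_below_m1(self):
        """Smokers concentrated in the low-education group: the education
        coefficient shrinks once smoking is adjusted for (M2)."""
        cfg = SimulationConfig(
            n_cohorts=1, n_per_cohort=1200, seed=2,
            exposure_effects_years={("smoking", "Current"): 1.5},
            sem_exposure_log_effects={},
            confounding_matrix={"smoking": {
                "High": {"Never": 0.8, "Former": 0.1, "Current": 0.1},
                "Medium": {"Never": 0.5, "Former": 0.2, "Current": 0.3},
                "Low": {"Never": 0.2, "Former": 0.2, "Current": 0.6}}},
            between_cohort_sd=0.0)
        c = simulate_cohorts(cfg)[0]
        y = pd.Series(c.truth.delta, index=c.phenotypes.sample_ids, name="delta")
        m1 = next(e for e in fit_cohort_models(y, c.phenotypes, "education", "M1")
                  if e.category == "Low")
        m2 = next(e for e in fit_cohort_models(y, c.phenotypes, "education", "M2")
                  if e.category == "Low")
        assert m1.beta > 0.3          # confounded estimate is inflated
        assert abs(m2.beta) < abs(m1.beta)

    def test_sample_order_and_covariate_scale_invariance(self, rng):
        df = _pheno_frame(rng, 120)
        df["crp"] = rng.normal(3.0, 1.0, 120)
        pt = PhenotypeTable(df)
        y = pd.Series(rng.normal(0, 1, 120), index=pt.sample_ids, name="out")
        base = fit_cohort_models(y, pt, "smoking", "M1", extra_covariates=["crp"])
        perm = rng.permutation(120)
        pt_perm = PhenotypeTable(df.iloc[perm])
        shuffled = fit_cohort_models(y, pt_perm, "smoking", "M1",
                                     extra_covariates=["crp"])
        df2 = df.copy()
        df2["crp"] = 100.0 * df2["crp"] - 42.0
        rescaled = fit_cohort_models(y, PhenotypeTable(df2), "smoking", "M1",
                                     extra_covariates=["crp"])
        for a, b, c in zip(base, shuffled, rescaled):
            assert b.beta == pytest.approx(a.beta, abs=1e-9)
            assert c.beta == pytest.approx(a.beta, abs=1e-9)
            assert c.se == pytest.approx(a.se, abs=1e-9)

    def test_multi_cohort_input_rejected(self, rng):
        df = pd.concat([_pheno_frame(rng, 40, "c1"), _pheno_frame(rng, 40, "c2")])
        pt = PhenotypeTable(df)
        y = pd.Series(rng.normal(0, 1, 80), index=pt.sample_ids, name="out")
        with pytest.raises(ValueError, match="one cohort"):
            fit_cohort_models(y, pt, "education", "M1")

    def test_collinear_design_names_columns(self, rng):
        df = _pheno_frame(rng, 60)
        df["dup_age"] = df["age"]
        pt = PhenotypeTable(df)
        y = pd.Series(rng.normal(0, 1, 60), index=pt.sample_ids, name="out")
        with pytest.raises(ValueError, match="dup_age"):
            fit_cohort_models(y, pt, "education", "M1", extra_covariates=["dup_age"])

    def test_eaa_outcome_effect_in_years(self):
        """A +0.6-year planted education effect on the clock outcome is
        recovered as beta ~ 0.6 years, not a standardized quantity."""
        cfg = SimulationConfig(
            n_cohorts=1, n_per_cohort=2000, seed=9,
            exposure_effects_years={("education", "Low"): 0.6},
            sem_exposure_log_effects={}, between_cohort_sd=0.0, delta_sd=1.0)
        c = simulate_cohorts(cfg)[0]
        clock = next(cl for cl in c.true_clocks if cl.name == "blood")
        dn = predict_dnam_age(c.beta, clock)
        acc = compute_acceleration(dn, c.phenotypes, "blood")
        y = pd.Series(acc["eaa"].to_numpy(), index=acc["sample_id"], name="blood")
        est = next(e for e in fit_cohort_models(y, c.phenotypes, "education", "M1")
                   if e.category == "Low")
        assert abs(est.beta - 0.6) < 3 * est.se
        assert 0.3 < est.beta < 0.9


class TestInteractions:
    def test_age_varying_effect_detected(self):
        """An exposure whose effect grows with age yields a positive
        Low x age product term at n=2000."""
        rng = np.random.default_rng(31)
        df = _pheno_frame(rng, 2000)
        pt = PhenotypeTable(df)
        low = (df["education"] == "Low").to_numpy(float)
        age_c = df["age"].to_numpy() - df["age"].mean()
        y = pd.Series(0.02 * low * age_c + 0.3 * low + rng.normal(0, 0.5, 2000),
                      index=pt.sample_ids, name="out")
        est = next(e for e in fit_interaction(y, pt, "education", "age")
                   if e.category.startswith("Low"))
        assert est.beta > 0
        assert est.beta - Z975 * est.se > 0  # significantly positive

    def test_null_interaction_rejection_rate(self):
        """Without a true product effect the age-interaction test rejects
        at about the nominal 5% level."""
        rejections = 0
        n_sims = 120
        for s in range(n_sims):
            rng = np.random.default_rng(1000 + s)
            df = _pheno_frame(rng, 150)
            pt = PhenotypeTable(df)
            low = (df["education"] == "Low").to_numpy(float)
            y = pd.Series(0.4 * low + rng.normal(0, 1, 150),
                          index=pt.sample_ids, name="out")
            est = next(e for e in fit_interaction(y, pt, "education", "age")
                       if e.category.startswith("Low"))
            if est.p_value < 0.05:
                rejections += 1
        # binomial band around 0.05 at 120 sims
        assert 0.005 <= rejections / n_sims <= 0.12

    def test_null_sex_interaction_centered(self, rng):
        df = _pheno_frame(rng, 800)
        pt = PhenotypeTable(df)
        low = (df["education"] == "Low").to_numpy(float)
        y = pd.Series(0.5 * low + rng.normal(0, 1, 800), index=pt.sample_ids,
                      name="out")
        est = next(e for e in fit_interaction(y, pt, "education", "sex")
                   if e.category.startswith("Low"))
        assert abs(est.beta) < 3 * est.se

    def test_sex_stratified_both_strata(self, rng):
        df = _pheno_frame(rng, 300)
        pt = PhenotypeTable(df)
        y = pd.Series(rng.normal(0, 1, 300), index=pt.sample_ids, name="out")
        ests = fit_sex_stratified(y, pt, "education")
        strata = {e.category.split("|")[1] for e in ests}
        assert strata == {"male", "female"}
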