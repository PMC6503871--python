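# Methods

This note documents the models implemented in `epiaging`, the assumptions
behind the synthetic-cohort generator, and the numerical and design choices
made where more than one reasonable convention exists. Nothing here states
an empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Stochastic epimutation calling

For each CpG probe the cross-sample distribution of beta values defines
quartiles Q1 and Q3 and extreme fences `Q1 − 3·IQR` and `Q3 + 3·IQR`. A
sample's value is a SEM when it lies **strictly** outside a fence; values
exactly on a fence — including every value of a constant probe, whose
fences collapse to a point — are not calls. The per-sample burden is the
raw count of calls over available probes, transformed as `ln(burden + 1)`
for modelling.

Conventions, each configurable:

* **Quantile rule.** Hyndman–Fan type 7 (linear interpolation), the
  default of numpy, R and pandas; type 2 (averaged inverted CDF) is also
  offered. The fence definition itself does not prescribe one.
* **Log transform.** `ln(burden + 1)` rather than `ln(burden)`, because
  small probe panels produce zero burdens; `ln(burden)` with zero exclusion
  is available. With genome-scale panels burdens are large and the two
  differ negligibly.
* **Fence scope.** Fences are computed within cohort, mirroring a design
  in which each cohort is analyzed separately and only summary estimates
  are shared; a pooled-fence mode exists but is off by default.
* **Missing data.** Missing cells are excluded from quantiles and are
  never SEMs; probes with fewer than 8 non-missing samples (configurable)
  are dropped with a log message, since quartiles of a handful of points
  give meaningless fences.
* **Cell-composition adjustment.** The WBC-adjusted variant residualizes
  each probe on the cell-fraction matrix by per-probe OLS (intercept always
  included, last fraction column dropped because fractions sum to one) and
  re-derives fences and calls on the residuals. Constant fraction columns
  degenerate into the intercept harmlessly; genuine collinearity among
  varying columns is an error naming the offending columns.

## Clocks and age acceleration

A clock is an intercept plus per-probe weights, optionally followed by the
inverse of the piecewise log-linear age transform used by pan-tissue
clocks (`adult_age` knot, default 20 years): the linear predictor y maps to
`(1 + A)·e^y − 1` for `y < 0` and `(1 + A)·y + A` otherwise. Coefficient
tables are runtime inputs with a reserved `(Intercept)` row; at least 95%
of a clock's probes must be present (configurable), and missing cells are
imputed with the probe mean or rejected, per policy.

`AA = DNAm age − age`; `EAA` is the OLS residual of AA on age with
intercept, so it has mean zero and zero sample correlation with age by
construction — equivalently the residual of DNAm age on age, an identity
the tests assert to 1e-10. `IEAA` additionally partials out the WBC
fractions (one column dropped). Residualization is performed **within
cohort**, consistent with per-cohort modelling followed by meta-analysis;
a pooled mode exists.

## Association models

Risk factors are three-level categoricals with fixed references: education
High, smoking Never, obesity NormalWeight, alcohol Abstainer, physical
activity High. Treatment (dummy) coding is used throughout; a category
absent from a cohort loses its dummy with a warning rather than failing
the whole fit. Model 1 adjusts for age, sex and any cohort-specific
covariates; Model 2 adds the dummies of all five risk factors, so the
focal coefficient is the mutually adjusted one. Clock outcomes are EAA in
years, making coefficients directly interpretable as years of epigenetic
age difference; the SEM outcome enters as `ln(burden + 1)`.

Standard errors are classical homoskedastic OLS (HC1 available as a
flag); 95% intervals are Wald, `β ± 1.959964·se`. Missing covariates cause
listwise deletion, with counts logged; an outcome missing in more than 10%
of a cohort's samples is an error. Age interactions add focal-dummy ×
centred-age product terms to M1 (centring keeps main effects
interpretable); sex is handled both by product terms and by stratified
fits, reported separately.

## Random-effects meta-analysis

The pooled model is `β_i ~ N(β, v_i + τ²)` with known `v_i = se_i²`. τ² is
estimated by REML on the profile likelihood

```
l(τ²) = −½ Σ ln(v_i + τ²) − ½ ln(Σ w_i) − ½ Σ w_i (β_i − β̂)² ,
w_i = 1/(v_i + τ²),  β̂ = Σ w_i β_i / Σ w_i .
```

Numerically, the problem is first standardized by the mean sampling
variance (making pooling exactly equivariant under linear rescaling of the
inputs — the property the Cohen's-d conversion relies on), and the
stationary point is found by bracketing the root of the closed-form score
`dl/dτ²` on `[0, 10·max(v_i)·k]` to near machine precision, with truncation
at zero when the score at the boundary is non-positive and bounded scalar
minimization as a fallback if no interior root exists. Heterogeneity is
summarized by Cochran's Q (fixed-effect weights) and
`I² = max(0, (Q − (k−1))/Q)·100`; `I² = 0` whenever `Q ≤ k − 1`.

Pooled intervals are plain Wald normal intervals, matching the convention
of reporting simple 95% CIs; the Knapp–Hartung t-adjustment is available
as a flag but off by default. The DerSimonian–Laird moment estimator is
implemented as an independent comparator, and one test cross-checks the
REML fit against R's `metafor::rma` on a fixed fixture.

## Rescaling SEM effects to years

Log-burden coefficients are converted to years in two steps: divide the
coefficient and its SE by the cohort's SD of the log-burden outcome
(yielding Cohen's d), then multiply by the SD of a reference clock's AA in
that cohort (default: the blood clock). Both SDs are treated as known
constants, so CIs scale by the same factor and significance is preserved;
the uncertainty in the SDs is deliberately not propagated (documented
limitation). Rescaling is applied **per cohort before pooling**; because
REML pooling is scale-equivariant, pooling and rescaling commute exactly
when cohorts share the same SDs. Per-cohort versus consortium-wide
reference SDs are both supported; the default is per-cohort.

## Region enrichment

The locus set is the probes carrying at least one SEM call (recurrence
threshold configurable). The null model resamples locus sets of the same
size uniformly **from the probe universe of the array**, rather than
shuffling genomic coordinates: methylation probes are a fixed,
non-uniformly spaced design, and preserving the universe is what controls
the probe-density confounder. The p-value uses the add-one rule
`(b + 1)/(n_perm + 1)` and is therefore never zero; batches of region sets
get independent derived seeds from one master seed, and a Bonferroni
column is optional (raw per-set p is the default report).

## The synthetic-cohort generator

The generator emulates the statistical structure the analysis assumes, at
desk scale:

* **Latent acceleration.** Each sample's δ (years) is the sum of additive
  exposure effects, a cohort-level random intercept
  (`between_cohort_sd = 0.5` y), and Gaussian noise (`delta_sd = 2.0` y —
  a deliberately moderate spread for small synthetic panels; empirical AA
  spreads in adult blood are somewhat larger).
* **Clock CpGs** drift linearly in `age + δ` with per-probe slopes of
  ±0.002–0.004 beta units/year and baselines chosen so the whole attainable
  age range stays strictly inside (0, 1) — no clipping, which is what makes
  the emitted true clock (weights `1/(m·s_j)`, matching intercept) invert
  the noise-free betas exactly. Per-CpG Gaussian noise of 0.01 beta units
  propagates to roughly half a year of clock noise at 60 CpGs per clock.
  Three clocks are generated by default on disjoint CpG sets.
* **SEM-prone CpGs** have tight Beta backgrounds (concentration 800,
  spread ≈ 0.02); each sample receives `K ~ Poisson(λ0 · exp(r·age + Σ
  exposure log-effects))` epimutations at probes drawn without replacement,
  each **deterministically pushed** to 0.01 or 0.99 (the far side of the
  background), so planted calls are exact ground truth and caller recall is
  testable as exactly 100%. Defaults: `λ0 = 1/sample` at age 0 and
  `r = 0.03/yr`, giving burdens of ~3–10 on the default 400-probe panel.
  Tests of the *log-linear age trend* use the high-burden setting
  `λ0 = 10`: `E[ln(K+1)]` is linear in age only up to an O(1/λ) curvature,
  so the slope is recoverable at the stated precision only when counts are
  well above one — as in genome-scale data, where burdens are in the
  hundreds.
* **WBC-sensitive CpGs** shift with the sample's first cell-type fraction
  (Dirichlet-distributed fractions, α = (60, 25, 10, 5)), inducing the
  cell-composition confounding the WBC-adjusted variants are meant to
  remove. Inert CpGs serve as negative controls.
* **Geometry.** Probes sit on a synthetic two-chromosome genome at 1 kb
  spacing with roles assigned by a seeded shuffle (decorrelating role from
  position), and region sets are deterministic tilings (open chromatin and
  Polycomb-repressed: disjoint 4 kb-on/12 kb-off phases ≈ 25% each; shores:
  2 kb tiles ≈ 20%), so expected overlaps follow from arithmetic.
  `enrichment_fold` up-weights epimutation placement inside the designated
  set.
* **Confounding** between education and the other factors is opt-in via a
  per-education-level prevalence table, used to reproduce the M1→M2
  attenuation pattern qualitatively.

Default study conditions are six cohorts of 300 adults aged 35–75 with
planted effects of +0.3/+0.6 years for medium/low education, +0.3/+0.6 for
former/current smoking, +0.2/+0.4 for overweight/obesity, +0.3 for
habitual alcohol and +0.2 for low physical activity, plus log-rate effects
of +0.15 (low education) and +0.10/+0.25 (former/current smoking) on the
SEM burden — magnitudes of the order reported by large consortium analyses
of these exposures.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: co-methylation and LD-like correlation
between probes, realistic 450K/EPIC probe-density and genomic annotation
structure, array normalization and batch artifacts, non-linear clock
mis-calibration, age-dependent cell-composition drift, and measurement
error in phenotypes. Because cohort random effects enter as intercepts
(which EAA residualization absorbs), association slopes are homogeneous
across synthetic cohorts and pooled I² is near zero under the defaults;
heterogeneity statistics are exercised by the meta-analysis simulations
rather than by the generator.

## Reproducibility and problem sizes

All randomness flows from a single master seed through named substreams
(one per stage, per cohort, per region set), so any stage re-run in
isolation reproduces its part of a full run bit for bit; derived seeds are
recorded in the run manifest. The bundled analyses use desk-scale problem
sizes chosen to keep every check fast while leaving comfortable statistical
margins: 6×300 samples and 660 probes for end-to-end runs, 1000 replicates
for meta-analysis calibration at 18 cohorts, 100–200 simulations of 500
permutations for the enrichment error rates, and 2000 samples for slope
recovery.

## Known limitations

* SE propagation in the Cohen's-d rescaling ignores the sampling
  variability of the two SDs.
* The permutation null resamples probes exchangeably; it does not preserve
  per-chromosome locus counts or local clustering of calls.
* Classical OLS standard errors assume homoskedastic residuals within
  cohort (HC1 optional).
* The clock engine applies published linear clocks; it does not train or
  re-calibrate them.
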