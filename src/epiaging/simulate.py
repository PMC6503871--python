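"""Synthetic multi-cohort methylation data with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes, at a scale where every stage can be exercised in seconds:

* clock CpGs whose betas drift linearly with (age + delta), where delta is
  a latent per-sample age acceleration in years built from additive
  exposure effects, a cohort-level random intercept, and Gaussian noise —
  together with the exactly-inverting linear ClockModel for each clock;
* SEM-prone CpGs with tight Beta-distributed background and per-sample
  epimutation counts drawn Poisson with a log-linear age trend (burden
  grows exponentially with age), epimutated values pushed deterministically
  beyond any 3*IQR fence so caller recall is an exact ground truth;
* WBC-sensitive CpGs shifted by the sample's first cell-type fraction to
  induce cell-composition confounding, with Dirichlet-distributed fractions;
* inert CpGs as negative controls.

Probes live on a synthetic two-chromosome genome with deterministically
tiled region sets, so expected region overlaps are computable by hand.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import substream
from .io import (FACTOR_LEVELS, FACTORS, BetaMatrix, ClockModel, PhenotypeTable,
                 ProbeAnnotation, RegionSet)

logger = logging.getLogger("epiaging")

__all__ = ["SimulationConfig", "CohortTruth", "SyntheticCohort",
           "simulate_cohorts", "truth_report", "build_region_sets",
           "PROBE_SPACING"]

#: distance between adjacent probe positions on each synthetic chromosome
PROBE_SPACING = 1_000


def _default_prevalences() -> dict[str, dict[str, float]]:
    return {
        "education": {"High": 0.35, "Medium": 0.35, "Low": 0.30},
        "smoking": {"Never": 0.45, "Former": 0.30, "Current": 0.25},
        "obesity": {"NormalWeight": 0.40, "Overweight": 0.35, "Obese": 0.25},
        "alcohol": {"Abstainer": 0.30, "Occasional": 0.45, "Habitual": 0.25},
        "physical_activity": {"High": 0.40, "Medium": 0.35, "Low": 0.25},
    }


def _default_effects() -> dict[tuple[str, str], float]:
    # additive effects on latent age acceleration, in years
    return {
        ("education", "Medium"): 0.3, ("education", "Low"): 0.6,
        ("smoking", "Former"): 0.3, ("smoking", "Current"): 0.6,
        ("obesity", "Overweight"): 0.2, ("obesity", "Obese"): 0.4,
        ("alcohol", "Habitual"): 0.3,
        ("physical_activity", "Low"): 0.2,
    }


def _default_sem_log_effects() -> dict[tuple[str, str], float]:
    # additive terms on the log epimutation rate
    return {
        ("education", "Low"): 0.15,
        ("smoking", "Former"): 0.10, ("smoking", "Current"): 0.25,
    }


@dataclass
class SimulationConfig:
    """Everything the generator needs; defaults give six mid-sized cohorts
    with moderate exposure effects, a log-linear SEM age trend, and no
    exposure-education confounding or regional SEM enrichment."""

    n_cohorts: int = 6
    n_per_cohort: int = 300
    age_range: tuple[float, float] = (35.0, 75.0)
    clock_names: tuple[str, ...] = ("pantissue", "blood", "phenoage")
    n_clock_cpgs: int = 60          # per clock
    n_sem_cpgs: int = 400
    n_wbc_cpgs: int = 40
    n_inert_cpgs: int = 40
    exposure_prevalences: dict[str, dict[str, float]] = field(default_factory=_default_prevalences)
    exposure_effects_years: dict[tuple[str, str], float] = field(default_factory=_default_effects)
    sem_rate_base: float = 1.0      # expected epimutations per sample at age 0
    sem_age_slope: float = 0.03     # per-year log-rate slope
    sem_exposure_log_effects: dict[tuple[str, str], float] = field(default_factory=_default_sem_log_effects)
    between_cohort_sd: float = 0.5  # SD of cohort random intercept, years
    delta_sd: float = 2.0           # SD of individual latent acceleration, years
    noise_sd_beta: float = 0.01     # Gaussian beta noise on clock/WBC CpGs
    sem_background_conc: float = 800.0  # Beta concentration of SEM-CpG background
    wbc_dirichlet_alpha: tuple[float, ...] = (60.0, 25.0, 10.0, 5.0)
    wbc_gamma_range: tuple[float, float] = (0.3, 0.6)
    confounding_matrix: dict[str, dict[str, dict[str, float]]] | None = None
    enrichment_fold: float = 1.0
    enrichment_region: str = "open_chromatin"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_cohort < 30:
            raise ValueError("n_per_cohort must be >= 30")
        if self.sem_rate_base <= 0:
            raise ValueError("sem_rate_base must be > 0")
        if self.enrichment_fold <= 0:
            raise ValueError("enrichment_fold must be > 0")
        for factor, prev in self.exposure_prevalences.items():
            if set(prev) != set(FACTOR_LEVELS[factor]):
                raise ValueError(f"prevalences for {factor} must cover {FACTOR_LEVELS[factor]}")
            vals = np.array(list(prev.values()))
            if (vals < 0).any() or (vals > 1).any() or abs(vals.sum() - 1) > 1e-9:
                raise ValueError(f"prevalences for {factor} must be in [0,1] and sum to 1")
        if self.confounding_matrix:
            for factor, by_edu in self.confounding_matrix.items():
                for edu, prev in by_edu.items():
                    vals = np.array([prev[l] for l in FACTOR_LEVELS[factor]])
                    if abs(vals.sum() - 1) > 1e-9:
                        raise ValueError(
                            f"confounded prevalences for {factor}|education={edu} must sum to 1")

    @property
    def n_probes(self) -> int:
        return (len(self.clock_names) * self.n_clock_cpgs + self.n_sem_cpgs
                + self.n_wbc_cpgs + self.n_inert_cpgs)


@dataclass
class CohortTruth:
    """Ground truth recorded for one cohort."""

    delta: np.ndarray            # latent age acceleration, years
    sem_count: np.ndarray        # planted epimutations per sample
    sem_rate: np.ndarray         # Poisson mean per sample
    cohort_effect: float         # cohort random intercept, years
    sem_cells: np.ndarray | None = None  # (n_samples, n_probes) planted mask


@dataclass
class SyntheticCohort:
    cohort_id: str
    beta: BetaMatrix
    phenotypes: PhenotypeTable
    annotation: ProbeAnnotation          # shared across cohorts
    probe_roles: np.ndarray              # shared; one of clock:<name>|sem|wbc|inert
    true_clocks: list[ClockModel]        # shared
    truth: CohortTruth
    config: SimulationConfig


def build_region_sets(config: SimulationConfig) -> list[RegionSet]:
    """Deterministically tiled region sets on the synthetic genome.

    open_chromatin and polycomb_repressed tile disjoint quarters of each
    chromosome in 4 kb blocks; shores covers a fifth in 2 kb blocks. All
    expected probe overlaps follow from the tiling arithmetic.
    """
    m = config.n_probes
    chrom_len = ((m + 1) // 2) * PROBE_SPACING
    sets = []
    for name, tile, phase, period in [
        ("open_chromatin", 4 * PROBE_SPACING, 0, 4),
        ("polycomb_repressed", 4 * PROBE_SPACING, 2, 4),
        ("shores", 2 * PROBE_SPACING, 1, 5),
    ]:
        ivs = []
        for chrom in ("chr1", "chr2"):
            start = phase * tile
            while start < chrom_len:
                ivs.append((chrom, start, min(start + tile, chrom_len)))
                start += period * tile
        sets.append(RegionSet(name, ivs))
    return sets


def _probe_layout(config: SimulationConfig) -> tuple[ProbeAnnotation, np.ndarray]:
    """Probe ids, positions on two chromosomes, and shuffled roles."""
    m = config.n_probes
    probe_ids = [f"cg{k:06d}" for k in range(m)]
    chrom = ["chr1" if k % 2 == 0 else "chr2" for k in range(m)]
    pos = np.array([(k // 2) * PROBE_SPACING for k in range(m)], dtype=np.int64)
    roles = []
    for name in config.clock_names:
        roles += [f"clock:{name}"] * config.n_clock_cpgs
    roles += ["sem"] * config.n_sem_cpgs
    roles += ["wbc"] * config.n_wbc_cpgs
    roles += ["inert"] * config.n_inert_cpgs
    roles = np.array(roles)
    # decorrelate role from genomic position (seeded shuffle)
    substream(config.seed, "probe_roles").shuffle(roles)
    return ProbeAnnotation(probe_ids, chrom, pos), roles


def _clock_params(config: SimulationConfig, roles: np.ndarray):
    """Per-clock slopes/intercepts guaranteed clip-free over the attainable
    (age + delta) range, and the exactly-inverting true ClockModel."""
    rng = substream(config.seed, "clock_params")
    amin = config.age_range[0] - 6 * config.delta_sd - 5.0
    amax = config.age_range[1] + 6 * config.delta_sd + 5.0
    margin = 0.02
    params: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for name in config.clock_names:
        cols = np.where(roles == f"clock:{name}")[0]
        m = len(cols)
        for _attempt in range(20):
            sign = np.where(rng.random(m) < 0.5, 1.0, -1.0)
            s = sign * rng.uniform(0.002, 0.004, size=m)
            span = s * (amax - amin)
            # value at amin drawn so the full age trajectory stays in (0, 1)
            lo = np.where(s > 0, margin, margin - span)
            hi = np.where(s > 0, 1 - margin - span, 1 - margin)
            v0 = rng.uniform(lo, hi)
            mu = v0 - s * amin
            feas_frac = np.mean((mu + s * amin >= 0) & (mu + s * amax <= 1)
                                & (mu + s * amax >= 0) & (mu + s * amin <= 1))
            if feas_frac >= 0.9:
                break
            logger.warning("clock %s: %.0f%% of CpGs would clip; resampling", name,
                           100 * (1 - feas_frac))
        params[name] = (cols, mu, s)
    return params


def _true_clock(name: str, probe_ids: list[str], cols: np.ndarray,
                mu: np.ndarray, s: np.ndarray) -> ClockModel:
    m = len(cols)
    w = 1.0 / (m * s)
    intercept = -float(np.sum(mu / s)) / m
    return ClockModel(name=name, intercept=intercept,
                      coefficients={probe_ids[c]: float(wj) for c, wj in zip(cols, w)},
                      age_transform="identity")


def _draw_categories(rng: np.random.Generator, config: SimulationConfig,
                     n: int) -> pd.DataFrame:
    out = {}
    edu_levels = FACTOR_LEVELS["education"]
    edu_p = [config.exposure_prevalences["education"][l] for l in edu_levels]
    edu = rng.choice(edu_levels, size=n, p=edu_p)
    out["education"] = edu
    for factor in FACTORS:
        if factor == "education":
            continue
        levels = FACTOR_LEVELS[factor]
        conf = (config.confounding_matrix or {}).get(factor)
        if conf:
            vals = np.empty(n, dtype=object)
            for lev in edu_levels:
                mask = edu == lev
                p = [conf[lev][l] for l in levels]
                vals[mask] = rng.choice(levels, size=int(mask.sum()), p=p)
            out[factor] = vals.astype(str)
        else:
            p = [config.exposure_prevalences[factor][l] for l in levels]
            out[factor] = rng.choice(levels, size=n, p=p)
    return pd.DataFrame(out)


def simulate_cohorts(config: SimulationConfig) -> list[SyntheticCohort]:
    """Generate all cohorts; bit-identical for identical config (incl. seed)."""
    annotation, roles = _probe_layout(config)
    probe_ids = annotation.probe_ids
    clock_params = _clock_params(config, roles)
    true_clocks = [_true_clock(nm, probe_ids, *clock_params[nm]) for nm in config.clock_names]

    rng_bg = substream(config.seed, "background_params")
    sem_cols = np.where(roles == "sem")[0]
    sem_mu = rng_bg.uniform(0.15, 0.85, size=len(sem_cols))
    wbc_cols = np.where(roles == "wbc")[0]
    wbc_mu = rng_bg.uniform(0.2, 0.8, size=len(wbc_cols))
    wbc_gamma = (np.where(rng_bg.random(len(wbc_cols)) < 0.5, 1.0, -1.0)
                 * rng_bg.uniform(*config.wbc_gamma_range, size=len(wbc_cols)))
    inert_cols = np.where(roles == "inert")[0]
    inert_mu = rng_bg.uniform(0.15, 0.85, size=len(inert_cols))

    # epimutation placement weights: enrichment_fold inside the designated set
    sem_weights = np.ones(len(sem_cols))
    if config.enrichment_fold != 1.0:
        region = next(r for r in build_region_sets(config)
                      if r.name == config.enrichment_region)
        from .enrich import overlap_mask
        inside = overlap_mask(annotation.subset([probe_ids[c] for c in sem_cols]), region)
        sem_weights = np.where(inside, config.enrichment_fold, 1.0)
    sem_weights = sem_weights / sem_weights.sum()

    alpha = np.asarray(config.wbc_dirichlet_alpha, dtype=float)
    mean_frac1 = alpha[0] / alpha.sum()
    conc = config.sem_background_conc

    cohorts: list[SyntheticCohort] = []
    for c in range(config.n_cohorts):
        cid = f"cohort{c + 1:02d}"
        rng = substream(config.seed, f"cohort:{cid}")
        n = config.n_per_cohort
        u_c = rng.normal(0.0, config.between_cohort_sd)
        age = rng.uniform(*config.age_range, size=n)
        cats = _draw_categories(rng, config, n)
        effect = np.zeros(n)
        log_rate_exposure = np.zeros(n)
        for factor in FACTORS:
            lab = cats[factor].to_numpy()
            for level in FACTOR_LEVELS[factor][1:]:
                hit = lab == level
                effect[hit] += config.exposure_effects_years.get((factor, level), 0.0)
                log_rate_exposure[hit] += config.sem_exposure_log_effects.get((factor, level), 0.0)
        delta = effect + u_c + rng.normal(0.0, config.delta_sd, size=n)
        wbc = rng.dirichlet(alpha, size=n)
        sex = rng.choice(["female", "male"], size=n)

        values = np.empty((n, config.n_probes))
        bio_age = age + delta
        for name in config.clock_names:
            cols, mu, s = clock_params[name]
            clean = mu[None, :] + np.outer(bio_age, s)
            noisy = clean + rng.normal(0.0, config.noise_sd_beta, size=clean.shape)
            values[:, cols] = np.clip(noisy, 0.0, 1.0)
        # SEM-prone background: tight Beta around each probe mean
        a = sem_mu * conc
        b = (1 - sem_mu) * conc
        values[:, sem_cols] = rng.beta(a[None, :], b[None, :], size=(n, len(sem_cols)))
        # plant epimutations
        sem_rate = config.sem_rate_base * np.exp(config.sem_age_slope * age
                                                 + log_rate_exposure)
        k_raw = rng.poisson(sem_rate)
        sem_count = np.minimum(k_raw, len(sem_cols))
        push = np.where(sem_mu >= 0.5, 0.01, 0.99)  # far side of the background
        sem_cells = np.zeros((n, config.n_probes), dtype=bool)
        for i in range(n):
            if sem_count[i] == 0:
                continue
            chosen = rng.choice(len(sem_cols), size=sem_count[i], replace=False,
                                p=sem_weights)
            values[i, sem_cols[chosen]] = push[chosen]
            sem_cells[i, sem_cols[chosen]] = True
        # WBC-sensitive CpGs
        shift = np.outer(wbc[:, 0] - mean_frac1, wbc_gamma)
        wbc_vals = wbc_mu[None, :] + shift + rng.normal(
            0.0, config.noise_sd_beta, size=(n, len(wbc_cols)))
        values[:, wbc_cols] = np.clip(wbc_vals, 0.0, 1.0)
        # inert CpGs
        ia = inert_mu * conc
        ib = (1 - inert_mu) * conc
        values[:, inert_cols] = rng.beta(ia[None, :], ib[None, :],
                                         size=(n, len(inert_cols)))

        sample_ids = [f"{cid}_s{i:04d}" for i in range(n)]
        pheno_df = pd.DataFrame({
            "sample_id": sample_ids,
            "age": age,
            "sex": sex,
            "cohort_id": cid,
            **{f: cats[f].to_numpy() for f in FACTORS},
            **{f"wbc_{j + 1}": wbc[:, j] for j in range(len(alpha))},
        })
        cohorts.append(SyntheticCohort(
            cohort_id=cid,
            beta=BetaMatrix(sample_ids, probe_ids, values),
            phenotypes=PhenotypeTable(pheno_df,
                                      wbc_columns=[f"wbc_{j + 1}" for j in range(len(alpha))]),
            annotation=annotation,
            probe_roles=roles,
            true_clocks=true_clocks,
            truth=CohortTruth(delta=delta, sem_count=sem_count,
                              sem_rate=sem_rate, cohort_effect=float(u_c),
                              sem_cells=sem_cells),
            config=config,
        ))
    return cohorts


def truth_report(cohorts: list[SyntheticCohort]) -> pd.DataFrame:
    """One row per cohort with the planted parameters — the targets for
    parameter-recovery tests."""
    if not cohorts:
        raise ValueError("no cohorts")
    rows = []
    for ch in cohorts:
        cfg = ch.config
        row = {
            "cohort_id": ch.cohort_id,
            "n": len(ch.phenotypes),
            "cohort_effect_years": ch.truth.cohort_effect,
            "sem_rate_base": cfg.sem_rate_base,
            "sem_age_slope": cfg.sem_age_slope,
            "enrichment_fold": cfg.enrichment_fold,
            "mean_true_sem_count": float(ch.truth.sem_count.mean()),
            "mean_true_delta_years": float(ch.truth.delta.mean()),
        }
        for (factor, level), eff in sorted(cfg.exposure_effects_years.items()):
            row[f"effect_{factor}_{level}_years"] = eff
        rows.append(row)
    return pd.DataFrame(rows)
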