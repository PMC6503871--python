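"""End-to-end orchestration: simulate (or load) -> SEM calling -> clocks ->
per-cohort association models -> REML pooling -> SEM-effect rescaling ->
region enrichment, as one reproducible run from a single config.

The default run covers the full grid of four outcomes (log SEM burden,
rescaled to years, plus one EAA per clock) x five risk factors x two
non-reference categories x two adjustment models, pooled across cohorts —
an 80-row table of pooled estimates plus a compact formatted report.
All randomness flows from one master seed through named substreams.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._rng import child_seed
from .assoc import AssocEstimate, fit_cohort_models
from .clocks import compute_acceleration, predict_dnam_age
from .enrich import EnrichmentResult, enrichment_batch
from .io import (FACTOR_LEVELS, FACTORS, REFERENCE_LEVELS, BetaMatrix,
                 PhenotypeTable, ProbeAnnotation, read_beta_matrix,
                 read_clock_model, read_phenotypes, read_regions_bed,
                 write_results_table)
from .meta import MetaResult, forest_plot, reml_pool
from .rescale import rescale_sem_effect
from .sem import call_sems, compute_fences, sem_loci, wbc_adjust_betas
from .simulate import SimulationConfig, build_region_sets, simulate_cohorts

logger = logging.getLogger("epiaging")

__all__ = ["RunConfig", "RunManifest", "PipelineError", "run_pipeline",
           "make_table2_like", "pool_estimates"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """One pipeline run. With no input paths the synthetic generator
    provides the cohorts and the generator's own true clocks are applied."""

    simulate: SimulationConfig = field(default_factory=SimulationConfig)
    factors: tuple[str, ...] = FACTORS
    models: tuple[str, ...] = ("M1", "M2")
    reference_clock: str = "blood"   # clock whose AA SD sets the year scale
    use_wbc_adjusted_sem: bool = False
    sem_min_samples: int = 8
    quantile_type: int = 7
    n_perm: int = 500
    min_recurrence: int = 1
    extra_covariates: tuple[str, ...] = ()
    seed: int = 0
    # optional file inputs (one beta matrix per cohort); when set they
    # replace the simulate block
    beta_paths: tuple[str, ...] | None = None
    phenotype_path: str | None = None
    clock_paths: tuple[str, ...] | None = None
    annotation_path: str | None = None
    region_bed_paths: tuple[str, ...] | None = None
    beta_dialect: str = "samples-in-rows"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("simulate", {})
        for key in ("exposure_effects_years", "sem_exposure_log_effects"):
            if key in sim_raw:
                sim_raw[key] = {tuple(k.split(":")): float(v)
                                for k, v in sim_raw[key].items()}
        if "age_range" in sim_raw:
            sim_raw["age_range"] = tuple(sim_raw["age_range"])
        if "clock_names" in sim_raw:
            sim_raw["clock_names"] = tuple(sim_raw["clock_names"])
        sim = SimulationConfig(**sim_raw)
        for key in ("factors", "models", "extra_covariates", "beta_paths",
                    "clock_paths", "region_bed_paths"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(simulate=sim, **raw)

    def config_hash(self) -> str:
        blob = repr(dataclasses.asdict(self)).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    versions: dict[str, str]
    stage_rows: dict[str, int]
    stage_seconds: dict[str, float]
    derived_seeds: dict[str, int]


def _versions() -> dict[str, str]:
    import scipy
    import statsmodels

    from . import __version__
    return {"epiaging": __version__, "numpy": np.__version__,
            "scipy": scipy.__version__, "pandas": pd.__version__,
            "statsmodels": statsmodels.__version__}


def pool_estimates(estimates: list[AssocEstimate]) -> list[MetaResult]:
    """REML-pool estimates grouped by outcome x factor x category x model."""
    groups: dict[tuple, list[AssocEstimate]] = {}
    for e in estimates:
        groups.setdefault((e.outcome, e.factor, e.category, e.model), []).append(e)
    out = []
    for key in sorted(groups):
        ests = groups[key]
        if len(ests) >= 2:
            out.append(reml_pool(ests))
        else:
            logger.warning("group %s pooled from %d cohort(s); skipped", key, len(ests))
    return out


def _load_cohort_inputs(config: RunConfig):
    """File-input branch: one beta matrix per cohort + shared tables."""
    pheno_all = read_phenotypes(config.phenotype_path)
    clocks = [read_clock_model(p, name=Path(p).stem.removeprefix("clock_"))
              for p in config.clock_paths or ()]
    annotation = None
    if config.annotation_path:
        annotation = ProbeAnnotation.from_frame(pd.read_csv(config.annotation_path, sep="\t"))
    region_sets = [read_regions_bed(p) for p in config.region_bed_paths or ()]
    items = []
    for path in config.beta_paths:
        beta = read_beta_matrix(path, dialect=config.beta_dialect)
        missing = set(beta.sample_ids) - set(pheno_all.sample_ids)
        if missing:
            raise ValueError(f"samples in {path} absent from phenotype table: "
                             f"{sorted(missing)[:5]} (orientation mismatch?)")
        pheno = pheno_all.loc(beta.sample_ids)
        cids = pheno.cohort_ids
        if len(cids) != 1:
            raise ValueError(f"beta matrix {path} mixes cohorts {cids}")
        items.append((cids[0], beta, pheno))
    return items, clocks, annotation, region_sets


def run_pipeline(config: RunConfig, output_dir: str | Path | None = None
                 ) -> tuple[RunManifest, dict]:
    """Run every stage; returns the manifest and a dict of result objects.
    When ``output_dir`` is given, every stage's table is written there in
    the same formats the readers accept, so stages can be re-run alone."""
    t_all: dict[str, float] = {}
    rows: dict[str, int] = {}
    seeds = {"simulate": child_seed(config.seed, "simulate"),
             "enrich": child_seed(config.seed, "enrich")}
    outdir = Path(output_dir) if output_dir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    def stage(name):
        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()
                logger.info("stage %s: start", name)
                return self

            def __exit__(self, exc_type, exc, tb):
                t_all[name] = time.perf_counter() - self.t0
                logger.info("stage %s: %.2fs", name, t_all[name])
                if exc is not None and not isinstance(exc, PipelineError):
                    raise PipelineError(name, exc) from exc
        return _Timer()

    # --- inputs -----------------------------------------------------------
    with stage("inputs"):
        if config.beta_paths:
            items, clocks, annotation, region_sets = _load_cohort_inputs(config)
        else:
            sim = dataclasses.replace(config.simulate, seed=seeds["simulate"])
            cohorts = simulate_cohorts(sim)
            items = [(c.cohort_id, c.beta, c.phenotypes) for c in cohorts]
            clocks = cohorts[0].true_clocks
            annotation = cohorts[0].annotation
            region_sets = build_region_sets(sim)
        rows["cohorts"] = len(items)
    clock_names = [c.name for c in clocks]
    outcome_names = ["sem"] + clock_names

    # --- SEM calling ------------------------------------------------------
    sem_results = {}
    with stage("sem-call"):
        for cid, beta, pheno in items:
            fences = compute_fences(beta, min_samples=config.sem_min_samples,
                                    quantile_type=config.quantile_type)
            res = call_sems(beta, fences)
            if config.use_wbc_adjusted_sem:
                frac = pheno.wbc_fractions()
                if frac is None:
                    raise ValueError(f"cohort {cid}: WBC-adjusted SEMs requested "
                                     "but no WBC fractions present")
                resid = wbc_adjust_betas(beta, frac)
                res = call_sems(resid, compute_fences(
                    resid, min_samples=config.sem_min_samples,
                    quantile_type=config.quantile_type), variant="wbc_adjusted")
            sem_results[cid] = res
        rows["sem-call"] = sum(len(r.sample_ids) for r in sem_results.values())
        if outdir:
            burden = pd.concat([
                pd.DataFrame({"sample_id": r.sample_ids, "cohort_id": cid,
                              "burden": r.burden, "log_burden": r.log_burden})
                for cid, r in sem_results.items()])
            burden.to_csv(outdir / "sem_burden.tsv", sep="\t", index=False,
                          float_format="%.12g")

    # --- clocks -----------------------------------------------------------
    accel = {}
    with stage("clock"):
        frames = []
        for cid, beta, pheno in items:
            for model, name in zip(clocks, clock_names):
                dnam = predict_dnam_age(beta, model)
                acc = compute_acceleration(dnam, pheno, clock_name=name,
                                           use_wbc=bool(pheno.wbc_columns))
                accel[(cid, name)] = acc
                frames.append(acc)
        rows["clock"] = sum(len(a) for a in accel.values())
        if outdir:
            pd.concat(frames).to_csv(outdir / "age_acceleration.tsv", sep="\t",
                                     index=False, float_format="%.12g")

    # --- association models ----------------------------------------------
    estimates: list[AssocEstimate] = []
    with stage("assoc"):
        for cid, beta, pheno in items:
            semres = sem_results[cid]
            log_burden = pd.Series(semres.log_burden, index=semres.sample_ids,
                                   name="sem_log")
            sigma_out = float(log_burden.std(ddof=1))
            ref_aa = accel[(cid, config.reference_clock)]["aa"]
            sigma_ref = float(ref_aa.std(ddof=1))
            outcome_series = {"sem_log": log_burden}
            for name in clock_names:
                acc = accel[(cid, name)]
                outcome_series[name] = pd.Series(acc["eaa"].to_numpy(),
                                                 index=acc["sample_id"], name=name)
            for factor in config.factors:
                for model in config.models:
                    for oname, series in outcome_series.items():
                        ests = fit_cohort_models(
                            series, pheno, factor, model,
                            extra_covariates=list(config.extra_covariates) or None)
                        if oname == "sem_log":
                            estimates.extend(ests)  # keep raw log-scale rows
                            estimates.extend(
                                rescale_sem_effect(e, sigma_out, sigma_ref)
                                .as_estimate("sem") for e in ests)
                        else:
                            estimates.extend(ests)
        rows["assoc"] = len(estimates)
        if outdir:
            write_results_table(estimates, outdir / "assoc_estimates.tsv")

    # --- meta-analysis ----------------------------------------------------
    with stage("meta"):
        meta_results = pool_estimates(estimates)
        grid = [m for m in meta_results if m.outcome in outcome_names]
        rows["meta"] = len(grid)
        if outdir:
            write_results_table(meta_results, outdir / "meta_results.tsv")
            forest_plot(grid, str(outdir / "forest.svg"))

    # --- enrichment -------------------------------------------------------
    enrichment: list[EnrichmentResult] = []
    with stage("enrich"):
        if annotation is not None and region_sets:
            counts = None
            for cid, res in sem_results.items():
                c = res.sem_mask.sum(axis=0)
                s = pd.Series(c, index=res.probe_ids)
                counts = s if counts is None else counts.add(s, fill_value=0)
            loci = list(counts.index[counts >= config.min_recurrence])
            if loci:
                enrichment = enrichment_batch(loci, annotation, region_sets,
                                              n_perm=config.n_perm,
                                              seed=seeds["enrich"])
        rows["enrich"] = len(enrichment)
        if outdir and enrichment:
            write_results_table(enrichment, outdir / "enrichment.tsv")

    # --- report -----------------------------------------------------------
    with stage("report"):
        table = make_table2_like(grid, outcome_order=outcome_names,
                                 model_order=list(config.models))
        rows["report"] = len(table)
        if outdir:
            table.to_csv(outdir / "pooled_table.tsv", sep="\t")

    manifest = RunManifest(config_hash=config.config_hash(), seed=config.seed,
                           versions=_versions(), stage_rows=rows,
                           stage_seconds=t_all, derived_seeds=seeds)
    if outdir:
        with open(outdir / "manifest.json", "w") as fh:
            d = dataclasses.asdict(manifest)
            d["stage_seconds"] = {k: round(v, 3) for k, v in d["stage_seconds"].items()}
            json.dump(d, fh, indent=2)
    return manifest, {"estimates": estimates, "meta_results": meta_results,
                      "grid": grid, "enrichment": enrichment, "table": table,
                      "sem_results": sem_results, "accel": accel}


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def make_table2_like(meta_results: list[MetaResult],
                     outcome_order: list[str] | None = None,
                     model_order: list[str] | None = None) -> pd.DataFrame:
    """Compact report: rows = factor x non-reference category (with the
    reference named), columns = outcome x model, cells 'b (lo; hi)' with
    significance stars; missing cells rendered as an em dash."""
    by_key = {(m.outcome, m.factor, m.category, m.model): m for m in meta_results}
    outcomes = outcome_order or sorted({m.outcome for m in meta_results})
    models = model_order or sorted({m.model for m in meta_results})
    index, rows = [], []
    for factor in FACTORS:
        ref = REFERENCE_LEVELS[factor]
        for category in FACTOR_LEVELS[factor][1:]:
            index.append((f"{factor} (ref: {ref})", category))
            row = {}
            for outcome in outcomes:
                for model in models:
                    m = by_key.get((outcome, factor, category, model))
                    if m is None:
                        row[(outcome, model)] = "—"
                    else:
                        lo, hi = m.ci95
                        row[(outcome, model)] = (
                            f"{m.beta_pooled:.2f} ({lo:.2f}; {hi:.2f})"
                            f"{_stars(m.p_value)}")
            rows.append(row)
    df = pd.DataFrame(rows, index=pd.MultiIndex.from_tuples(index,
                                                            names=["factor", "category"]))
    df.columns = pd.MultiIndex.from_tuples(df.columns, names=["outcome", "model"])
    return df
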