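"""Stochastic epigenetic mutation (SEM) calling.

A SEM is a sample whose methylation beta at one CpG lies outside Tukey-style
extreme fences computed from the cross-sample distribution at that CpG:
strictly below Q1 - 3*IQR or strictly above Q3 + 3*IQR. Each sample's
epimutation burden is the count of such outlier calls across all probes;
because the burden grows exponentially with age it is modelled on a log
scale, ln(burden + 1) by default.

A white-blood-cell-adjusted variant first residualizes each probe's betas
on estimated WBC fractions (dropping one fraction to avoid the sum-to-one
collinearity) and calls SEMs on the residuals, removing outliers driven by
unusual cell composition rather than epigenetic drift.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import BetaMatrix

logger = logging.getLogger("epiaging")

__all__ = [
    "FenceTable",
    "SEMResult",
    "ResidualMatrix",
    "compute_fences",
    "call_sems",
    "wbc_adjust_betas",
    "sem_loci",
]

FENCE_MULTIPLIER = 3.0

#: Hyndman-Fan quantile types supported; 7 (linear interpolation) is the
#: default of numpy, R and pandas, 2 averages the inverted CDF at ties.
_QUANTILE_METHODS = {7: "linear", 2: "averaged_inverted_cdf"}


@dataclass
class ResidualMatrix:
    """Beta residuals after covariate adjustment: same layout as BetaMatrix
    but values are unbounded."""

    sample_ids: list[str]
    probe_ids: list[str]
    values: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class FenceTable:
    """Per-probe quartiles and extreme fences.

    lower = Q1 - 3*IQR, upper = Q3 + 3*IQR; n_used counts the non-missing
    samples that entered the quantile computation.
    """

    probe_ids: list[str]
    q1: np.ndarray
    q3: np.ndarray
    n_used: np.ndarray
    multiplier: float = FENCE_MULTIPLIER

    def __post_init__(self) -> None:
        if np.any(self.q1 > self.q3):
            raise ValueError("Q1 > Q3: quantile computation is broken")

    @property
    def iqr(self) -> np.ndarray:
        return self.q3 - self.q1

    @property
    def lower(self) -> np.ndarray:
        return self.q1 - self.multiplier * self.iqr

    @property
    def upper(self) -> np.ndarray:
        return self.q3 + self.multiplier * self.iqr

    def __len__(self) -> int:
        return len(self.probe_ids)


@dataclass
class SEMResult:
    """SEM calls for one cohort: boolean mask (samples x probes), per-sample
    burden, and its log transform."""

    sample_ids: list[str]
    fences: FenceTable
    sem_mask: np.ndarray
    burden: np.ndarray
    log_burden: np.ndarray
    variant: str = "raw"

    @property
    def probe_ids(self) -> list[str]:
        return self.fences.probe_ids


def compute_fences(beta: BetaMatrix | ResidualMatrix, min_samples: int = 8,
                   quantile_type: int = 7,
                   multiplier: float = FENCE_MULTIPLIER) -> FenceTable:
    """Compute per-probe quartiles and extreme fences across samples.

    Missing values are excluded probe-wise. Probes with fewer than
    ``min_samples`` non-missing values are dropped (logged, not an error):
    quartiles from a handful of samples give meaningless fences.
    """
    if quantile_type not in _QUANTILE_METHODS:
        raise ValueError(f"quantile_type must be one of {sorted(_QUANTILE_METHODS)}")
    method = _QUANTILE_METHODS[quantile_type]
    vals = beta.values
    n_used = np.sum(~np.isnan(vals), axis=0)
    keep = n_used >= min_samples
    if not np.all(keep):
        dropped = int((~keep).sum())
        logger.info("compute_fences: dropping %d probes with < %d non-missing samples",
                    dropped, min_samples)
    vals = vals[:, keep]
    probe_ids = [p for p, k in zip(beta.probe_ids, keep) if k]
    with np.errstate(invalid="ignore"):
        q1 = np.nanquantile(vals, 0.25, axis=0, method=method)
        q3 = np.nanquantile(vals, 0.75, axis=0, method=method)
    return FenceTable(probe_ids, q1, q3, n_used[keep], multiplier)


def call_sems(beta: BetaMatrix | ResidualMatrix, fences: FenceTable,
              log_mode: str = "log1p", variant: str = "raw") -> SEMResult:
    """Call SEMs against precomputed fences and tally per-sample burden.

    The fence comparison is strict (< lower or > upper), so values exactly
    on a fence — including every value of a constant probe, whose fences
    collapse to a point — are not SEMs. Missing values are never SEMs.

    ``log_mode``: 'log1p' gives ln(burden + 1) (defined at zero burden);
    'log' gives ln(burden) with zero burdens mapped to NaN.
    """
    probe_pos = {p: i for i, p in enumerate(beta.probe_ids)}
    missing = [p for p in fences.probe_ids if p not in probe_pos]
    if missing:
        raise ValueError(f"fences refer to probes absent from matrix: {missing[:5]}")
    cols = [probe_pos[p] for p in fences.probe_ids]
    vals = beta.values[:, cols]
    with np.errstate(invalid="ignore"):
        mask = (vals < fences.lower) | (vals > fences.upper)
    mask &= ~np.isnan(vals)
    burden = mask.sum(axis=1).astype(np.int64)
    if log_mode == "log1p":
        log_burden = np.log1p(burden.astype(float))
    elif log_mode == "log":
        with np.errstate(divide="ignore"):
            log_burden = np.where(burden > 0, np.log(burden.astype(float)), np.nan)
    else:
        raise ValueError(f"unknown log_mode {log_mode!r}")
    return SEMResult(list(beta.sample_ids), fences, mask, burden, log_burden, variant)


def wbc_adjust_betas(beta: BetaMatrix, wbc_fractions: np.ndarray,
                     drop_column: int = -1) -> ResidualMatrix:
    """Residualize each probe's betas on WBC fractions by per-probe OLS.

    One fraction column (by default the last) is dropped because the
    fractions sum to one; an intercept is always included. Returns the
    residual matrix, on which fences and SEM calls can be recomputed.
    """
    frac = np.asarray(wbc_fractions, dtype=float)
    if frac.ndim != 2 or frac.shape[0] != len(beta.sample_ids):
        raise ValueError("wbc_fractions must be (n_samples, n_celltypes)")
    kept = np.delete(frac, drop_column % frac.shape[1], axis=1)
    n = kept.shape[0]
    X = np.column_stack([np.ones(n), kept])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # constant columns degenerate into the intercept; true collinearity
        # among varying fractions is a data error
        stds = kept.std(axis=0)
        varying = stds > 1e-12
        if np.linalg.matrix_rank(np.column_stack([np.ones(n), kept[:, varying]])) < 1 + varying.sum():
            raise ValueError("WBC design is rank deficient after dropping one column; "
                             "check for linearly dependent fraction columns")
        X = np.column_stack([np.ones(n), kept[:, varying]])
    vals = beta.values
    if np.isnan(vals).any():
        resid = np.full_like(vals, np.nan)
        for j in range(vals.shape[1]):
            y = vals[:, j]
            ok = ~np.isnan(y)
            if ok.sum() <= X.shape[1]:
                continue
            coef, *_ = np.linalg.lstsq(X[ok], y[ok], rcond=None)
            resid[ok, j] = y[ok] - X[ok] @ coef
    else:
        coef, *_ = np.linalg.lstsq(X, vals, rcond=None)
        resid = vals - X @ coef
    return ResidualMatrix(list(beta.sample_ids), list(beta.probe_ids), resid)


def sem_loci(result: SEMResult, min_recurrence: int = 1) -> list[str]:
    """Probes carrying at least ``min_recurrence`` SEM calls across samples —
    the locus set fed to region-enrichment testing."""
    counts = result.sem_mask.sum(axis=0)
    return [p for p, c in zip(result.probe_ids, counts) if c >= min_recurrence]
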