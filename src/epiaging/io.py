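"""Domain types and file I/O for the epigenetic-aging pipeline.

The pipeline works on four kinds of tabular inputs: DNA-methylation beta
matrices (samples x CpG probes, values in [0, 1]), probe genomic
annotations, linear clock coefficient tables, and sample phenotype tables.
Genomic region sets are read from BED. All coordinates are 0-based
half-open; a probe locus is the single-base interval [pos, pos + 1).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("epiaging")

__all__ = [
    "FACTORS",
    "FACTOR_LEVELS",
    "REFERENCE_LEVELS",
    "BetaMatrix",
    "ProbeAnnotation",
    "PhenotypeTable",
    "ClockModel",
    "RegionSet",
    "read_beta_matrix",
    "write_beta_matrix",
    "read_phenotypes",
    "read_clock_model",
    "write_clock_model",
    "read_regions_bed",
    "write_regions_bed",
    "write_results_table",
    "read_results_table",
]

#: The five lifestyle risk factors, each a three-level categorical.
FACTORS = ("education", "smoking", "obesity", "alcohol", "physical_activity")

#: Category labels per factor; the first label is always the reference.
FACTOR_LEVELS: Mapping[str, tuple[str, str, str]] = {
    "education": ("High", "Medium", "Low"),
    "smoking": ("Never", "Former", "Current"),
    "obesity": ("NormalWeight", "Overweight", "Obese"),
    "alcohol": ("Abstainer", "Occasional", "Habitual"),
    "physical_activity": ("High", "Medium", "Low"),
}

REFERENCE_LEVELS: Mapping[str, str] = {f: levels[0] for f, levels in FACTOR_LEVELS.items()}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class BetaMatrix:
    """Methylation beta values, shape (n_samples, n_probes), NaN = missing.

    All non-missing values must lie in [0, 1]; sample and probe identifiers
    must be unique.
    """

    sample_ids: list[str]
    probe_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.probe_ids = [str(p) for p in self.probe_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.probe_ids)):
            raise ValueError(
                f"beta matrix shape {self.values.shape} does not match "
                f"({len(self.sample_ids)} samples, {len(self.probe_ids)} probes)"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids in beta matrix")
        if len(set(self.probe_ids)) != len(self.probe_ids):
            raise ValueError("duplicate probe ids in beta matrix")
        bad = np.where((self.values < 0) | (self.values > 1))
        if bad[0].size:
            i, j = bad[0][0], bad[1][0]
            raise ValueError(
                f"beta value out of [0, 1]: {self.values[i, j]!r} at "
                f"sample {self.sample_ids[i]!r}, probe {self.probe_ids[j]!r}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.probe_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "BetaMatrix":
        return cls(list(df.index.astype(str)), list(df.columns.astype(str)), df.to_numpy(float))

    def subset_probes(self, probes: Sequence[str]) -> "BetaMatrix":
        idx = {p: i for i, p in enumerate(self.probe_ids)}
        cols = [idx[p] for p in probes]
        return BetaMatrix(self.sample_ids, list(probes), self.values[:, cols])


@dataclass
class ProbeAnnotation:
    """Genomic position of each probe: single-base locus [pos, pos + 1)."""

    probe_ids: list[str]
    chrom: list[str]
    pos: np.ndarray  # 0-based
    strand: list[str] | None = None

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=np.int64)
        n = len(self.probe_ids)
        if len(self.chrom) != n or self.pos.shape != (n,):
            raise ValueError("probe annotation field lengths disagree")
        if len(set(self.probe_ids)) != n:
            raise ValueError("duplicate probe ids in annotation")
        if n and self.pos.min() < 0:
            raise ValueError("probe position must be >= 0")

    def __len__(self) -> int:
        return len(self.probe_ids)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"probe_id": self.probe_ids, "chrom": self.chrom, "pos": self.pos})
        if self.strand is not None:
            df["strand"] = self.strand
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ProbeAnnotation":
        strand = list(df["strand"]) if "strand" in df.columns else None
        return cls(list(df["probe_id"].astype(str)), list(df["chrom"].astype(str)),
                   df["pos"].to_numpy(np.int64), strand)

    def subset(self, probes: Sequence[str]) -> "ProbeAnnotation":
        idx = {p: i for i, p in enumerate(self.probe_ids)}
        rows = [idx[p] for p in probes]
        return ProbeAnnotation(
            [self.probe_ids[i] for i in rows],
            [self.chrom[i] for i in rows],
            self.pos[rows],
            [self.strand[i] for i in rows] if self.strand is not None else None,
        )


class PhenotypeTable:
    """Sample phenotypes: age, sex, the five categorical risk factors,
    optional white-blood-cell fractions and extra covariates.

    Backed by a DataFrame indexed by sample_id. Category labels are
    case-sensitive exact strings; a relabel map may be applied on read to
    harmonize cohort-specific codings.
    """

    REQUIRED = ("age", "sex", "cohort_id") + FACTORS

    def __init__(self, df: pd.DataFrame, wbc_columns: Sequence[str] = ()):
        df = df.copy()
        if df.index.name != "sample_id":
            if "sample_id" in df.columns:
                df = df.set_index("sample_id")
            else:
                raise ValueError("phenotype table needs a sample_id column or index")
        df.index = df.index.astype(str)
        if df.index.duplicated().any():
            raise ValueError("duplicate sample ids in phenotype table")
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"phenotype table missing columns: {missing}")
        if (df["age"] <= 0).any():
            raise ValueError("ages must be positive")
        bad_sex = set(df["sex"].dropna().unique()) - {"male", "female"}
        if bad_sex:
            raise ValueError(f"unknown sex labels: {sorted(bad_sex)}")
        for f in FACTORS:
            bad = set(df[f].dropna().unique()) - set(FACTOR_LEVELS[f])
            if bad:
                raise ValueError(f"unknown {f} labels: {sorted(bad)} "
                                 f"(expected {list(FACTOR_LEVELS[f])})")
        self.wbc_columns = list(wbc_columns)
        if self.wbc_columns:
            frac = df[self.wbc_columns].to_numpy(float)
            if (frac < 0).any():
                raise ValueError("WBC fractions must be non-negative")
            sums = frac.sum(axis=1)
            if np.abs(sums - 1.0).max() > 1e-6:
                raise ValueError("WBC fractions must sum to 1 per sample")
        self.df = df

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def cohort_ids(self) -> list[str]:
        return sorted(self.df["cohort_id"].astype(str).unique())

    def __len__(self) -> int:
        return len(self.df)

    def loc(self, sample_ids: Sequence[str]) -> "PhenotypeTable":
        return PhenotypeTable(self.df.loc[list(sample_ids)], self.wbc_columns)

    def cohort(self, cohort_id: str) -> "PhenotypeTable":
        sub = self.df[self.df["cohort_id"].astype(str) == str(cohort_id)]
        return PhenotypeTable(sub, self.wbc_columns)

    def wbc_fractions(self) -> np.ndarray | None:
        if not self.wbc_columns:
            return None
        return self.df[self.wbc_columns].to_numpy(float)


@dataclass
class ClockModel:
    """A linear CpG clock: predicted age = g(intercept + sum_j w_j * beta_j).

    ``age_transform`` is either ``identity`` or ``horvath_logadult``, the
    piecewise log transform used by pan-tissue clocks, with parameter
    ``adult_age`` in years.
    """

    name: str
    intercept: float
    coefficients: dict[str, float]
    age_transform: str = "identity"
    adult_age: float = 20.0

    def __post_init__(self) -> None:
        if not self.coefficients:
            raise ValueError("clock model needs at least one coefficient")
        if self.age_transform not in ("identity", "horvath_logadult"):
            raise ValueError(f"unknown age_transform {self.age_transform!r}")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.coefficients)

    def __len__(self) -> int:
        return len(self.coefficients)


@dataclass
class RegionSet:
    """A named set of genomic intervals, 0-based half-open."""

    name: str
    intervals: list[tuple[str, int, int]]

    def __post_init__(self) -> None:
        for chrom, start, end in self.intervals:
            if start >= end:
                raise ValueError(f"empty/inverted interval {chrom}:{start}-{end}")

    def __len__(self) -> int:
        return len(self.intervals)

    def merged(self) -> "RegionSet":
        """Merge overlapping or abutting intervals per chromosome."""
        out: list[tuple[str, int, int]] = []
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, s, e in self.intervals:
            by_chrom.setdefault(chrom, []).append((s, e))
        for chrom in sorted(by_chrom):
            ivs = sorted(by_chrom[chrom])
            cur_s, cur_e = ivs[0]
            for s, e in ivs[1:]:
                if s <= cur_e:  # overlap or abut (half-open)
                    cur_e = max(cur_e, e)
                else:
                    out.append((chrom, cur_s, cur_e))
                    cur_s, cur_e = s, e
            out.append((chrom, cur_s, cur_e))
        return RegionSet(self.name, out)

    def total_span(self) -> int:
        return sum(e - s for _, s, e in self.merged().intervals)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_beta_matrix(path: str | Path, dialect: str = "samples-in-rows",
                     sep: str = "\t") -> BetaMatrix:
    """Read a delimited beta matrix.

    ``dialect`` is explicit — 'samples-in-rows' or 'probes-in-rows' — and is
    never guessed from the file: silent transposition of a methylation
    matrix is unrecoverable downstream.
    """
    if dialect not in ("samples-in-rows", "probes-in-rows"):
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, sep=sep, index_col=0)
    for col in df.columns:
        nonnum = df[col].map(lambda v: isinstance(v, str))
        if nonnum.any():
            row = df.index[nonnum.idxmax() if isinstance(nonnum.idxmax(), int) else 0]
            bad_rows = df.index[nonnum].tolist()
            raise ValueError(
                f"non-numeric beta value in column {col!r}, row(s) {bad_rows[:5]}"
            )
    df = df.astype(float)
    if dialect == "probes-in-rows":
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return BetaMatrix.from_frame(df)


def write_beta_matrix(beta: BetaMatrix, path: str | Path,
                      dialect: str = "samples-in-rows", sep: str = "\t") -> None:
    df = beta.to_frame()
    if dialect == "probes-in-rows":
        df = df.T
    elif dialect != "samples-in-rows":
        raise ValueError(f"unknown dialect {dialect!r}")
    df.to_csv(path, sep=sep, float_format="%.12g", index_label="id")


def read_phenotypes(path: str | Path, sep: str = "\t",
                    wbc_columns: Sequence[str] = (),
                    relabel: Mapping[str, Mapping[str, str]] | None = None) -> PhenotypeTable:
    """Read a phenotype table; ``relabel`` maps cohort idiosyncratic labels
    to the canonical ones, per factor (e.g. {'smoking': {'ex': 'Former'}})."""
    df = pd.read_csv(path, sep=sep)
    if relabel:
        for factor, mapping in relabel.items():
            df[factor] = df[factor].replace(dict(mapping))
    wbc = list(wbc_columns) or [c for c in df.columns if c.startswith("wbc_")]
    return PhenotypeTable(df, wbc_columns=wbc)


def write_phenotypes(pheno: PhenotypeTable, path: str | Path, sep: str = "\t") -> None:
    pheno.df.to_csv(path, sep=sep, float_format="%.12g", index_label="sample_id")


INTERCEPT_KEY = "(Intercept)"


def read_clock_model(path: str | Path, name: str | None = None) -> ClockModel:
    """Read a clock coefficient CSV with columns probe_id, weight and one
    reserved '(Intercept)' row; optional columns age_transform, adult_age."""
    df = pd.read_csv(path)
    if "probe_id" not in df.columns or "weight" not in df.columns:
        raise ValueError("clock file needs probe_id and weight columns")
    is_int = df["probe_id"] == INTERCEPT_KEY
    if is_int.sum() != 1:
        raise ValueError(f"clock file must contain exactly one {INTERCEPT_KEY} row")
    intercept = float(df.loc[is_int, "weight"].iloc[0])
    rest = df[~is_int]
    if rest["probe_id"].duplicated().any():
        dups = rest.loc[rest["probe_id"].duplicated(), "probe_id"].tolist()
        raise ValueError(f"duplicate probe rows in clock file: {dups[:5]}")
    transform = "identity"
    adult_age = 20.0
    if "age_transform" in df.columns:
        transform = str(df["age_transform"].iloc[0])
    if "adult_age" in df.columns:
        adult_age = float(df["adult_age"].iloc[0])
    return ClockModel(
        name=name or Path(path).stem,
        intercept=intercept,
        coefficients=dict(zip(rest["probe_id"].astype(str), rest["weight"].astype(float))),
        age_transform=transform,
        adult_age=adult_age,
    )


def write_clock_model(model: ClockModel, path: str | Path) -> None:
    rows = [{"probe_id": INTERCEPT_KEY, "weight": model.intercept}]
    rows += [{"probe_id": p, "weight": w} for p, w in model.coefficients.items()]
    df = pd.DataFrame(rows)
    df["age_transform"] = model.age_transform
    df["adult_age"] = model.adult_age
    df.to_csv(path, index=False, float_format="%.12g")


def read_regions_bed(path: str | Path, name: str | None = None,
                     merge: bool = False) -> RegionSet:
    """Read a 3+ column BED file (0-based half-open)."""
    intervals: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED line has <3 columns")
            chrom, start_s, end_s = parts[0], parts[1], parts[2]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start {start} >= end {end}")
            intervals.append((chrom, start, end))
    rs = RegionSet(name or Path(path).stem, intervals)
    return rs.merged() if merge else rs


def write_regions_bed(regions: RegionSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, s, e in regions.intervals:
            fh.write(f"{chrom}\t{s}\t{e}\n")


def write_results_table(records: Iterable, path: str | Path, sep: str = "\t") -> None:
    """Write a collection of result dataclasses (AssocEstimate, MetaResult,
    EnrichmentResult, ...) as one delimited table, full float precision.

    Nested collections (e.g. the per-cohort estimates inside a pooled
    result) are dropped; tuple fields are expanded into _lo/_hi columns.
    """
    rows = []
    for rec in records:
        d = dataclasses.asdict(rec) if dataclasses.is_dataclass(rec) else dict(rec)
        flat = {}
        for k, v in d.items():
            if isinstance(v, (list, dict)):
                continue
            if isinstance(v, tuple) and len(v) == 2:
                flat[f"{k}_lo"], flat[f"{k}_hi"] = v
            else:
                flat[k] = v
        rows.append(flat)
    df = pd.DataFrame(rows)
    df.to_csv(path, sep=sep, index=False, float_format="%.12g")


def read_results_table(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep=sep)
    except pd.errors.EmptyDataError:
        return pd.DataFrame()
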