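"""Permutation test for regional enrichment of SEM loci.

Null model: SEM-carrying probes are an exchangeable draw from the probe
universe of the array. Each permutation resamples |loci| probes uniformly
without replacement from the universe and recounts the overlap with the
region set; resampling probe identities (rather than shuffling genomic
coordinates) respects the fixed, non-uniform probe density of methylation
arrays, which is the dominant confounder of naive overlap statistics.
P-values use the add-one rule (b + 1) / (n_perm + 1) and are therefore
never zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._rng import substream
from .io import ProbeAnnotation, RegionSet

__all__ = ["EnrichmentResult", "overlap_mask", "overlap_count",
           "permutation_test", "enrichment_batch"]


@dataclass
class EnrichmentResult:
    region_set_name: str
    n_loci: int
    observed_overlap: int
    perm_mean: float
    perm_sd: float
    fold: float
    p_value: float
    n_perm: int
    alternative: str
    p_bonferroni: float | None = None


class _IntervalIndex:
    """Merged, sorted intervals per chromosome for O(log n) point queries."""

    def __init__(self, regions: RegionSet):
        merged = regions.merged()
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, s, e in merged.intervals:
            by_chrom.setdefault(chrom, []).append((s, e))
        for chrom, ivs in by_chrom.items():
            arr = np.array(sorted(ivs), dtype=np.int64)
            self._starts[chrom] = arr[:, 0]
            self._ends[chrom] = arr[:, 1]

    def contains(self, chrom: np.ndarray | list[str], pos: np.ndarray) -> np.ndarray:
        pos = np.asarray(pos, dtype=np.int64)
        out = np.zeros(len(pos), dtype=bool)
        chrom = np.asarray(chrom)
        for c in np.unique(chrom):
            if c not in self._starts:
                continue  # chromosome absent from region set: non-overlap
            sel = chrom == c
            p = pos[sel]
            idx = np.searchsorted(self._starts[c], p, side="right") - 1
            ok = idx >= 0
            hit = np.zeros(len(p), dtype=bool)
            hit[ok] = p[ok] < self._ends[c][idx[ok]]
            out[sel] = hit
        return out


def overlap_mask(loci: ProbeAnnotation, regions: RegionSet) -> np.ndarray:
    """Boolean per-locus flag: the single-base locus [pos, pos+1) intersects
    some interval of the set."""
    return _IntervalIndex(regions).contains(np.asarray(loci.chrom), loci.pos)


def overlap_count(loci: ProbeAnnotation, regions: RegionSet) -> int:
    return int(overlap_mask(loci, regions).sum())


def permutation_test(sem_loci: list[str], universe: ProbeAnnotation,
                     regions: RegionSet, n_perm: int = 1000, seed: int = 0,
                     alternative: str = "greater") -> EnrichmentResult:
    """Test whether ``sem_loci`` (probe ids, a subset of ``universe``)
    overlap ``regions`` more (or less) than uniform draws from the universe."""
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    uni_ids = universe.probe_ids
    pos_of = {p: i for i, p in enumerate(uni_ids)}
    missing = [p for p in sem_loci if p not in pos_of]
    if missing:
        raise ValueError(f"loci not in universe: {missing[:5]}")
    n_loci = len(sem_loci)
    if n_loci > len(uni_ids):
        raise ValueError("more loci than universe probes")
    if n_loci == 0:
        raise ValueError("empty locus set")
    in_region = _IntervalIndex(regions).contains(np.asarray(universe.chrom),
                                                 universe.pos)
    observed = int(in_region[[pos_of[p] for p in sem_loci]].sum())
    rng = substream(seed, f"enrich:{regions.name}")
    m = len(uni_ids)
    perm_overlap = np.empty(n_perm, dtype=np.int64)
    # chunked vectorized draws: argpartition of random keys = uniform
    # sample without replacement of n_loci indices per row
    chunk = max(1, min(n_perm, int(2e6 // max(m, 1)) or 1))
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        keys = rng.random((b, m))
        picks = np.argpartition(keys, n_loci - 1, axis=1)[:, :n_loci]
        perm_overlap[done:done + b] = in_region[picks].sum(axis=1)
        done += b
    if alternative == "greater":
        b_count = int((perm_overlap >= observed).sum())
    else:
        b_count = int((perm_overlap <= observed).sum())
    perm_mean = float(perm_overlap.mean())
    return EnrichmentResult(
        region_set_name=regions.name,
        n_loci=n_loci,
        observed_overlap=observed,
        perm_mean=perm_mean,
        perm_sd=float(perm_overlap.std(ddof=1)) if n_perm > 1 else 0.0,
        fold=observed / perm_mean if perm_mean > 0 else float("inf"),
        p_value=(b_count + 1) / (n_perm + 1),
        n_perm=n_perm,
        alternative=alternative,
    )


def enrichment_batch(sem_loci: list[str], universe: ProbeAnnotation,
                     region_sets: list[RegionSet], n_perm: int = 1000,
                     seed: int = 0, alternative: str = "greater",
                     bonferroni: bool = False) -> list[EnrichmentResult]:
    """One permutation test per region set, each on its own derived seed."""
    if not region_sets:
        raise ValueError("need at least one region set")
    names = [r.name for r in region_sets]
    if len(set(names)) != len(names):
        raise ValueError("duplicate region set names")
    results = [permutation_test(sem_loci, universe, rs, n_perm=n_perm,
                                seed=seed, alternative=alternative)
               for rs in region_sets]
    if bonferroni:
        k = len(results)
        for r in results:
            r.p_bonferroni = min(1.0, r.p_value * k)
    return results
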