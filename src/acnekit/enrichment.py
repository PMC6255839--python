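"""Resampling and classical tests for genomic enrichment.

Two permutation nulls are provided:

* *placement* — the query segments keep their lengths but are re-placed
  uniformly at random across a workspace of chromosome sizes, and the
  statistic is the total base-pair overlap with an annotation (the null
  behind GAT-style interval-overlap tests).  Placed segments may overlap
  one another; positions are drawn independently.
* *selection* — the query is a subset of a finite universe of regions, and
  each permutation redraws ``|query|`` members without replacement; the
  statistic is the number of drawn members satisfying a predicate (the
  null behind "compared to randomly selected open chromatin regions").

Empirical p-values use the convention ``max(b, 1) / n_perm`` with ``b`` the
number of permutations at least as extreme as the observed value in the
enrichment direction, so the smallest reportable p at 1000 permutations is
0.001.  Z-scores use the sample standard deviation (n-1 denominator).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import stats

from .intervals import GenomicInterval, IntervalSet, ScoredPeak

PLACEMENT = "placement"
SELECTION = "selection"


@dataclass
class EnrichmentConfig:
    """``workspace`` maps chrom name to size (placement mode); ``universe``
    is the finite region pool (selection mode).  The PRNG is numpy's
    default (PCG64), seeded explicitly; the seed is echoed in results."""

    n_perm: int = 1000
    seed: int = 0
    mode: str = SELECTION
    workspace: Mapping[str, int] | None = None
    universe: IntervalSet | None = None

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.mode not in (PLACEMENT, SELECTION):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == PLACEMENT and not self.workspace:
            raise ValueError("placement mode requires a workspace")
        if self.mode == SELECTION and self.universe is None:
            raise ValueError("selection mode requires a universe")


@dataclass(frozen=True)
class EnrichmentResult:
    """``p_emp`` is always the enrichment-side tail, max(b, 1)/n_perm with
    b the permutations >= observed; ``p_emp_depletion`` is the symmetric
    lower tail.  ``direction`` records which side of the permutation mean
    the observation fell on."""

    observed: float
    perm_mean: float
    perm_sd: float
    z: float | None
    p_emp: float
    n_perm: int
    p_emp_depletion: float = 1.0
    direction: str = "enrichment"
    seed: int | None = None

    def __post_init__(self) -> None:
        for p in (self.p_emp, self.p_emp_depletion):
            if not (0.0 < p <= 1.0):
                raise ValueError("empirical p must lie in (0, 1]")
            if p < 1.0 / self.n_perm - 1e-12:
                raise ValueError("empirical p below the 1/n_perm floor")


def _summarize_permutations(
    observed: float, perm: np.ndarray, n_perm: int, seed: int
) -> EnrichmentResult:
    mean = float(perm.mean())
    sd = float(perm.std(ddof=1)) if len(perm) > 1 else 0.0
    z = (observed - mean) / sd if sd > 0 else None
    b_hi = int(np.sum(perm >= observed - 1e-12))
    b_lo = int(np.sum(perm <= observed + 1e-12))
    return EnrichmentResult(
        observed=observed,
        perm_mean=mean,
        perm_sd=sd,
        z=z,
        p_emp=max(b_hi, 1) / n_perm,
        n_perm=n_perm,
        p_emp_depletion=max(b_lo, 1) / n_perm,
        direction="enrichment" if observed >= mean else "depletion",
        seed=seed,
    )


class _CoverageIndex:
    """Per-chrom merged annotation with prefix sums for O(log n) overlap of
    an arbitrary segment with the annotation union."""

    def __init__(self, annotation: IntervalSet) -> None:
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom in annotation.chroms:
            merged: list[list[int]] = []
            for iv in annotation.on_chrom(chrom):
                if merged and iv.start <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], iv.end)
                else:
                    merged.append([iv.start, iv.end])
            starts = np.array([m[0] for m in merged])
            ends = np.array([m[1] for m in merged])
            prefix = np.concatenate([[0], np.cumsum(ends - starts)])
            self._by_chrom[chrom] = (starts, ends, prefix)

    def _coverage_before(self, chrom: str, x: int) -> int:
        starts, ends, prefix = self._by_chrom[chrom]
        i = int(np.searchsorted(starts, x, side="right"))
        if i == 0:
            return 0
        return int(prefix[i - 1] + min(int(ends[i - 1]), x) - int(starts[i - 1])
                   if x < ends[i - 1] else prefix[i])

    def overlap(self, chrom: str, start: int, end: int) -> int:
        if chrom not in self._by_chrom:
            return 0
        return self._coverage_before(chrom, end) - self._coverage_before(chrom, start)


def total_bp_overlap(query: IntervalSet, annotation: IntervalSet) -> int:
    """Total bases of the query covered by the annotation union."""
    return sum(annotation.total_overlap(q) for q in query)


def placement_permutation(
    query: IntervalSet, annotation: IntervalSet, cfg: EnrichmentConfig
) -> EnrichmentResult:
    """Permutation test on total bp overlap under uniform re-placement.

    Each query segment is re-placed on a chromosome drawn with probability
    proportional to its number of valid start positions, then at a uniform
    start; segment lengths are preserved.
    """
    if cfg.mode != PLACEMENT:
        raise ValueError("config mode must be 'placement'")
    rng = np.random.default_rng(cfg.seed)
    cov = _CoverageIndex(annotation)
    lengths = [q.length for q in query]
    chrom_names = sorted(cfg.workspace)
    chrom_sizes = np.array([cfg.workspace[c] for c in chrom_names])
    for L in lengths:
        if L > chrom_sizes.max():
            raise ValueError(
                f"query segment of {L} bp exceeds every workspace chromosome"
            )
    observed = float(total_bp_overlap(query, annotation))
    perm = np.empty(cfg.n_perm)
    for i in range(cfg.n_perm):
        total = 0
        for L in lengths:
            slots = np.maximum(chrom_sizes - L + 1, 0)
            probs = slots / slots.sum()
            ci = rng.choice(len(chrom_names), p=probs)
            start = int(rng.integers(0, slots[ci]))
            total += cov.overlap(chrom_names[ci], start, start + L)
        perm[i] = total
    return _summarize_permutations(observed, perm, cfg.n_perm, cfg.seed)


def selection_permutation(
    query: Sequence[GenomicInterval],
    label: Callable[[GenomicInterval], bool],
    cfg: EnrichmentConfig,
) -> EnrichmentResult:
    """Permutation test on the count of labelled members under redrawing
    ``|query|`` regions from the universe without replacement."""
    if cfg.mode != SELECTION:
        raise ValueError("config mode must be 'selection'")
    universe = list(cfg.universe)
    query = list(query)
    if len(universe) < len(query):
        raise ValueError("universe smaller than query")
    rng = np.random.default_rng(cfg.seed)
    flags = np.array([bool(label(iv)) for iv in universe])
    observed = float(sum(1 for iv in query if label(iv)))
    n_q = len(query)
    perm = np.empty(cfg.n_perm)
    for i in range(cfg.n_perm):
        draw = rng.choice(len(universe), size=n_q, replace=False)
        perm[i] = flags[draw].sum()
    return _summarize_permutations(observed, perm, cfg.n_perm, cfg.seed)


def overlap_predicate(annotation: IntervalSet) -> Callable[[GenomicInterval], bool]:
    """Predicate: does a region overlap the annotation by >= 1 bp."""
    return annotation.overlaps


@dataclass(frozen=True)
class ContingencyTable:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("empty table")


def chi_square_2x2(
    t: ContingencyTable, correction: bool = False
) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, df=1, two-sided; Yates continuity
    correction off by default.  Zero margins are errors."""
    margins = (t.a + t.b, t.c + t.d, t.a + t.c, t.b + t.d)
    if min(margins) == 0:
        raise ValueError("chi-square undefined for a zero margin")
    res = stats.chi2_contingency(
        [[t.a, t.b], [t.c, t.d]], correction=correction
    )
    return float(res.statistic), float(res.pvalue)


def hypergeom_enrichment(
    k_query_hits: int,
    n_query: int,
    k_universe_hits: int,
    n_universe: int,
    n_tests: int = 1,
) -> tuple[float, float, float]:
    """Fold enrichment and one-sided (upper-tail) hypergeometric p.

    Returns ``(fold, p, p_bonferroni)`` with the Bonferroni p capped at 1.
    """
    if not (0 <= k_query_hits <= n_query <= n_universe):
        raise ValueError("require k_query <= n_query <= n_universe")
    if k_universe_hits == 0:
        raise ValueError("fold enrichment undefined: no hits in the universe")
    if k_universe_hits > n_universe:
        raise ValueError("universe hits exceed universe size")
    fold = (k_query_hits / n_query) / (k_universe_hits / n_universe)
    p = float(
        stats.hypergeom.sf(k_query_hits - 1, n_universe, k_universe_hits, n_query)
    )
    return fold, p, min(1.0, p * n_tests)


def compare_region_properties(
    set_a: Sequence[ScoredPeak],
    set_b: Sequence[ScoredPeak],
    n_perm: int = 1000,
    seed: int = 0,
) -> dict[str, float]:
    """Compare peak width / GC / signal between two peak sets.

    Width and GC: label-permutation test on the absolute difference of
    means (p floor 1/n_perm).  Signal: two-sided Wilcoxon rank-sum
    (exact for small samples via scipy's Mann-Whitney U).
    GC is skipped when either set lacks GC values.
    """
    if not set_a or not set_b:
        raise ValueError("both peak sets must be non-empty")
    rng = np.random.default_rng(seed)

    def perm_p(x: np.ndarray, y: np.ndarray) -> float:
        obs = abs(x.mean() - y.mean())
        pooled = np.concatenate([x, y])
        n_x = len(x)
        b = 0
        for _ in range(n_perm):
            rng.shuffle(pooled)
            if abs(pooled[:n_x].mean() - pooled[n_x:].mean()) >= obs - 1e-12:
                b += 1
        return max(b, 1) / n_perm

    widths_a = np.array([p.interval.length for p in set_a], dtype=float)
    widths_b = np.array([p.interval.length for p in set_b], dtype=float)
    out = {"width_p": perm_p(widths_a, widths_b)}

    if all(p.gc_fraction is not None for p in set_a) and all(
        p.gc_fraction is not None for p in set_b
    ):
        gc_a = np.array([p.gc_fraction for p in set_a])
        gc_b = np.array([p.gc_fraction for p in set_b])
        out["gc_p"] = perm_p(gc_a, gc_b)

    sig_a = [p.signal for p in set_a]
    sig_b = [p.signal for p in set_b]
    out["signal_p"] = float(
        stats.mannwhitneyu(sig_a, sig_b, alternative="two-sided").pvalue
    )
    return out
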