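# Methods

## The discovery model

The pipeline operates entirely on genomic intervals; sequence content
enters only through the motif census.  All coordinates are 0-based
half-open (BED convention), and every reader normalizes to it.  Strand is
carried through I/O but ignored by overlap operations, since chromatin
accessibility is strandless.

An element is called an aCNE through a chain of one-base-pair overlap
rules: a zebrafish ATAC-seq peak must overlap a CNE's zebrafish
coordinates by ≥ 1 bp (making the peak *sequence-conserved*), and that
CNE's target-species coordinates must overlap a DNase hypersensitive site
by ≥ 1 bp.  With half-open intervals "≥ 1 bp" is equivalent to "any
overlap"; touching intervals never count.  The 1 bp thresholds, the 15 bp
direct-alignment rule and the 200 bp DHS merge gap are all exposed in
configuration with these defaults.

### Direct vs indirect alignment

A zCNE is *direct* when its zebrafish coordinates overlap **any**
well-aligning window by ≥ 15 bp (the max over windows decides; using the
best window rather than a designated one is a deliberate choice where the
original procedure is ambiguous).  garCNE records are indirect by
construction and only join the catalog when they overlap no zCNE at all —
read literally as zero-bp overlap, so a 1 bp overlap excludes.  zCNE
records carry a free-text provenance field; records without provenance
are rejected at parse time.  Catalog summaries enforce the exact
partition `total = direct + indirect`.

### Chain lifting (minMatch semantics)

`lift_interval` reproduces liftOver's `-minMatch` behaviour: the matched
fraction is the share of the interval's bases falling in aligned blocks
of the single best-scoring chain overlapping it (ties broken by longest
overlap, then chain id, for reproducibility); the mapped interval is the
bounding span of the per-base images, so deletions inside the interval
are tolerated while unaligned bases count against the fraction.
Negative-strand query chains produce coordinates flipped back to the
plus strand.  Two or more chains each satisfying `min_match` yield a
`MULTIPLE` rejection unless multiple mappings are explicitly allowed.
Defaults follow the use sites: 0.1 for CNE conversion, 0.95 for DHS
master-list conversion.

### DHS merging and multiplicity

DHS master lists can produce chains of sites conserved with one peak.
DHSs within 200 bp ("within" read inclusively: a distance of exactly
200 bp merges) **and linked to the same peak** are merged; DHSs linked to
different peaks are never merged, and both original and merged
coordinates are retained.  The per-peak multiplicity statistic is the
number of merged target-species DHS groups divided by the number of
zebrafish aCNE peaks.

## Statistics

* **Fisher feature enrichment** — regions are assigned a single feature
  class by priority promoter > exon > intron > intergenic.  The proximal
  promoter window is strand-aware `[−1000, +200)` bp around the TSS — a
  common convention chosen because the category is otherwise undefined;
  it is configurable and a pre-made promoter BED can replace it.
  Two-sided Fisher tests per feature are adjusted across tested features,
  Bonferroni by default (Holm available).
* **Permutation nulls** — *placement*: query segments keep their lengths
  and are re-placed uniformly (chromosome chosen proportionally to its
  number of valid start positions); placed segments may overlap each
  other, the simplest faithful GAT-like null.  The default statistic is
  nucleotide overlap; the segment-count statistic is the labelled-member
  count of the *selection* null, which redraws `|query|` regions from a
  finite universe without replacement.  Empirical p is always
  `max(b, 1)/n_perm` on the enrichment side (`b` = permutations ≥
  observed), so the smallest reportable p at 1000 permutations is 0.001;
  the depletion-side p is reported symmetrically in a separate field.
  Z-scores use the sample standard deviation (n − 1); a zero-variance
  null leaves Z undefined and flagged rather than infinite.  The PRNG is
  numpy's default (PCG64) with the seed echoed in every result.
* **Chi-square** — Pearson, df = 1, two-sided, no continuity correction
  by default (required to target the conservation-table computation);
  Yates available via a flag.  Zero margins are errors.
* **Hypergeometric enrichment** — fold = (query rate)/(universe rate),
  upper-tail p, Bonferroni capped at 1.
* **Peak-property comparison** — width and GC by label-permutation on the
  absolute difference of means (same p floor), signal by two-sided
  Wilcoxon rank-sum (exact for small samples via the Mann–Whitney U
  implementation).

## Chromatin states

Core-15 ChromHMM mnemonics are simplified to five categories.  The
default map groups 1–7 as Active, 10–12 as Bivalent, 13–14 as Polycomb,
15 as Quiescent and 8–9 as Other; the upstream study's exact grouping is
in supplementary material that is not redistributable, so the map is a
documented stand-in and fully configurable.  A region's per-epigenome
category is the one covering most of its bases, ties broken Active >
Bivalent > Polycomb > Quiescent > Other; a region outside segmented
territory is an error.  Across N epigenomes, *constitutively active*
means Active in strictly more than 80 % and *lineage-specific* means
Active in at least one epigenome and Polycomb-or-Quiescent in strictly
more than 70 % — both thresholds strict, as printed, and configurable.

## Motif census

Detection is exact consensus matching of `AGATAA` on either strand with
overlaps counted and `N` never matching; `max_mismatches` generalizes it.
Exact consensus is the reproducible floor where the original census
threshold is unstated, so absolute rates on real data may differ from the
published census.  The mutagenesis helper replaces every occurrence
(minus-strand occurrences with the reverse-complemented replacement) and
iterates until no site remains.

## Synthetic scenarios

The generator plants homologous elements at chain-consistent positions
rather than simulating sequence evolution — the analysis consumes
intervals, so realized-by-construction homology is the right level of
abstraction.  Defaults are the reference study conditions: 100 planted
CNEs, 30 % direct, 60 % accessible in both species, zero coordinate
jitter and label noise.  Quantities the analysis conditions leave open
were fixed once at desk scale: two chromosomes per species (400–500 kb),
element lengths 60–200 bp on 3 kb slots, 20 epigenomes (the original
comparison used 127; 20 keeps strict-threshold arithmetic meaningful
while the suite stays fast) with ~10 % constitutively-active and ~20 %
lineage-specific planted classes, 50 decoy peaks, 100 decoy DHSs per
species, and a GATA plant rate of 0.66 mirroring the published census
rate among conserved accessible elements.  Chain files split each
element's block with a 10 bp internal gap and include planted elements
that fall in chain gaps or outside chains entirely, so the minMatch,
LOW_MATCH and NOT_COVERED paths are all exercised.  Accidental GATA sites
inside element spans are scrubbed before planting so manifest motif
counts are exact.

What the generator does **not** emulate: read-level noise and peak-caller
artifacts, realistic DHS density (real master lists have millions of
sites, so absolute seqCon/aCNE rates on synthetic data are not comparable
to genome-scale rates), inter-element synteny structure, sequence-level
conservation, or epigenome-to-epigenome correlation.  Passing recovery
tests therefore demonstrate the correctness of the interval logic and
statistics, not performance on real data.

Noise knobs (uniform coordinate jitter, independent label flips) default
to zero; they are stand-ins for real-data messiness, and the exact-recovery
guarantees hold only at zero.

## Numerical and degenerate-input choices

Empirical p-values are never reported below `1/n_perm`.  Percentages are
rendered by rounding half away from zero at the stated decimals, and the
raw numerator/denominator always accompanies the rendered string in
reports.  Identical inputs yield byte-identical outputs everywhere: files
are written in sorted order, permutation streams are seeded explicitly,
and the per-epigenome stream is derived from the seed and a CRC of the
epigenome id (never Python's salted `hash`).  Degenerate cases are
explicit: empty query sets, zero contingency margins, universes smaller
than the query, regions outside segmentations, and chains whose blocks do
not sum to their stated spans are all errors naming the offending object.

## Known limitations

* The catalog/lift machinery is built for desk-scale inputs (up to ~10^5
  chains/intervals); whole-genome chain indexing is out of scope.
* The placement null is uniform, not isochore- or GC-aware.
* Differential-accessibility classes (the GFP+/GFP− style labels) are
  consumed as externally supplied label files; the differential test
  itself is out of scope.
* The chromatin-state category map is a documented default, not the
  original supplementary grouping.
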