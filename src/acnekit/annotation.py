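"""Genomic feature classification (promoter/exon/intron/intergenic) and
Fisher-exact feature enrichment.

A region is assigned a single feature class by priority: promoter beats
exon beats intron beats intergenic, so a region touching a TSS window is a
promoter even when it also covers exonic sequence.  The proximal promoter
window defaults to 1000 bp upstream through 200 bp downstream of the TSS,
strand-aware; the study never pins this down, so it is configurable and a
pre-made promoter BED can replace it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from scipy import stats

from .intervals import GenomicInterval, IntervalSet

FEATURES = ("promoter", "exon", "intron", "intergenic")

BONFERRONI = "bonferroni"
HOLM = "holm"


@dataclass(frozen=True)
class Transcript:
    """Minimal gene model: exon structure of one transcript.

    ``tss`` is the first transcribed base: ``start`` on the + strand and
    ``end - 1`` on the - strand.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.transcript_id}: strand must be + or -")
        prev_end = None
        for s, e in self.exons:
            if not (self.start <= s < e <= self.end):
                raise ValueError(f"{self.transcript_id}: exon outside span")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"{self.transcript_id}: exons overlap")
            prev_end = e

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 > e1:
                out.append((e1, s2))
        return tuple(out)

    def promoter_window(self, upstream: int = 1000, downstream: int = 200) -> GenomicInterval:
        """Strand-aware proximal promoter window around the TSS."""
        if self.strand == "+":
            start, end = self.tss - upstream, self.tss + downstream
        else:
            start, end = self.tss - downstream + 1, self.tss + upstream + 1
        return GenomicInterval(self.chrom, max(0, start), max(1, end))


def read_bed12(path: str | Path) -> list[Transcript]:
    """Read transcripts from BED12 (name column = ``gene:transcript`` or a
    plain id used for both)."""
    transcripts = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}:{lineno}: BED12 needs 12 columns")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            name, strand = f[3], f[5]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != int(f[9]) or len(offsets) != int(f[9]):
                raise ValueError(f"{path}:{lineno}: blockCount mismatch")
            exons = tuple(
                (start + o, start + o + s) for o, s in zip(offsets, sizes)
            )
            gene_id, _, tx_id = name.partition(":")
            transcripts.append(
                Transcript(
                    gene_id=gene_id,
                    transcript_id=tx_id or name,
                    chrom=chrom,
                    strand=strand,
                    start=start,
                    end=end,
                    exons=exons,
                )
            )
    return transcripts


class FeatureIndex:
    """Pre-built interval sets for fast repeated classification."""

    def __init__(
        self,
        transcripts: Sequence[Transcript],
        promoter_upstream: int = 1000,
        promoter_downstream: int = 200,
        promoters: IntervalSet | None = None,
    ) -> None:
        self.promoters = promoters or IntervalSet(
            t.promoter_window(promoter_upstream, promoter_downstream)
            for t in transcripts
        )
        self.exons = IntervalSet(
            GenomicInterval(t.chrom, s, e)
            for t in transcripts
            for s, e in t.exons
        )
        self.introns = IntervalSet(
            GenomicInterval(t.chrom, s, e)
            for t in transcripts
            for s, e in t.introns
        )


def classify_region(region: GenomicInterval, index: FeatureIndex) -> str:
    """Single feature class per region, priority promoter > exon > intron."""
    if index.promoters.overlaps(region):
        return "promoter"
    if index.exons.overlaps(region):
        return "exon"
    if index.introns.overlaps(region):
        return "intron"
    return "intergenic"


@dataclass(frozen=True)
class FeatureEnrichmentResult:
    feature: str
    a: int  # query in feature
    b: int  # query not in feature
    c: int  # background in feature
    d: int  # background not in feature
    odds_ratio: float
    p: float
    p_adj: float

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")
        if self.p_adj < self.p - 1e-12:
            raise ValueError("adjusted p cannot be below raw p")


def adjust_pvalues(pvalues: Sequence[float], method: str = BONFERRONI) -> list[float]:
    """Bonferroni (default) or Holm step-down adjustment."""
    m = len(pvalues)
    if method == BONFERRONI:
        return [min(1.0, p * m) for p in pvalues]
    if method == HOLM:
        order = sorted(range(m), key=lambda i: pvalues[i])
        adj = [0.0] * m
        running = 0.0
        for rank, i in enumerate(order):
            running = max(running, min(1.0, (m - rank) * pvalues[i]))
            adj[i] = running
        return adj
    raise ValueError(f"unknown adjustment method {method!r}")


def feature_enrichment(
    query: Iterable[GenomicInterval],
    background: Iterable[GenomicInterval],
    index: FeatureIndex,
    features: Sequence[str] = FEATURES,
    method: str = BONFERRONI,
) -> list[FeatureEnrichmentResult]:
    """Per-feature 2x2 Fisher's exact test (two-sided), query vs background.

    The table per feature is (query in / not in feature) against
    (background in / not in feature); p-values are adjusted across the
    tested features (Bonferroni by default).
    """
    query = list(query)
    background = list(background)
    if not query:
        raise ValueError("query set is empty")
    if not background:
        raise ValueError("background set is empty")
    q_classes = [classify_region(r, index) for r in query]
    b_classes = [classify_region(r, index) for r in background]
    results = []
    for feat in features:
        a = sum(1 for c in q_classes if c == feat)
        b = len(q_classes) - a
        c = sum(1 for cl in b_classes if cl == feat)
        d = len(b_classes) - c
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        results.append((feat, a, b, c, d, odds, p))
    adj = adjust_pvalues([r[6] for r in results], method)
    return [
        FeatureEnrichmentResult(feat, a, b, c, d, float(odds), float(p), pa)
        for (feat, a, b, c, d, odds, p), pa in zip(results, adj)
    ]


def write_enrichment_tsv(
    results: Sequence[FeatureEnrichmentResult], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("feature\ta\tb\tc\td\todds_ratio\tp\tp_adj\n")
        for r in results:
            fh.write(
                f"{r.feature}\t{r.a}\t{r.b}\t{r.c}\t{r.d}\t"
                f"{r.odds_ratio:.6g}\t{r.p:.6g}\t{r.p_adj:.6g}\n"
            )
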