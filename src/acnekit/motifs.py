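"""IUPAC consensus motif scanning on region sequences.

Built for the GATA-site census on accessible conserved elements: count, per
region, every position (overlaps allowed) where a window matches the
consensus on either strand.  The default motif is the GATA consensus
``AGATAA`` matched exactly; ``max_mismatches`` relaxes it.  ``N`` in the
sequence never matches any consensus letter.  A mutagenesis helper
replaces each motif occurrence with a neutral run (``AGATAA`` -> ``CCCCCC``)
to model loss-of-site constructs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

from .intervals import GenomicInterval

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

GATA_CONSENSUS = "AGATAA"


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifConsensus:
    name: str
    iupac: str = GATA_CONSENSUS
    max_mismatches: int = 0

    def __post_init__(self) -> None:
        if not self.iupac:
            raise ValueError("empty consensus")
        bad = set(self.iupac.upper()) - set(IUPAC)
        if bad:
            raise ValueError(f"invalid IUPAC letters {sorted(bad)}")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")


@dataclass(frozen=True)
class MotifHit:
    position: int  # 0-based start on the + strand
    strand: str


@dataclass(frozen=True)
class MotifSummary:
    n_regions: int
    n_ge1: int
    n_gt1: int
    frac_ge1: float
    frac_gt1: float

    def __post_init__(self) -> None:
        if not (self.n_gt1 <= self.n_ge1 <= self.n_regions):
            raise ValueError("require n_gt1 <= n_ge1 <= n_regions")


def _matches(window: str, consensus: str, budget: int) -> bool:
    mismatches = 0
    for base, code in zip(window, consensus):
        if base not in IUPAC[code] or base == "N":
            mismatches += 1
            if mismatches > budget:
                return False
    return True


def scan(
    seq: str, motif: MotifConsensus, both_strands: bool = True
) -> list[MotifHit]:
    """All motif occurrences in *seq*; overlapping hits all count.

    Minus-strand hits are found by matching the reverse complement of the
    consensus on the forward sequence; positions are + strand starts.
    """
    seq = seq.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"sequence contains invalid letters {sorted(bad)}")
    consensus = motif.iupac.upper()
    m = len(consensus)
    patterns = [(consensus, "+")]
    if both_strands:
        patterns.append((reverse_complement(consensus), "-"))
    hits = []
    for i in range(len(seq) - m + 1):
        window = seq[i : i + m]
        for pat, strand in patterns:
            if _matches(window, pat, motif.max_mismatches):
                hits.append(MotifHit(i, strand))
    return hits


def summarize(hit_counts: Iterable[int]) -> MotifSummary:
    """Census over regions from per-region hit counts."""
    counts = list(hit_counts)
    n = len(counts)
    n_ge1 = sum(1 for c in counts if c >= 1)
    n_gt1 = sum(1 for c in counts if c > 1)
    return MotifSummary(
        n_regions=n,
        n_ge1=n_ge1,
        n_gt1=n_gt1,
        frac_ge1=n_ge1 / n if n else 0.0,
        frac_gt1=n_gt1 / n if n else 0.0,
    )


def read_fasta(path: str | Path) -> dict[str, str]:
    """Multi-record FASTA (wrapped lines fine) into a name -> sequence dict."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def region_sequences(
    sequences: Mapping[str, str], regions: Iterable[GenomicInterval]
) -> dict[str, str]:
    """Extract each region's sequence; FASTA names must match chrom names."""
    out = {}
    for iv in regions:
        if iv.chrom not in sequences:
            raise KeyError(f"no sequence named {iv.chrom!r} in FASTA")
        seq = sequences[iv.chrom]
        if iv.end > len(seq):
            raise ValueError(f"region {iv} extends past sequence end")
        out[iv.id or str(iv)] = seq[iv.start : iv.end]
    return out


def census(
    sequences: Mapping[str, str],
    regions: Sequence[GenomicInterval],
    motif: MotifConsensus = MotifConsensus("GATA"),
    both_strands: bool = True,
) -> tuple[MotifSummary, dict[str, int]]:
    """Motif summary plus per-region hit counts for a region set."""
    seqs = region_sequences(sequences, regions)
    counts = {rid: len(scan(s, motif, both_strands)) for rid, s in seqs.items()}
    return summarize(counts.values()), counts


def mutate_motif(
    seq: str, motif: MotifConsensus, replacement: str = "CCCCCC"
) -> str:
    """Replace every motif occurrence (both strands) with *replacement*.

    Minus-strand occurrences receive the reverse complement of the
    replacement, so a follow-up scan of either strand finds nothing.
    Replacement length must equal motif length.  Applied iteratively until
    no occurrence remains (replacements could in principle recreate sites).
    """
    if len(replacement) != len(motif.iupac):
        raise ValueError("replacement must have the motif's length")
    out = seq.upper()
    for _ in range(len(seq)):
        hits = scan(out, motif, both_strands=True)
        if not hits:
            break
        h = hits[0]
        sub = replacement if h.strand == "+" else reverse_complement(replacement)
        out = out[: h.position] + sub + out[h.position + len(sub) :]
    return out
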