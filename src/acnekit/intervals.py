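"""Genomic-interval arithmetic and BED-like I/O.

All coordinates in this package are 0-based half-open (BED convention):
an interval ``[start, end)`` covers ``end - start`` bases and two intervals
that merely touch (``a.end == b.start``) do not overlap.  Strand is carried
through I/O but ignored by every overlap operation, since chromatin
accessibility is a strandless property.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from intervaltree import IntervalTree

VALID_STRANDS = ("+", "-", ".")


class BedParseError(ValueError):
    """Raised for malformed BED-like input; message carries the line number."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open interval on a named chromosome.

    Parameters
    ----------
    chrom : str
        Chromosome / sequence name (non-empty).
    start, end : int
        0-based half-open coordinates, ``0 <= start < end``.
    strand : str
        One of ``+``, ``-`` or ``.`` (unstranded).
    id : str, optional
        Record identifier (BED name column).
    score : float, optional
        BED score column (used for ATAC-seq signal on peaks).
    extra : tuple of str
        Additional BED columns, preserved opaquely through round-trips.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    id: str | None = None
    score: float | None = None
    extra: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def __len__(self) -> int:
        return self.length

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"

    def contains(self, other: "GenomicInterval") -> bool:
        """True if *other* lies fully inside this interval (same chrom)."""
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass(frozen=True)
class ScoredPeak:
    """An open-chromatin peak with accessibility signal and optional GC content."""

    interval: GenomicInterval
    signal: float
    gc_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.signal < 0:
            raise ValueError("signal must be non-negative")
        if self.gc_fraction is not None and not (0.0 <= self.gc_fraction <= 1.0):
            raise ValueError("gc_fraction must lie in [0, 1]")


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of bases shared by two intervals; 0 when chroms differ."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def _sort_key(iv: GenomicInterval) -> tuple[str, int, int, str]:
    return (iv.chrom, iv.start, iv.end, iv.id or "")


class IntervalSet:
    """An immutable, sorted collection of intervals with fast overlap queries.

    Backed by one interval tree per chromosome; ``overlapping`` runs in
    O(log n + k).  Duplicated coordinates with distinct ids are allowed.
    """

    def __init__(self, intervals: Iterable[GenomicInterval] = ()) -> None:
        self._intervals: list[GenomicInterval] = sorted(intervals, key=_sort_key)
        self._trees: dict[str, IntervalTree] = {}
        for idx, iv in enumerate(self._intervals):
            self._trees.setdefault(iv.chrom, IntervalTree()).addi(
                iv.start, iv.end, idx
            )

    def __len__(self) -> int:
        return len(self._intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self._intervals)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return self._intervals == other._intervals

    def __repr__(self) -> str:
        return f"IntervalSet(n={len(self)})"

    @property
    def chroms(self) -> list[str]:
        return sorted(self._trees)

    def on_chrom(self, chrom: str) -> list[GenomicInterval]:
        return [iv for iv in self._intervals if iv.chrom == chrom]

    def overlapping(self, query: GenomicInterval) -> list[GenomicInterval]:
        """All members overlapping *query* by >= 1 bp, in sorted order."""
        tree = self._trees.get(query.chrom)
        if tree is None:
            return []
        hits = sorted(node.data for node in tree.overlap(query.start, query.end))
        return [self._intervals[i] for i in hits]

    def overlaps(self, query: GenomicInterval) -> bool:
        tree = self._trees.get(query.chrom)
        return tree is not None and bool(tree.overlap(query.start, query.end))

    def total_overlap(self, query: GenomicInterval) -> int:
        """Bases of *query* covered by the union of overlapping members."""
        hits = self.overlapping(query)
        if not hits:
            return 0
        covered = 0
        cur_start = cur_end = None
        for iv in hits:
            s, e = max(iv.start, query.start), min(iv.end, query.end)
            if cur_end is None:
                cur_start, cur_end = s, e
            elif s <= cur_end:
                cur_end = max(cur_end, e)
            else:
                covered += cur_end - cur_start
                cur_start, cur_end = s, e
        covered += cur_end - cur_start
        return covered


def merge_groups(
    iset: IntervalSet | Sequence[GenomicInterval], gap: int
) -> list[list[GenomicInterval]]:
    """Transitively group intervals whose same-chrom distance is <= gap.

    Distance between consecutive sorted intervals is ``next.start - prev.end``;
    a distance exactly equal to *gap* merges ("within" read inclusively).
    """
    if gap < 0:
        raise ValueError("gap must be >= 0")
    intervals = sorted(iset, key=_sort_key)
    groups: list[list[GenomicInterval]] = []
    cur: list[GenomicInterval] = []
    cur_end = None
    cur_chrom = None
    for iv in intervals:
        if cur and iv.chrom == cur_chrom and iv.start - cur_end <= gap:
            cur.append(iv)
            cur_end = max(cur_end, iv.end)
        else:
            if cur:
                groups.append(cur)
            cur = [iv]
            cur_chrom = iv.chrom
            cur_end = iv.end
    if cur:
        groups.append(cur)
    return groups


def merge_within(iset: IntervalSet, gap: int) -> IntervalSet:
    """Merge intervals separated by <= *gap* bp on the same chromosome.

    The merged interval spans the group's min start to max end; its id joins
    the member ids with ``;`` (members lacking ids contribute nothing).
    """
    merged = []
    for group in merge_groups(iset, gap):
        ids = [iv.id for iv in group if iv.id]
        merged.append(
            GenomicInterval(
                chrom=group[0].chrom,
                start=min(iv.start for iv in group),
                end=max(iv.end for iv in group),
                id=";".join(ids) if ids else None,
            )
        )
    return IntervalSet(merged)


def fraction_of_length_covered(
    target: GenomicInterval, covering: IntervalSet
) -> float:
    """Fraction of *target*'s length covered by the union of *covering*.

    Overlapping covers are unioned, never double-counted.
    """
    return covering.total_overlap(target) / target.length


# ---------------------------------------------------------------------------
# BED I/O
# ---------------------------------------------------------------------------

def _parse_score(token: str, path: str, lineno: int) -> float | None:
    if token == ".":
        return None
    try:
        return float(token)
    except ValueError:
        raise BedParseError(f"{path}:{lineno}: bad score {token!r}") from None


def read_bed(path: str | Path, min_columns: int = 3) -> IntervalSet:
    """Read a BED3/BED6(+) file into an :class:`IntervalSet`.

    ``name``/``score``/``strand`` columns map to ``id``/``score``/``strand``
    (``.`` meaning absent); columns beyond the sixth are preserved in
    ``extra``.  Malformed lines raise :class:`BedParseError` naming the line.
    """
    path = Path(path)
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < max(3, min_columns):
                raise BedParseError(
                    f"{path}:{lineno}: expected >= {max(3, min_columns)} "
                    f"columns, got {len(fields)}"
                )
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise BedParseError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from None
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = (
                _parse_score(fields[4], str(path), lineno)
                if len(fields) > 4
                else None
            )
            strand = fields[5] if len(fields) > 5 else "."
            extra = tuple(fields[6:])
            try:
                intervals.append(
                    GenomicInterval(chrom, start, end, strand, name, score, extra)
                )
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from None
    return IntervalSet(intervals)


def _format_score(score: float | None) -> str:
    if score is None:
        return "."
    if float(score).is_integer():
        return str(int(score))
    return repr(float(score))


def bed_line(iv: GenomicInterval) -> str:
    fields = [iv.chrom, str(iv.start), str(iv.end)]
    if iv.id is not None or iv.score is not None or iv.strand != "." or iv.extra:
        fields += [iv.id or ".", _format_score(iv.score), iv.strand]
        fields += list(iv.extra)
    return "\t".join(fields)


def write_bed(iset: IntervalSet | Iterable[GenomicInterval], path: str | Path) -> None:
    """Write intervals as BED; uses 3 columns when no optional field is set."""
    with open(path, "w") as fh:
        for iv in sorted(iset, key=_sort_key):
            fh.write(bed_line(iv) + "\n")


def gc_fraction_of(seq: str) -> float:
    """GC fraction of a sequence, ignoring Ns; 0.0 for empty/all-N input."""
    acgt = sum(seq.upper().count(b) for b in "ACGT")
    if acgt == 0:
        return 0.0
    gc = seq.upper().count("G") + seq.upper().count("C")
    return gc / acgt
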