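"""UCSC chain-file parsing and interval lifting with minMatch semantics.

Implements the coordinate conversion used when moving CNEs or DHS master
lists between assemblies: an interval on the *target* (reference) assembly
of a chain is mapped to the *query* assembly, and the lift succeeds only
when at least ``min_match`` of its bases fall inside aligned blocks of the
single best-scoring covering chain — the behaviour of ``liftOver -minMatch``.

Chain format refresher: a header line

    chain score tName tSize tStrand tStart tEnd qName qSize qStrand qStart qEnd id

followed by alignment data lines ``size dt dq`` (``size`` aligned bases,
``dt``/``dq`` gap to the next block on target/query), the last line bearing
only ``size``.  Target strand is always ``+``; a ``-`` query strand means
query coordinates count from the reverse-complemented sequence and are
flipped back to ``+`` coordinates on output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .intervals import GenomicInterval, IntervalSet


class ChainParseError(ValueError):
    """Malformed chain file; message cites the chain id or line number."""


@dataclass(frozen=True)
class ChainBlock:
    size: int
    dt: int = 0
    dq: int = 0

    def __post_init__(self) -> None:
        if self.size <= 0:
            raise ValueError("block size must be > 0")
        if self.dt < 0 or self.dq < 0:
            raise ValueError("block gaps must be >= 0")


@dataclass(frozen=True)
class ChainAlignment:
    score: float
    t_name: str
    t_size: int
    t_strand: str
    t_start: int
    t_end: int
    q_name: str
    q_size: int
    q_strand: str
    q_start: int
    q_end: int
    chain_id: str
    blocks: tuple[ChainBlock, ...]

    def __post_init__(self) -> None:
        if self.t_strand != "+":
            raise ChainParseError(
                f"chain {self.chain_id}: target strand must be '+'"
            )
        if self.q_strand not in "+-":
            raise ChainParseError(f"chain {self.chain_id}: bad query strand")
        t_span = sum(b.size + b.dt for b in self.blocks)
        q_span = sum(b.size + b.dq for b in self.blocks)
        if t_span != self.t_end - self.t_start:
            raise ChainParseError(
                f"chain {self.chain_id}: blocks span {t_span} bp on target, "
                f"header states {self.t_end - self.t_start}"
            )
        if q_span != self.q_end - self.q_start:
            raise ChainParseError(
                f"chain {self.chain_id}: blocks span {q_span} bp on query, "
                f"header states {self.q_end - self.q_start}"
            )
        if self.blocks and (self.blocks[-1].dt or self.blocks[-1].dq):
            raise ChainParseError(
                f"chain {self.chain_id}: final block must have zero gaps"
            )

    def block_coords(self) -> list[tuple[int, int, int]]:
        """(t_block_start, q_block_start, size) per block, chain coordinates."""
        out = []
        t, q = self.t_start, self.q_start
        for b in self.blocks:
            out.append((t, q, b.size))
            t += b.size + b.dt
            q += b.size + b.dq
        return out


def parse_chain(path: str | Path) -> list[ChainAlignment]:
    """Parse a UCSC chain file; block-span invariants are enforced per chain."""
    chains: list[ChainAlignment] = []
    header: list[str] | None = None
    blocks: list[ChainBlock] = []

    def finish() -> None:
        nonlocal header, blocks
        if header is None:
            return
        (_, score, t_name, t_size, t_strand, t_start, t_end,
         q_name, q_size, q_strand, q_start, q_end, *rest) = header
        chain_id = rest[0] if rest else str(len(chains) + 1)
        chains.append(
            ChainAlignment(
                score=float(score),
                t_name=t_name, t_size=int(t_size), t_strand=t_strand,
                t_start=int(t_start), t_end=int(t_end),
                q_name=q_name, q_size=int(q_size), q_strand=q_strand,
                q_start=int(q_start), q_end=int(q_end),
                chain_id=chain_id,
                blocks=tuple(blocks),
            )
        )
        header, blocks = None, []

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("chain"):
                finish()
                header = line.split()
                if len(header) not in (12, 13):
                    raise ChainParseError(
                        f"{path}:{lineno}: chain header has {len(header)} fields"
                    )
                continue
            if header is None:
                raise ChainParseError(
                    f"{path}:{lineno}: alignment line outside a chain"
                )
            parts = line.split()
            try:
                if len(parts) == 1:
                    blocks.append(ChainBlock(int(parts[0])))
                elif len(parts) == 3:
                    blocks.append(
                        ChainBlock(int(parts[0]), int(parts[1]), int(parts[2]))
                    )
                else:
                    raise ValueError("expected 1 or 3 fields")
            except ValueError as exc:
                raise ChainParseError(f"{path}:{lineno}: {exc}") from None
    finish()
    return chains


def write_chain(chains: Iterable[ChainAlignment], path: str | Path) -> None:
    with open(path, "w") as fh:
        for c in chains:
            fh.write(
                "chain "
                + " ".join(
                    str(x)
                    for x in (
                        int(c.score) if float(c.score).is_integer() else c.score,
                        c.t_name, c.t_size, c.t_strand, c.t_start, c.t_end,
                        c.q_name, c.q_size, c.q_strand, c.q_start, c.q_end,
                        c.chain_id,
                    )
                )
                + "\n"
            )
            for i, b in enumerate(c.blocks):
                if i == len(c.blocks) - 1:
                    fh.write(f"{b.size}\n")
                else:
                    fh.write(f"{b.size}\t{b.dt}\t{b.dq}\n")
            fh.write("\n")


@dataclass(frozen=True)
class LiftoverConfig:
    """``min_match``: minimum fraction of bases that must remap (liftOver
    -minMatch); the study uses 0.1 for CNE conversion and 0.95 for DHS lists.
    ``allow_multiple``: accept an interval covered by several qualifying
    chains (liftOver default is to reject these)."""

    min_match: float = 0.1
    allow_multiple: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.min_match <= 1.0):
            raise ValueError("min_match must lie in (0, 1]")


MAPPED = "MAPPED"
NOT_COVERED = "NOT_COVERED"
LOW_MATCH = "LOW_MATCH"
MULTIPLE = "MULTIPLE"


@dataclass(frozen=True)
class LiftoverResult:
    status: str
    mapped: GenomicInterval | None = None
    matched_fraction: float = 0.0
    chain_id: str | None = None

    def __post_init__(self) -> None:
        if (self.status == MAPPED) != (self.mapped is not None):
            raise ValueError("mapped interval present iff status is MAPPED")


def _lift_on_chain(
    iv: GenomicInterval, chain: ChainAlignment
) -> tuple[int, int | None, int | None]:
    """(matched bp, min query image, max query image end) on chain q-coords."""
    matched = 0
    qmin: int | None = None
    qmax: int | None = None
    for t0, q0, size in chain.block_coords():
        lo, hi = max(iv.start, t0), min(iv.end, t0 + size)
        if hi > lo:
            matched += hi - lo
            img_lo = q0 + (lo - t0)
            img_hi = q0 + (hi - t0)
            qmin = img_lo if qmin is None else min(qmin, img_lo)
            qmax = img_hi if qmax is None else max(qmax, img_hi)
    return matched, qmin, qmax


def lift_interval(
    iv: GenomicInterval,
    chains: Sequence[ChainAlignment],
    cfg: LiftoverConfig = LiftoverConfig(),
) -> LiftoverResult:
    """Map *iv* (target-assembly coordinates) to the query assembly.

    The matched fraction is computed on the single best-scoring chain
    overlapping the interval (ties: longest overlap, then chain id); the
    mapped interval is the bounding span of the per-base images, so
    deletions inside the interval are tolerated, while bases falling in
    target gaps count against the fraction.  Negative-strand query chains
    yield coordinates flipped back to the + strand.
    """
    candidates = []
    for chain in chains:
        if chain.t_name != iv.chrom:
            continue
        if chain.t_end <= iv.start or chain.t_start >= iv.end:
            continue
        matched, qmin, qmax = _lift_on_chain(iv, chain)
        candidates.append((chain, matched, qmin, qmax))
    if not candidates:
        return LiftoverResult(NOT_COVERED)

    qualifying = [c for c in candidates if c[1] / iv.length >= cfg.min_match]
    if not qualifying:
        best = max(candidates, key=lambda c: (c[0].score, c[1], c[0].chain_id))
        return LiftoverResult(
            LOW_MATCH,
            matched_fraction=best[1] / iv.length,
            chain_id=best[0].chain_id,
        )
    if len(qualifying) > 1 and not cfg.allow_multiple:
        best = max(qualifying, key=lambda c: (c[0].score, c[1], c[0].chain_id))
        return LiftoverResult(
            MULTIPLE,
            matched_fraction=best[1] / iv.length,
            chain_id=best[0].chain_id,
        )
    chain, matched, qmin, qmax = max(
        qualifying, key=lambda c: (c[0].score, c[1], c[0].chain_id)
    )
    if chain.q_strand == "-":
        start, end = chain.q_size - qmax, chain.q_size - qmin
    else:
        start, end = qmin, qmax
    mapped = GenomicInterval(chain.q_name, start, end, id=iv.id, score=iv.score)
    return LiftoverResult(
        MAPPED,
        mapped=mapped,
        matched_fraction=matched / iv.length,
        chain_id=chain.chain_id,
    )


@dataclass(frozen=True)
class LiftRejection:
    id: str
    status: str
    matched_fraction: float


def lift_set(
    iset: IntervalSet,
    chains: Sequence[ChainAlignment],
    cfg: LiftoverConfig = LiftoverConfig(),
) -> tuple[IntervalSet, list[LiftRejection]]:
    """Lift every member; failures are logged, never raised."""
    mapped = []
    rejections = []
    for i, iv in enumerate(iset):
        res = lift_interval(iv, chains, cfg)
        if res.status == MAPPED:
            mapped.append(res.mapped)
        else:
            rejections.append(
                LiftRejection(iv.id or f"iv{i}", res.status, res.matched_fraction)
            )
    return IntervalSet(mapped), rejections


def write_rejections(rejections: Iterable[LiftRejection], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tstatus\tmatched_fraction\n")
        for r in rejections:
            fh.write(f"{r.id}\t{r.status}\t{r.matched_fraction:.6f}\n")
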