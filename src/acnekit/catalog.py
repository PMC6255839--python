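"""Integrated CNE catalogs with direct/indirect alignment classification.

Two CNE resources feed the catalog: zCNE-style records (zebrafish elements
conserved with human or mouse, carrying provenance for how the homology was
established) and garCNE-style records (zebrafish-human elements found by
transitive alignment through the spotted gar genome).  A zCNE overlapping a
zebrafish-target "well-aligning window" by at least 15 bp is *directly*
aligned; everything else — including every garCNE addition — is *indirect*.
garCNEs enter the catalog only when their zebrafish coordinates overlap no
zCNE record at all (zero base pairs).

For the zebrafish-mouse catalog the garCNE target coordinates, which are
given on the human assembly, are first lifted to mouse through a chain file
with min_match 0.1; lift failures are dropped and logged.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

from .intervals import GenomicInterval, IntervalSet, overlap_length
from .liftover import (
    ChainAlignment,
    LiftoverConfig,
    LiftRejection,
    MAPPED,
    lift_interval,
)

DIRECT = "direct"
INDIRECT = "indirect"
SOURCES = ("zcne", "garcne")
SPECIES = ("human", "mouse")

CNE_TSV_HEADER = "#acnekit-cne-v1"
_CNE_COLUMNS = (
    "id", "source", "species", "zf_chrom", "zf_start", "zf_end",
    "target_chrom", "target_start", "target_end", "provenance", "mode",
)


class CneParseError(ValueError):
    pass


@dataclass(frozen=True)
class CneRecord:
    """One conserved non-coding element.

    ``zf`` holds zebrafish coordinates, ``target`` the coordinates on the
    conserved species (``species``).  ``provenance`` records the alignment
    evidence (free text, e.g. ``alignment`` / ``transitive`` / ``ancestral``)
    and must be non-empty.  ``mode`` is assigned by classification; only
    zCNE records can be direct.
    """

    id: str
    source: str
    zf: GenomicInterval
    species: str
    target: GenomicInterval | None = None
    mode: str | None = None
    provenance: str = "alignment"

    def __post_init__(self) -> None:
        if self.source not in SOURCES:
            raise ValueError(f"unknown source {self.source!r}")
        if self.species not in SPECIES:
            raise ValueError(f"unknown species {self.species!r}")
        if not self.provenance:
            raise ValueError(f"CNE {self.id}: provenance must be non-empty")
        if self.mode not in (None, DIRECT, INDIRECT):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == DIRECT and self.source != "zcne":
            raise ValueError(
                f"CNE {self.id}: only zCNE records may be directly aligned"
            )


@dataclass(frozen=True)
class CatalogSummary:
    species: str
    n_total: int
    n_direct: int
    n_indirect: int

    def __post_init__(self) -> None:
        if self.n_total != self.n_direct + self.n_indirect:
            raise ValueError(
                f"catalog counts do not partition: {self.n_direct} direct + "
                f"{self.n_indirect} indirect != {self.n_total} total"
            )


def classify_mode(
    rec: CneRecord, windows: IntervalSet, min_overlap: int = 15
) -> str:
    """Direct iff the zebrafish coordinates overlap any well-aligning window
    by at least *min_overlap* bp (default 15); otherwise indirect."""
    if rec.source != "zcne":
        return INDIRECT
    best = max(
        (overlap_length(rec.zf, w) for w in windows.overlapping(rec.zf)),
        default=0,
    )
    return DIRECT if best >= min_overlap else INDIRECT


def integrate_garcne(
    zcnes: Sequence[CneRecord],
    garcnes: Sequence[CneRecord],
    windows: IntervalSet,
    min_overlap: int = 15,
) -> list[CneRecord]:
    """Union of classified zCNEs and the garCNEs disjoint from all of them.

    A garCNE whose zebrafish coordinates overlap any zCNE by >= 1 bp is
    excluded; the survivors are labelled indirect.
    """
    classified = [
        replace(rec, mode=classify_mode(rec, windows, min_overlap))
        for rec in zcnes
    ]
    zcne_set = IntervalSet(
        replace(rec.zf, id=rec.id) for rec in zcnes
    )
    out = list(classified)
    for rec in garcnes:
        if rec.source != "garcne":
            raise ValueError(f"record {rec.id} is not a garCNE")
        if not zcne_set.overlaps(rec.zf):
            out.append(replace(rec, mode=INDIRECT))
    return out


def build_mouse_catalog(
    zcne_mouse: Sequence[CneRecord],
    garcne_human: Sequence[CneRecord],
    chains_hg_to_mm: Sequence[ChainAlignment],
    windows_mouse: IntervalSet,
    lift_cfg: LiftoverConfig = LiftoverConfig(min_match=0.1),
    min_overlap: int = 15,
) -> tuple[list[CneRecord], list[LiftRejection]]:
    """Zebrafish-mouse catalog: garCNE human targets lifted to mouse, then
    integrated against the zCNE mouse records.

    Returns the catalog and the lift rejection log (garCNEs whose human
    coordinates failed to convert are dropped, not errors).
    """
    if not chains_hg_to_mm:
        raise ValueError("no human-to-mouse chains provided")
    lifted: list[CneRecord] = []
    rejections: list[LiftRejection] = []
    for rec in garcne_human:
        if rec.target is None:
            raise ValueError(f"garCNE {rec.id} lacks target coordinates")
        res = lift_interval(rec.target, chains_hg_to_mm, lift_cfg)
        if res.status == MAPPED:
            lifted.append(
                replace(rec, species="mouse", target=res.mapped, mode=None)
            )
        else:
            rejections.append(
                LiftRejection(rec.id, res.status, res.matched_fraction)
            )
    catalog = integrate_garcne(zcne_mouse, lifted, windows_mouse, min_overlap)
    return catalog, rejections


def summarize_catalog(catalog: Sequence[CneRecord], species: str | None = None) -> CatalogSummary:
    """Count direct/indirect records; total always equals their sum."""
    if species is None:
        species_set = {rec.species for rec in catalog}
        species = species_set.pop() if len(species_set) == 1 else "mixed"
    n_direct = sum(1 for rec in catalog if rec.mode == DIRECT)
    n_indirect = sum(1 for rec in catalog if rec.mode == INDIRECT)
    if n_direct + n_indirect != len(catalog):
        raise ValueError("catalog contains unclassified records")
    return CatalogSummary(species, len(catalog), n_direct, n_indirect)


# ---------------------------------------------------------------------------
# TSV schema
# ---------------------------------------------------------------------------

def write_cne_tsv(records: Iterable[CneRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(CNE_TSV_HEADER + "\n")
        fh.write("\t".join(_CNE_COLUMNS) + "\n")
        for rec in records:
            t = rec.target
            fh.write(
                "\t".join(
                    [
                        rec.id, rec.source, rec.species,
                        rec.zf.chrom, str(rec.zf.start), str(rec.zf.end),
                        t.chrom if t else ".",
                        str(t.start) if t else ".",
                        str(t.end) if t else ".",
                        rec.provenance,
                        rec.mode or ".",
                    ]
                )
                + "\n"
            )


def read_cne_tsv(path: str | Path) -> list[CneRecord]:
    """Read the normalized CNE TSV schema (versioned header line)."""
    path = Path(path)
    records = []
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
        if first != CNE_TSV_HEADER:
            raise CneParseError(
                f"{path}:1: expected header {CNE_TSV_HEADER!r}, got {first!r}"
            )
        cols = fh.readline().rstrip("\n").split("\t")
        if tuple(cols) != _CNE_COLUMNS:
            raise CneParseError(f"{path}:2: unexpected column names")
        for lineno, line in enumerate(fh, start=3):
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            if len(f) != len(_CNE_COLUMNS):
                raise CneParseError(
                    f"{path}:{lineno}: expected {len(_CNE_COLUMNS)} columns"
                )
            row = dict(zip(_CNE_COLUMNS, f))
            if row["provenance"] in ("", "."):
                raise CneParseError(
                    f"{path}:{lineno}: CNE {row['id']} has no provenance"
                )
            target = None
            if row["target_chrom"] != ".":
                target = GenomicInterval(
                    row["target_chrom"],
                    int(row["target_start"]),
                    int(row["target_end"]),
                    id=row["id"],
                )
            try:
                records.append(
                    CneRecord(
                        id=row["id"],
                        source=row["source"],
                        species=row["species"],
                        zf=GenomicInterval(
                            row["zf_chrom"], int(row["zf_start"]),
                            int(row["zf_end"]), id=row["id"],
                        ),
                        target=target,
                        mode=None if row["mode"] == "." else row["mode"],
                        provenance=row["provenance"],
                    )
                )
            except ValueError as exc:
                raise CneParseError(f"{path}:{lineno}: {exc}") from None
    return records
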