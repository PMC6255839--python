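"""Calling accessible CNEs (aCNEs) and the associated accounting.

An ATAC-seq peak is *sequence-conserved* (seqCon) when it overlaps a CNE's
zebrafish coordinates by at least one base pair.  It becomes an *aCNE* when
one of its linking CNEs also overlaps, on the target species, a DNase I
hypersensitive site by at least one base pair — open chromatin conserved
through sequence homology.  DHS master lists can yield chains of sites
conserved with the same peak, so DHSs within 200 bp that link to the same
peak are merged before per-peak multiplicity statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .catalog import CneRecord
from .intervals import (
    GenomicInterval,
    IntervalSet,
    fraction_of_length_covered,
    merge_groups,
)


@dataclass(frozen=True)
class SeqConLink:
    """A peak with the CNEs it overlaps on zebrafish coordinates (>= 1 bp)."""

    peak_id: str
    cne_ids: tuple[str, ...]
    species: str

    def __post_init__(self) -> None:
        if not self.cne_ids:
            raise ValueError(f"seqCon link for {self.peak_id} cites no CNEs")


@dataclass(frozen=True)
class AcneLink:
    """A peak-CNE pair whose CNE target coordinates overlap >= 1 DHS."""

    peak_id: str
    cne_id: str
    dhs_ids: tuple[str, ...]
    species: str

    def __post_init__(self) -> None:
        if not self.dhs_ids:
            raise ValueError(
                f"aCNE link {self.peak_id}/{self.cne_id} cites no DHSs"
            )


@dataclass(frozen=True)
class LinkStats:
    n_peaks_total: int
    n_seqcon: int
    n_acne: int
    pct_seqcon: float
    pct_acne_of_seqcon: float
    mean_target_acnes_per_zf_acne: float
    frac_cnes_fully_contained: float
    mean_peak_fraction_covered_by_cne: float

    def __post_init__(self) -> None:
        if not (self.n_acne <= self.n_seqcon <= self.n_peaks_total):
            raise ValueError("require n_acne <= n_seqcon <= n_peaks_total")


def find_seqcon(
    peaks: IntervalSet, catalog: Sequence[CneRecord], min_overlap_bp: int = 1
) -> list[SeqConLink]:
    """One link per peak overlapping >= 1 CNE (zebrafish coordinates).

    Every peak must carry an id.  ``min_overlap_bp`` defaults to the study's
    one-base-pair rule; with half-open intervals any overlap is >= 1 bp, so
    larger values tighten the rule.
    """
    by_species: dict[str, str] = {}
    cne_set = IntervalSet(
        GenomicInterval(
            rec.zf.chrom, rec.zf.start, rec.zf.end, id=rec.id
        )
        for rec in catalog
    )
    for rec in catalog:
        by_species[rec.id] = rec.species
    links = []
    for peak in peaks:
        if peak.id is None:
            raise ValueError(f"peak {peak} lacks an id")
        hits = [
            c for c in cne_set.overlapping(peak)
            if min(c.end, peak.end) - max(c.start, peak.start) >= min_overlap_bp
        ]
        if not hits:
            continue
        species = {by_species[c.id] for c in hits}
        links.append(
            SeqConLink(
                peak_id=peak.id,
                cne_ids=tuple(sorted(c.id for c in hits)),
                species=species.pop() if len(species) == 1 else "mixed",
            )
        )
    return links


def call_acnes(
    seqcon: Sequence[SeqConLink],
    catalog: Sequence[CneRecord],
    dhs: IntervalSet,
    species: str,
    min_overlap_bp: int = 1,
) -> list[AcneLink]:
    """aCNE links: for each seqCon (peak, CNE) pair, the DHSs the CNE's
    target-species coordinates overlap by >= ``min_overlap_bp``.

    Raises if a cited CNE lacks target coordinates, naming the CNE.
    """
    by_id: dict[str, CneRecord] = {rec.id: rec for rec in catalog}
    links = []
    for sc in seqcon:
        for cne_id in sc.cne_ids:
            rec = by_id[cne_id]
            if rec.species != species:
                continue
            if rec.target is None:
                raise ValueError(
                    f"CNE {cne_id} has no target-species coordinates"
                )
            hits = [
                d for d in dhs.overlapping(rec.target)
                if min(d.end, rec.target.end) - max(d.start, rec.target.start)
                >= min_overlap_bp
            ]
            if hits:
                links.append(
                    AcneLink(
                        peak_id=sc.peak_id,
                        cne_id=cne_id,
                        dhs_ids=tuple(
                            sorted(d.id or str(d) for d in hits)
                        ),
                        species=species,
                    )
                )
    return links


def merge_linked_dhs(
    acne_links: Sequence[AcneLink],
    dhs: IntervalSet,
    gap: int = 200,
) -> tuple[dict[str, list[GenomicInterval]], dict[str, tuple[str, ...]]]:
    """Merge DHSs within *gap* bp that are conserved with the same peak.

    Returns ``(merged_by_peak, members)``: per peak the merged DHS intervals
    (ids ``<peak>|m<i>``), and per merged id the original DHS ids.  DHSs
    linked to different peaks are grouped independently and never merged
    across peaks; original coordinates stay available through *dhs*.
    """
    dhs_by_id = {d.id or str(d): d for d in dhs}
    per_peak: dict[str, set[str]] = {}
    for link in acne_links:
        per_peak.setdefault(link.peak_id, set()).update(link.dhs_ids)
    merged_by_peak: dict[str, list[GenomicInterval]] = {}
    members: dict[str, tuple[str, ...]] = {}
    for peak_id in sorted(per_peak):
        group_src = [dhs_by_id[i] for i in sorted(per_peak[peak_id])]
        merged = []
        for gi, group in enumerate(merge_groups(group_src, gap)):
            mid = f"{peak_id}|m{gi}"
            merged.append(
                GenomicInterval(
                    group[0].chrom,
                    min(iv.start for iv in group),
                    max(iv.end for iv in group),
                    id=mid,
                )
            )
            members[mid] = tuple(iv.id or str(iv) for iv in group)
        merged_by_peak[peak_id] = merged
    return merged_by_peak, members


def compute_link_stats(
    peaks: IntervalSet,
    seqcon: Sequence[SeqConLink],
    acnes: Sequence[AcneLink],
    merged_by_peak: Mapping[str, Sequence[GenomicInterval]],
    catalog: Sequence[CneRecord],
) -> LinkStats:
    """Accounting across one species' run.

    Percentages are raw (not rounded; rendering is the report's job).  The
    per-peak multiplicity is the number of merged target-species DHS groups
    divided by the number of zebrafish aCNE peaks.  Containment counts a
    linked CNE as fully contained when some linking peak spans it entirely.
    """
    peaks_by_id = {p.id: p for p in peaks}
    cne_by_id = {rec.id: rec for rec in catalog}
    n_peaks = len(peaks)
    seqcon_peaks = {sc.peak_id for sc in seqcon}
    acne_peaks = {a.peak_id for a in acnes}
    n_seqcon, n_acne = len(seqcon_peaks), len(acne_peaks)

    cne_contained: dict[str, bool] = {}
    cover_fracs = []
    for sc in seqcon:
        peak = peaks_by_id[sc.peak_id]
        linked = [cne_by_id[c].zf for c in sc.cne_ids]
        for cne_iv, cid in zip(linked, sc.cne_ids):
            contained = peak.contains(cne_iv)
            cne_contained[cid] = cne_contained.get(cid, False) or contained
        cover_fracs.append(
            fraction_of_length_covered(peak, IntervalSet(linked))
        )

    n_groups = sum(len(merged_by_peak.get(p, ())) for p in acne_peaks)
    return LinkStats(
        n_peaks_total=n_peaks,
        n_seqcon=n_seqcon,
        n_acne=n_acne,
        pct_seqcon=100.0 * n_seqcon / n_peaks if n_peaks else 0.0,
        pct_acne_of_seqcon=100.0 * n_acne / n_seqcon if n_seqcon else 0.0,
        mean_target_acnes_per_zf_acne=n_groups / n_acne if n_acne else 0.0,
        frac_cnes_fully_contained=(
            sum(cne_contained.values()) / len(cne_contained)
            if cne_contained
            else 0.0
        ),
        mean_peak_fraction_covered_by_cne=(
            sum(cover_fracs) / len(cover_fracs) if cover_fracs else 0.0
        ),
    )


def coding_exclusion_fraction(
    peaks: IntervalSet | Iterable[GenomicInterval],
    coding_exons: IntervalSet,
) -> float:
    """Fraction of peaks completely excluded from coding exons (zero bp
    overlap with every exon); 1.0 for an empty exon set."""
    peaks = list(peaks)
    if not peaks:
        return 0.0
    clean = sum(1 for p in peaks if not coding_exons.overlaps(p))
    return clean / len(peaks)


def write_links_tsv(
    seqcon: Sequence[SeqConLink],
    acnes: Sequence[AcneLink],
    path: str | Path,
) -> None:
    """Serialize link tables: one row per peak-CNE pair with its DHS ids."""
    acne_by_pair = {(a.peak_id, a.cne_id): a for a in acnes}
    with open(path, "w") as fh:
        fh.write("peak_id\tcne_id\tspecies\tis_acne\tdhs_ids\n")
        for sc in seqcon:
            for cid in sc.cne_ids:
                a = acne_by_pair.get((sc.peak_id, cid))
                fh.write(
                    f"{sc.peak_id}\t{cid}\t{sc.species}\t"
                    f"{int(a is not None)}\t"
                    f"{','.join(a.dhs_ids) if a else '.'}\n"
                )
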