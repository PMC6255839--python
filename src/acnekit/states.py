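"""Chromatin-state simplification and activity classification across
epigenomes.

Core-15 chromatin-state segmentations (ChromHMM mnemonics) are collapsed
into five categories — Active, Bivalent, Polycomb, Quiescent, Other — and
each region receives, per epigenome, the category covering most of its
bases.  Across N epigenomes a region is *constitutively active* when it is
Active in more than 80% of them, and *lineage-specific* when it is Active
in at least one epigenome yet Polycomb-repressed or Quiescent in more than
70% (both strict inequalities).  Per-epigenome enrichment of each category
in a region set relative to a universe of open regions uses the selection
permutation null.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .enrichment import EnrichmentConfig, EnrichmentResult, _summarize_permutations
from .intervals import GenomicInterval, IntervalSet, overlap_length

CATEGORIES = ("Active", "Bivalent", "Polycomb", "Quiescent", "Other")

# Category grouping of the core-15 mnemonics.  Configurable: the study's own
# supplementary grouping is not redistributable, so this default follows the
# category names in the analysis and standard core-15 semantics.
DEFAULT_CATEGORY_MAP: dict[str, str] = {
    "1_TssA": "Active",
    "2_TssAFlnk": "Active",
    "3_TxFlnk": "Active",
    "4_Tx": "Active",
    "5_TxWk": "Active",
    "6_EnhG": "Active",
    "7_Enh": "Active",
    "8_ZNF/Rpts": "Other",
    "9_Het": "Other",
    "10_TssBiv": "Bivalent",
    "11_BivFlnk": "Bivalent",
    "12_EnhBiv": "Bivalent",
    "13_ReprPC": "Polycomb",
    "14_ReprPCWk": "Polycomb",
    "15_Quies": "Quiescent",
}

CONSTITUTIVE = "constitutive_active"
LINEAGE_SPECIFIC = "lineage_specific"
OTHER = "other"


def validate_category_map(cmap: Mapping[str, str]) -> None:
    bad = {v for v in cmap.values()} - set(CATEGORIES)
    if bad:
        raise ValueError(f"unknown categories in map: {sorted(bad)}")


@dataclass
class StateSegmentation:
    """One epigenome's segmentation: state-labelled intervals tiling each
    chromosome without overlap (interval ``id`` carries the mnemonic)."""

    epigenome_id: str
    segments: IntervalSet

    def __post_init__(self) -> None:
        for chrom in self.segments.chroms:
            prev_end = None
            for iv in self.segments.on_chrom(chrom):
                if iv.id is None:
                    raise ValueError(
                        f"{self.epigenome_id}: segment {iv} lacks a state"
                    )
                if prev_end is not None and iv.start < prev_end:
                    raise ValueError(
                        f"{self.epigenome_id}: overlapping segments on {chrom}"
                    )
                prev_end = iv.end


def read_segmentation_bed(path: str | Path, epigenome_id: str) -> StateSegmentation:
    """4-column BED (chrom, start, end, state mnemonic)."""
    from .intervals import read_bed

    return StateSegmentation(epigenome_id, read_bed(path, min_columns=4))


def assign_region_state(
    region: GenomicInterval,
    seg: StateSegmentation,
    cmap: Mapping[str, str] = DEFAULT_CATEGORY_MAP,
) -> str:
    """Majority-coverage category for *region* in one epigenome.

    Ties break by the fixed priority Active > Bivalent > Polycomb >
    Quiescent > Other.  A region not fully inside segmented territory is an
    error naming the region.
    """
    hits = seg.segments.overlapping(region)
    bp: dict[str, int] = {}
    covered = 0
    for iv in hits:
        ov = overlap_length(region, iv)
        covered += ov
        cat = cmap.get(iv.id)
        if cat is None:
            raise ValueError(
                f"{seg.epigenome_id}: unmapped state mnemonic {iv.id!r}"
            )
        bp[cat] = bp.get(cat, 0) + ov
    if covered < region.length:
        raise ValueError(
            f"region {region.id or region} extends outside the segmentation "
            f"of {seg.epigenome_id}"
        )
    return max(CATEGORIES, key=lambda c: (bp.get(c, 0), -CATEGORIES.index(c)))


@dataclass(frozen=True)
class ActivityProfile:
    region_id: str
    category_counts: Mapping[str, int]
    n_epigenomes: int
    classification: str

    def __post_init__(self) -> None:
        if sum(self.category_counts.values()) != self.n_epigenomes:
            raise ValueError(
                f"{self.region_id}: category counts do not sum to the number "
                "of epigenomes"
            )


def classify_activity(
    category_counts: Mapping[str, int],
    n_epigenomes: int,
    active_frac: float = 0.80,
    repressed_frac: float = 0.70,
) -> str:
    """Strict-threshold activity classification across epigenomes.

    constitutive_active iff Active count > active_frac * N; else
    lineage_specific iff Active >= 1 and Polycomb + Quiescent count >
    repressed_frac * N; else other.
    """
    if n_epigenomes < 1:
        raise ValueError("need at least one epigenome")
    n_active = category_counts.get("Active", 0)
    n_repressed = category_counts.get("Polycomb", 0) + category_counts.get(
        "Quiescent", 0
    )
    if n_active > active_frac * n_epigenomes:
        return CONSTITUTIVE
    if n_active >= 1 and n_repressed > repressed_frac * n_epigenomes:
        return LINEAGE_SPECIFIC
    return OTHER


def build_activity_profiles(
    regions: Sequence[GenomicInterval],
    segmentations: Sequence[StateSegmentation],
    cmap: Mapping[str, str] = DEFAULT_CATEGORY_MAP,
    active_frac: float = 0.80,
    repressed_frac: float = 0.70,
) -> list[ActivityProfile]:
    validate_category_map(cmap)
    profiles = []
    n = len(segmentations)
    for region in regions:
        counts = {c: 0 for c in CATEGORIES}
        for seg in segmentations:
            counts[assign_region_state(region, seg, cmap)] += 1
        profiles.append(
            ActivityProfile(
                region_id=region.id or str(region),
                category_counts=counts,
                n_epigenomes=n,
                classification=classify_activity(
                    counts, n, active_frac, repressed_frac
                ),
            )
        )
    return profiles


def state_enrichment_by_epigenome(
    regions: Sequence[GenomicInterval],
    universe: IntervalSet,
    segmentations: Sequence[StateSegmentation],
    cmap: Mapping[str, str] = DEFAULT_CATEGORY_MAP,
    cfg: EnrichmentConfig | None = None,
) -> dict[tuple[str, str], EnrichmentResult]:
    """Per (epigenome, category): enrichment of the category fraction in
    *regions* against random same-size draws from *universe*.

    One permutation stream per epigenome feeds all five categories, so the
    per-category nulls are computed on shared draws.
    """
    validate_category_map(cmap)
    if cfg is None:
        cfg = EnrichmentConfig(universe=universe)
    universe_list = list(universe)
    n_q = len(regions)
    if n_q == 0:
        raise ValueError("empty region set")
    if len(universe_list) < n_q:
        raise ValueError("universe smaller than the region set")
    out: dict[tuple[str, str], EnrichmentResult] = {}
    for seg in segmentations:
        cat_of = np.array(
            [CATEGORIES.index(assign_region_state(iv, seg, cmap)) for iv in universe_list]
        )
        obs_counts = np.zeros(len(CATEGORIES))
        for iv in regions:
            obs_counts[CATEGORIES.index(assign_region_state(iv, seg, cmap))] += 1
        # crc32, not hash(): string hashing is salted per interpreter run
        rng = np.random.default_rng(
            [cfg.seed, zlib.crc32(seg.epigenome_id.encode()) % (2**31)]
        )
        perm = np.zeros((cfg.n_perm, len(CATEGORIES)))
        for i in range(cfg.n_perm):
            draw = rng.choice(len(universe_list), size=n_q, replace=False)
            for ci in range(len(CATEGORIES)):
                perm[i, ci] = np.sum(cat_of[draw] == ci)
        for ci, cat in enumerate(CATEGORIES):
            out[(seg.epigenome_id, cat)] = _summarize_permutations(
                float(obs_counts[ci]) / n_q, perm[:, ci] / n_q, cfg.n_perm, cfg.seed
            )
    return out


def write_profiles_tsv(profiles: Sequence[ActivityProfile], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "region_id\t" + "\t".join(CATEGORIES) + "\tn_epigenomes\tclassification\n"
        )
        for p in profiles:
            fh.write(
                p.region_id
                + "\t"
                + "\t".join(str(p.category_counts.get(c, 0)) for c in CATEGORIES)
                + f"\t{p.n_epigenomes}\t{p.classification}\n"
            )
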