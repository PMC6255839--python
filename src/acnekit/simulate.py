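"""Synthetic paired-genome scenarios with a ground-truth manifest.

The generator plants homologous non-coding elements into toy zebrafish,
human and mouse genomes and emits every file the discovery pipeline
consumes — ATAC-seq peaks with signal, zCNE/garCNE tables, well-aligning
windows, a human-to-mouse chain realizing the planted homology (with block
gaps so minMatch cases exist), DNase master lists, per-epigenome
chromatin-state segmentations, gene models, a zebrafish FASTA with planted
GATA consensus sites, peak-class labels — together with a JSON manifest
recording, per element, its coordinates in all species, alignment mode,
accessibility, activity class and motif count.

Homology is realized by construction: element coordinates are planted at
chain-consistent positions, not simulated from sequence evolution, because
the discovery method operates on intervals; sequence content matters only
to the motif census.  With the noise knobs at their default of zero, the
full pipeline recovers the planted truth exactly, which is what the
end-to-end tests assert.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .catalog import CneRecord, write_cne_tsv
from .intervals import GenomicInterval, IntervalSet, bed_line, write_bed
from .liftover import ChainAlignment, ChainBlock, parse_chain, write_chain
from .motifs import GATA_CONSENSUS, MotifConsensus, reverse_complement, scan
from .states import CATEGORIES, DEFAULT_CATEGORY_MAP, classify_activity

_ACTIVE_STATES = ("1_TssA", "7_Enh", "4_Tx")
_POLYCOMB_STATES = ("13_ReprPC", "14_ReprPCWk")
_BIVALENT_STATES = ("10_TssBiv", "12_EnhBiv")
_OTHER_STATES = ("9_Het", "8_ZNF/Rpts")
_QUIES = "15_Quies"

_SLOT = 3000          # per-element slot width, bp
_MARGIN = 2000        # chromosome head/tail kept free
_INTERNAL_GAP = 10    # chain gap splitting each element block


class InfeasibleScenario(ValueError):
    pass


@dataclass
class ScenarioConfig:
    """Knobs of the synthetic study; defaults are the noise-free reference
    scenario (100 planted CNEs, 30% direct, 60% accessible in both
    species), with 20 epigenomes at the activity mixture the chromatin
    analyses assume (~10% constitutively active, ~20% lineage-specific)."""

    seed: int = 0
    zf_chroms: dict[str, int] = field(
        default_factory=lambda: {"zchr1": 400_000, "zchr2": 400_000}
    )
    human_chroms: dict[str, int] = field(
        default_factory=lambda: {"hchr1": 500_000, "hchr2": 500_000}
    )
    mouse_chroms: dict[str, int] = field(
        default_factory=lambda: {"mchr1": 500_000, "mchr2": 500_000}
    )
    n_planted_cnes: int = 100
    frac_direct: float = 0.3
    frac_accessible_both: float = 0.6
    frac_garcne_only: float = 0.2
    n_overlapping_garcne: int = 5
    n_lift_fail_garcne: int = 2
    n_epigenomes: int = 20
    frac_constitutive: float = 0.1
    frac_lineage: float = 0.2
    n_decoy_peaks: int = 50
    n_decoy_dhs: int = 100
    motif_plant_rate: float = 0.66
    jitter_bp: int = 0
    label_flip_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in (
            "frac_direct", "frac_accessible_both", "frac_garcne_only",
            "frac_constitutive", "frac_lineage", "motif_plant_rate",
            "label_flip_rate",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        for chroms in (self.zf_chroms, self.human_chroms, self.mouse_chroms):
            if any(size <= 0 for size in chroms.values()):
                raise ValueError("chromosome lengths must be positive")
        if self.jitter_bp < 0:
            raise ValueError("jitter_bp must be >= 0")
        if self.n_epigenomes < 4:
            # below 4 the strict >70% repression rule leaves no room for the
            # lineage-specific class's obligatory active epigenome
            raise ValueError("n_epigenomes must be >= 4")


@dataclass(frozen=True)
class PlantedElement:
    id: str
    zf: tuple[str, int, int]
    human: tuple[str, int, int]
    mouse: tuple[str, int, int]
    source: str                  # zcne | garcne
    mode: str                    # direct | indirect
    accessible_both: bool
    has_peak: bool
    peak_id: str | None
    label: str | None            # gfp_pos | gfp_neg | shared
    activity_class: str
    category_counts: dict[str, int]
    motif_count: int
    human_dhs_ids: tuple[str, ...]
    mouse_dhs_ids: tuple[str, ...]


@dataclass
class ValidationReport:
    ok: bool
    issues: list[str]


def _slots(chroms: Mapping[str, int], n: int, width: int = _SLOT,
           start_index: int = 0) -> list[tuple[str, int]]:
    """Deterministic non-overlapping slot positions, round-robin over
    chromosomes in sorted order; raises when the genome cannot hold them."""
    names = sorted(chroms)
    out = []
    for k in range(start_index, start_index + n):
        chrom = names[k % len(names)]
        pos = _MARGIN + (k // len(names)) * width
        if pos + width + _MARGIN > chroms[chrom]:
            raise InfeasibleScenario(
                f"cannot place slot {k} on {chrom}: genome too small for "
                "the requested element/decoy counts"
            )
        out.append((chrom, pos))
    return out


def _count_round(n: int, frac: float) -> int:
    return int(round(n * frac))


def _jitter(rng: np.random.Generator, start: int, end: int, j: int) -> tuple[int, int]:
    if j <= 0:
        return start, end
    d1 = int(rng.integers(-j, j + 1))
    d2 = int(rng.integers(-j, j + 1))
    s, e = max(0, start + d1), end + d2
    return (s, e) if e > s else (start, end)


def _scrub_motif(seq: np.ndarray, start: int, end: int) -> None:
    """Destroy accidental GATA consensus hits (either strand) in-place."""
    pats = (GATA_CONSENSUS, reverse_complement(GATA_CONSENSUS))
    window = "".join(seq[max(0, start - 6) : end + 6])
    base = max(0, start - 6)
    changed = True
    while changed:
        changed = False
        for pat in pats:
            i = window.find(pat)
            while i != -1:
                # flip the third base to break the site
                pos = base + i + 2
                seq[pos] = "C" if seq[pos] != "C" else "G"
                window = "".join(seq[max(0, start - 6) : end + 6])
                changed = True
                i = window.find(pat)


def generate_scenario(cfg: ScenarioConfig, outdir: str | Path) -> dict:
    """Write the full file bundle under *outdir*; returns the manifest dict.

    Identical configs (same seed) produce byte-identical bundles.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "segmentations").mkdir(exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_planted_cnes

    n_pairs = min(len(cfg.human_chroms), len(cfg.mouse_chroms))
    h_names = sorted(cfg.human_chroms)[:n_pairs]
    m_names = sorted(cfg.mouse_chroms)[:n_pairs]

    # --- geometry -----------------------------------------------------------
    lengths = rng.integers(60, 201, size=n)
    zf_slots = _slots(cfg.zf_chroms, n)
    h_slots = _slots(dict(zip(h_names, (cfg.human_chroms[c] for c in h_names))), n)
    m_slots = _slots(dict(zip(m_names, (cfg.mouse_chroms[c] for c in m_names))), n)

    # --- role assignment ----------------------------------------------------
    ids = [f"E{i:03d}" for i in range(n)]
    idx = np.arange(n)
    gar_idx = set(rng.choice(idx, size=_count_round(n, cfg.frac_garcne_only),
                             replace=False).tolist())
    zcne_idx = [i for i in range(n) if i not in gar_idx]
    n_direct = _count_round(n, cfg.frac_direct)
    if n_direct > len(zcne_idx):
        raise InfeasibleScenario(
            "frac_direct exceeds the zCNE fraction: garCNE additions are "
            "always indirect"
        )
    direct_idx = set(
        rng.choice(np.array(zcne_idx), size=n_direct, replace=False).tolist()
    )
    acc_idx = set(rng.choice(idx, size=_count_round(n, cfg.frac_accessible_both),
                             replace=False).tolist())
    non_acc = [i for i in range(n) if i not in acc_idx]
    peak_only_idx = set(non_acc[: len(non_acc) // 2])  # seqCon but never aCNE

    # --- activity classes ---------------------------------------------------
    n_epi = cfg.n_epigenomes
    n_const = _count_round(n, cfg.frac_constitutive)
    n_lin = _count_round(n, cfg.frac_lineage)
    class_idx = rng.permutation(idx)
    const_set = set(class_idx[:n_const].tolist())
    lin_set = set(class_idx[n_const : n_const + n_lin].tolist())

    def plant_states(i: int) -> list[str]:
        """Per-epigenome state mnemonics for element i's human region."""
        states = [_QUIES] * n_epi
        order = rng.permutation(n_epi)
        if i in const_set:
            n_act = int(rng.integers(int(0.8 * n_epi) + 1, n_epi + 1))
            for j in order[:n_act]:
                states[j] = str(rng.choice(_ACTIVE_STATES))
            for j in order[n_act:]:
                states[j] = str(rng.choice(_BIVALENT_STATES + (_QUIES,)))
        elif i in lin_set:
            lo = int(0.7 * n_epi) + 1
            n_act = int(rng.integers(1, min(3, n_epi - lo + 1)))
            n_rep = int(rng.integers(lo, n_epi - n_act + 1))
            for j in order[:n_act]:
                states[j] = str(rng.choice(_ACTIVE_STATES))
            for j in order[n_act : n_act + n_rep]:
                states[j] = str(rng.choice(_POLYCOMB_STATES + (_QUIES,)))
            for j in order[n_act + n_rep :]:
                states[j] = str(rng.choice(_BIVALENT_STATES))
        else:
            n_act = max(2, int(round(0.5 * n_epi)))
            n_biv = (n_epi - n_act) // 2
            for j in order[:n_act]:
                states[j] = str(rng.choice(_ACTIVE_STATES))
            for j in order[n_act : n_act + n_biv]:
                states[j] = str(rng.choice(_BIVALENT_STATES + _OTHER_STATES))
            # remainder stays Quiescent; kept below the lineage threshold
        return states

    # --- per-element records ------------------------------------------------
    elements: list[dict] = []
    windows: list[GenomicInterval] = []
    peaks: list[GenomicInterval] = []
    dhs_human: list[GenomicInterval] = []
    dhs_mouse: list[GenomicInterval] = []
    labels: dict[str, str] = {}
    state_by_element: list[list[str]] = []

    for i in range(n):
        L = int(lengths[i])
        zc, zp = zf_slots[i]
        hc, hp = h_slots[i]
        mc, mp = m_slots[i]
        zf = (zc, zp + 1000, zp + 1000 + L)
        human = (hc, hp + 1000, hp + 1000 + L)
        mouse = (mc, mp + 1000, mp + 1000 + L)
        eid = ids[i]

        mode = "direct" if i in direct_idx else "indirect"
        if i in direct_idx:
            wstart = int(rng.integers(zf[1], zf[2] - 20 + 1))
            windows.append(GenomicInterval(zc, wstart, wstart + 40, id=f"win_{eid}"))
        elif i not in gar_idx and rng.random() < 0.33:
            # near-miss window: overlap of 5..14 bp, still indirect
            k = int(rng.integers(5, 15))
            windows.append(
                GenomicInterval(zc, zf[1] - (40 - k), zf[1] + k, id=f"win_{eid}")
            )

        has_peak = i in acc_idx or i in peak_only_idx
        peak_id = None
        label = None
        if has_peak:
            peak_id = f"peak_{eid}"
            f1, f2 = int(rng.integers(50, 301)), int(rng.integers(50, 301))
            ps, pe = _jitter(rng, zf[1] - f1, zf[2] + f2, cfg.jitter_bp)
            signal = float(np.round(rng.uniform(5, 50), 2))
            peaks.append(GenomicInterval(zc, ps, pe, id=peak_id, score=signal))
            label = str(rng.choice(["gfp_pos", "gfp_neg", "shared"],
                                   p=[0.3, 0.3, 0.4]))
            if cfg.label_flip_rate > 0 and rng.random() < cfg.label_flip_rate:
                label = str(rng.choice(["gfp_pos", "gfp_neg", "shared"]))
            labels[peak_id] = label

        h_ids: list[str] = []
        m_ids: list[str] = []
        if i in acc_idx:
            if rng.random() < 0.2 and L >= 90:
                # a chain of two DHSs on one element; the gap straddles the
                # 200 bp merge threshold so some pairs merge and some don't
                third = L // 3
                gap2 = int(rng.integers(50, 401))
                a_end = human[1] + third
                b_start = min(a_end + gap2, human[2] - 10)
                h_ids = [f"dhs_h_{eid}a", f"dhs_h_{eid}b"]
                s1, e1 = _jitter(rng, human[1] - 50, a_end, cfg.jitter_bp)
                s2, e2 = _jitter(rng, b_start, human[2] + 50, cfg.jitter_bp)
                dhs_human.append(GenomicInterval(hc, s1, e1, id=h_ids[0]))
                dhs_human.append(GenomicInterval(hc, s2, e2, id=h_ids[1]))
            else:
                h_ids = [f"dhs_h_{eid}"]
                r1, r2 = int(rng.integers(20, 151)), int(rng.integers(20, 151))
                s, e = _jitter(rng, human[1] - r1, human[2] + r2, cfg.jitter_bp)
                dhs_human.append(GenomicInterval(hc, s, e, id=h_ids[0]))
            m_ids = [f"dhs_m_{eid}"]
            r1, r2 = int(rng.integers(20, 151)), int(rng.integers(20, 151))
            s, e = _jitter(rng, mouse[1] - r1, mouse[2] + r2, cfg.jitter_bp)
            dhs_mouse.append(GenomicInterval(mc, s, e, id=m_ids[0]))

        states = plant_states(i)
        state_by_element.append(states)
        counts = {c: 0 for c in CATEGORIES}
        for s in states:
            counts[DEFAULT_CATEGORY_MAP[s]] += 1
        activity = classify_activity(counts, n_epi)

        elements.append(
            dict(
                id=eid, zf=zf, human=human, mouse=mouse,
                source="garcne" if i in gar_idx else "zcne",
                mode=mode,
                accessible_both=bool(i in acc_idx),
                has_peak=bool(has_peak),
                peak_id=peak_id,
                label=label,
                activity_class=activity,
                category_counts=counts,
                motif_count=0,  # filled after sequence planting
                human_dhs_ids=h_ids,
                mouse_dhs_ids=m_ids,
            )
        )

    # --- decoys -------------------------------------------------------------
    decoy_peak_slots = _slots(cfg.zf_chroms, cfg.n_decoy_peaks, start_index=n)
    for k, (chrom, pos) in enumerate(decoy_peak_slots):
        width = int(rng.integers(200, 801))
        signal = float(np.round(rng.uniform(5, 50), 2))
        pid = f"peak_decoy{k:03d}"
        peaks.append(
            GenomicInterval(chrom, pos + 500, pos + 500 + width, id=pid,
                            score=signal)
        )
        labels[pid] = "shared"

    h_decoy_slots = _slots(
        {c: cfg.human_chroms[c] for c in h_names}, cfg.n_decoy_dhs,
        start_index=n + cfg.n_lift_fail_garcne + 2,
    )
    m_decoy_slots = _slots(
        {c: cfg.mouse_chroms[c] for c in m_names}, cfg.n_decoy_dhs,
        start_index=n,
    )
    for k, (chrom, pos) in enumerate(h_decoy_slots):
        width = int(rng.integers(100, 501))
        dhs_human.append(
            GenomicInterval(chrom, pos + 500, pos + 500 + width,
                            id=f"dhs_h_decoy{k:03d}")
        )
    for k, (chrom, pos) in enumerate(m_decoy_slots):
        width = int(rng.integers(100, 501))
        dhs_mouse.append(
            GenomicInterval(chrom, pos + 500, pos + 500 + width,
                            id=f"dhs_m_decoy{k:03d}")
        )

    # --- CNE tables ---------------------------------------------------------
    def iv(coords: tuple[str, int, int], rid: str) -> GenomicInterval:
        return GenomicInterval(coords[0], coords[1], coords[2], id=rid)

    zcne_human: list[CneRecord] = []
    zcne_mouse: list[CneRecord] = []
    garcne: list[CneRecord] = []
    for i, el in enumerate(elements):
        prov = "alignment" if el["mode"] == "direct" else "transitive"
        if el["source"] == "zcne":
            zcne_human.append(
                CneRecord(el["id"], "zcne", iv(el["zf"], el["id"]), "human",
                          iv(el["human"], el["id"]), provenance=prov)
            )
            zcne_mouse.append(
                CneRecord(el["id"], "zcne", iv(el["zf"], el["id"]), "mouse",
                          iv(el["mouse"], el["id"]), provenance=prov)
            )
        else:
            garcne.append(
                CneRecord(el["id"], "garcne", iv(el["zf"], el["id"]), "human",
                          iv(el["human"], el["id"]), provenance="gar_transitive")
            )

    # garCNEs overlapping a zCNE on zebrafish coordinates: must be excluded
    # by catalog integration.
    overl_ids = []
    zcne_elements = [elements[i] for i in zcne_idx]
    for k in range(min(cfg.n_overlapping_garcne, len(zcne_elements))):
        host = zcne_elements[k]
        gid = f"GOVL{k:02d}"
        overl_ids.append(gid)
        zc, zs, ze = host["zf"]
        hc_, hs, he = host["human"]
        garcne.append(
            CneRecord(
                gid, "garcne",
                GenomicInterval(zc, max(0, zs - 30), zs + 10, id=gid),
                "human",
                GenomicInterval(hc_, max(0, hs - 30), hs + 10, id=gid),
                provenance="gar_transitive",
            )
        )

    # --- chain file (human -> mouse) ---------------------------------------
    chains: list[ChainAlignment] = []
    per_pair: dict[tuple[str, str], list[int]] = {}
    for i, el in enumerate(elements):
        per_pair.setdefault((el["human"][0], el["mouse"][0]), []).append(i)
    for ci, ((hc_, mc_), members) in enumerate(sorted(per_pair.items())):
        members = sorted(members, key=lambda i: elements[i]["human"][1])
        blocks: list[ChainBlock] = []
        t0 = elements[members[0]]["human"][1]
        q0 = elements[members[0]]["mouse"][1]
        for j, i_el in enumerate(members):
            _, hs, he = elements[i_el]["human"]
            _, ms, me = elements[i_el]["mouse"]
            L = he - hs
            g = _INTERNAL_GAP if L >= 40 else 0
            a = (L - g) // 2
            b = L - g - a
            if j < len(members) - 1:
                nxt = elements[members[j + 1]]
                dt = nxt["human"][1] - he
                dq = nxt["mouse"][1] - me
                blocks += [ChainBlock(a, g, g), ChainBlock(b, dt, dq)]
            else:
                if g:
                    blocks += [ChainBlock(a, g, g), ChainBlock(b)]
                else:
                    blocks += [ChainBlock(a + b)]
        t_end = elements[members[-1]]["human"][2]
        q_end = elements[members[-1]]["mouse"][2]
        chains.append(
            ChainAlignment(
                score=1_000_000 - ci,
                t_name=hc_, t_size=cfg.human_chroms[hc_], t_strand="+",
                t_start=t0, t_end=t_end,
                q_name=mc_, q_size=cfg.mouse_chroms[mc_], q_strand="+",
                q_start=q0, q_end=q_end,
                chain_id=f"chain{ci}",
                blocks=tuple(blocks),
            )
        )

    # garCNEs whose human coordinates cannot be lifted: one sitting in a
    # chain gap (LOW_MATCH at any threshold: zero bases remap), one beyond
    # every chain span (NOT_COVERED).
    lift_fail_ids = []
    fail_zf_slots = _slots(cfg.zf_chroms, cfg.n_lift_fail_garcne,
                           start_index=n + cfg.n_decoy_peaks)
    for k in range(cfg.n_lift_fail_garcne):
        gid = f"GFAIL{k:02d}"
        lift_fail_ids.append(gid)
        zc, zp = fail_zf_slots[k]
        zf_iv = GenomicInterval(zc, zp + 100, zp + 180, id=gid)
        if k % 2 == 0 and chains:
            ch = chains[0]
            coords = ch.block_coords()
            if len(coords) >= 3:
                # start of the widest inter-element target gap
                t_gap_start = coords[1][0] + coords[1][2] + _INTERNAL_GAP + 20
                h_iv = GenomicInterval(ch.t_name, t_gap_start, t_gap_start + 80,
                                       id=gid)
            else:
                h_iv = GenomicInterval(ch.t_name, ch.t_end + 1000,
                                       ch.t_end + 1080, id=gid)
        else:
            hc_ = h_names[0]
            pos = cfg.human_chroms[hc_] - _MARGIN - 500
            h_iv = GenomicInterval(hc_, pos, pos + 80, id=gid)
        garcne.append(
            CneRecord(gid, "garcne", zf_iv, "human", h_iv,
                      provenance="gar_transitive")
        )

    # --- gene models --------------------------------------------------------
    n_genes = 4 * len(cfg.zf_chroms)
    gene_slots = _slots(
        cfg.zf_chroms, n_genes,
        start_index=n + cfg.n_decoy_peaks + cfg.n_lift_fail_garcne,
    )
    bed12_lines = []
    coding_exons: list[GenomicInterval] = []
    for k, (chrom, pos) in enumerate(gene_slots):
        strand = "+" if k % 2 == 0 else "-"
        start = pos + 200
        exon_sizes = [int(rng.integers(80, 200)) for _ in range(3)]
        intron_sizes = [int(rng.integers(200, 600)) for _ in range(2)]
        offsets = [0]
        for es, isz in zip(exon_sizes[:-1], intron_sizes):
            offsets.append(offsets[-1] + es + isz)
        end = start + offsets[-1] + exon_sizes[-1]
        name = f"gene{k:02d}:tx{k:02d}"
        bed12_lines.append(
            "\t".join(
                [
                    chrom, str(start), str(end), name, "0", strand,
                    str(start), str(end), "0",
                    "3",
                    ",".join(str(s) for s in exon_sizes) + ",",
                    ",".join(str(o) for o in offsets) + ",",
                ]
            )
        )
        for o, s in zip(offsets, exon_sizes):
            coding_exons.append(
                GenomicInterval(chrom, start + o, start + o + s,
                                id=f"exon_g{k:02d}")
            )

    # --- TF binding clusters on the human assembly --------------------------
    tf_lines = []
    factors = {"GATA4": 0.8, "NKX2-5": 0.3}
    for fname, rate in sorted(factors.items()):
        cl = 0
        for i in sorted(acc_idx):
            if rng.random() < rate:
                hc_, hs, he = elements[i]["human"]
                tf_lines.append(f"{hc_}\t{hs - 20}\t{he + 20}\tcl_{fname}_{cl}\t0\t.\t{fname}")
                cl += 1
        for k, (chrom, pos) in enumerate(h_decoy_slots[: max(3, cfg.n_decoy_dhs // 20)]):
            tf_lines.append(
                f"{chrom}\t{pos + 600}\t{pos + 800}\tcl_{fname}_d{k}\t0\t.\t{fname}"
            )

    # --- zebrafish sequence with planted GATA sites -------------------------
    seq_by_chrom: dict[str, np.ndarray] = {}
    for chrom in sorted(cfg.zf_chroms):
        seq_by_chrom[chrom] = rng.choice(list("ACGT"), size=cfg.zf_chroms[chrom])
    motif_idx = set(
        rng.choice(idx, size=_count_round(n, cfg.motif_plant_rate),
                   replace=False).tolist()
    )
    motif = MotifConsensus("GATA", GATA_CONSENSUS)
    for i, el in enumerate(elements):
        zc, zs, ze = el["zf"]
        arr = seq_by_chrom[zc]
        _scrub_motif(arr, zs, ze)
        if i in motif_idx:
            k_sites = 1 + int(rng.random() < 0.4)
            positions = [zs + 5]
            if k_sites == 2 and ze - zs >= 40:
                positions.append(ze - 15)
            for p in positions:
                arr[p : p + len(GATA_CONSENSUS)] = list(GATA_CONSENSUS)
        el["motif_count"] = len(
            scan("".join(arr[zs:ze]), motif, both_strands=True)
        )

    # --- write everything ---------------------------------------------------
    write_bed(IntervalSet(peaks), outdir / "peaks.bed")
    write_bed(IntervalSet(dhs_human), outdir / "dhs_human.bed")
    write_bed(IntervalSet(dhs_mouse), outdir / "dhs_mouse.bed")
    write_bed(IntervalSet(windows), outdir / "windows_human.bed")
    write_bed(IntervalSet(windows), outdir / "windows_mouse.bed")
    write_bed(IntervalSet(coding_exons), outdir / "coding_exons.bed")
    write_cne_tsv(sorted(zcne_human, key=lambda r: r.id),
                  outdir / "zcne_human.tsv")
    write_cne_tsv(sorted(zcne_mouse, key=lambda r: r.id),
                  outdir / "zcne_mouse.tsv")
    write_cne_tsv(sorted(garcne, key=lambda r: r.id),
                  outdir / "garcne_human.tsv")
    write_chain(chains, outdir / "human_to_mouse.chain")
    with open(outdir / "genes.bed12", "w") as fh:
        fh.write("\n".join(bed12_lines) + "\n")
    with open(outdir / "tf_clusters.bed", "w") as fh:
        fh.write("\n".join(tf_lines) + "\n")
    with open(outdir / "peak_labels.tsv", "w") as fh:
        fh.write("peak_id\tlabel\n")
        for pid in sorted(labels):
            fh.write(f"{pid}\t{labels[pid]}\n")
    for species, chroms in (
        ("zebrafish", cfg.zf_chroms),
        ("human", cfg.human_chroms),
        ("mouse", cfg.mouse_chroms),
    ):
        with open(outdir / f"chrom_sizes_{species}.tsv", "w") as fh:
            for c in sorted(chroms):
                fh.write(f"{c}\t{chroms[c]}\n")
    with open(outdir / "zebrafish_genome.fa", "w") as fh:
        for chrom in sorted(seq_by_chrom):
            fh.write(f">{chrom}\n")
            s = "".join(seq_by_chrom[chrom])
            for off in range(0, len(s), 80):
                fh.write(s[off : off + 80] + "\n")

    # per-epigenome segmentations tiling every human chromosome
    epi_ids = [f"Epi{j:02d}" for j in range(n_epi)]
    el_by_chrom: dict[str, list[int]] = {}
    for i, el in enumerate(elements):
        el_by_chrom.setdefault(el["human"][0], []).append(i)
    for j, epi in enumerate(epi_ids):
        with open(outdir / "segmentations" / f"{epi}.bed", "w") as fh:
            for chrom in sorted(cfg.human_chroms):
                cursor = 0
                for i in sorted(el_by_chrom.get(chrom, []),
                                key=lambda i: elements[i]["human"][1]):
                    _, hs, he = elements[i]["human"]
                    if hs > cursor:
                        fh.write(f"{chrom}\t{cursor}\t{hs}\t{_QUIES}\n")
                    fh.write(f"{chrom}\t{hs}\t{he}\t{state_by_element[i][j]}\n")
                    cursor = he
                size = cfg.human_chroms[chrom]
                if cursor < size:
                    fh.write(f"{chrom}\t{cursor}\t{size}\t{_QUIES}\n")
    with open(outdir / "epigenomes.tsv", "w") as fh:
        fh.write("epigenome_id\tpath\n")
        for epi in epi_ids:
            fh.write(f"{epi}\tsegmentations/{epi}.bed\n")

    manifest = dict(
        config=asdict(cfg),
        elements={el["id"]: el for el in elements},
        extra_garcne_overlapping=overl_ids,
        extra_garcne_lift_fail=lift_fail_ids,
        epigenomes=epi_ids,
        n_decoy_peaks=cfg.n_decoy_peaks,
        n_decoy_dhs=cfg.n_decoy_dhs,
    )
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest


def load_manifest(bundle_dir: str | Path) -> dict:
    with open(Path(bundle_dir) / "manifest.json") as fh:
        return json.load(fh)


def validate_bundle(bundle_dir: str | Path, manifest: dict | None = None) -> ValidationReport:
    """Cross-check the emitted files against the manifest.

    Verifies chain block-span invariants, element coordinate consistency
    (peaks/DHSs present and overlapping where the manifest promises them),
    the direct/indirect window-overlap construction, segmentation tiling
    and the planted motif counts.
    """
    from .intervals import overlap_length, read_bed
    from .motifs import read_fasta

    bundle_dir = Path(bundle_dir)
    if manifest is None:
        manifest = load_manifest(bundle_dir)
    issues: list[str] = []
    cfg = manifest["config"]

    try:
        parse_chain(bundle_dir / "human_to_mouse.chain")
    except Exception as exc:  # span violations surface here
        issues.append(f"chain file invalid: {exc}")

    peaks = {iv.id: iv for iv in read_bed(bundle_dir / "peaks.bed")}
    dhs_h = {iv.id: iv for iv in read_bed(bundle_dir / "dhs_human.bed")}
    dhs_m = {iv.id: iv for iv in read_bed(bundle_dir / "dhs_mouse.bed")}
    windows = read_bed(bundle_dir / "windows_human.bed")
    genome = read_fasta(bundle_dir / "zebrafish_genome.fa")
    motif = MotifConsensus("GATA", GATA_CONSENSUS)

    sizes = {
        "zf": cfg["zf_chroms"], "human": cfg["human_chroms"],
        "mouse": cfg["mouse_chroms"],
    }
    for eid, el in sorted(manifest["elements"].items()):
        for key in ("zf", "human", "mouse"):
            chrom, s, e = el[key]
            if chrom not in sizes[key] or not (0 <= s < e <= sizes[key][chrom]):
                issues.append(f"{eid}: {key} coordinates out of range")
        zf = GenomicInterval(*el["zf"])
        best = max((overlap_length(zf, w) for w in windows.overlapping(zf)),
                   default=0)
        if el["source"] == "zcne":
            if el["mode"] == "direct" and best < 15:
                issues.append(f"{eid}: direct element overlaps windows by {best} bp")
            if el["mode"] == "indirect" and best >= 15:
                issues.append(f"{eid}: indirect element overlaps a window by {best} bp")
        if el["has_peak"]:
            pk = peaks.get(el["peak_id"])
            if pk is None or overlap_length(pk, zf) < 1:
                issues.append(f"{eid}: promised peak missing or disjoint")
        if el["accessible_both"]:
            for ids_, pool, key in (
                (el["human_dhs_ids"], dhs_h, "human"),
                (el["mouse_dhs_ids"], dhs_m, "mouse"),
            ):
                target = GenomicInterval(*el[key])
                for did in ids_:
                    d = pool.get(did)
                    if d is None or overlap_length(d, target) < 1:
                        issues.append(f"{eid}: DHS {did} missing or disjoint")
        zc, zs, ze = el["zf"]
        found = len(scan(genome[zc][zs:ze], motif, both_strands=True))
        if found != el["motif_count"]:
            issues.append(
                f"{eid}: motif count {found} != manifest {el['motif_count']}"
            )

    for epi in manifest["epigenomes"]:
        seg = read_bed(bundle_dir / "segmentations" / f"{epi}.bed",
                       min_columns=4)
        for chrom, size in sorted(cfg["human_chroms"].items()):
            cursor = 0
            for iv in seg.on_chrom(chrom):
                if iv.start != cursor:
                    issues.append(f"{epi}: segmentation gap on {chrom} at {cursor}")
                    break
                cursor = iv.end
            else:
                if cursor != size:
                    issues.append(f"{epi}: segmentation ends at {cursor} != {size}")

    zcne_zf = read_bed(bundle_dir / "windows_human.bed")  # placeholder reuse
    del zcne_zf
    from .catalog import read_cne_tsv

    zcnes = read_cne_tsv(bundle_dir / "zcne_human.tsv")
    zset = IntervalSet(r.zf for r in zcnes)
    gars = {r.id: r for r in read_cne_tsv(bundle_dir / "garcne_human.tsv")}
    for gid in manifest["extra_garcne_overlapping"]:
        if gid not in gars:
            issues.append(f"overlapping garCNE {gid} missing from file")
        elif not zset.overlaps(gars[gid].zf):
            issues.append(f"garCNE {gid} was promised to overlap a zCNE")

    return ValidationReport(ok=not issues, issues=issues)
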