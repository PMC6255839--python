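"""End-to-end orchestration: catalogs -> seqCon -> aCNEs -> characterization.

``run`` drives the stages in dependency order over a :class:`RunConfig`
(paths plus every threshold, all config-exposed with the study's defaults:
15 bp direct-alignment window overlap, 1 bp linking overlaps, 200 bp DHS
merging, minMatch 0.1 for CNE conversion) and serializes a JSON report in
which every percentage carries its raw numerator and denominator, plus a
human-readable text rendering.  Reruns with the same config and seed are
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import yaml

from . import acne as acne_mod
from . import catalog as cat_mod
from .annotation import FeatureIndex, feature_enrichment, read_bed12
from .enrichment import EnrichmentConfig, overlap_predicate, selection_permutation
from .intervals import GenomicInterval, IntervalSet, read_bed
from .liftover import LiftoverConfig, parse_chain
from .motifs import GATA_CONSENSUS, MotifConsensus, census, read_fasta
from .states import (
    DEFAULT_CATEGORY_MAP,
    build_activity_profiles,
    read_segmentation_bed,
)

log = logging.getLogger("acnekit")


class ConfigurationError(ValueError):
    pass


def render_percentage(numerator: int, denominator: int, decimals: int = 1) -> str:
    """Percentage string rounded half-away-from-zero at *decimals* places
    (the convention behind printed figures like "6294 (3.1%)")."""
    if denominator == 0:
        raise ValueError("zero denominator")
    pct = Decimal(100 * numerator) / Decimal(denominator)
    quant = Decimal(1).scaleb(-decimals)
    return f"{pct.quantize(quant, rounding=ROUND_HALF_UP)}%"


def pct_entry(numerator: int, denominator: int, decimals: int = 1) -> dict:
    """Report entry: rendered percentage always next to its raw fraction."""
    return {
        "numerator": numerator,
        "denominator": denominator,
        "fraction": numerator / denominator if denominator else None,
        "rendered": render_percentage(numerator, denominator, decimals)
        if denominator
        else None,
    }


@dataclass
class RunConfig:
    """Paths and thresholds for one pipeline run.

    File paths default to the layout the synthetic-data generator emits;
    ``from_bundle`` fills them from a bundle directory.  Stage toggles let
    partial runs skip characterization stages.
    """

    bundle_dir: str
    outdir: str
    seed: int = 0
    # thresholds, study defaults
    direct_min_overlap_bp: int = 15
    link_min_overlap_bp: int = 1
    dhs_merge_gap_bp: int = 200
    cne_lift_min_match: float = 0.1
    active_frac: float = 0.80
    repressed_frac: float = 0.70
    n_perm: int = 1000
    # stage toggles
    run_mouse: bool = True
    run_annotation: bool = True
    run_states: bool = True
    run_motifs: bool = True
    run_tf_enrichment: bool = False  # permutation-heavy; opt in
    files: dict[str, str] = field(default_factory=dict)

    _DEFAULT_FILES = {
        "peaks": "peaks.bed",
        "zcne_human": "zcne_human.tsv",
        "zcne_mouse": "zcne_mouse.tsv",
        "garcne_human": "garcne_human.tsv",
        "windows_human": "windows_human.bed",
        "windows_mouse": "windows_mouse.bed",
        "chain_hg_to_mm": "human_to_mouse.chain",
        "dhs_human": "dhs_human.bed",
        "dhs_mouse": "dhs_mouse.bed",
        "coding_exons": "coding_exons.bed",
        "genes": "genes.bed12",
        "fasta": "zebrafish_genome.fa",
        "labels": "peak_labels.tsv",
        "epigenomes": "epigenomes.tsv",
        "tf_clusters": "tf_clusters.bed",
    }

    def path(self, key: str) -> Path:
        rel = self.files.get(key, self._DEFAULT_FILES[key])
        return Path(self.bundle_dir) / rel

    @classmethod
    def from_bundle(cls, bundle_dir: str | Path, outdir: str | Path,
                    **kwargs) -> "RunConfig":
        return cls(bundle_dir=str(bundle_dir), outdir=str(outdir), **kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def validate(self) -> None:
        required = ["peaks", "zcne_human", "garcne_human", "windows_human",
                    "dhs_human"]
        if self.run_mouse:
            required += ["zcne_mouse", "windows_mouse", "chain_hg_to_mm",
                         "dhs_mouse"]
        for key in required:
            if not self.path(key).exists():
                raise ConfigurationError(
                    f"required input {key!r} not found at {self.path(key)}"
                )

    def config_hash(self) -> str:
        # outdir is where results land, not an analytic input
        payload = {k: v for k, v in asdict(self).items() if k != "outdir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:12]


def read_labels(path: str | Path) -> dict[str, str]:
    labels = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("peak_id"):
            raise ValueError(f"{path}: expected a 'peak_id\\tlabel' header")
        for line in fh:
            if line.strip():
                pid, lab = line.rstrip("\n").split("\t")
                labels[pid] = lab
    return labels


def _species_block(cfg: RunConfig, peaks: IntervalSet, catalog, dhs: IntervalSet,
                   species: str) -> dict:
    seqcon = acne_mod.find_seqcon(peaks, catalog, cfg.link_min_overlap_bp)
    acnes = acne_mod.call_acnes(seqcon, catalog, dhs, species,
                                cfg.link_min_overlap_bp)
    merged_by_peak, members = acne_mod.merge_linked_dhs(
        acnes, dhs, cfg.dhs_merge_gap_bp
    )
    stats = acne_mod.compute_link_stats(peaks, seqcon, acnes, merged_by_peak,
                                        catalog)
    return {
        "seqcon": seqcon,
        "acnes": acnes,
        "merged_by_peak": merged_by_peak,
        "merged_members": members,
        "stats": stats,
    }


def run(cfg: RunConfig) -> dict:
    """Execute the pipeline; writes stage outputs and the report, returns
    the report dict."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO, format="%(name)s: %(message)s")
    log.info("run config hash %s, seed %d", cfg.config_hash(), cfg.seed)
    log.info(
        "thresholds: direct window >=%d bp, linking >=%d bp, DHS merge "
        "<=%d bp, CNE lift minMatch %.2f (promoter window and category map "
        "are defaults the source analyses leave unspecified)",
        cfg.direct_min_overlap_bp, cfg.link_min_overlap_bp,
        cfg.dhs_merge_gap_bp, cfg.cne_lift_min_match,
    )

    report: dict = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "thresholds": {
            "direct_min_overlap_bp": cfg.direct_min_overlap_bp,
            "link_min_overlap_bp": cfg.link_min_overlap_bp,
            "dhs_merge_gap_bp": cfg.dhs_merge_gap_bp,
            "cne_lift_min_match": cfg.cne_lift_min_match,
            "active_frac": cfg.active_frac,
            "repressed_frac": cfg.repressed_frac,
        },
    }

    # --- catalogs -----------------------------------------------------------
    try:
        peaks = read_bed(cfg.path("peaks"))
        zcne_h = cat_mod.read_cne_tsv(cfg.path("zcne_human"))
        gar_h = cat_mod.read_cne_tsv(cfg.path("garcne_human"))
        windows_h = read_bed(cfg.path("windows_human"))
    except Exception as exc:
        raise ConfigurationError(f"stage catalog(human): {exc}") from exc
    catalog_h = cat_mod.integrate_garcne(zcne_h, gar_h, windows_h,
                                         cfg.direct_min_overlap_bp)
    cat_mod.write_cne_tsv(catalog_h, outdir / "catalog_human.tsv")
    summary_h = cat_mod.summarize_catalog(catalog_h, "human")
    report["catalog_human"] = asdict(summary_h)

    catalog_m = None
    if cfg.run_mouse:
        zcne_m = cat_mod.read_cne_tsv(cfg.path("zcne_mouse"))
        chains = parse_chain(cfg.path("chain_hg_to_mm"))
        windows_m = read_bed(cfg.path("windows_mouse"))
        catalog_m, rejections = cat_mod.build_mouse_catalog(
            zcne_m, gar_h, chains, windows_m,
            LiftoverConfig(min_match=cfg.cne_lift_min_match),
            cfg.direct_min_overlap_bp,
        )
        cat_mod.write_cne_tsv(catalog_m, outdir / "catalog_mouse.tsv")
        from .liftover import write_rejections

        write_rejections(rejections, outdir / "mouse_lift_rejections.tsv")
        report["catalog_mouse"] = asdict(
            cat_mod.summarize_catalog(catalog_m, "mouse")
        )
        report["catalog_mouse"]["n_lift_rejected"] = len(rejections)

    # --- aCNE calling -------------------------------------------------------
    dhs_h = read_bed(cfg.path("dhs_human"))
    blocks = {"human": _species_block(cfg, peaks, catalog_h, dhs_h, "human")}
    if cfg.run_mouse:
        dhs_m = read_bed(cfg.path("dhs_mouse"))
        blocks["mouse"] = _species_block(cfg, peaks, catalog_m, dhs_m, "mouse")
    for species, blk in blocks.items():
        acne_mod.write_links_tsv(blk["seqcon"], blk["acnes"],
                                 outdir / f"links_{species}.tsv")
        st = blk["stats"]
        report[f"links_{species}"] = asdict(st)
        report[f"links_{species}"]["pct_seqcon_rendered"] = pct_entry(
            st.n_seqcon, st.n_peaks_total, 1
        )
        report[f"links_{species}"]["pct_acne_of_seqcon_rendered"] = pct_entry(
            st.n_acne, st.n_seqcon, 0
        ) if st.n_seqcon else None

    # --- coding exclusion ---------------------------------------------------
    if cfg.path("coding_exons").exists():
        exons = read_bed(cfg.path("coding_exons"))
        peaks_by_id = {p.id: p for p in peaks}
        seqcon_peaks = [
            peaks_by_id[sc.peak_id] for sc in blocks["human"]["seqcon"]
        ]
        report["coding_exclusion_fraction"] = acne_mod.coding_exclusion_fraction(
            seqcon_peaks, exons
        )

    # --- feature annotation -------------------------------------------------
    if cfg.run_annotation and cfg.path("genes").exists():
        transcripts = read_bed12(cfg.path("genes"))
        index = FeatureIndex(transcripts)
        acne_peak_ids = {a.peak_id for a in blocks["human"]["acnes"]}
        query = [p for p in peaks if p.id in acne_peak_ids]
        if query:
            results = feature_enrichment(query, list(peaks), index)
            report["feature_enrichment"] = [asdict(r) for r in results]

    # --- chromatin states ---------------------------------------------------
    if cfg.run_states and cfg.path("epigenomes").exists():
        segmentations = []
        with open(cfg.path("epigenomes")) as fh:
            fh.readline()
            for line in fh:
                if line.strip():
                    epi, rel = line.rstrip("\n").split("\t")
                    segmentations.append(
                        read_segmentation_bed(
                            Path(cfg.bundle_dir) / rel, epi
                        )
                    )
        by_id = {rec.id: rec for rec in catalog_h}
        acne_regions = sorted(
            {a.cne_id for a in blocks["human"]["acnes"]}
        )
        regions = [
            GenomicInterval(
                by_id[cid].target.chrom, by_id[cid].target.start,
                by_id[cid].target.end, id=cid,
            )
            for cid in acne_regions
        ]
        if regions:
            profiles = build_activity_profiles(
                regions, segmentations, DEFAULT_CATEGORY_MAP,
                cfg.active_frac, cfg.repressed_frac,
            )
            from .states import write_profiles_tsv

            write_profiles_tsv(profiles, outdir / "activity_profiles.tsv")
            tally: dict[str, int] = {}
            for p in profiles:
                tally[p.classification] = tally.get(p.classification, 0) + 1
            report["activity_classification"] = {
                "n_regions": len(profiles),
                "tally": tally,
                "n_epigenomes": len(segmentations),
            }

    # --- TF occupancy enrichment (selection permutation) --------------------
    if cfg.run_tf_enrichment and cfg.path("tf_clusters").exists():
        by_id = {rec.id: rec for rec in catalog_h}
        regions = [
            by_id[cid].target
            for cid in sorted({a.cne_id for a in blocks["human"]["acnes"]})
        ]
        clusters_by_factor: dict[str, list[GenomicInterval]] = {}
        for iv in read_bed(cfg.path("tf_clusters"), min_columns=7):
            clusters_by_factor.setdefault(iv.extra[0], []).append(iv)
        ecfg = EnrichmentConfig(n_perm=cfg.n_perm, seed=cfg.seed,
                                universe=dhs_h)
        tf_report = {}
        for factor in sorted(clusters_by_factor):
            res = selection_permutation(
                regions, overlap_predicate(IntervalSet(clusters_by_factor[factor])),
                ecfg,
            )
            tf_report[factor] = {
                "observed": res.observed, "perm_mean": res.perm_mean,
                "perm_sd": res.perm_sd, "z": res.z, "p_emp": res.p_emp,
                "n_perm": res.n_perm, "seed": res.seed,
            }
        report["tf_occupancy"] = tf_report

    # --- motif census -------------------------------------------------------
    if cfg.run_motifs and cfg.path("fasta").exists():
        genome = read_fasta(cfg.path("fasta"))
        by_id = {rec.id: rec for rec in catalog_h}
        acne_cnes = sorted({a.cne_id for a in blocks["human"]["acnes"]})
        regions = [by_id[cid].zf for cid in acne_cnes]
        if regions:
            summary, counts = census(
                genome, regions, MotifConsensus("GATA", GATA_CONSENSUS)
            )
            report["gata_census"] = {
                **asdict(summary),
                "pct_ge1": pct_entry(summary.n_ge1, summary.n_regions, 0),
                "pct_gt1": pct_entry(summary.n_gt1, summary.n_regions, 0),
            }
            with open(outdir / "gata_counts.tsv", "w") as fh:
                fh.write("region_id\tn_hits\n")
                for rid in sorted(counts):
                    fh.write(f"{rid}\t{counts[rid]}\n")

    # --- serialize ----------------------------------------------------------
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=str)
        fh.write("\n")
    with open(outdir / "report.txt", "w") as fh:
        fh.write(render_report_text(report))
    return report


def render_report_text(report: dict) -> str:
    lines = [
        f"acnekit run (config {report['config_hash']}, seed {report['seed']})",
        "",
    ]
    for species in ("human", "mouse"):
        key = f"links_{species}"
        if key not in report:
            continue
        st = report[key]
        pr = st["pct_seqcon_rendered"]
        lines.append(
            f"{species}: {st['n_seqcon']} of {st['n_peaks_total']} peaks "
            f"sequence-conserved ({pr['rendered']}); "
            f"{st['n_acne']} aCNE peaks"
        )
        if st.get("pct_acne_of_seqcon_rendered"):
            pa = st["pct_acne_of_seqcon_rendered"]
            lines.append(
                f"  aCNE/seqCon: {pa['numerator']}/{pa['denominator']} "
                f"({pa['rendered']}); mean target aCNEs per zebrafish aCNE "
                f"{st['mean_target_acnes_per_zf_acne']:.2f}"
            )
    if "catalog_human" in report:
        c = report["catalog_human"]
        lines.append(
            f"human CNE catalog: {c['n_total']} total = {c['n_direct']} "
            f"direct + {c['n_indirect']} indirect"
        )
    if "catalog_mouse" in report:
        c = report["catalog_mouse"]
        lines.append(
            f"mouse CNE catalog: {c['n_total']} total = {c['n_direct']} "
            f"direct + {c['n_indirect']} indirect "
            f"({c['n_lift_rejected']} garCNE lift failures)"
        )
    if "coding_exclusion_fraction" in report:
        lines.append(
            "fraction of CNE-associated peaks excluded from coding exons: "
            f"{report['coding_exclusion_fraction']:.3f}"
        )
    if "activity_classification" in report:
        a = report["activity_classification"]
        lines.append(
            f"activity over {a['n_epigenomes']} epigenomes "
            f"({a['n_regions']} regions): "
            + ", ".join(f"{k}={v}" for k, v in sorted(a["tally"].items()))
        )
    if "gata_census" in report:
        g = report["gata_census"]
        lines.append(
            f"GATA census: {g['n_ge1']}/{g['n_regions']} with >=1 site "
            f"({g['pct_ge1']['rendered']}), {g['n_gt1']} with >1 "
            f"({g['pct_gt1']['rendered']})"
        )
    return "\n".join(lines) + "\n"
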