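"""aCNE calling: peak-CNE-DHS linking, DHS merging and accounting."""

import numpy as np
import pytest

from acnekit.acne import (
    call_acnes,
    coding_exclusion_fraction,
    compute_link_stats,
    find_seqcon,
    merge_linked_dhs,
)
from acnekit.catalog import CneRecord
from acnekit.intervals import GenomicInterval, IntervalSet


def cne(cid, zf_start, zf_end, t_start=None, t_end=None, species="human"):
    target = None
    if t_start is not None:
        target = GenomicInterval("h1", t_start, t_end, id=cid)
    return CneRecord(
        cid, "zcne", GenomicInterval("z1", zf_start, zf_end, id=cid),
        species, target, mode="indirect", provenance="transitive",
    )


def peaks(*coords):
    return IntervalSet(
        GenomicInterval("z1", s, e, id=f"p{i}")
        for i, (s, e) in enumerate(coords)
    )


def dhs_set(*coords):
    return IntervalSet(
        GenomicInterval("h1", s, e, id=f"d{i}")
        for i, (s, e) in enumerate(coords)
    )


class TestFindSeqcon:
    def test_one_bp_rule(self):
        catalog = [cne("c_in", 480, 520, 0, 40), cne("c_out", 500, 600, 0, 40)]
        pk = peaks((0, 500))
        links = find_seqcon(pk, catalog)
        assert len(links) == 1
        assert links[0].cne_ids == ("c_in",)  # [500,600) touches, no overlap

    def test_all_overlapping_cnes_listed(self):
        catalog = [cne(f"c{i}", 100 + i * 50, 140 + i * 50, 0, 40) for i in range(3)]
        links = find_seqcon(peaks((0, 500)), catalog)
        assert links[0].cne_ids == ("c0", "c1", "c2")

    def test_peak_without_id_rejected(self):
        pk = IntervalSet([GenomicInterval("z1", 0, 100)])
        with pytest.raises(ValueError, match="id"):
            find_seqcon(pk, [cne("c", 0, 50, 0, 40)])


class TestCallAcnes:
    def test_target_dhs_overlap(self):
        catalog = [cne("c", 10, 60, 1000, 1040)]
        links = find_seqcon(peaks((0, 100)), catalog)
        acnes = call_acnes(links, catalog, dhs_set((1030, 1200)), "human")
        assert [(a.peak_id, a.cne_id, a.dhs_ids) for a in acnes] == [
            ("p0", "c", ("d0",))
        ]

    def test_no_dhs_overlap_stays_seqcon_only(self):
        catalog = [cne("c", 10, 60, 1000, 1040)]
        links = find_seqcon(peaks((0, 100)), catalog)
        assert call_acnes(links, catalog, dhs_set((1040, 1200)), "human") == []

    def test_two_dhs_one_link(self):
        catalog = [cne("c", 10, 60, 1000, 1100)]
        links = find_seqcon(peaks((0, 100)), catalog)
        acnes = call_acnes(
            links, catalog, dhs_set((990, 1020), (1080, 1150)), "human"
        )
        assert acnes[0].dhs_ids == ("d0", "d1")

    def test_missing_target_names_cne(self):
        catalog = [cne("orphan", 10, 60)]
        links = find_seqcon(peaks((0, 100)), catalog)
        with pytest.raises(ValueError, match="orphan"):
            call_acnes(links, catalog, dhs_set((0, 10)), "human")


class TestMergeLinkedDhs:
    def _acnes(self, same_peak):
        catalog = [
            cne("c1", 10, 60, 1000, 1040),
            cne("c2", 400, 460, 1200, 1260) if not same_peak
            else cne("c2", 70, 95, 1200, 1260),
        ]
        pk = peaks((0, 100), (390, 480))
        links = find_seqcon(pk, catalog)
        dhs = dhs_set((990, 1040), (1190, 1260))  # 150 bp apart
        return call_acnes(links, catalog, dhs, "human"), dhs

    def test_same_peak_within_gap_merged(self):
        acnes, dhs = self._acnes(same_peak=True)
        merged, members = merge_linked_dhs(acnes, dhs, gap=200)
        assert len(merged["p0"]) == 1
        assert members["p0|m0"] == ("d0", "d1")
        assert (merged["p0"][0].start, merged["p0"][0].end) == (990, 1260)

    def test_different_peaks_never_merged(self):
        acnes, dhs = self._acnes(same_peak=False)
        merged, _ = merge_linked_dhs(acnes, dhs, gap=200)
        assert len(merged["p0"]) == 1 and len(merged["p1"]) == 1

    def test_single_dhs_unchanged(self):
        catalog = [cne("c", 10, 60, 1000, 1040)]
        links = find_seqcon(peaks((0, 100)), catalog)
        dhs = dhs_set((990, 1040))
        acnes = call_acnes(links, catalog, dhs, "human")
        merged, _ = merge_linked_dhs(acnes, dhs, gap=200)
        assert [(iv.start, iv.end) for iv in merged["p0"]] == [(990, 1040)]


class TestLinkStats:
    def test_percentage_arithmetic(self):
        catalog = [cne(f"c{i}", 1000 * i + 10, 1000 * i + 60,
                       2000 + 100 * i, 2040 + 100 * i) for i in range(4)]
        pk = peaks(*[(1000 * i, 1000 * i + 100) for i in range(10)])
        seqcon = find_seqcon(pk, catalog)
        dhs = dhs_set((2030, 2041), (2130, 2141), (2230, 2241))  # first 3 CNEs
        acnes = call_acnes(seqcon, catalog, dhs, "human")
        merged, _ = merge_linked_dhs(acnes, dhs)
        stats = compute_link_stats(pk, seqcon, acnes, merged, catalog)
        assert (stats.n_peaks_total, stats.n_seqcon, stats.n_acne) == (10, 4, 3)
        assert stats.pct_seqcon == pytest.approx(40.0)
        assert stats.pct_acne_of_seqcon == pytest.approx(75.0)

    def test_multiplicity_three_groups_over_two_peaks(self):
        catalog = [
            cne("c1", 10, 60, 1000, 1400),
            cne("c2", 2010, 2060, 5000, 5100),
        ]
        pk = peaks((0, 100), (2000, 2100))
        seqcon = find_seqcon(pk, catalog)
        # c1 hits two DHSs 340 bp apart (2 merged groups), c2 one DHS
        dhs = IntervalSet(
            list(dhs_set((990, 1010), (4990, 5010)))
            + [GenomicInterval("h1", 1350, 1500, id="far")]
        )
        acnes = call_acnes(seqcon, catalog, dhs, "human")
        merged, _ = merge_linked_dhs(acnes, dhs)
        stats = compute_link_stats(pk, seqcon, acnes, merged, catalog)
        assert stats.mean_target_acnes_per_zf_acne == pytest.approx(1.5)

    def test_containment_accounting(self):
        catalog = [cne("inside", 10, 20, 1000, 1010),
                   cne("straddle", 90, 110, 1020, 1030)]
        pk = peaks((0, 100))
        seqcon = find_seqcon(pk, catalog)
        stats = compute_link_stats(pk, seqcon, [], {}, catalog)
        assert stats.frac_cnes_fully_contained == pytest.approx(0.5)

    def test_invariant_on_random_fixtures(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n_peaks = int(rng.integers(1, 15))
            pk = IntervalSet(
                GenomicInterval(
                    "z1", s := int(rng.integers(0, 5000)),
                    s + int(rng.integers(50, 300)), id=f"p{i}",
                )
                for i, s_ in enumerate(range(n_peaks))
            )
            catalog = [
                cne(f"c{i}", s := int(rng.integers(0, 5000)),
                    s + int(rng.integers(20, 100)),
                    t := int(rng.integers(0, 5000)),
                    t + int(rng.integers(20, 100)))
                for i in range(int(rng.integers(0, 10)))
            ]
            dhs = IntervalSet(
                GenomicInterval(
                    "h1", s := int(rng.integers(0, 5000)),
                    s + int(rng.integers(20, 200)), id=f"d{i}",
                )
                for i in range(int(rng.integers(0, 10)))
            )
            seqcon = find_seqcon(pk, catalog)
            acnes = call_acnes(seqcon, catalog, dhs, "human")
            merged, _ = merge_linked_dhs(acnes, dhs)
            stats = compute_link_stats(pk, seqcon, acnes, merged, catalog)
            assert stats.n_acne <= stats.n_seqcon <= stats.n_peaks_total

    def test_growing_dhs_never_decreases_acnes(self):
        catalog = [cne(f"c{i}", 1000 * i, 1000 * i + 50,
                       3000 + 500 * i, 3050 + 500 * i) for i in range(5)]
        pk = peaks(*[(1000 * i - 20 if i else 0, 1000 * i + 70)
                     for i in range(5)])
        seqcon = find_seqcon(pk, catalog)
        small = dhs_set((3040, 3060))
        big = IntervalSet(list(small) + [
            GenomicInterval("h1", 3540, 3560, id="extra1"),
            GenomicInterval("h1", 4040, 4060, id="extra2"),
        ])
        n_small = len({a.peak_id for a in call_acnes(seqcon, catalog, small, "human")})
        n_big = len({a.peak_id for a in call_acnes(seqcon, catalog, big, "human")})
        assert n_big >= n_small


class TestCodingExclusion:
    def test_boundary(self):
        exons = IntervalSet([GenomicInterval("z1", 100, 200)])
        clean = GenomicInterval("z1", 200, 300, id="a")    # touches only
        dirty = GenomicInterval("z1", 199, 300, id="b")    # 1 bp overlap
        assert coding_exclusion_fraction([clean, dirty], exons) == 0.5

    def test_empty_exon_set(self):
        assert coding_exclusion_fraction(
            [GenomicInterval("z1", 0, 10, id="a")], IntervalSet()
        ) == 1.0
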