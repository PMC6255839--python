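"""Permutation nulls and classical tests against closed-form oracles."""

import numpy as np
import pytest
from scipy import stats as sps

from acnekit.enrichment import (
    ContingencyTable,
    EnrichmentConfig,
    chi_square_2x2,
    compare_region_properties,
    hypergeom_enrichment,
    overlap_predicate,
    placement_permutation,
    selection_permutation,
    total_bp_overlap,
)
from acnekit.intervals import GenomicInterval, IntervalSet, ScoredPeak


def iv(chrom, start, end, id=None):
    return GenomicInterval(chrom, start, end, id=id)


class TestChiSquare:
    def test_closed_form(self):
        # N(ad-bc)^2 / (r1 r2 c1 c2) for [[20,10],[10,20]] = 20/3
        stat, p = chi_square_2x2(ContingencyTable(20, 10, 10, 20))
        assert stat == pytest.approx(20 / 3)
        assert p == pytest.approx(float(sps.chi2.sf(20 / 3, 1)))

    def test_balanced_table_null(self):
        stat, p = chi_square_2x2(ContingencyTable(10, 10, 10, 10))
        assert stat == 0.0 and p == 1.0

    def test_conservation_contingency_from_printed_counts(self):
        # GFP+ specific: 176 conserved of 3838; GFP-: 264 of 1633
        t = ContingencyTable(176, 3838 - 176, 264, 1633 - 264)
        stat, p = chi_square_2x2(t, correction=False)
        n = 3838 + 1633
        closed = (
            n * (176 * 1369 - 3662 * 264) ** 2
            / (3838 * 1633 * (176 + 264) * (3662 + 1369))
        )
        assert stat == pytest.approx(closed)
        assert p == pytest.approx(float(sps.chi2.sf(closed, 1)))

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi_square_2x2(ContingencyTable(0, 0, 5, 5))


class TestHypergeom:
    def test_equal_proportions_fold_one(self):
        fold, p, _ = hypergeom_enrichment(2, 10, 4, 20)
        assert fold == pytest.approx(1.0)

    def test_urn_enumeration(self):
        # urn: universe 20, 5 hits, draw 5, observe 4 -> upper tail by hand
        from math import comb

        expected = sum(
            comb(5, i) * comb(15, 5 - i) for i in range(4, 6)
        ) / comb(20, 5)
        _, p, _ = hypergeom_enrichment(4, 5, 5, 20)
        assert p == pytest.approx(expected, rel=1e-12)

    def test_bonferroni_triples_and_caps(self):
        _, p, p3 = hypergeom_enrichment(4, 5, 5, 20, n_tests=3)
        assert p3 == pytest.approx(min(1.0, 3 * p))
        _, p, p_cap = hypergeom_enrichment(1, 5, 5, 20, n_tests=50)
        assert p_cap == 1.0

    def test_empty_universe_hits_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_enrichment(0, 5, 0, 20)


class TestPlacementPermutation:
    def test_annotation_covering_workspace_gives_p_one(self):
        cfg = EnrichmentConfig(
            n_perm=50, seed=1, mode="placement", workspace={"c": 100}
        )
        query = IntervalSet([iv("c", 10, 30)])
        annotation = IntervalSet([iv("c", 0, 100)])
        res = placement_permutation(query, annotation, cfg)
        assert res.p_emp == 1.0
        assert res.perm_sd == 0.0 and res.z is None

    def test_mean_matches_exhaustive_placement_oracle(self):
        # one 10 bp segment on a 100 bp chrom: 91 equally likely starts
        annotation = IntervalSet([iv("c", 0, 10)])
        overlaps = [
            max(0, min(10, s + 10) - max(0, s)) for s in range(91)
        ]
        exact_mean = np.mean(overlaps)
        exact_sd = np.std(overlaps)
        cfg = EnrichmentConfig(
            n_perm=4000, seed=3, mode="placement", workspace={"c": 100}
        )
        res = placement_permutation(IntervalSet([iv("c", 40, 50)]), annotation, cfg)
        se = exact_sd / np.sqrt(cfg.n_perm)
        assert res.perm_mean == pytest.approx(exact_mean, abs=3 * se)

    def test_extreme_observation_hits_floor(self):
        cfg = EnrichmentConfig(
            n_perm=1000, seed=5, mode="placement", workspace={"c": 100_000}
        )
        query = IntervalSet([iv("c", 0, 50)])
        annotation = IntervalSet([iv("c", 0, 50)])
        res = placement_permutation(query, annotation, cfg)
        assert res.p_emp == pytest.approx(0.001)  # max(b,1)/1000 floor

    def test_oversized_segment_rejected(self):
        cfg = EnrichmentConfig(
            n_perm=10, seed=0, mode="placement", workspace={"c": 100}
        )
        with pytest.raises(ValueError):
            placement_permutation(
                IntervalSet([iv("c", 0, 99)]), IntervalSet([iv("c", 0, 10)]),
                EnrichmentConfig(n_perm=10, seed=0, mode="placement",
                                 workspace={"tiny": 50}),
            )

    def test_total_bp_overlap_unions_covers(self):
        query = IntervalSet([iv("c", 0, 100)])
        annotation = IntervalSet([iv("c", 0, 50), iv("c", 25, 75)])
        assert total_bp_overlap(query, annotation) == 75


class TestSelectionPermutation:
    def universe(self, n=6, hits=3):
        return IntervalSet(
            iv("c", i * 100, i * 100 + 50, id=f"u{i}") for i in range(n)
        ), lambda r: r.start // 100 < hits

    def test_moments_match_hypergeometric(self):
        universe, label = self.universe(6, 3)
        cfg = EnrichmentConfig(n_perm=4000, seed=2, universe=universe)
        query = list(universe)[:2]
        res = selection_permutation(query, label, cfg)
        # closed form: mean n*K/N = 1.0, var = n*(K/N)*(1-K/N)*(N-n)/(N-1)
        var = 2 * 0.5 * 0.5 * 4 / 5
        se = np.sqrt(var / cfg.n_perm)
        assert res.perm_mean == pytest.approx(1.0, abs=3 * se)
        assert res.perm_sd == pytest.approx(np.sqrt(var), rel=0.1)

    def test_all_labelled_universe_degenerate(self):
        universe, _ = self.universe(6, 6)
        cfg = EnrichmentConfig(n_perm=100, seed=2, universe=universe)
        res = selection_permutation(list(universe)[:3], lambda r: True, cfg)
        assert res.perm_sd == 0.0 and res.z is None
        assert res.p_emp == 1.0

    def test_planted_extreme_enrichment(self):
        universe = IntervalSet(
            iv("c", i * 100, i * 100 + 50, id=f"u{i}") for i in range(100)
        )
        label = lambda r: r.start // 100 < 10
        query = [r for r in universe if label(r)]
        cfg = EnrichmentConfig(n_perm=1000, seed=4, universe=universe)
        res = selection_permutation(query, label, cfg)
        assert res.z is not None and res.z > 0
        assert res.p_emp == pytest.approx(1 / cfg.n_perm)

    def test_universe_smaller_than_query_rejected(self):
        universe, label = self.universe(3, 1)
        cfg = EnrichmentConfig(n_perm=10, seed=0, universe=universe)
        with pytest.raises(ValueError):
            selection_permutation(
                [iv("c", i, i + 1, id=str(i)) for i in range(5)], label, cfg
            )

    def test_fixed_seed_bit_reproducible(self):
        universe, label = self.universe(10, 4)
        cfg = EnrichmentConfig(n_perm=200, seed=9, universe=universe)
        a = selection_permutation(list(universe)[:4], label, cfg)
        b = selection_permutation(list(universe)[:4], label, cfg)
        assert a == b

    def test_overlap_predicate(self):
        annotation = IntervalSet([iv("c", 100, 200)])
        pred = overlap_predicate(annotation)
        assert pred(iv("c", 150, 160)) and not pred(iv("c", 200, 210))


class TestCompareRegionProperties:
    def peak(self, length, signal, gc=0.5, start=0):
        return ScoredPeak(iv("c", start, start + length), signal, gc)

    def test_identical_sets_are_null(self):
        peaks = [self.peak(100 + i, 5 + i, 0.4, i * 1000) for i in range(6)]
        rep = compare_region_properties(peaks, list(peaks), n_perm=200, seed=1)
        assert rep["width_p"] == 1.0
        assert rep["gc_p"] == 1.0
        assert rep["signal_p"] == pytest.approx(1.0)

    def test_rank_sum_small_sample_exact(self):
        a = [self.peak(100, s) for s in (1, 2, 3)]
        b = [self.peak(100, s) for s in (4, 5, 6)]
        rep = compare_region_properties(a, b, n_perm=100, seed=1)
        assert rep["signal_p"] == pytest.approx(0.1)  # 2 * 1/C(6,3)... by enumeration

    def test_planted_width_shift_hits_floor(self):
        rng = np.random.default_rng(0)
        a = [self.peak(500 + int(rng.integers(0, 10)), 5.0, 0.5, i * 2000)
             for i in range(12)]
        b = [self.peak(700 + int(rng.integers(0, 10)), 5.0, 0.5, i * 2000)
             for i in range(12)]
        rep = compare_region_properties(a, b, n_perm=500, seed=3)
        assert rep["width_p"] == pytest.approx(1 / 500)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            compare_region_properties([], [self.peak(10, 1)], n_perm=10)
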