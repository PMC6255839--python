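"""Chain parsing and interval lifting, checked against a per-base oracle."""

import numpy as np
import pytest

from acnekit.intervals import GenomicInterval, IntervalSet
from acnekit.liftover import (
    LOW_MATCH,
    MAPPED,
    MULTIPLE,
    NOT_COVERED,
    ChainAlignment,
    ChainBlock,
    ChainParseError,
    LiftoverConfig,
    lift_interval,
    lift_set,
    parse_chain,
    write_chain,
)


def identity_chain(size=1000, name="chrA"):
    return ChainAlignment(
        score=100, t_name=name, t_size=size, t_strand="+", t_start=0,
        t_end=size, q_name=name, q_size=size, q_strand="+", q_start=0,
        q_end=size, chain_id="1", blocks=(ChainBlock(size),),
    )


def per_base_oracle(iv, chain):
    """Map every base individually; return (matched bp, + strand span)."""
    images = []
    matched = 0
    for t0, q0, size in chain.block_coords():
        for t in range(max(iv.start, t0), min(iv.end, t0 + size)):
            matched += 1
            q = q0 + (t - t0)
            if chain.q_strand == "-":
                q = chain.q_size - 1 - q
            images.append(q)
    if not images:
        return 0, None
    return matched, (min(images), max(images) + 1)


def random_chain(rng, max_blocks=5):
    n_blocks = int(rng.integers(1, max_blocks + 1))
    blocks = []
    for i in range(n_blocks):
        size = int(rng.integers(1, 51))
        if i == n_blocks - 1:
            blocks.append(ChainBlock(size))
        else:
            blocks.append(
                ChainBlock(size, int(rng.integers(0, 31)), int(rng.integers(0, 31)))
            )
    t_span = sum(b.size + b.dt for b in blocks)
    q_span = sum(b.size + b.dq for b in blocks)
    t_start = int(rng.integers(0, 200))
    q_start = int(rng.integers(0, 200))
    return ChainAlignment(
        score=float(rng.integers(1, 1000)),
        t_name="chrT", t_size=t_start + t_span + 200, t_strand="+",
        t_start=t_start, t_end=t_start + t_span,
        q_name="chrQ", q_size=q_start + q_span + 200,
        q_strand="-" if rng.random() < 0.5 else "+",
        q_start=q_start, q_end=q_start + q_span,
        chain_id="r1", blocks=tuple(blocks),
    )


class TestParseChain:
    def test_identity_chain(self, tmp_path):
        p = tmp_path / "c.chain"
        p.write_text("chain 100 chrA 1000 + 0 1000 chrA 1000 + 0 1000 1\n1000\n\n")
        (chain,) = parse_chain(p)
        assert chain.blocks == (ChainBlock(1000),)
        assert chain.t_end == 1000 and chain.q_end == 1000

    def test_span_mismatch_cites_chain(self, tmp_path):
        p = tmp_path / "bad.chain"
        p.write_text("chain 100 chrA 1000 + 0 1000 chrA 1000 + 0 1000 7\n900\n\n")
        with pytest.raises(ChainParseError, match="chain 7"):
            parse_chain(p)

    def test_gaps_survive_round_trip(self, tmp_path):
        chain = ChainAlignment(
            score=5, t_name="chrA", t_size=500, t_strand="+", t_start=0,
            t_end=110, q_name="chrB", q_size=500, q_strand="+", q_start=0,
            q_end=100, chain_id="2",
            blocks=(ChainBlock(40, 10, 0), ChainBlock(60)),
        )
        p = tmp_path / "rt.chain"
        write_chain([chain], p)
        (back,) = parse_chain(p)
        assert back == chain


class TestLiftInterval:
    def test_identity_mapping(self):
        res = lift_interval(
            GenomicInterval("chrA", 100, 200), [identity_chain()],
            LiftoverConfig(min_match=0.95),
        )
        assert res.status == MAPPED
        assert (res.mapped.start, res.mapped.end) == (100, 200)
        assert res.matched_fraction == 1.0

    def test_translation_by_1000(self):
        chain = ChainAlignment(
            score=10, t_name="chrA", t_size=2000, t_strand="+", t_start=0,
            t_end=500, q_name="chrB", q_size=5000, q_strand="+",
            q_start=1000, q_end=1500, chain_id="1", blocks=(ChainBlock(500),),
        )
        res = lift_interval(GenomicInterval("chrA", 100, 200), [chain])
        assert res.status == MAPPED
        assert (res.mapped.chrom, res.mapped.start, res.mapped.end) == (
            "chrB", 1100, 1200,
        )

    def test_min_match_threshold(self):
        # only the first 50 bp of [0, 100) sit inside an aligned block
        chain = ChainAlignment(
            score=10, t_name="chrA", t_size=1000, t_strand="+", t_start=0,
            t_end=50, q_name="chrB", q_size=1000, q_strand="+", q_start=0,
            q_end=50, chain_id="1", blocks=(ChainBlock(50),),
        )
        iv = GenomicInterval("chrA", 0, 100)
        strict = lift_interval(iv, [chain], LiftoverConfig(min_match=0.95))
        assert strict.status == LOW_MATCH
        assert strict.matched_fraction == pytest.approx(0.5)
        loose = lift_interval(iv, [chain], LiftoverConfig(min_match=0.1))
        assert loose.status == MAPPED

    def test_uncovered_interval(self):
        res = lift_interval(
            GenomicInterval("chrZ", 0, 10), [identity_chain()], LiftoverConfig()
        )
        assert res.status == NOT_COVERED

    def test_multiple_qualifying_chains_rejected_by_default(self):
        c1 = identity_chain()
        c2 = ChainAlignment(
            score=50, t_name="chrA", t_size=1000, t_strand="+", t_start=0,
            t_end=1000, q_name="chrC", q_size=1000, q_strand="+", q_start=0,
            q_end=1000, chain_id="2", blocks=(ChainBlock(1000),),
        )
        iv = GenomicInterval("chrA", 10, 60)
        assert lift_interval(iv, [c1, c2], LiftoverConfig()).status == MULTIPLE
        res = lift_interval(
            iv, [c1, c2], LiftoverConfig(allow_multiple=True)
        )
        # best score wins (c1: 100 > c2: 50)
        assert res.status == MAPPED and res.chain_id == "1"

    def test_negative_strand_query_flips_coordinates(self):
        # one block: target [0,100) -> query strand coords [0,100) on '-',
        # i.e. + strand [q_size-100, q_size)
        chain = ChainAlignment(
            score=10, t_name="chrA", t_size=500, t_strand="+", t_start=0,
            t_end=100, q_name="chrB", q_size=300, q_strand="-", q_start=0,
            q_end=100, chain_id="1", blocks=(ChainBlock(100),),
        )
        res = lift_interval(GenomicInterval("chrA", 10, 30), [chain])
        assert res.status == MAPPED
        matched, span = per_base_oracle(GenomicInterval("chrA", 10, 30), chain)
        assert (res.mapped.start, res.mapped.end) == span

    def test_matches_per_base_oracle_on_random_chains(self):
        rng = np.random.default_rng(7)
        cfg = LiftoverConfig(min_match=0.05)
        for _ in range(300):
            chain = random_chain(rng)
            lo = int(rng.integers(0, chain.t_size - 60))
            iv = GenomicInterval("chrT", lo, lo + int(rng.integers(1, 60)))
            res = lift_interval(iv, [chain], cfg)
            matched, span = per_base_oracle(iv, chain)
            if matched == 0:
                assert res.status == NOT_COVERED or res.matched_fraction == 0.0
                continue
            assert res.matched_fraction == pytest.approx(matched / iv.length)
            if res.status == MAPPED:
                assert (res.mapped.start, res.mapped.end) == span


class TestLiftSet:
    def test_counts_partition_input(self):
        chain = identity_chain()
        ivs = IntervalSet(
            [
                GenomicInterval("chrA", 0, 100, id="a"),
                GenomicInterval("chrA", 200, 300, id="b"),
                GenomicInterval("chrZ", 0, 100, id="c"),
            ]
        )
        mapped, rejections = lift_set(ivs, [chain], LiftoverConfig())
        assert len(mapped) + len(rejections) == 3
        assert {r.id for r in rejections} == {"c"}
        assert {r.status for r in rejections} == {NOT_COVERED}

    def test_mapped_count_monotone_in_min_match(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            chain = random_chain(rng)
            ivs = IntervalSet(
                GenomicInterval(
                    "chrT",
                    s := int(rng.integers(0, chain.t_size - 50)),
                    s + int(rng.integers(1, 50)),
                    id=f"iv{k}",
                )
                for k in range(10)
            )
            counts = []
            for mm in (0.95, 0.5, 0.1):
                mapped, _ = lift_set(ivs, [chain], LiftoverConfig(min_match=mm))
                counts.append(len(mapped))
            assert counts == sorted(counts)

    def test_identity_chain_is_identity_for_all(self):
        chain = identity_chain()
        ivs = IntervalSet(
            GenomicInterval("chrA", i * 10, i * 10 + 5, id=str(i))
            for i in range(20)
        )
        mapped, rejections = lift_set(ivs, [chain], LiftoverConfig(min_match=1.0))
        assert not rejections
        assert [(iv.start, iv.end) for iv in mapped] == [
            (iv.start, iv.end) for iv in ivs
        ]
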