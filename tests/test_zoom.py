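"""Region propagation through the syntenic backbone, and zoom clipping."""
import random

import pytest
from hypothesis import given, strategies as st

from synvis.exceptions import ZoomError
from synvis.fixtures import (
    FixtureSpec,
    build_truth,
    comparisons_from_truth,
    oracle_map_region,
)
from synvis.formats_io import AlignmentBlock
from synvis.model import (
    ChromosomeRecord,
    GenomeSpec,
    PairwiseComparison,
    build_chain,
)
from synvis.zoom import (
    QRY_TO_REF,
    REF_TO_QRY,
    RegionRequest,
    clip_to_selection,
    interpolate,
    map_region_step,
    propagate_region,
)


def _syn(rc, rs, re, qc, qs, qe, bid="S"):
    return AlignmentBlock(rc, rs, re, qc, qs, qe, "SYN", bid)


def _comp(blocks, ref="A", qry="B"):
    return PairwiseComparison(ref, qry, tuple(blocks))


class TestInterpolate:
    @given(st.integers(0, 500))
    def test_monotone_forward(self, off):
        s0, s1, t0, t1 = 100, 601, 1000, 2501
        a = interpolate(s0 + off, s0, s1, t0, t1)
        b = interpolate(s0 + off + 1, s0, s1, t0, t1)
        assert t0 <= a <= b <= t1

    def test_endpoints_map_to_endpoints(self):
        assert interpolate(100, 100, 200, 300, 400) == 300
        assert interpolate(200, 100, 200, 300, 400) == 400
        assert interpolate(100, 100, 200, 300, 400, inverted=True) == 400
        assert interpolate(200, 100, 200, 300, 400, inverted=True) == 300


class TestMapRegionStep:
    def test_linear_map_within_single_block(self):
        comp = _comp([_syn("c1", 100, 200, "cA", 300, 400)])
        assert map_region_step(("c1", 150, 180), comp) == ("cA", 350, 380)

    def test_identity_comparison_returns_same_interval(self):
        blocks = [_syn("c1", i * 100 + 1, (i + 1) * 100, "c1",
                       i * 100 + 1, (i + 1) * 100) for i in range(10)]
        comp = _comp(blocks)
        assert map_region_step(("c1", 42, 857), comp) == ("c1", 42, 857)

    def test_exact_block_maps_to_exact_counterpart(self):
        comp = _comp([_syn("c1", 100, 200, "cA", 300, 400)])
        assert map_region_step(("c1", 100, 200), comp) == ("cA", 300, 400)

    def test_gap_endpoint_snaps_to_nearest_overlapping_edge(self):
        comp = _comp([
            _syn("c1", 100, 200, "cA", 1100, 1200),
            _syn("c1", 300, 400, "cA", 1300, 1400),
        ])
        # right endpoint in the gap: snaps to block 1's right edge image
        assert map_region_step(("c1", 150, 250), comp) == ("cA", 1150, 1200)
        # both blocks overlapped: interior gap vanishes into the span
        assert map_region_step(("c1", 150, 350), comp) == ("cA", 1150, 1350)

    def test_no_overlap_dead_end_raises(self):
        comp = _comp([_syn("c1", 100, 200, "cA", 300, 400)])
        with pytest.raises(ZoomError, match="dead-end"):
            map_region_step(("c1", 500, 600), comp)

    def test_qry_to_ref_direction(self):
        comp = _comp([_syn("c1", 100, 200, "cA", 300, 400)])
        assert map_region_step(("cA", 350, 380), comp, QRY_TO_REF) == \
            ("c1", 150, 180)

    def test_sr_blocks_do_not_influence_mapping(self):
        syn = [_syn("c1", 1, 1000, "cA", 1, 1000)]
        srs = [AlignmentBlock("c1", 200, 300, "cA", 200, 300, t, "")
               for t in ("INV", "TRANS", "DUP")]
        with_sr = map_region_step(("c1", 100, 900), _comp(syn + srs))
        without = map_region_step(("c1", 100, 900), _comp(syn))
        assert with_sr == without

    @pytest.mark.parametrize("direction", [REF_TO_QRY, QRY_TO_REF])
    def test_agrees_with_per_base_oracle(self, direction):
        """Endpoint interpolation equals the exhaustive per-base map."""
        rng = random.Random(17)
        for seed in range(10):
            truth = build_truth(FixtureSpec(
                n_genomes=2, chroms_per_genome=2, chrom_length=8_000,
                dilation=rng.choice([1.0, 1.0, 1.5, 0.7]), seed=seed,
            ))
            comp = comparisons_from_truth(truth)[0]
            genome = truth.genomes[0 if direction == REF_TO_QRY else 1]
            for _ in range(30):
                chrom = rng.choice(genome.chromosomes)
                a = rng.randint(1, chrom.length - 5)
                b = rng.randint(a, min(chrom.length, a + 2000))
                region = (chrom.name, a, b)
                expected = oracle_map_region(region, comp.blocks, direction)
                try:
                    got = map_region_step(region, comp, direction)
                except ZoomError:
                    got = None  # dead-end <=> oracle's "no mapping"
                assert got == expected

    def test_round_trip_contains_backbone_intersection(self):
        rng = random.Random(3)
        truth = build_truth(FixtureSpec(
            n_genomes=2, chroms_per_genome=1, chrom_length=9_000, seed=8,
        ))
        comp = comparisons_from_truth(truth)[0]
        chrom = truth.genomes[0].chromosomes[0]
        for _ in range(20):
            a = rng.randint(1, chrom.length - 10)
            b = rng.randint(a, chrom.length)
            _, qa, qb = map_region_step((chrom.name, a, b), comp)
            qc = comp.blocks[0].qry_chrom
            _, ra, rb = map_region_step((qc, qa, qb), comp, QRY_TO_REF)
            covered = [
                (max(a, blk.ref_start), min(b, blk.ref_end))
                for blk in comp.blocks
                if blk.btype == "SYN" and blk.ref_start <= b and blk.ref_end >= a
            ]
            lo = min(x for x, _ in covered)
            hi = max(y for _, y in covered)
            assert ra <= lo and rb >= hi


class TestPropagateRegion:
    def _chain(self, **kw):
        truth = build_truth(FixtureSpec(**kw))
        return build_chain(truth.genomes, comparisons_from_truth(truth)), truth

    def test_identity_chain_from_middle_origin(self):
        chain, _ = self._chain(
            n_genomes=3, chroms_per_genome=1, chrom_length=10_000,
            n_inversions=0, n_translocations=0, n_duplications=0, seed=0,
        )
        sel = propagate_region(RegionRequest("g2", "chr01", 10, 20), chain)
        assert sel.intervals == {
            "g1": ("chr01", 10, 20),
            "g2": ("chr01", 10, 20),
            "g3": ("chr01", 10, 20),
        }

    def test_one_interval_per_genome(self):
        chain, _ = self._chain(n_genomes=5, chroms_per_genome=2,
                               chrom_length=50_000, seed=2)
        sel = propagate_region(RegionRequest("g1", "chr01", 100, 5000), chain)
        assert set(sel.intervals) == set(chain.genome_names)

    def test_dilation_scales_interval_width_per_hop(self):
        chain, _ = self._chain(
            n_genomes=4, chroms_per_genome=1, chrom_length=10_000,
            n_inversions=0, n_translocations=0, n_duplications=0,
            dilation=2.0, seed=0,
        )
        sel = propagate_region(RegionRequest("g1", "chr01", 1001, 2000), chain)
        widths = [
            sel.intervals[f"g{i + 1}"][2] - sel.intervals[f"g{i + 1}"][1] + 1
            for i in range(4)
        ]
        for i in range(3):
            assert widths[i + 1] / widths[i] == pytest.approx(2.0, rel=0.01)

    def test_request_beyond_chromosome_rejected(self):
        chain, _ = self._chain(n_genomes=2, chroms_per_genome=1,
                               chrom_length=10_000, seed=0)
        with pytest.raises(ZoomError, match="exceeds"):
            propagate_region(RegionRequest("g1", "chr01", 1, 99_999), chain)

    def test_unknown_genome_or_chromosome_rejected(self):
        chain, _ = self._chain(n_genomes=2, chroms_per_genome=1,
                               chrom_length=10_000, seed=0)
        with pytest.raises(Exception, match="gX"):
            propagate_region(RegionRequest("gX", "chr01", 1, 10), chain)
        with pytest.raises(ZoomError, match="chrZZ"):
            propagate_region(RegionRequest("g1", "chrZZ", 1, 10), chain)


class TestClipToSelection:
    def _setup(self, seed=5):
        truth = build_truth(FixtureSpec(
            n_genomes=3, chroms_per_genome=2, chrom_length=50_000, seed=seed,
        ))
        chain = build_chain(truth.genomes, comparisons_from_truth(truth))
        sel = propagate_region(
            RegionRequest("g1", "chr01", 5_000, 30_000), chain
        )
        return chain, sel

    def test_both_sides_rule_matches_bruteforce(self):
        """Retention equals double interval intersection on both anchors."""
        for seed in range(5):
            chain, sel = self._setup(seed)
            clipped, _, _ = clip_to_selection(chain, [], [], sel)
            for comp, kept in zip(chain.comparisons, clipped.comparisons):
                rc, rlo, rhi = sel.intervals[comp.ref_genome]
                qc, qlo, qhi = sel.intervals[comp.qry_genome]
                expected = [
                    b for b in comp.blocks
                    if (not b.ref_chrom or (b.ref_chrom == rc
                        and b.ref_start <= rhi and b.ref_end >= rlo))
                    and (not b.qry_chrom or (b.qry_chrom == qc
                         and b.qry_start <= qhi and b.qry_end >= qlo))
                ]
                got_ids = [b.source_id for b in kept.blocks]
                assert got_ids == [b.source_id for b in expected]

    def test_retained_blocks_are_clipped_to_windows(self):
        chain, sel = self._setup()
        clipped, _, _ = clip_to_selection(chain, [], [], sel)
        for comp in clipped.comparisons:
            _, rlo, rhi = sel.intervals[comp.ref_genome]
            _, qlo, qhi = sel.intervals[comp.qry_genome]
            for b in comp.blocks:
                if b.ref_chrom:
                    assert rlo <= b.ref_start <= b.ref_end <= rhi
                if b.qry_chrom:
                    assert qlo <= b.qry_start <= b.qry_end <= qhi

    def test_clipping_is_idempotent_and_monotone(self):
        chain, sel = self._setup()
        once, _, _ = clip_to_selection(chain, [], [], sel)
        twice, _, _ = clip_to_selection(once, [], [], sel)
        assert twice == once
        for full, kept in zip(chain.comparisons, once.comparisons):
            assert len(kept.blocks) <= len(full.blocks)

    def test_markers_filtered_by_genome_window(self):
        from synvis.formats_io import MarkerRecord
        chain, sel = self._setup()
        chrom, lo, hi = sel.intervals["g2"]
        inside = MarkerRecord("g2", chrom, lo + 10, lo + 10, "in")
        outside = MarkerRecord("g2", chrom, hi + 100, hi + 100, "out")
        _, markers, _ = clip_to_selection(chain, [inside, outside], [], sel)
        assert markers == [inside]

    def test_zoom_selection_insensitive_to_sr_blocks(self):
        """Adding or removing rearranged blocks never moves the windows."""
        truth = build_truth(FixtureSpec(
            n_genomes=3, chroms_per_genome=1, chrom_length=40_000, seed=9,
        ))
        chain = build_chain(truth.genomes, comparisons_from_truth(truth))
        req = RegionRequest("g1", "chr01", 2_000, 30_000)
        sel_full = propagate_region(req, chain)
        stripped = build_chain(
            chain.genomes,
            [PairwiseComparison(
                c.ref_genome, c.qry_genome,
                tuple(b for b in c.blocks if b.btype == "SYN"))
             for c in chain.comparisons],
        )
        sel_syn = propagate_region(req, stripped)
        assert sel_full.intervals == sel_syn.intervals
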