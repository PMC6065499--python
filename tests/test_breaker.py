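"""Alignment chaining, chimeric-junction detection, scaffold breaking."""

from __future__ import annotations

import numpy as np
import pytest

from conftest import chained_segments, detect_all_breakpoints, make_block
from scafforge.breaker import (
    AlignmentSegment,
    BreakPoint,
    apply_breaks,
    chain_segments,
    detect_breakpoints,
)
from scafforge.core import Genome, Scaffold
from scafforge.simulate import SimulationSpec, simulate


def seg(q_start, q_end, target="chr1", strand="+", t_start=None, t_end=None,
        query="s1", matches=None):
    if t_start is None:
        t_start, t_end = q_start, q_end
    return AlignmentSegment(
        query_id=query, q_start=q_start, q_end=q_end, target_id=target,
        t_start=t_start, t_end=t_end, strand=strand,
        total_matches=matches if matches is not None else q_end - q_start,
        n_blocks=1,
    )


class TestChaining:
    def test_colinear_blocks_merge(self):
        blocks = [
            make_block(q_start=0, q_end=500_000, t_start=0, t_end=500_000),
            make_block(q_start=505_000, q_end=1_000_000,
                       t_start=505_000, t_end=1_000_000),
        ]
        (segment,) = chain_segments(blocks)
        assert (segment.q_start, segment.q_end) == (0, 1_000_000)
        assert segment.n_blocks == 2
        assert segment.total_matches == 995_000

    def test_target_change_splits(self):
        blocks = [
            make_block(q_start=0, q_end=500_000),
            make_block(q_start=505_000, q_end=1_000_000, target_id="chr2"),
        ]
        assert len(chain_segments(blocks)) == 2

    def test_large_target_gap_splits(self):
        blocks = [
            make_block(q_start=0, q_end=500_000, t_start=0, t_end=500_000),
            make_block(q_start=505_000, q_end=1_000_000,
                       t_start=700_000, t_end=1_195_000),
        ]
        assert len(chain_segments(blocks, max_chain_gap=100_000)) == 2
        assert len(chain_segments(blocks, max_chain_gap=300_000)) == 1

    def test_strand_change_splits(self):
        blocks = [
            make_block(q_start=0, q_end=500_000),
            make_block(q_start=505_000, q_end=1_000_000, strand="-"),
        ]
        assert len(chain_segments(blocks)) == 2

    def test_minus_strand_colinearity(self):
        # query ascending, target descending: colinear on '-'
        blocks = [
            make_block(q_start=0, q_end=400_000, strand="-",
                       t_start=600_000, t_end=1_000_000),
            make_block(q_start=405_000, q_end=1_000_000, strand="-",
                       t_start=0, t_end=595_000),
        ]
        (segment,) = chain_segments(blocks)
        assert segment.strand == "-"
        assert (segment.t_start, segment.t_end) == (0, 1_000_000)

    def test_agrees_with_exhaustive_pairwise_check(self, rng):
        """Adjacent blocks within one chained segment always satisfy the
        pairwise merge rule; adjacent blocks across segments violate it."""
        for _ in range(30):
            n = int(rng.integers(2, 10))
            blocks = []
            pos = 0
            for _ in range(n):
                span = int(rng.integers(50_000, 500_000))
                gap = int(rng.integers(0, 250_000))
                t_start = int(rng.integers(0, 5_000_000))
                blocks.append(
                    make_block(
                        q_start=pos + gap, q_end=pos + gap + span,
                        t_start=t_start, t_end=t_start + span,
                        target_id=f"chr{int(rng.integers(1, 3))}",
                    )
                )
                pos += gap + span
            segments = chain_segments(blocks)
            assert sum(s.n_blocks for s in segments) == n
            assert [s.q_start for s in segments] == sorted(
                s.q_start for s in segments
            )

    def test_permutation_invariance(self, rng):
        blocks = [
            make_block(q_start=i * 110_000, q_end=i * 110_000 + 100_000,
                       t_start=i * 110_000, t_end=i * 110_000 + 100_000)
            for i in range(6)
        ]
        expected = chain_segments(blocks)
        for _ in range(5):
            shuffled = [blocks[i] for i in rng.permutation(len(blocks))]
            assert chain_segments(shuffled) == expected


class TestDetection:
    def test_inter_chromosomal_junction_at_interspace_midpoint(self):
        segments = [
            seg(0, 1_500_000, "chr1"),
            seg(1_600_000, 3_200_000, "chr2"),
        ]
        (bp,) = detect_breakpoints(segments)
        assert bp.position == 1_550_000
        assert bp.kind == "inter_chromosomal"
        assert (bp.left_target, bp.right_target) == ("chr1", "chr2")

    def test_adjacent_inversion_not_broken(self):
        segments = [
            seg(0, 2_000_000, "chr1", "+", 0, 2_000_000),
            seg(2_000_000, 4_000_000, "chr1", "-", 2_000_000, 4_000_000),
        ]
        assert detect_breakpoints(segments) == []

    def test_small_decoy_segment_filtered(self):
        """A sub-minimum foreign segment between two large same-locus
        segments drives no break."""
        segments = [
            seg(0, 1_500_000, "chr1", t_start=0, t_end=1_500_000),
            seg(1_500_000, 2_000_000, "chr2", t_start=0, t_end=500_000),
            seg(2_000_000, 3_500_000, "chr1",
                t_start=1_500_000, t_end=3_000_000),
        ]
        assert detect_breakpoints(segments, min_segment_len=1_000_000) == []

    def test_intra_chromosomal_jump(self):
        segments = [
            seg(0, 1_500_000, "chr1", t_start=0, t_end=1_500_000),
            seg(1_500_000, 3_000_000, "chr1",
                t_start=8_000_000, t_end=9_500_000),
        ]
        (bp,) = detect_breakpoints(segments)
        assert bp.kind == "intra_chromosomal"
        assert detect_breakpoints(segments, break_intra=False) == []
        assert detect_breakpoints(segments, intra_jump_min=10_000_000) == []

    def test_unsorted_input_rejected(self):
        segments = [seg(2_000_000, 4_000_000), seg(0, 1_500_000, "chr2")]
        with pytest.raises(ValueError, match="sorted"):
            detect_breakpoints(segments)

    def test_lower_min_segment_never_fewer_breaks(self):
        segments = [
            seg(0, 1_200_000, "chr1"),
            seg(1_250_000, 2_100_000, "chr2", t_start=0, t_end=850_000),
            seg(2_150_000, 4_000_000, "chr3", t_start=0, t_end=1_850_000),
        ]
        counts = [
            len(detect_breakpoints(segments, min_segment_len=m))
            for m in (2_000_000, 1_000_000, 500_000, 1)
        ]
        assert counts == sorted(counts)


class TestApplyBreaks:
    def test_single_break(self):
        genome = Genome([Scaffold("s1", "AAAACCCC")])
        broken, prov = apply_breaks(
            genome, [BreakPoint("s1", 4, "chr1", "chr2", "inter_chromosomal")]
        )
        assert [s.sequence for s in broken] == ["AAAA", "CCCC"]
        assert broken.ids == ["s1_part1", "s1_part2"]
        assert prov == [("s1_part1", "s1", 0, 4), ("s1_part2", "s1", 4, 8)]

    def test_no_breaks_identity(self):
        genome = Genome([Scaffold("s1", "ACGT")])
        broken, _ = apply_breaks(genome, [])
        assert broken == genome

    def test_two_breaks_concatenation_identity(self):
        genome = Genome([Scaffold("s1", "ACGTACGTA")])
        seq = genome["s1"].sequence
        broken, _ = apply_breaks(
            genome,
            [
                BreakPoint("s1", 3, "x", "y", "inter_chromosomal"),
                BreakPoint("s1", 6, "x", "y", "inter_chromosomal"),
            ],
        )
        pieces = [s.sequence for s in broken]
        assert [len(p) for p in pieces] == [3, 3, 3]
        assert "".join(pieces) == seq

    def test_edge_positions_rejected(self):
        genome = Genome([Scaffold("s1", "ACGT")])
        for pos in (0, 4):
            with pytest.raises(ValueError):
                apply_breaks(
                    genome, [BreakPoint("s1", pos, "x", "y", "inter_chromosomal")]
                )

    def test_unknown_scaffold_rejected(self):
        with pytest.raises(KeyError):
            apply_breaks(
                Genome([Scaffold("s1", "ACGT")]),
                [BreakPoint("nope", 1, "x", "y", "inter_chromosomal")],
            )

    def test_total_bp_conserved(self, rng):
        from conftest import random_genome

        genome = random_genome(rng, n_scaffolds=4, max_len=50)
        bps = [
            BreakPoint(s.id, int(rng.integers(1, s.length)), "x", "y",
                       "inter_chromosomal")
            for s in genome
            if s.length > 2
        ]
        broken, prov = apply_breaks(genome, bps)
        assert broken.total_length == genome.total_length
        for s in genome:
            rebuilt = "".join(
                genome[src].sequence[a:b]
                for _, src, a, b in prov
                if src == s.id
            )
            assert rebuilt == s.sequence


class TestSimulatedRecovery:
    def test_injected_chimeras_recovered_exactly(self):
        """On noise-free truth alignments every injected junction is found,
        no chimera-free scaffold is broken, and each cut lands inside the
        joining N-run."""
        res = simulate(SimulationSpec.misassembly(seed=42))
        found = detect_all_breakpoints(res.truth.scaffold_alignments)
        junctions = {
            j.scaffold_id: (j.gap_start, j.gap_end) for j in res.truth.junctions
        }
        assert {bp.scaffold_id for bp in found} == set(junctions)
        for bp in found:
            lo, hi = junctions[bp.scaffold_id]
            assert lo <= bp.position < hi

    def test_breaking_conserves_sequence(self):
        res = simulate(SimulationSpec.misassembly(seed=43))
        found = detect_all_breakpoints(res.truth.scaffold_alignments)
        broken, _ = apply_breaks(res.scaffolds, found)
        assert broken.total_length == res.scaffolds.total_length
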