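"""Windowed depth, duplication calling, boundary continuity, scenarios."""

from __future__ import annotations

import numpy as np
import pytest

from conftest import chained_segments
from scafforge.breaker import AlignmentSegment
from scafforge.depth import (
    AMBIGUOUS,
    SCENARIO_1,
    SCENARIO_2_OR_3,
    BoundaryPattern,
    DegenerateInputError,
    DuplicatedSegment,
    boundary_continuity,
    call_duplications,
    classify_rearrangement,
    estimate_reference_gap,
    evaluate_boundaries,
    profile_from_bedgraph,
    profile_from_counts,
    windowed_depth,
)
from scafforge.simulate import SimulationSpec, simulate, simulate_depth_track


def seg(query, t_start, t_end, target="chr1"):
    return AlignmentSegment(
        query_id=query, q_start=0, q_end=t_end - t_start, target_id=target,
        t_start=t_start, t_end=t_end, strand="+",
        total_matches=t_end - t_start, n_blocks=1,
    )


class TestWindowedDepth:
    def test_uniform_coverage_ratios_one(self):
        intervals = [(i * 100, i * 100 + 100) for i in range(100)]
        profile = windowed_depth(intervals, target_len=10_000, window=1000)
        assert np.allclose(profile.ratios, 1.0)

    def test_zero_median_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            windowed_depth([(0, 1000)], target_len=10_000, window=1000)

    def test_counts_match_per_base_oracle(self, rng):
        target_len, window = 5000, 700
        for _ in range(20):
            intervals = []
            for _ in range(30):
                s = int(rng.integers(0, target_len - 1))
                e = int(rng.integers(s + 1, target_len + 1))
                intervals.append((s, e))
            per_base = np.zeros(target_len)
            for s, e in intervals:
                per_base[s:e] += 1
            expected = [
                per_base[i : i + window].sum()
                for i in range(0, target_len, window)
            ]
            profile = windowed_depth(intervals, target_len, window)
            assert np.allclose(profile.counts, expected)

    def test_conservation_of_interval_bp(self, rng):
        target_len = 4000
        intervals = [
            (int(s), int(s) + int(l))
            for s, l in zip(
                rng.integers(0, 3500, size=40), rng.integers(1, 400, size=40)
            )
        ]
        profile = windowed_depth(intervals, target_len, window=512)
        clipped = sum(min(e, target_len) - max(s, 0) for s, e in intervals)
        assert profile.counts.sum() == clipped


class TestCallDuplications:
    def _profile(self, ratios, window=10_000):
        counts = np.asarray(ratios, dtype=float) * 30
        return profile_from_counts(counts, "chr1", len(ratios) * window, window)

    def test_flat_track_no_calls(self):
        assert call_duplications(self._profile([1.0] * 50)) == []

    def test_clean_block_called_exactly(self):
        ratios = [1.0] * 20 + [2.0] * 20 + [1.0] * 20
        (segment,) = call_duplications(self._profile(ratios))
        assert (segment.start, segment.end) == (200_000, 400_000)
        assert segment.mean_ratio == pytest.approx(2.0)

    def test_short_runs_discarded(self):
        ratios = [1.0] * 20 + [2.0] * 4 + [1.0] * 20
        assert call_duplications(self._profile(ratios)) == []

    def test_small_gaps_merged(self):
        ratios = [1.0] * 10 + [2.0] * 5 + [1.0] * 2 + [2.0] * 5 + [1.0] * 10
        (segment,) = call_duplications(self._profile(ratios))
        assert (segment.start, segment.end) == (100_000, 220_000)

    def test_scale_invariance(self):
        ratios = [1.0] * 20 + [2.0] * 10 + [1.0] * 20
        base = call_duplications(self._profile(ratios))
        scaled = profile_from_counts(
            np.asarray(ratios) * 12345.0, "chr1", 500_000, 10_000
        )
        assert call_duplications(scaled) == base

    def test_high_ratio_windows_excluded(self):
        """Collapsed repeats (ratio above the band) do not call as 2x."""
        ratios = [1.0] * 20 + [4.0] * 10 + [1.0] * 20
        assert call_duplications(self._profile(ratios)) == []


class TestReferenceGap:
    def test_abutting_zero(self):
        assert estimate_reference_gap(100, 100) == 0

    def test_intervening_region_arithmetic(self):
        assert estimate_reference_gap(1_000_000, 1_412_600) == 412_600

    def test_overlap_rejected(self):
        with pytest.raises(ValueError):
            estimate_reference_gap(101, 100)

    def test_simulator_truth_closes_loop(self):
        res = simulate(SimulationSpec.fm_scenario(seed=5, scenario=1))
        (sv,) = res.truth.svs
        (d1s, d1e), (d2s, d2e) = sv.dup_segments
        assert estimate_reference_gap(d1e, d2s) == sv.intervening == 412_600


class TestBoundaryContinuity:
    def test_single_scaffold_spanning(self):
        segments = [seg("sc1", 960_000, 1_040_000)]
        assert boundary_continuity(segments, boundary=1_000_000) is True

    def test_two_scaffolds_meeting_is_discontinuous(self):
        segments = [seg("sc1", 900_000, 1_000_000), seg("sc2", 1_000_000, 1_100_000)]
        assert boundary_continuity(segments, boundary=1_000_000) is False

    def test_anchor_below_minimum_not_spanning(self):
        segments = [seg("sc1", 995_000, 1_040_000)]  # 5 kb left anchor
        assert boundary_continuity(segments, boundary=1_000_000) is False

    def test_matches_bruteforce_overlap_oracle(self, rng):
        boundary, flank, min_anchor = 500_000, 50_000, 10_000
        for _ in range(30):
            segments = []
            for i in range(12):
                s = int(rng.integers(350_000, 640_000))
                e = s + int(rng.integers(2_000, 120_000))
                segments.append(seg(f"sc{int(rng.integers(0, 4))}", s, e))
            per_scaffold: dict[str, list[int]] = {}
            for sg in segments:
                left = min(sg.t_end, boundary) - max(sg.t_start, boundary - flank)
                right = min(sg.t_end, boundary + flank) - max(sg.t_start, boundary)
                acc = per_scaffold.setdefault(sg.query_id, [0, 0])
                acc[0] += max(0, left)
                acc[1] += max(0, right)
            expected = any(
                l >= min_anchor and r >= min_anchor
                for l, r in per_scaffold.values()
            )
            assert boundary_continuity(segments, boundary) == expected


class TestClassification:
    def _dups(self):
        return [
            DuplicatedSegment("chr1", 1_000_000, 1_130_000, 2.0),
            DuplicatedSegment("chr1", 1_540_000, 1_710_000, 2.0),
        ]

    def pattern(self, inner1, inner2):
        return BoundaryPattern(True, inner1, inner2, True)

    def test_both_inner_discontinuous_is_scenario_1(self):
        call = classify_rearrangement(self._dups(), self.pattern(False, False))
        assert call.scenario == SCENARIO_1
        assert call.intervening == 410_000

    @pytest.mark.parametrize("inner1, inner2", [(False, True), (True, False)])
    def test_one_sided_discontinuity_is_2_or_3(self, inner1, inner2):
        call = classify_rearrangement(self._dups(), self.pattern(inner1, inner2))
        assert call.scenario == SCENARIO_2_OR_3

    def test_both_spanned_is_ambiguous(self):
        call = classify_rearrangement(self._dups(), self.pattern(True, True))
        assert call.scenario == AMBIGUOUS

    def test_overlapping_segments_rejected(self):
        dups = [
            DuplicatedSegment("chr1", 0, 200_000, 2.0),
            DuplicatedSegment("chr1", 100_000, 300_000, 2.0),
        ]
        with pytest.raises(ValueError):
            classify_rearrangement(dups, self.pattern(False, False))

    def test_wrong_count_rejected(self):
        with pytest.raises(ValueError):
            classify_rearrangement(self._dups()[:1], self.pattern(False, False))


class TestSimulatedRecovery:
    def test_planted_segments_recovered(self):
        """Poisson 30 vs 60 planted segments recover with small boundary error."""
        planted = [(1_000_000, 1_300_000), (2_000_000, 2_150_000)]
        rows = simulate_depth_track(
            "chr1", 5_000_000, 10_000, 30.0, planted, seed=77
        )
        calls = call_duplications(profile_from_bedgraph(rows))
        for t_start, t_end in planted:
            overlapping = [
                c for c in calls if c.end > t_start and c.start < t_end
            ]
            assert overlapping
            union = (min(c.start for c in overlapping),
                     max(c.end for c in overlapping))
            assert abs(union[0] - t_start) <= 20_000
            assert abs(union[1] - t_end) <= 20_000

    @pytest.mark.parametrize("scenario", [1, 2, 3])
    def test_scenario_constructions_classified(self, scenario):
        res = simulate(SimulationSpec.fm_scenario(seed=9, scenario=scenario))
        calls = call_duplications(profile_from_bedgraph(res.depth_rows))
        assert len(calls) == 2
        d1, d2 = sorted(calls, key=lambda c: c.start)
        segments = chained_segments(res.truth.scaffold_alignments)
        pattern = evaluate_boundaries(d1, d2, segments)
        call = classify_rearrangement([d1, d2], pattern)
        assert call.scenario == (SCENARIO_1 if scenario == 1 else SCENARIO_2_OR_3)

    def test_sv_free_track_mostly_clean(self):
        clean = 0
        for s in range(10):
            rows = simulate_depth_track("chr1", 5_000_000, 10_000, 30.0, (), seed=s)
            if not call_duplications(profile_from_bedgraph(rows)):
                clean += 1
        assert clean >= 9
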