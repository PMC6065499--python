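"""Chimeric-scaffold (misassembly) detection and breaking.

Whole-genome alignment of assembly scaffolds to a trusted reference
exposes misjoins as translocation patterns: a scaffold whose large
alignment segments point at two different chromosomes (or at distant
loci on one chromosome) was almost certainly chimerically joined by the
scaffolder. Raw alignment blocks are first chained into large colinear
segments; a break point is then placed in the unaligned interspace
between adjacent segments whose targets disagree, provided both flanking
segments exceed a minimum scaffold-side span (1 Mbp by default, so that
repeat-driven stray alignments never drive a break). An orientation flip
to the same locus is a biological inversion, not necessarily a misjoin,
and is never broken.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

from .core import AlignmentBlock, Genome, Scaffold

logger = logging.getLogger(__name__)

INTER_CHROMOSOMAL = "inter_chromosomal"
INTRA_CHROMOSOMAL = "intra_chromosomal"


@dataclass(frozen=True)
class AlignmentSegment:
    """A chained run of colinear alignment blocks on one (query, target) pair."""

    query_id: str
    q_start: int
    q_end: int
    target_id: str
    t_start: int
    t_end: int
    strand: str
    total_matches: int
    n_blocks: int

    @property
    def q_span(self) -> int:
        return self.q_end - self.q_start

    @property
    def t_midpoint(self) -> float:
        return (self.t_start + self.t_end) / 2.0


@dataclass(frozen=True)
class BreakPoint:
    """A chimeric junction: the scaffold is cut between position-1 and position."""

    scaffold_id: str
    position: int
    left_target: str
    right_target: str
    kind: str


def chain_segments(
    blocks: Iterable[AlignmentBlock],
    max_chain_gap: int = 100_000,
    colinear_slop: int = 10_000,
) -> list[AlignmentSegment]:
    """Chain blocks of one query into colinear segments.

    Blocks are sorted by query start; consecutive blocks merge into one
    segment iff they share target and strand, are colinear on the target
    (the facing target gap stays within (-colinear_slop, max_chain_gap))
    and the query gap is below ``max_chain_gap``. The slop tolerates
    small target-side overlaps from jittered or fragmented alignments
    without fusing order-violating placements.
    """
    blocks = sorted(blocks, key=lambda b: (b.q_start, b.q_end, b.target_id))
    if not blocks:
        return []
    queries = {b.query_id for b in blocks}
    if len(queries) > 1:
        raise ValueError(f"chain_segments expects a single query, got {queries}")

    segments: list[AlignmentSegment] = []
    cur = list(blocks[:1])

    def flush(chunk: Sequence[AlignmentBlock]) -> None:
        segments.append(
            AlignmentSegment(
                query_id=chunk[0].query_id,
                q_start=min(b.q_start for b in chunk),
                q_end=max(b.q_end for b in chunk),
                target_id=chunk[0].target_id,
                t_start=min(b.t_start for b in chunk),
                t_end=max(b.t_end for b in chunk),
                strand=chunk[0].strand,
                total_matches=sum(b.matches for b in chunk),
                n_blocks=len(chunk),
            )
        )

    for nxt in blocks[1:]:
        prev = cur[-1]
        mergeable = nxt.target_id == prev.target_id and nxt.strand == prev.strand
        if mergeable:
            q_gap = nxt.q_start - max(b.q_end for b in cur)
            if prev.strand == "+":
                t_gap = nxt.t_start - max(b.t_end for b in cur)
            else:
                t_gap = min(b.t_start for b in cur) - nxt.t_end
            mergeable = (
                q_gap < max_chain_gap and -colinear_slop < t_gap < max_chain_gap
            )
        if mergeable:
            cur.append(nxt)
        else:
            flush(cur)
            cur = [nxt]
    flush(cur)
    segments.sort(key=lambda s: (s.q_start, s.q_end, s.target_id))
    return segments


def _facing_jump(left: AlignmentSegment, right: AlignmentSegment) -> int:
    """Target-space jump between the facing ends of two same-target segments.

    For equal strands the facing ends follow the reading direction; for a
    strand flip the jump is the separation between the two target
    intervals (zero for an adjacent inversion), so a flip alone never
    registers as a jump.
    """
    if left.strand == right.strand:
        left_face = left.t_end if left.strand == "+" else left.t_start
        right_face = right.t_start if right.strand == "+" else right.t_end
        return abs(right_face - left_face)
    return max(
        0, max(left.t_start, right.t_start) - min(left.t_end, right.t_end)
    )


def detect_breakpoints(
    segments: Sequence[AlignmentSegment],
    min_segment_len: int = 1_000_000,
    intra_jump_min: int = 2_000_000,
    break_intra: bool = True,
) -> list[BreakPoint]:
    """Find chimeric junctions between adjacent large segments of one scaffold.

    Segments spanning less than ``min_segment_len`` on the scaffold are
    discarded. For each surviving adjacent pair a break point is emitted
    when the targets differ (inter-chromosomal translocation) or, with
    ``break_intra``, when the orientation-aware target jump exceeds
    ``intra_jump_min`` (intra-chromosomal translocation). The cut is
    placed at the midpoint of the query interval between the segments.
    """
    if any(
        segments[i].q_start > segments[i + 1].q_start
        for i in range(len(segments) - 1)
    ):
        raise ValueError("segments must be sorted by q_start")
    queries = {s.query_id for s in segments}
    if len(queries) > 1:
        raise ValueError(f"detect_breakpoints expects a single scaffold, got {queries}")

    surviving = [s for s in segments if s.q_span >= min_segment_len]
    breakpoints: list[BreakPoint] = []
    for left, right in zip(surviving, surviving[1:]):
        if left.target_id != right.target_id:
            kind = INTER_CHROMOSOMAL
        elif break_intra and _facing_jump(left, right) > intra_jump_min:
            kind = INTRA_CHROMOSOMAL
        else:
            continue
        position = (left.q_end + right.q_start) // 2
        breakpoints.append(
            BreakPoint(
                scaffold_id=left.query_id,
                position=position,
                left_target=left.target_id,
                right_target=right.target_id,
                kind=kind,
            )
        )
    return breakpoints


def apply_breaks(
    genome: Genome, breakpoints: Iterable[BreakPoint]
) -> tuple[Genome, list[tuple[str, str, int, int]]]:
    """Cut scaffolds at their break points.

    A scaffold with k break points becomes pieces ``<id>_part1`` ..
    ``<id>_part<k+1>`` (left to right); untouched scaffolds keep their
    id. Returns the new genome plus a provenance table of
    (piece_id, source_id, source_start, source_end) rows whose
    concatenation identity reconstructs every source scaffold.
    """
    by_scaffold: dict[str, list[int]] = defaultdict(list)
    for bp in breakpoints:
        if bp.scaffold_id not in genome:
            raise KeyError(f"breakpoint references unknown scaffold {bp.scaffold_id!r}")
        length = genome[bp.scaffold_id].length
        if not 0 < bp.position < length:
            raise ValueError(
                f"breakpoint at {bp.position} is not interior to "
                f"{bp.scaffold_id!r} (length {length})"
            )
        by_scaffold[bp.scaffold_id].append(bp.position)

    out = Genome()
    provenance: list[tuple[str, str, int, int]] = []
    for scaffold in genome:
        positions = sorted(set(by_scaffold.get(scaffold.id, [])))
        if not positions:
            out.add(scaffold)
            provenance.append((scaffold.id, scaffold.id, 0, scaffold.length))
            continue
        bounds = [0, *positions, scaffold.length]
        for i, (start, end) in enumerate(zip(bounds, bounds[1:]), start=1):
            piece_id = f"{scaffold.id}_part{i}"
            out.add(Scaffold(piece_id, scaffold.sequence[start:end]))
            provenance.append((piece_id, scaffold.id, start, end))
    return out, provenance
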