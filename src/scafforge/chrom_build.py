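"""Chromosome-level assembly: order/orient grouped scaffolds and emit AGP.

Scaffolds assigned to a chromosome are anchored at the match-weighted
median midpoint of their alignment segments on that chromosome, oriented
by the strand carrying the majority of matched bp, and concatenated in
anchor order with a fixed-size run of Ns (100 kb by default) between
neighbours — no gap before the first or after the last component. The
accompanying AGP v2.1 table describes the construction with 1-based
inclusive coordinates and round-trips byte-for-byte against the built
sequences.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .breaker import AlignmentSegment
from .core import FormatError, Genome, Scaffold, reverse_complement
from .grouping import GroupAssignment

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PlanEntry:
    scaffold_id: str
    orientation: str  # '+' or '-'
    anchor: float  # reference bp; weighted median of segment midpoints
    anchored_weight: int  # matched bp supporting the placement


@dataclass
class ChromosomePlan:
    chromosome_id: str
    entries: list[PlanEntry]


def _weighted_median(values: Sequence[float], weights: Sequence[int]) -> float:
    """Smallest value whose cumulative weight reaches half the total."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    total = sum(weights)
    acc = 0
    for i in order:
        acc += weights[i]
        if acc * 2 >= total:
            return values[i]
    return values[order[-1]]


def order_and_orient(
    assignment: GroupAssignment,
    scaffold_to_ref: Iterable[AlignmentSegment],
) -> list[ChromosomePlan]:
    """Build per-chromosome ordering plans from placed scaffolds.

    Only segments on a scaffold's assigned chromosome count. Orientation
    is the majority strand by matched bp (tie -> '+'); entries sort by
    anchor, ties by scaffold id.
    """
    by_scaffold: dict[str, list[AlignmentSegment]] = defaultdict(list)
    for seg in scaffold_to_ref:
        by_scaffold[seg.query_id].append(seg)

    plans: dict[str, list[PlanEntry]] = defaultdict(list)
    for scaffold_id in sorted(assignment.assignments):
        placement = assignment[scaffold_id]
        if not placement.placed:
            continue
        segs = [
            s
            for s in by_scaffold.get(scaffold_id, [])
            if s.target_id == placement.chromosome
        ]
        if not segs:
            logger.warning(
                "scaffold %s has no segments on its assigned chromosome %s; dropped",
                scaffold_id, placement.chromosome,
            )
            continue
        weights = [s.total_matches for s in segs]
        anchor = _weighted_median([s.t_midpoint for s in segs], weights)
        minus = sum(w for s, w in zip(segs, weights) if s.strand == "-")
        plus = sum(weights) - minus
        orientation = "-" if minus > plus else "+"
        plans[placement.chromosome].append(
            PlanEntry(scaffold_id, orientation, anchor, sum(weights))
        )

    out = []
    for chrom in sorted(plans):
        entries = sorted(plans[chrom], key=lambda e: (e.anchor, e.scaffold_id))
        out.append(ChromosomePlan(chrom, entries))
    return out


@dataclass(frozen=True)
class AgpRow:
    """One AGP v2.1 line (1-based inclusive object coordinates)."""

    object_id: str
    object_beg: int
    object_end: int
    part_number: int
    component_type: str  # 'W' (component) or 'N' (gap)
    # W fields
    component_id: str = ""
    component_beg: int = 0
    component_end: int = 0
    orientation: str = "+"
    # N fields
    gap_length: int = 0
    gap_type: str = "scaffold"
    linkage: str = "no"
    linkage_evidence: str = "align_genus"


def build_chromosomes(
    plans: Iterable[ChromosomePlan],
    genome: Genome,
    gap_size: int = 100_000,
) -> tuple[Genome, list[AgpRow]]:
    """Materialize chromosome sequences and their AGP description.

    Each chromosome is its plan's scaffolds (reverse-complemented for
    '-' entries) joined by exactly ``gap_size`` Ns, so the chromosome
    length is sum(scaffold lengths) + gap_size * (n - 1).
    """
    chroms = Genome()
    rows: list[AgpRow] = []
    for plan in plans:
        if not plan.entries:
            logger.warning("chromosome %s has an empty plan; skipped", plan.chromosome_id)
            continue
        pieces: list[str] = []
        pos = 0  # 0-based running length
        part = 0
        for i, entry in enumerate(plan.entries):
            if entry.scaffold_id not in genome:
                raise KeyError(f"plan references unknown scaffold {entry.scaffold_id!r}")
            if i > 0:
                part += 1
                rows.append(
                    AgpRow(
                        object_id=plan.chromosome_id,
                        object_beg=pos + 1,
                        object_end=pos + gap_size,
                        part_number=part,
                        component_type="N",
                        gap_length=gap_size,
                    )
                )
                pieces.append("N" * gap_size)
                pos += gap_size
            scaffold = genome[entry.scaffold_id]
            seq = scaffold.sequence
            if entry.orientation == "-":
                seq = reverse_complement(seq)
            part += 1
            rows.append(
                AgpRow(
                    object_id=plan.chromosome_id,
                    object_beg=pos + 1,
                    object_end=pos + scaffold.length,
                    part_number=part,
                    component_type="W",
                    component_id=entry.scaffold_id,
                    component_beg=1,
                    component_end=scaffold.length,
                    orientation=entry.orientation,
                )
            )
            pieces.append(seq)
            pos += scaffold.length
        chroms.add(Scaffold(plan.chromosome_id, "".join(pieces)))
        part = 0
    return chroms, rows


def _check_consistency(rows: Sequence[AgpRow]) -> None:
    pos: dict[str, int] = {}
    parts: dict[str, int] = {}
    for row in rows:
        expected_beg = pos.get(row.object_id, 0) + 1
        if row.object_beg != expected_beg:
            raise FormatError(
                f"AGP discontinuity in {row.object_id}: part {row.part_number} "
                f"begins at {row.object_beg}, expected {expected_beg}"
            )
        expected_part = parts.get(row.object_id, 0) + 1
        if row.part_number != expected_part:
            raise FormatError(
                f"AGP part numbering broken in {row.object_id}: "
                f"{row.part_number} != {expected_part}"
            )
        span = row.object_end - row.object_beg + 1
        if row.component_type == "N" and span != row.gap_length:
            raise FormatError(f"AGP gap length mismatch in {row.object_id}")
        if row.component_type == "W" and span != row.component_end - row.component_beg + 1:
            raise FormatError(f"AGP component span mismatch in {row.object_id}")
        pos[row.object_id] = row.object_end
        parts[row.object_id] = row.part_number


def write_agp(rows: Sequence[AgpRow], path: str | Path) -> None:
    """Write an AGP v2.1 file after validating coordinate contiguity."""
    _check_consistency(rows)
    with Path(path).open("w") as fh:
        if rows:
            fh.write("##agp-version\t2.1\n")
        for r in rows:
            if r.component_type == "W":
                tail = (r.component_id, r.component_beg, r.component_end, r.orientation)
            else:
                tail = (r.gap_length, r.gap_type, r.linkage, r.linkage_evidence)
            fh.write(
                "\t".join(
                    str(v)
                    for v in (
                        r.object_id,
                        r.object_beg,
                        r.object_end,
                        r.part_number,
                        r.component_type,
                        *tail,
                    )
                )
                + "\n"
            )


def read_agp(path: str | Path) -> list[AgpRow]:
    rows: list[AgpRow] = []
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 9:
                raise FormatError(f"{path}:{lineno}: AGP rows need 9 columns")
            common = dict(
                object_id=f[0],
                object_beg=int(f[1]),
                object_end=int(f[2]),
                part_number=int(f[3]),
                component_type=f[4],
            )
            if f[4] == "W":
                rows.append(
                    AgpRow(
                        **common,
                        component_id=f[5],
                        component_beg=int(f[6]),
                        component_end=int(f[7]),
                        orientation=f[8],
                    )
                )
            elif f[4] == "N":
                rows.append(
                    AgpRow(
                        **common,
                        gap_length=int(f[5]),
                        gap_type=f[6],
                        linkage=f[7],
                        linkage_evidence=f[8],
                    )
                )
            else:
                raise FormatError(f"{path}:{lineno}: unsupported component type {f[4]!r}")
    _check_consistency(rows)
    return rows


def reconstruct_from_agp(rows: Sequence[AgpRow], genome: Genome) -> Genome:
    """Rebuild object sequences from AGP rows plus the component FASTA."""
    _check_consistency(rows)
    pieces: dict[str, list[str]] = defaultdict(list)
    order: list[str] = []
    for row in rows:
        if row.object_id not in pieces:
            order.append(row.object_id)
        if row.component_type == "N":
            pieces[row.object_id].append("N" * row.gap_length)
        else:
            seq = genome[row.component_id].sequence[
                row.component_beg - 1 : row.component_end
            ]
            if row.orientation == "-":
                seq = reverse_complement(seq)
            pieces[row.object_id].append(seq)
    return Genome(Scaffold(oid, "".join(pieces[oid])) for oid in order)
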