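"""Hierarchical bipartite grouping of reads/contigs and scaffolds to chromosomes.

Two stacked bipartite layers — elements (long reads, auxiliary contigs)
versus scaffolds, and scaffolds versus reference chromosomes — carry
alignment-weighted edges (summed residue matches). Each scaffold is
assigned to the chromosome holding the maximal upper-layer weight, and
elements inherit chromosome votes from their neighbouring scaffolds
through the lower layer. The point of the two-hop structure is repeat
robustness: a repetitive element that touches many scaffolds only
contributes where its scaffolds were confidently placed, and any
candidate whose runner-up weight is too close to the winner is abstained
on (UNPLACED) rather than forced.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .core import AlignmentBlock

UNPLACED = "UNPLACED"


class HierBipartiteGraph:
    """Two-layer weighted graph: elements <-> scaffolds <-> chromosomes.

    Multi-edges collapse by weight summation; zero-match blocks are
    ignored so every stored weight is positive.
    """

    def __init__(self) -> None:
        self._lower: dict[str, dict[str, int]] = defaultdict(lambda: defaultdict(int))
        self._upper: dict[str, dict[str, int]] = defaultdict(lambda: defaultdict(int))
        self.elements: set[str] = set()
        self.scaffolds: set[str] = set()
        self.chromosomes: set[str] = set()

    def add_lower(self, element_id: str, scaffold_id: str, weight: int) -> None:
        if weight <= 0:
            return
        self._lower[element_id][scaffold_id] += weight
        self.elements.add(element_id)
        self.scaffolds.add(scaffold_id)

    def add_upper(self, scaffold_id: str, chromosome_id: str, weight: int) -> None:
        if weight <= 0:
            return
        self._upper[scaffold_id][chromosome_id] += weight
        self.scaffolds.add(scaffold_id)
        self.chromosomes.add(chromosome_id)

    @property
    def lower(self) -> dict[tuple[str, str], int]:
        """Lower-layer edges as a flat (element, scaffold) -> weight map."""
        return {
            (e, s): w for e, sw in self._lower.items() for s, w in sw.items()
        }

    @property
    def upper(self) -> dict[tuple[str, str], int]:
        """Upper-layer edges as a flat (scaffold, chromosome) -> weight map."""
        return {
            (s, c): w for s, cw in self._upper.items() for c, w in cw.items()
        }

    def upper_weights(self, scaffold_id: str) -> dict[str, int]:
        return dict(self._upper.get(scaffold_id, {}))

    def lower_weights(self, element_id: str) -> dict[str, int]:
        return dict(self._lower.get(element_id, {}))


def build_hier_graph(
    element_to_scaffold: Iterable[AlignmentBlock],
    scaffold_to_ref: Iterable[AlignmentBlock],
) -> HierBipartiteGraph:
    """Accumulate alignment blocks into the two weighted layers."""
    graph = HierBipartiteGraph()
    for block in element_to_scaffold:
        graph.add_lower(block.query_id, block.target_id, block.matches)
    for block in scaffold_to_ref:
        graph.add_upper(block.query_id, block.target_id, block.matches)
    return graph


@dataclass(frozen=True)
class Placement:
    chromosome: str  # UNPLACED when abstained
    best_weight: int
    ambiguity_ratio: float

    @property
    def placed(self) -> bool:
        return self.chromosome != UNPLACED


@dataclass
class GroupAssignment:
    """element/scaffold id -> chromosome placement (or UNPLACED)."""

    assignments: dict[str, Placement] = field(default_factory=dict)

    def __getitem__(self, key: str) -> Placement:
        return self.assignments[key]

    def __contains__(self, key: str) -> bool:
        return key in self.assignments

    def __len__(self) -> int:
        return len(self.assignments)

    def placed_ids(self) -> list[str]:
        return [k for k, v in self.assignments.items() if v.placed]

    def unplaced_ids(self) -> list[str]:
        return [k for k, v in self.assignments.items() if not v.placed]


def _argmax_with_abstention(
    weights: Mapping[str, int], ambiguity_max: float
) -> Placement:
    """Max-weight candidate with a runner-up ratio test.

    Abstains (UNPLACED) on empty candidates, exact ties, and whenever
    second_best / best exceeds ``ambiguity_max``.
    """
    if not weights:
        return Placement(UNPLACED, 0, 0.0)
    ranked = sorted(weights.items(), key=lambda kv: (-kv[1], kv[0]))
    best_id, best_w = ranked[0]
    second_w = ranked[1][1] if len(ranked) > 1 else 0
    ratio = second_w / best_w
    if second_w == best_w or ratio > ambiguity_max:
        return Placement(UNPLACED, best_w, ratio)
    return Placement(best_id, best_w, ratio)


def assign_scaffold_groups(
    graph: HierBipartiteGraph, ambiguity_max: float = 0.5
) -> GroupAssignment:
    """Assign every scaffold in the graph to its best-supported chromosome."""
    assignment = GroupAssignment()
    for scaffold_id in sorted(graph.scaffolds):
        assignment.assignments[scaffold_id] = _argmax_with_abstention(
            graph.upper_weights(scaffold_id), ambiguity_max
        )
    return assignment


def propagate_read_groups(
    graph: HierBipartiteGraph,
    scaffold_assignment: GroupAssignment,
    ambiguity_max: float = 0.5,
) -> GroupAssignment:
    """Propagate scaffold placements down to elements through the lower layer.

    An element's candidate chromosomes are the placements of its
    neighbouring scaffolds, each weighted by the element-to-scaffold
    matched bp summed per chromosome; UNPLACED scaffolds contribute
    nothing.
    """
    assignment = GroupAssignment()
    for element_id in sorted(graph.elements):
        votes: dict[str, int] = defaultdict(int)
        for scaffold_id, weight in graph.lower_weights(element_id).items():
            if scaffold_id not in scaffold_assignment:
                raise KeyError(
                    f"scaffold {scaffold_id!r} missing from scaffold assignment"
                )
            placement = scaffold_assignment[scaffold_id]
            if placement.placed:
                votes[placement.chromosome] += weight
        assignment.assignments[element_id] = _argmax_with_abstention(
            votes, ambiguity_max
        )
    return assignment
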