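"""Assembly statistics: Nx/NGx lengths, pseudo-contigs and summary reports.

A *pseudo-contig* is a scaffold piece obtained by splitting at every run
of two or more consecutive Ns; single Ns are retained inside pieces.
N50 is the length L such that sequences of length >= L cover half the
assembly; NG50 replaces the assembly total with an assumed genome size.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Sequence

from .core import Genome, Scaffold

logger = logging.getLogger(__name__)


def nx_length(lengths: Iterable[int], x: float) -> int:
    """Nx statistic: the largest L with sum(lengths >= L) >= x% of the total.

    Computed as the length at which the descending cumulative sum first
    reaches x% of the total.
    """
    lens = sorted(lengths, reverse=True)
    if not lens:
        raise ValueError("nx_length requires a non-empty length collection")
    if not 0 < x <= 100:
        raise ValueError("x must be in (0, 100]")
    if any(l <= 0 for l in lens):
        raise ValueError("all lengths must be positive")
    total = sum(lens)
    acc = 0
    for l in lens:
        acc += l
        # acc >= (x/100) * total, kept in integer-exact form
        if acc * 100 >= x * total:
            return l
    return lens[-1]  # unreachable: acc == total >= threshold


def ngx_length(lengths: Iterable[int], genome_size: int, x: float) -> int:
    """NGx statistic: like Nx but thresholded at x% of ``genome_size``.

    Returns 0 (with a warning) when the assembly never reaches the
    threshold, so reports on partial assemblies still render.
    """
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    lens = sorted(lengths, reverse=True)
    if not lens:
        raise ValueError("ngx_length requires a non-empty length collection")
    if any(l <= 0 for l in lens):
        raise ValueError("all lengths must be positive")
    acc = 0
    for l in lens:
        acc += l
        if acc * 100 >= x * genome_size:
            return l
    logger.warning(
        "assembly total %d never reaches %.1f%% of genome size %d; NGx = 0",
        acc, x, genome_size,
    )
    return 0


def pseudo_contigs(scaffold: Scaffold, min_n_run: int = 2) -> list[str]:
    """Split a scaffold at every maximal N-run of length >= ``min_n_run``.

    Leading/trailing runs yield no empty pieces; shorter N-runs are kept
    inside pieces. Concatenating the pieces with the removed runs
    reconstructs the scaffold.
    """
    if min_n_run < 1:
        raise ValueError("min_n_run must be >= 1")
    pattern = re.compile("N{%d,}" % min_n_run)
    return [piece for piece in pattern.split(scaffold.sequence) if piece]


@dataclass(frozen=True)
class AssemblyReport:
    """Flat summary of assembly statistics (all lengths in bp)."""

    n_scaffolds: int
    total_bp: int
    n50: int
    ng50: int
    n_pseudo_contigs: int
    pseudo_contig_n50: int
    pseudo_contig_ng50: int
    gap_fraction: float
    mean_length: float
    genome_size_used: int

    def as_dict(self) -> dict[str, float | int]:
        return {
            "n_scaffolds": self.n_scaffolds,
            "total_bp": self.total_bp,
            "n50": self.n50,
            "ng50": self.ng50,
            "n_pseudo_contigs": self.n_pseudo_contigs,
            "pseudo_contig_n50": self.pseudo_contig_n50,
            "pseudo_contig_ng50": self.pseudo_contig_ng50,
            "gap_fraction": self.gap_fraction,
            "mean_length": self.mean_length,
            "genome_size_used": self.genome_size_used,
        }


def assembly_report(
    genome: Genome, genome_size: int, min_n_run: int = 2
) -> AssemblyReport:
    """Compute scaffold and pseudo-contig statistics for ``genome``.

    ``gap_fraction`` counts every N base (including single Ns that do
    not split pseudo-contigs) over the assembly total. ``mean_length``
    is the arithmetic mean scaffold length.
    """
    if len(genome) == 0:
        raise ValueError("cannot report on an empty genome")
    scaffold_lens = [s.length for s in genome]
    total_bp = sum(scaffold_lens)
    pieces: list[int] = []
    total_n = 0
    for s in genome:
        total_n += s.sequence.count("N")
        pieces.extend(len(p) for p in pseudo_contigs(s, min_n_run=min_n_run))
    return AssemblyReport(
        n_scaffolds=len(genome),
        total_bp=total_bp,
        n50=nx_length(scaffold_lens, 50),
        ng50=ngx_length(scaffold_lens, genome_size, 50),
        n_pseudo_contigs=len(pieces),
        pseudo_contig_n50=nx_length(pieces, 50),
        pseudo_contig_ng50=ngx_length(pieces, genome_size, 50),
        gap_fraction=total_n / total_bp,
        mean_length=total_bp / len(genome),
        genome_size_used=genome_size,
    )
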