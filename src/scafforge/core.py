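"""Core domain types: scaffolds, genomes, gap runs, and pairwise alignment blocks.

All coordinates in this package are 0-based half-open unless a format
dictates otherwise (AGP output is 1-based inclusive, per its spec).
Sequences are uppercase strings over the alphabet {A, C, G, T, N}; IUPAC
ambiguity codes are collapsed to N at ingestion time.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# any uppercase character that is not A/C/G/T/N becomes N
_NON_ACGTN = re.compile(r"[^ACGTN]")


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


def reverse_complement(seq: str) -> str:
    """Reverse complement of an {A,C,G,T,N} sequence (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_sequence(raw: str) -> tuple[str, int]:
    """Uppercase ``raw`` and collapse non-ACGTN characters to N.

    Returns the normalized sequence and the number of substituted
    (non-N ambiguity) characters.
    """
    seq = raw.upper()
    n_before = seq.count("N")
    cleaned = _NON_ACGTN.sub("N", seq)
    n_substituted = cleaned.count("N") - n_before
    return cleaned, n_substituted


@dataclass(frozen=True)
class Scaffold:
    """A named assembled sequence, possibly containing N-gap runs."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("scaffold id must be non-empty")
        if not self.sequence:
            raise ValueError(f"scaffold {self.id!r} has an empty sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)


class Genome:
    """An ordered, id-indexed collection of scaffolds.

    Iteration order is the insertion order, so round trips through FASTA
    are byte-stable.
    """

    def __init__(self, scaffolds: Iterable[Scaffold] = ()) -> None:
        self._scaffolds: dict[str, Scaffold] = {}
        for s in scaffolds:
            self.add(s)

    def add(self, scaffold: Scaffold) -> None:
        if scaffold.id in self._scaffolds:
            raise FormatError(f"duplicate scaffold id {scaffold.id!r}")
        self._scaffolds[scaffold.id] = scaffold

    def __iter__(self) -> Iterator[Scaffold]:
        return iter(self._scaffolds.values())

    def __len__(self) -> int:
        return len(self._scaffolds)

    def __contains__(self, scaffold_id: str) -> bool:
        return scaffold_id in self._scaffolds

    def __getitem__(self, scaffold_id: str) -> Scaffold:
        return self._scaffolds[scaffold_id]

    @property
    def ids(self) -> list[str]:
        return list(self._scaffolds)

    @property
    def total_length(self) -> int:
        return sum(s.length for s in self)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Genome):
            return NotImplemented
        return [(s.id, s.sequence) for s in self] == [(s.id, s.sequence) for s in other]


@dataclass(frozen=True)
class GapRun:
    """A maximal run of Ns inside one scaffold, 0-based half-open."""

    scaffold_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid gap run [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


_N_RUN = re.compile(r"N+")


def find_gap_runs(scaffold: Scaffold, min_run: int = 1) -> list[GapRun]:
    """All maximal N-runs of length >= ``min_run``, sorted by start."""
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    return [
        GapRun(scaffold.id, m.start(), m.end())
        for m in _N_RUN.finditer(scaffold.sequence)
        if m.end() - m.start() >= min_run
    ]


@dataclass(frozen=True)
class AlignmentBlock:
    """One pairwise alignment record (the 12 mandatory PAF columns)."""

    query_id: str
    query_len: int
    q_start: int
    q_end: int
    strand: str
    target_id: str
    target_len: int
    t_start: int
    t_end: int
    matches: int
    block_len: int
    mapq: int = 60

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")
        if not (0 <= self.q_start < self.q_end <= self.query_len):
            raise ValueError(
                f"invalid query interval [{self.q_start}, {self.q_end}) "
                f"for {self.query_id!r} (len {self.query_len})"
            )
        if not (0 <= self.t_start < self.t_end <= self.target_len):
            raise ValueError(
                f"invalid target interval [{self.t_start}, {self.t_end}) "
                f"for {self.target_id!r} (len {self.target_len})"
            )
        if self.matches > self.block_len:
            raise ValueError("matches cannot exceed block length")
        if not (0 <= self.mapq <= 255):
            raise ValueError(f"mapq {self.mapq} out of range 0-255")

    @property
    def q_span(self) -> int:
        return self.q_end - self.q_start

    @property
    def t_span(self) -> int:
        return self.t_end - self.t_start
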