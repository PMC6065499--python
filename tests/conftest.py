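"""Shared fixtures and helpers for the scafforge test suite."""

from __future__ import annotations

from collections import defaultdict

import numpy as np
import pytest

from scafforge.breaker import AlignmentSegment, chain_segments, detect_breakpoints
from scafforge.core import AlignmentBlock, Genome, Scaffold


def random_genome(rng: np.random.Generator, n_scaffolds: int = 5,
                  max_len: int = 200, gap_prob: float = 0.1) -> Genome:
    """Small random genome over {A,C,G,T,N} for round-trip/property tests."""
    alphabet = np.array(list("ACGT"))
    genome = Genome()
    for i in range(n_scaffolds):
        length = int(rng.integers(1, max_len + 1))
        bases = alphabet[rng.integers(0, 4, size=length)]
        mask = rng.random(length) < gap_prob
        bases[mask] = "N"
        seq = "".join(bases)
        if set(seq) == {"N"}:
            seq = "A" + seq  # all-N scaffolds are legal FASTA but dull
        genome.add(Scaffold(f"s{i}", seq))
    return genome


def chained_segments(blocks: list[AlignmentBlock], **kwargs) -> list[AlignmentSegment]:
    """Chain blocks per query and concatenate the segments."""
    by_query: dict[str, list[AlignmentBlock]] = defaultdict(list)
    for b in blocks:
        by_query[b.query_id].append(b)
    out: list[AlignmentSegment] = []
    for q in sorted(by_query):
        out.extend(chain_segments(by_query[q], **kwargs))
    return out


def detect_all_breakpoints(blocks: list[AlignmentBlock], **kwargs):
    """Chain per query, then detect break points per scaffold."""
    by_query: dict[str, list[AlignmentBlock]] = defaultdict(list)
    for b in blocks:
        by_query[b.query_id].append(b)
    found = []
    for q in sorted(by_query):
        found.extend(detect_breakpoints(chain_segments(by_query[q]), **kwargs))
    return found


def make_block(
    query_id="s1",
    query_len=10_000_000,
    q_start=0,
    q_end=1_000_000,
    strand="+",
    target_id="chr1",
    target_len=50_000_000,
    t_start=0,
    t_end=1_000_000,
    matches=None,
    block_len=None,
    mapq=60,
) -> AlignmentBlock:
    span = q_end - q_start
    return AlignmentBlock(
        query_id, query_len, q_start, q_end, strand, target_id, target_len,
        t_start, t_end,
        span if matches is None else matches,
        span if block_len is None else block_len,
        mapq,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
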