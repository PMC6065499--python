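"""Readers and writers for the plain-text formats the toolkit consumes.

FASTA parsing goes through Biopython's SeqIO; the PAF (12 mandatory
minimap2 columns), BED3 and bedGraph readers are line oriented so that
format errors can name the offending line.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

from .core import AlignmentBlock, FormatError, Genome, Scaffold, normalize_sequence

logger = logging.getLogger(__name__)


def read_fasta(path: str | Path) -> Genome:
    """Read a (multi-line) FASTA file into a Genome.

    Sequences are uppercased; lowercase and IUPAC ambiguity codes other
    than N are collapsed to N, with the substitution count logged.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    genome = Genome()
    n_substituted = 0
    for record in SeqIO.parse(str(path), "fasta"):
        seq, subs = normalize_sequence(str(record.seq))
        n_substituted += subs
        if not seq:
            raise FormatError(f"empty record {record.id!r} in {path}")
        genome.add(Scaffold(record.id, seq))
    if n_substituted:
        logger.warning(
            "%s: %d ambiguity characters collapsed to N", path, n_substituted
        )
    return genome


def write_fasta(genome: Genome, path: str | Path, line_width: int = 60) -> None:
    """Write ``genome`` as FASTA wrapped at ``line_width`` columns."""
    if line_width < 1:
        raise ValueError("line_width must be >= 1")
    path = Path(path)
    with path.open("w") as fh:
        for scaffold in genome:
            fh.write(f">{scaffold.id}\n")
            seq = scaffold.sequence
            for i in range(0, len(seq), line_width):
                fh.write(seq[i : i + line_width])
                fh.write("\n")


_PAF_COLUMNS = 12


def parse_alignment_table(
    path: str | Path, min_mapq: int = 0
) -> list[AlignmentBlock]:
    """Parse a PAF-style table (>=12 tab-separated columns) into blocks.

    Blocks with mapq below ``min_mapq`` are dropped (count logged);
    optional SAM-style tags after column 12 are ignored.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"alignment table not found: {path}")
    blocks: list[AlignmentBlock] = []
    dropped = 0
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < _PAF_COLUMNS:
                raise FormatError(
                    f"{path}:{lineno}: expected >= {_PAF_COLUMNS} columns, "
                    f"found {len(fields)}"
                )
            try:
                block = AlignmentBlock(
                    query_id=fields[0],
                    query_len=int(fields[1]),
                    q_start=int(fields[2]),
                    q_end=int(fields[3]),
                    strand=fields[4],
                    target_id=fields[5],
                    target_len=int(fields[6]),
                    t_start=int(fields[7]),
                    t_end=int(fields[8]),
                    matches=int(fields[9]),
                    block_len=int(fields[10]),
                    mapq=int(fields[11]),
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if block.mapq < min_mapq:
                dropped += 1
                continue
            blocks.append(block)
    if dropped:
        logger.info("%s: dropped %d blocks with mapq < %d", path, dropped, min_mapq)
    return blocks


def write_alignment_table(
    blocks: Iterable[AlignmentBlock], path: str | Path
) -> None:
    """Write blocks as 12-column PAF."""
    with Path(path).open("w") as fh:
        for b in blocks:
            fh.write(
                "\t".join(
                    str(v)
                    for v in (
                        b.query_id,
                        b.query_len,
                        b.q_start,
                        b.q_end,
                        b.strand,
                        b.target_id,
                        b.target_len,
                        b.t_start,
                        b.t_end,
                        b.matches,
                        b.block_len,
                        b.mapq,
                    )
                )
                + "\n"
            )


def read_bed3(path: str | Path) -> list[tuple[str, int, int]]:
    """Read a 3+ column BED file as (chrom, start, end) tuples."""
    path = Path(path)
    out: list[tuple[str, int, int]] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: BED needs >= 3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if start < 0 or end <= start:
                raise FormatError(f"{path}:{lineno}: invalid interval [{start}, {end})")
            out.append((fields[0], start, end))
    return out


def read_bedgraph(path: str | Path) -> list[tuple[str, int, int, float]]:
    """Read a 4-column bedGraph as (chrom, start, end, value) tuples."""
    path = Path(path)
    out: list[tuple[str, int, int, float]] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"{path}:{lineno}: bedGraph needs 4 columns")
            try:
                start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if start < 0 or end <= start:
                raise FormatError(f"{path}:{lineno}: invalid interval [{start}, {end})")
            out.append((fields[0], start, end, value))
    return out


def write_bedgraph(
    rows: Iterable[tuple[str, int, int, float]], path: str | Path
) -> None:
    with Path(path).open("w") as fh:
        for chrom, start, end, value in rows:
            v = int(value) if float(value).is_integer() else value
            fh.write(f"{chrom}\t{start}\t{end}\t{v}\n")
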