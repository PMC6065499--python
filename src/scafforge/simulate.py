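"""Seeded simulator: reference genomes, rearranged samples, scaffold
assemblies with injected chimeric misjoins, truth alignments and Poisson
depth tracks.

Truth alignments are emitted directly from the construction bookkeeping
instead of running an aligner, which makes every downstream contract
exactly testable; an optional jitter perturbs block boundaries by a
bounded amount to exercise robustness. Reads are interval placements
(id plus coordinates), not base-accurate sequences, because the grouping
stage consumes alignment evidence only.

The built-in presets encode the three study conditions the test-suite
and acceptance checks run under:

* ``misassembly`` — several ~12 Mbp chromosomes fragmented into >=1.5 Mbp
  pieces, a handful of which are joined across chromosomes through an
  N-gap run (the chimeras the breaker must find);
* ``grouping`` — a small multi-chromosome genome, ~200 kbp scaffolds and
  ~10 kbp read placements with a configurable decoy-alignment fraction;
* ``fm_scenario`` — a single chromosome carrying a two-locus inverted
  duplication in one of three arrangements, with duplicated loci of
  130 / 170 kbp separated by the 412.6 kbp intervening region reported
  for the fibromelanosis locus, scaffolds that break at rearrangement
  junctions (the regime of an assembly whose scaffold N50 dwarfs the
  locus), and a deep Poisson depth track doubled inside the duplicated
  loci.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .core import AlignmentBlock, Genome, Scaffold, reverse_complement
from .io import write_alignment_table, write_bedgraph, write_fasta

SCENARIO_KINDS = ("scenario_1", "scenario_2", "scenario_3")
SV_KINDS = ("inverted_duplication", "inversion", "deletion", "insertion") + SCENARIO_KINDS

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SVSpec:
    """One engineered structural variant.

    ``start``/``end`` delimit the (first) affected region; scenario
    kinds use ``start2``/``end2`` for the second duplicated locus;
    ``insert_at`` places the inverted copy for ``inverted_duplication``;
    ``size`` is the novel length for ``insertion``.
    """

    kind: str
    chromosome: str
    start: int
    end: int
    start2: int | None = None
    end2: int | None = None
    insert_at: int | None = None
    size: int | None = None

    def footprint(self) -> tuple[int, int]:
        if self.kind in SCENARIO_KINDS:
            return self.start, self.end2  # type: ignore[return-value]
        if self.kind == "inverted_duplication":
            return self.start, self.insert_at  # type: ignore[return-value]
        if self.kind == "insertion":
            return self.start, self.start
        return self.start, self.end

    def validate(self, chrom_len: int) -> None:
        if self.kind not in SV_KINDS:
            raise ValueError(f"unknown SV kind {self.kind!r}")
        if self.kind in SCENARIO_KINDS:
            if None in (self.start2, self.end2):
                raise ValueError(f"{self.kind} needs start2/end2")
            if not 0 <= self.start < self.end < self.start2 < self.end2 <= chrom_len:
                raise ValueError(f"{self.kind} coordinates out of order or bounds")
        elif self.kind == "inverted_duplication":
            if self.insert_at is None:
                raise ValueError("inverted_duplication needs insert_at")
            if not 0 <= self.start < self.end <= self.insert_at <= chrom_len:
                raise ValueError("inverted_duplication coordinates invalid")
        elif self.kind == "insertion":
            if not self.size or self.size <= 0:
                raise ValueError("insertion needs a positive size")
            if not 0 <= self.start <= chrom_len:
                raise ValueError("insertion position out of bounds")
        else:
            if not 0 <= self.start < self.end <= chrom_len:
                raise ValueError(f"{self.kind} coordinates invalid")


@dataclass
class SimulationSpec:
    """All knobs of one simulation; a fixed seed gives byte-identical outputs."""

    seed: int = 0
    chromosome_lengths: tuple[int, ...] = (12_000_000,) * 4
    gc: float = 0.42
    svs: tuple[SVSpec, ...] = ()
    mean_fragment: int = 3_000_000
    gap_run: int = 5_000
    internal_gap_prob: float = 0.3
    chimera_count: int = 0
    break_at_sv_junctions: bool = False
    read_fold: float = 0.0
    read_length: int = 10_000
    decoy_fraction: float = 0.0
    decoy_weight: float = 0.1
    jitter: int = 0
    depth_base_mean: float = 30.0
    depth_window: int = 10_000

    # --- study-condition presets -------------------------------------
    @classmethod
    def misassembly(
        cls, seed: int, chimera_count: int = 5, jitter: int = 0
    ) -> "SimulationSpec":
        """Inter-chromosomal chimera fixture: fragments >= 1.5 Mbp."""
        return cls(
            seed=seed,
            chromosome_lengths=(12_000_000,) * 4,
            mean_fragment=3_000_000,
            chimera_count=chimera_count,
            internal_gap_prob=0.3,
            jitter=jitter,
        )

    @classmethod
    def grouping(cls, seed: int, decoy_fraction: float = 0.1) -> "SimulationSpec":
        """Read/scaffold chromosome-grouping fixture with decoy edges."""
        return cls(
            seed=seed,
            chromosome_lengths=(2_000_000, 2_000_000, 2_000_000),
            mean_fragment=200_000,
            internal_gap_prob=0.0,
            read_fold=2.0,
            read_length=10_000,
            decoy_fraction=decoy_fraction,
        )

    @classmethod
    def fm_scenario(cls, seed: int, scenario: int) -> "SimulationSpec":
        """Two-locus inverted-duplication fixture (130/170 kbp loci,
        412.6 kbp intervening region) on one 4 Mbp chromosome."""
        if scenario not in (1, 2, 3):
            raise ValueError("scenario must be 1, 2 or 3")
        sv = SVSpec(
            kind=f"scenario_{scenario}",
            chromosome="chr1",
            start=1_500_000,
            end=1_630_000,
            start2=2_042_600,
            end2=2_212_600,
        )
        return cls(
            seed=seed,
            chromosome_lengths=(4_000_000,),
            svs=(sv,),
            mean_fragment=20_000_000,
            internal_gap_prob=0.0,
            break_at_sv_junctions=True,
            depth_base_mean=400.0,
        )


# ---------------------------------------------------------------------------
# reference and rearranged sample


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    cdf = np.cumsum(p)
    draws = np.searchsorted(cdf, rng.random(length), side="right")
    return _BASES[draws].tobytes().decode("ascii")


def make_reference(spec: SimulationSpec) -> Genome:
    """Random i.i.d. reference genome at the requested GC content."""
    if not 0 < spec.gc < 1:
        raise ValueError("gc must be in (0, 1)")
    if any(l < 10_000 for l in spec.chromosome_lengths):
        raise ValueError("chromosome lengths must be >= 10 kbp")
    rng = np.random.default_rng([spec.seed, 0])
    return Genome(
        Scaffold(f"chr{i + 1}", _random_sequence(rng, length, spec.gc))
        for i, length in enumerate(spec.chromosome_lengths)
    )


@dataclass(frozen=True)
class SourceBlock:
    """One building block of a sample chromosome, in reference coordinates.

    ``chrom is None`` marks novel inserted sequence carried in ``seq``.
    """

    chrom: str | None
    start: int
    end: int
    strand: str = "+"
    seq: str | None = None

    @property
    def length(self) -> int:
        return len(self.seq) if self.chrom is None else self.end - self.start


@dataclass(frozen=True)
class SVTruth:
    """Ground truth recorded for one applied rearrangement."""

    kind: str
    chromosome: str
    dup_segments: tuple[tuple[int, int], ...]  # reference coordinates
    intervening: int | None
    scenario: str | None


def _sv_pattern(sv: SVSpec, rng: np.random.Generator, gc: float) -> list[SourceBlock]:
    c = sv.chromosome
    if sv.kind == "inversion":
        return [SourceBlock(c, sv.start, sv.end, "-")]
    if sv.kind == "deletion":
        return []
    if sv.kind == "insertion":
        return [SourceBlock(None, 0, 0, "+", _random_sequence(rng, sv.size, gc))]
    if sv.kind == "inverted_duplication":
        return [
            SourceBlock(c, sv.start, sv.insert_at, "+"),
            SourceBlock(c, sv.start, sv.end, "-"),
        ]
    u1, v1, u2, v2 = sv.start, sv.end, sv.start2, sv.end2
    d1p, d1m = SourceBlock(c, u1, v1, "+"), SourceBlock(c, u1, v1, "-")
    d2p, d2m = SourceBlock(c, u2, v2, "+"), SourceBlock(c, u2, v2, "-")
    ip, im = SourceBlock(c, v1, u2, "+"), SourceBlock(c, v1, u2, "-")
    if sv.kind == "scenario_1":
        # inverted copy of the joined loci at the proximal flank, with the
        # intervening region additionally inverted: both inner reference
        # adjacencies are destroyed.
        return [d1p, d2m, d1m, im, d2p]
    if sv.kind == "scenario_2":
        # inverted copy abutting the proximal flank only.
        return [d1p, d2m, d1m, ip, d2p]
    # scenario_3: inverted copy abutting the distal flank only.
    return [d1p, ip, d2m, d1m, d2p]


def _sv_truth(sv: SVSpec) -> SVTruth:
    if sv.kind in SCENARIO_KINDS:
        return SVTruth(
            kind=sv.kind,
            chromosome=sv.chromosome,
            dup_segments=((sv.start, sv.end), (sv.start2, sv.end2)),
            intervening=sv.start2 - sv.end,
            scenario=sv.kind.removeprefix("scenario_"),
        )
    if sv.kind == "inverted_duplication":
        return SVTruth(
            kind=sv.kind,
            chromosome=sv.chromosome,
            dup_segments=((sv.start, sv.end),),
            intervening=sv.insert_at - sv.end,
            scenario=None,
        )
    return SVTruth(sv.kind, sv.chromosome, (), None, None)


def _render_blocks(blocks: Sequence[SourceBlock], reference: Genome) -> str:
    parts = []
    for b in blocks:
        if b.chrom is None:
            parts.append(b.seq)
        else:
            seq = reference[b.chrom].sequence[b.start : b.end]
            parts.append(reverse_complement(seq) if b.strand == "-" else seq)
    return "".join(parts)


def apply_rearrangements(
    reference: Genome, svs: Sequence[SVSpec], seed: int = 0, gc: float = 0.42
) -> tuple[Genome, list[SVTruth], dict[str, list[SourceBlock]]]:
    """Apply non-overlapping SVs to a reference, returning the sample
    genome, per-SV truth, and each sample chromosome's block decomposition."""
    rng = np.random.default_rng([seed, 7])
    by_chrom: dict[str, list[SVSpec]] = {}
    for sv in svs:
        if sv.chromosome not in reference:
            raise ValueError(f"SV references unknown chromosome {sv.chromosome!r}")
        sv.validate(reference[sv.chromosome].length)
        by_chrom.setdefault(sv.chromosome, []).append(sv)

    truths: list[SVTruth] = []
    blocks: dict[str, list[SourceBlock]] = {}
    sample = Genome()
    for chrom in reference:
        chrom_svs = sorted(by_chrom.get(chrom.id, []), key=lambda s: s.footprint())
        for a, b in zip(chrom_svs, chrom_svs[1:]):
            if a.footprint()[1] > b.footprint()[0]:
                raise ValueError(
                    f"overlapping SV footprints on {chrom.id}: "
                    f"{a.footprint()} and {b.footprint()}"
                )
        chain: list[SourceBlock] = []
        pos = 0
        for sv in chrom_svs:
            fs, fe = sv.footprint()
            if fs > pos:
                chain.append(SourceBlock(chrom.id, pos, fs, "+"))
            chain.extend(_sv_pattern(sv, rng, gc))
            truths.append(_sv_truth(sv))
            pos = fe
        if pos < chrom.length:
            chain.append(SourceBlock(chrom.id, pos, chrom.length, "+"))
        chain = [b for b in chain if b.length > 0]
        blocks[chrom.id] = chain
        sample.add(Scaffold(chrom.id, _render_blocks(chain, reference)))
    return sample, truths, blocks


def apply_rearrangement(
    reference: Genome, sv: SVSpec, seed: int = 0
) -> tuple[Genome, SVTruth]:
    """Single-SV convenience wrapper around :func:`apply_rearrangements`."""
    sample, truths, _ = apply_rearrangements(reference, [sv], seed=seed)
    return sample, truths[0]


# ---------------------------------------------------------------------------
# fragmentation into scaffolds, with injected chimeras and N-gap runs


@dataclass(frozen=True)
class ScaffoldPiece:
    """A run of scaffold bases: either sample sequence or an injected N-gap."""

    kind: str  # "seq" or "gap"
    chrom: str | None  # sample chromosome for "seq" pieces
    start: int  # sample coordinates, 0 for gaps
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ChimericJunction:
    scaffold_id: str
    gap_start: int  # scaffold coordinates of the joining N-run
    gap_end: int
    left_chrom: str
    right_chrom: str


@dataclass
class TruthTable:
    """Everything the simulator knows that the pipeline must rediscover."""

    sample_blocks: dict[str, list[SourceBlock]] = field(default_factory=dict)
    svs: list[SVTruth] = field(default_factory=list)
    scaffold_pieces: dict[str, list[ScaffoldPiece]] = field(default_factory=dict)
    scaffold_alignments: list[AlignmentBlock] = field(default_factory=list)
    junctions: list[ChimericJunction] = field(default_factory=list)
    read_alignments: list[AlignmentBlock] = field(default_factory=list)
    read_truth: dict[str, tuple[str, str]] = field(default_factory=dict)

    def scaffold_true_chroms(self, scaffold_id: str) -> set[str]:
        return {
            p.chrom
            for p in self.scaffold_pieces[scaffold_id]
            if p.kind == "seq" and p.chrom is not None
        }


def _reference_adjacent(a: SourceBlock, b: SourceBlock) -> bool:
    if a.chrom is None or b.chrom is None or a.chrom != b.chrom:
        return False
    if a.strand != b.strand:
        return False
    return a.end == b.start if a.strand == "+" else a.start == b.end


def _junction_offsets(chain: Sequence[SourceBlock]) -> list[int]:
    offsets = []
    pos = 0
    for a, b in zip(chain, chain[1:]):
        pos += a.length
        if not _reference_adjacent(a, b):
            offsets.append(pos)
    return offsets


def _cut_positions(
    rng: np.random.Generator, length: int, mean_fragment: int
) -> list[int]:
    lo, hi = mean_fragment // 2, mean_fragment * 3 // 2
    cuts: list[int] = []
    pos = 0
    while True:
        pos += int(rng.integers(lo, hi + 1))
        if pos > length - lo:
            break
        cuts.append(pos)
    return cuts


def _map_sample_interval(
    chain: Sequence[SourceBlock], s: int, e: int
) -> list[tuple[str | None, int, int, str]]:
    """Decompose sample interval [s, e) into reference blocks, in sample order."""
    out = []
    offset = 0
    for b in chain:
        lo, hi = offset, offset + b.length
        offset = hi
        if hi <= s or lo >= e:
            continue
        rel_s, rel_e = max(s, lo) - lo, min(e, hi) - lo
        if b.chrom is None:
            out.append((None, rel_s, rel_e, "+"))
        elif b.strand == "+":
            out.append((b.chrom, b.start + rel_s, b.start + rel_e, "+"))
        else:
            out.append((b.chrom, b.end - rel_e, b.end - rel_s, "-"))
    return out


def fragment_into_scaffolds(
    genome: Genome,
    spec: SimulationSpec,
    blocks: dict[str, list[SourceBlock]] | None = None,
    reference: Genome | None = None,
) -> tuple[Genome, TruthTable]:
    """Cut sample chromosomes into scaffolds with exact truth alignments.

    ``chimera_count`` pairs of fragments from different chromosomes are
    joined through an N-run of ``spec.gap_run`` (junction recorded);
    ordinary fragments may receive one internal N-run. With
    ``break_at_sv_junctions`` every novel (non-reference) block junction
    also becomes a cut, emulating an assembler that cannot resolve
    rearrangement break points.
    """
    rng = np.random.default_rng([spec.seed, 1])
    if blocks is None:
        blocks = {
            c.id: [SourceBlock(c.id, 0, c.length, "+")] for c in genome
        }
    if reference is None:
        reference = genome
    ref_lens = {c.id: c.length for c in reference}

    fragments: list[tuple[str, int, int]] = []  # (sample chrom, start, end)
    for chrom in genome:
        cuts = set(_cut_positions(rng, chrom.length, spec.mean_fragment))
        if spec.break_at_sv_junctions:
            cuts.update(_junction_offsets(blocks[chrom.id]))
        bounds = [0, *sorted(c for c in cuts if 0 < c < chrom.length), chrom.length]
        fragments.extend(
            (chrom.id, s, e) for s, e in zip(bounds, bounds[1:]) if e > s
        )

    order = rng.permutation(len(fragments))
    pool = [fragments[i] for i in order]

    # pair off chimeras greedily from the shuffled pool
    chimera_pairs: list[tuple[tuple[str, int, int], tuple[str, int, int]]] = []
    for _ in range(spec.chimera_count):
        mate = None
        if pool:
            first = pool.pop(0)
            mate = next((f for f in pool if f[0] != first[0]), None)
        if mate is None:
            raise ValueError(
                f"cannot inject {spec.chimera_count} chimeras from "
                f"{len(fragments)} fragments"
            )
        pool.remove(mate)
        chimera_pairs.append((first, mate))

    truth = TruthTable(sample_blocks=dict(blocks))
    scaffolds = Genome()
    counter = 0

    def next_id() -> str:
        nonlocal counter
        counter += 1
        return f"scaffold_{counter}"

    def emit(pieces: list[ScaffoldPiece], seqs: list[str]) -> str:
        sid = next_id()
        scaffolds.add(Scaffold(sid, "".join(seqs)))
        truth.scaffold_pieces[sid] = pieces
        return sid

    for (ca, sa, ea), (cb, sb, eb) in chimera_pairs:
        gap = "N" * spec.gap_run
        pieces = [
            ScaffoldPiece("seq", ca, sa, ea),
            ScaffoldPiece("gap", None, 0, spec.gap_run),
            ScaffoldPiece("seq", cb, sb, eb),
        ]
        sid = emit(
            pieces,
            [genome[ca].sequence[sa:ea], gap, genome[cb].sequence[sb:eb]],
        )
        truth.junctions.append(
            ChimericJunction(sid, ea - sa, ea - sa + spec.gap_run, ca, cb)
        )

    for chrom_id, s, e in pool:
        seq = genome[chrom_id].sequence[s:e]
        margin = max(spec.gap_run, 10_000)
        if (
            spec.internal_gap_prob > 0
            and e - s > 4 * margin
            and rng.random() < spec.internal_gap_prob
        ):
            split = s + int(rng.integers(margin, e - s - margin))
            pieces = [
                ScaffoldPiece("seq", chrom_id, s, split),
                ScaffoldPiece("gap", None, 0, spec.gap_run),
                ScaffoldPiece("seq", chrom_id, split, e),
            ]
            emit(
                pieces,
                [
                    genome[chrom_id].sequence[s:split],
                    "N" * spec.gap_run,
                    genome[chrom_id].sequence[split:e],
                ],
            )
        else:
            emit([ScaffoldPiece("seq", chrom_id, s, e)], [seq])

    truth.scaffold_alignments = _truth_alignments(
        scaffolds, truth, blocks, ref_lens, spec.jitter, rng
    )
    if spec.decoy_fraction > 0 and len(ref_lens) > 1:
        truth.scaffold_alignments.extend(
            _scaffold_decoys(scaffolds, truth, ref_lens, spec, rng)
        )
    return scaffolds, truth


def _scaffold_decoys(
    scaffolds: Genome,
    truth: TruthTable,
    ref_lens: dict[str, int],
    spec: SimulationSpec,
    rng: np.random.Generator,
) -> list[AlignmentBlock]:
    """Low-weight repeat-style decoy alignments to a wrong chromosome."""
    out: list[AlignmentBlock] = []
    for scaffold in scaffolds:
        if rng.random() >= spec.decoy_fraction:
            continue
        true_chroms = truth.scaffold_true_chroms(scaffold.id)
        others = sorted(
            c
            for c, l in ref_lens.items()
            if c not in true_chroms and l >= scaffold.length
        )
        if not others:
            continue
        chrom = others[int(rng.integers(0, len(others)))]
        start = int(rng.integers(0, ref_lens[chrom] - scaffold.length + 1))
        out.append(
            AlignmentBlock(
                query_id=scaffold.id,
                query_len=scaffold.length,
                q_start=0,
                q_end=scaffold.length,
                strand="+",
                target_id=chrom,
                target_len=ref_lens[chrom],
                t_start=start,
                t_end=start + scaffold.length,
                matches=max(1, int(spec.decoy_weight * scaffold.length)),
                block_len=scaffold.length,
                mapq=30,
            )
        )
    return out


def _truth_alignments(
    scaffolds: Genome,
    truth: TruthTable,
    blocks: dict[str, list[SourceBlock]],
    ref_lens: dict[str, int],
    jitter: int,
    rng: np.random.Generator,
) -> list[AlignmentBlock]:
    out: list[AlignmentBlock] = []
    for scaffold in scaffolds:
        qlen = scaffold.length
        qpos = 0
        for piece in truth.scaffold_pieces[scaffold.id]:
            if piece.kind == "gap":
                qpos += piece.length
                continue
            for chrom, ts, te, strand in _map_sample_interval(
                blocks[piece.chrom], piece.start, piece.end
            ):
                span = te - ts
                if chrom is None:  # novel insertion: unaligned
                    qpos += span
                    continue
                qs, qe = qpos, qpos + span
                tlen = ref_lens[chrom]
                if jitter > 0:
                    d1 = int(rng.integers(-jitter, jitter + 1))
                    d2 = int(rng.integers(-jitter, jitter + 1))
                    nqs, nqe = qs + d1, qe + d2
                    if strand == "+":
                        nts, nte = ts + d1, te + d2
                    else:
                        nts, nte = ts - d2, te - d1
                    if 0 <= nqs < nqe <= qlen and 0 <= nts < nte <= tlen:
                        qs, qe, ts, te = nqs, nqe, nts, nte
                out.append(
                    AlignmentBlock(
                        query_id=scaffold.id,
                        query_len=qlen,
                        q_start=qs,
                        q_end=qe,
                        strand=strand,
                        target_id=chrom,
                        target_len=tlen,
                        t_start=ts,
                        t_end=te,
                        matches=qe - qs,
                        block_len=qe - qs,
                        mapq=60,
                    )
                )
                qpos += span
    return out


# ---------------------------------------------------------------------------
# reads and depth


def simulate_reads(
    scaffolds: Genome, spec: SimulationSpec, truth: TruthTable | None = None
) -> tuple[dict[str, tuple[str, str]], list[AlignmentBlock]]:
    """Place reads uniformly on scaffolds; emit truth read->scaffold PAF.

    Returns (read_truth, blocks) where read_truth maps read id to its
    source (scaffold id, true chromosome). A ``decoy_fraction`` of reads
    receives a second, low-weight alignment to a random other scaffold.
    """
    rng = np.random.default_rng([spec.seed, 2])
    eligible = [s for s in scaffolds if s.length >= spec.read_length]
    if not eligible:
        raise ValueError("no scaffold is at least one read length long")
    lengths = np.array([s.length for s in eligible], dtype=float)
    n_reads = int(round(spec.read_fold * lengths.sum() / spec.read_length))
    weights = lengths / lengths.sum()

    read_truth: dict[str, tuple[str, str]] = {}
    out: list[AlignmentBlock] = []
    choices = rng.choice(len(eligible), size=n_reads, p=weights)
    for i, scaffold_idx in enumerate(choices):
        scaffold = eligible[int(scaffold_idx)]
        start = int(rng.integers(0, scaffold.length - spec.read_length + 1))
        read_id = f"read_{i + 1:06d}"
        chrom = _true_chrom(truth, scaffold.id, start + spec.read_length // 2)
        read_truth[read_id] = (scaffold.id, chrom)
        out.append(
            AlignmentBlock(
                query_id=read_id,
                query_len=spec.read_length,
                q_start=0,
                q_end=spec.read_length,
                strand="+",
                target_id=scaffold.id,
                target_len=scaffold.length,
                t_start=start,
                t_end=start + spec.read_length,
                matches=spec.read_length,
                block_len=spec.read_length,
                mapq=60,
            )
        )
        if len(eligible) > 1 and rng.random() < spec.decoy_fraction:
            other = eligible[
                int((scaffold_idx + 1 + rng.integers(0, len(eligible) - 1)) % len(eligible))
            ]
            dlen = min(spec.read_length, other.length)
            dstart = int(rng.integers(0, other.length - dlen + 1))
            out.append(
                AlignmentBlock(
                    query_id=read_id,
                    query_len=spec.read_length,
                    q_start=0,
                    q_end=dlen,
                    strand="+",
                    target_id=other.id,
                    target_len=other.length,
                    t_start=dstart,
                    t_end=dstart + dlen,
                    matches=max(1, int(spec.decoy_weight * spec.read_length)),
                    block_len=dlen,
                    mapq=30,
                )
            )
    return read_truth, out


def _true_chrom(truth: TruthTable | None, scaffold_id: str, pos: int) -> str:
    if truth is None or scaffold_id not in truth.scaffold_pieces:
        return scaffold_id
    offset = 0
    fallback = ""
    for piece in truth.scaffold_pieces[scaffold_id]:
        if piece.kind == "seq" and piece.chrom is not None:
            fallback = fallback or piece.chrom
            if offset <= pos < offset + piece.length:
                return piece.chrom
        offset += piece.length
    return fallback


def simulate_depth_track(
    target_id: str,
    target_len: int,
    window: int,
    base_mean: float,
    dup_segments: Sequence[tuple[int, int]] = (),
    seed: int = 0,
) -> list[tuple[str, int, int, float]]:
    """Poisson per-window depth, doubled inside planted segments.

    Windows partially overlapping a planted segment get a mean scaled by
    1 + overlap fraction. Returns bedGraph rows tiling [0, target_len).
    """
    if base_mean <= 0:
        raise ValueError("base_mean must be positive")
    rng = np.random.default_rng([seed, 3])
    n_windows = -(-target_len // window)
    means = np.full(n_windows, float(base_mean))
    for s, e in dup_segments:
        for i in range(s // window, -(-e // window)):
            ws, we = i * window, min((i + 1) * window, target_len)
            overlap = max(0, min(e, we) - max(s, ws))
            means[i] += base_mean * overlap / (we - ws)
    counts = rng.poisson(means)
    return [
        (target_id, i * window, min((i + 1) * window, target_len), float(counts[i]))
        for i in range(n_windows)
    ]


# ---------------------------------------------------------------------------
# orchestration


@dataclass
class SimulationResult:
    spec: SimulationSpec
    reference: Genome
    sample: Genome
    scaffolds: Genome
    truth: TruthTable
    depth_rows: list[tuple[str, int, int, float]]
    depth_target: str


def simulate(spec: SimulationSpec, outdir: str | Path | None = None) -> SimulationResult:
    """Run the full generator and optionally write all fixture files."""
    reference = make_reference(spec)
    sample, sv_truths, blocks = apply_rearrangements(
        reference, spec.svs, seed=spec.seed, gc=spec.gc
    )
    scaffolds, truth = fragment_into_scaffolds(
        sample, spec, blocks=blocks, reference=reference
    )
    truth.svs = sv_truths
    if spec.read_fold > 0:
        truth.read_truth, truth.read_alignments = simulate_reads(
            scaffolds, spec, truth
        )

    dup_segments: list[tuple[int, int]] = []
    depth_target = next(iter(reference)).id
    for sv in sv_truths:
        if sv.dup_segments:
            depth_target = sv.chromosome
            dup_segments.extend(sv.dup_segments)
    depth_rows = simulate_depth_track(
        depth_target,
        reference[depth_target].length,
        spec.depth_window,
        spec.depth_base_mean,
        dup_segments,
        seed=spec.seed,
    )

    result = SimulationResult(
        spec, reference, sample, scaffolds, truth, depth_rows, depth_target
    )
    if outdir is not None:
        _write_fixture(result, Path(outdir))
    return result


def _write_fixture(result: SimulationResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(result.reference, outdir / "reference.fa")
    write_fasta(result.sample, outdir / "sample.fa")
    write_fasta(result.scaffolds, outdir / "scaffolds.fa")
    write_alignment_table(
        result.truth.scaffold_alignments, outdir / "scaffolds_vs_ref.paf"
    )
    write_alignment_table(
        result.truth.read_alignments, outdir / "reads_vs_scaffolds.paf"
    )
    write_bedgraph(result.depth_rows, outdir / "depth.bedgraph")
    truth = result.truth
    payload = {
        "depth_target": result.depth_target,
        "svs": [
            {
                "kind": sv.kind,
                "chromosome": sv.chromosome,
                "dup_segments": [list(d) for d in sv.dup_segments],
                "intervening": sv.intervening,
                "scenario": sv.scenario,
            }
            for sv in truth.svs
        ],
        "junctions": [
            {
                "scaffold_id": j.scaffold_id,
                "gap_start": j.gap_start,
                "gap_end": j.gap_end,
                "left_chrom": j.left_chrom,
                "right_chrom": j.right_chrom,
            }
            for j in truth.junctions
        ],
        "scaffold_chroms": {
            sid: sorted(truth.scaffold_true_chroms(sid))
            for sid in truth.scaffold_pieces
        },
        "read_truth": {
            rid: {"scaffold": s, "chromosome": c}
            for rid, (s, c) in truth.read_truth.items()
        },
    }
    (outdir / "truth.json").write_text(json.dumps(payload, indent=1, sort_keys=True))
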