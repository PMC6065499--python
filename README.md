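# scafforge

Reference-assisted scaffolding and assembly-analysis toolkit for hybrid
whole-genome assemblies.

When a draft assembly (short-read contigs scaffolded with long reads and
mate pairs) is aligned against a trusted reference genome of a close
relative, several otherwise-hard problems become tractable:

* **Misassembly breaking** — a chimeric scaffold that erroneously joins
  two genomic loci shows up as a translocation pattern in the
  whole-genome alignment: adjacent multi-megabase alignment segments
  pointing at different chromosomes. `scafforge` chains raw alignment
  blocks into segments, requires each flanking segment to span at least
  1 Mbp of the scaffold, and cuts the scaffold in the unaligned
  interspace between them.
* **Chromosome grouping** — scaffolds, long reads and auxiliary contigs
  are assigned to reference chromosomes through a *hierarchical
  bipartite graph* (elements ↔ scaffolds ↔ chromosomes) with
  alignment-weighted edges, abstaining (`UNPLACED`) whenever the
  runner-up chromosome is too close to the winner; the two-hop
  structure damps the influence of repetitive sequence.
* **Chromosome building** — grouped scaffolds are ordered by the
  match-weighted median of their alignment positions, oriented by
  majority strand, and concatenated with fixed 100 kbp N-gaps into
  chromosome-level sequences, described by an AGP v2.1 file that
  round-trips byte-for-byte.
* **Assembly QC** — N50/NG50, pseudo-contig statistics (scaffold pieces
  split at runs of ≥ 2 Ns) and gap fractions.
* **Duplication analysis** — large segmental duplications appear as
  doubled read depth when sample reads are collapsed onto a single-copy
  reference. `scafforge` calls such 2× segments from a windowed,
  median-normalized depth track, estimates the intervening distance
  between two duplicated loci (the fibromelanosis-locus situation in
  hyperpigmented chicken breeds), tests scaffold continuity at the
  duplication boundaries, and classifies the rearrangement:
  discontinuity at *both* inner boundaries supports a one-step
  arrangement (scenario 1), at exactly one inner boundary the
  composite arrangements (reported jointly as `2_or_3`).

A fully deterministic simulator (`scafforge simulate`) generates
reference genomes, rearranged samples, fragmented scaffold assemblies
with injected chimeras, exact truth alignments (no aligner needed),
read placements and Poisson depth tracks, so that every stage is
testable offline.

## Core definitions

For scaffold lengths `L₁ ≥ L₂ ≥ …` and assembly total `T`:
`N50 = Lᵢ` at the smallest `i` with `Σ_{j≤i} Lⱼ ≥ T/2`; `NG50`
substitutes an assumed genome size `G` for `T`. A *pseudo-contig* is a
maximal scaffold substring containing no run of ≥ 2 Ns. Depth ratios
are per-window overlap counts divided by the genome-wide median window
count; windows with ratio in `[1.75, 2.5]` seed duplication calls,
which are run-merged, length-filtered and boundary-refined by a
max-sum changepoint sweep.

## Worked example

Simulate a genome carrying a two-locus inverted duplication
(scenario 1: 130 kb and 170 kb loci, 412.6 kb apart), call the doubled
segments, and classify the rearrangement:

```bash
scafforge simulate --preset scenario1 --seed 2 --outdir fix/
scafforge dupcall  --depth fix/depth.bedgraph --out dups.bed
scafforge classify --dups dups.bed --paf fix/scaffolds_vs_ref.paf --out call.tsv
```

`dups.bed` (window-aligned 2× segments; column 4 is the mean depth
ratio):

```
chr1	1500000	1630000	2.0391
chr1	2040000	2210000	1.9825
```

Both planted loci are recovered at their true coordinates to within one
10 kb window, each at a mean ratio of ~2.0. `call.tsv`:

```
target	scenario	intervening	dup1_start	dup1_end	dup2_start	dup2_end	dup1_left_spanned	dup1_right_spanned	dup2_left_spanned	dup2_right_spanned
chr1	1	410000	1500000	1630000	2040000	2210000	true	false	false	true
```

Reading the continuity flags: scaffolds run across both *outer*
boundaries but across neither *inner* boundary — the
both-sides-discontinuous signature — so the call is scenario 1, with
the intervening region estimated at 410 kb (truth: 412.6 kb, window
quantization accounts for the difference).

The misassembly stage works the same way from files:

```bash
scafforge simulate --preset misassembly --seed 1 --outdir mfix/
scafforge break --fasta mfix/scaffolds.fa --paf mfix/scaffolds_vs_ref.paf \
                --out broken.fa --breakpoints breaks.tsv
```

which, for this seed, detects all 5 injected inter-chromosomal chimeric
junctions (`breaks.tsv`), each cut placed inside the joining N-gap run,
and breaks nothing else.

## Layout

```
src/scafforge/
  core.py        domain types (Scaffold, Genome, GapRun, AlignmentBlock)
  io.py          FASTA / PAF / BED / bedGraph readers and writers
  qc.py          Nx/NGx, pseudo-contigs, assembly reports
  breaker.py     alignment chaining, chimera detection, scaffold breaking
  grouping.py    hierarchical bipartite grouping to chromosomes
  chrom_build.py ordering/orientation, chromosome FASTA + AGP
  depth.py       windowed depth, 2x segment calling, scenario classification
  simulate.py    deterministic fixture generator with exact truth
  cli.py         `scafforge` command-line interface
```

See `docs/methods.md` for the models, parameter choices and known
limitations.
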