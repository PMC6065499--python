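# Methods

This note records the models behind each `scafforge` stage, the
parameters that matter, what the simulator does and does not emulate,
and the numerical choices made where the design was genuinely open.

## Coordinates and formats

All internal coordinates are 0-based half-open. Alignments are ingested
as 12-column PAF only (any aligner output can be converted to it);
optional tag columns are ignored. AGP output is 1-based inclusive, per
that format's convention. Sequences are normalized to {A,C,G,T,N} at
ingestion: lowercase is uppercased and IUPAC ambiguity codes collapse
to N with a logged count — assemblies routinely contain a few, and
rejecting them would be hostile for no analytical gain.

## Assembly statistics

`nx_length` returns the length at which the descending cumulative sum
first reaches x % of the assembly total; the threshold comparison is
kept in integer form (`acc * 100 >= x * total`) so exact ties at a
length boundary resolve identically to a rational-arithmetic oracle.
When an assembly never reaches the NGx threshold the statistic is 0
with a warning rather than an error, so partial assemblies still
report. Pseudo-contigs split at runs of ≥ 2 Ns (the `min_n_run=2`
default); single Ns are retained inside pieces, and the gap fraction
counts *every* N over the assembly total. The report's "mean length"
is the arithmetic mean and is labelled as such.

## Misassembly breaking

Raw blocks of one scaffold are sorted by query start and chained:
consecutive blocks merge iff they share target and strand, the query
gap is < `max_chain_gap` (100 kb default — wide enough to bridge
within-scaffold N-gaps and alignment fragmentation, narrow enough not
to fuse distinct loci), and the facing target gap lies in
`(-colinear_slop, max_chain_gap)` with `colinear_slop` = 10 kb. The
negative slop tolerates small target-side overlaps produced by
jittered or locally ambiguous alignments while still rejecting
order-violating placements.

Break detection keeps only segments spanning ≥ `min_segment_len`
(1 Mbp) **on the scaffold axis** — the scaffold is the object being
judged, and the size filter is what prevents repeat-driven stray
alignments from driving cuts. Adjacent surviving segments trigger a
break when their targets differ (inter-chromosomal translocation), or
— when `break_intra` is set — when the orientation-aware jump between
their facing target ends exceeds `intra_jump_min` (2 Mbp, safely above
any chainable gap). For a strand flip the jump is measured as the
separation of the two target intervals, which is zero for an adjacent
inversion: an orientation flip to the same locus is a biological
inversion, not evidence of a misjoin, and alone never breaks anything.
The cut position is the midpoint of the inter-segment query interval
(or of the overlap, the same formula) — symmetric, deterministic, and
guaranteed to fall in the unaligned interspace, which in practice is
the scaffolder's joining N-run. Breaking replaces a scaffold with
`<id>_part<i>` pieces whose concatenation reproduces it exactly.

## Chromosome grouping

Edge weights are summed residue matches — proportional to alignable
sequence and insensitive to how an aligner fragments a region into
blocks (block counts and identity fractions are not). Scaffolds take
the chromosome with maximal upper-layer weight; elements inherit
chromosome votes from their neighbouring *placed* scaffolds, weighted
by lower-layer matches. Both layers abstain (`UNPLACED`) on exact ties
and whenever `second_best / best > ambiguity_max` (default 0.5): for a
repeat-dominated element, forcing a choice would be wrong half the
time, and abstention is recoverable downstream. Propagation is a
single two-hop pass — no iterative refinement, so the result is
order-independent and trivially deterministic (candidates are also
ranked lexicographically on ties of the sort key before the tie rule
abstains).

## Chromosome building

Each placed scaffold is anchored at the match-weighted median of its
segment midpoints on its assigned chromosome — a robust statistic that
one stray segment cannot move — and oriented by the strand carrying
the majority of matched bp (ties orient '+'). Entries sort by anchor,
then scaffold id. Chromosomes are scaffolds joined by exactly
`gap_size` Ns (100 kbp default), no terminal gaps, so the length
identity `Σ lengths + gap_size × (n − 1)` always holds. Overlapping
anchors are kept in anchor order without trimming — this stage spaces
components, it does not merge them. AGP gap rows use component type
`N`, gap type `scaffold`, linkage `no`, evidence `align_genus`
(reference-guided placement); reconstruction from AGP plus the
component FASTA is byte-identical to the built sequences, which the
tests enforce.

## Depth analysis and rearrangement classification

Windowed counts are overlap-bp per window; ratios divide by the
genome-wide **median** window count, which the duplication's own
inflation cannot skew (a mean could). A zero median is a degenerate
input and raises.

Calling marks windows with ratio in `[min_ratio, max_ratio]` =
`[1.75, 2.5]` — a symmetric band around the 2× expectation whose upper
bound keeps higher-order collapsed repeats out — merges marked runs
across ≤ 2 unmarked windows, and discards runs spanning < 5 windows.
At realistic per-window counts this band is deliberately conservative:
with Poisson counts of mean 60 against a baseline of 30, an individual
truly-duplicated window falls inside the band only ~81 % of the time,
so raw runs erode at their edges and occasionally fracture. The final
step therefore refines each surviving run's boundaries with a max-sum
changepoint sweep: windows score `ratio − 1.5` (the midpoint between
single-copy and duplicated expectations), windows above `max_ratio`
score `max_ratio − ratio` so collapsed repeats stop the sweep, and
each boundary moves outward to the extension maximizing the cumulative
score (never past a neighbouring run; runs that meet are merged). In
simulation this recovers both planted segments to within 2 windows in
498/500 seeds while leaving flat tracks call-free in 200/200 — the
sweep can only extend from an already-accepted run, so specificity is
unchanged. `refine=False` restores the raw band-run behaviour.

Boundary continuity asks whether any *single* scaffold holds
≥ `min_anchor` (10 kb) aligned bp within both `flank` (50 kb) windows
around a boundary. The anchor must exceed typical alignment-block
fragmentation; the flank must be small enough that "the same scaffold"
means "locally continuous". Classification evaluates the two *inner*
boundaries of an ordered two-locus duplication: both discontinuous →
scenario 1; exactly one → `2_or_3`; neither → ambiguous. Scenarios 2
and 3 are reported jointly because depth plus continuity cannot
distinguish which flank carries the extra inversion — that requires
oriented discordant-pair evidence, which is out of scope. The full
four-boundary pattern is always reported alongside the verdict.

### Scenario geometry

The two-locus constructions used by the simulator follow from a simple
adjacency argument. Write the reference locus as
`A · D1 · I · D2 · B` (D1/D2 the duplicated loci, I the intervening
region). Inserting an inverted copy of the joined unit `rc(D1·D2)`
anywhere destroys **at most one** of the two inner reference
adjacencies (`D1|I` and `I|D2`), because an insertion cuts the
original chain in exactly one place. Hence:

* insertion at the proximal flank (`A·D1·rc(D2)·rc(D1)·I·D2·B`)
  leaves `I|D2` intact → discontinuity at the D1-side inner boundary
  only (scenario 2);
* insertion at the distal flank (`A·D1·I·rc(D2)·rc(D1)·D2·B`) leaves
  `D1|I` intact → discontinuity at the D2-side inner boundary only
  (scenario 3);
* the both-sides-discontinuous pattern is geometrically impossible for
  a bare insertion and requires the intervening region's orientation
  to flip as part of the event
  (`A·D1·rc(D2)·rc(D1)·rc(I)·D2·B`, scenario 1).

All three add `|D1| + |D2|` bp, double exactly the two loci, and keep
I single copy. The classifier itself is construction-agnostic: it only
consumes the continuity pattern.

## The simulator

The generator is the package's study-conditions oracle: it emits the
truth directly (alignments, junction positions, duplicated segments,
read origins) instead of running an aligner, so downstream contracts
are exact; an optional jitter perturbs alignment block boundaries by a
bounded amount (±1 kb in the tests) to exercise robustness. Reads are
interval placements, not base-accurate sequences — the grouping stage
consumes alignment evidence only, so an error model would add cost
without testing anything.

Preset study conditions (chosen once, as realistic desk-scale
versions of the regimes each stage targets):

* `misassembly` — four 12 Mbp chromosomes at GC 0.42, fragments
  uniform in [1.5, 4.5] Mbp (mean 3 Mbp, three times the breaker's
  size filter so injected junctions are detectable), five
  inter-chromosomal chimeric joins through 5 kb N-runs, ~30 % of
  ordinary scaffolds carrying one internal N-run to exercise chaining
  across gaps.
* `grouping` — three 2 Mbp chromosomes, ~200 kbp scaffolds, 10 kbp
  read placements at 2× fold, 10 % decoy edges carrying 10 % of the
  element's matches (the ≥ 90 %-to-true-location regime the abstention
  rule is designed for).
* `fm_scenario` — one 4 Mbp chromosome carrying a 130 kb and a 170 kb
  duplicated locus separated by the 412.6 kb intervening distance
  characteristic of the fibromelanosis-locus duplication; depth tracks
  at 10 kb windows with per-window Poisson mean 400 (doubled inside
  the loci), reflecting deep short-read coverage; scaffolds break
  deterministically at every novel (non-reference-adjacent) block
  junction plus rare random cuts (mean fragment far above the locus
  size) — the regime of an assembly whose scaffold N50 dwarfs the
  locus, where discontinuities mark unresolvable duplication
  junctions rather than chance scaffold ends.

What the simulator does **not** emulate: sequencing errors and
alignment noise beyond boundary jitter, mapping ambiguity inside the
duplicated copies (truth alignments place every base at its source),
mate-pair/insert-size evidence, and biological repeat structure in the
i.i.d. background sequence. Passing tests therefore demonstrate the
*logic* of each stage under its stated evidence model, not robustness
to aligner-specific artefacts; on real data the PAF ingestion filters
(`min_mapq`, the chaining parameters, the size filters) carry that
load.

Determinism: every random stream derives from the spec seed plus a
fixed stage tag, so identical specs produce byte-identical FASTA, PAF,
bedGraph and JSON outputs — the end-to-end tests assert this at the
file level.

## Problem sizes

The test suite and `scripts/acceptance.py` run 20 misassembly
simulations per jitter condition (100 junctions each), 20 grouping
simulations (~25,000 placements), 20 depth-recovery seeds at Poisson
30/60, 10 flat-track seeds and 10 seeds per rearrangement scenario —
sizes at which the binomial success bounds asserted by the tests are
meaningful while a full run stays around a minute on one CPU.

## Known limitations

* Scenario 2 vs 3 cannot be separated without discordant-pair
  orientation evidence; the verdict `2_or_3` is as far as depth and
  continuity go.
* Breaking uses alignment evidence only; a true biological
  translocation relative to the reference will be "corrected" away.
  On real data the reference should be close, and `--no-break-intra`
  narrows the rule to inter-chromosomal events.
* The grouper's abstention threshold trades recall for precision; with
  `ambiguity_max` near 1 it degenerates to forced argmax.
* AGP output describes only the construction this tool performed
  (W and N rows); it does not model pre-existing within-scaffold gaps
  as separate components.
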