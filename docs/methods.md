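# Methods

## The measurement problem

In HaloTag protein barcoding, each protein molecule is covalently and
stoichiometrically (1:1) linked to a 100-mer single-stranded DNA oligo.
After an affinity step (pull-down, immunoprecipitation), the captured
oligos are PCR-amplified and sequenced; the read-out therefore reduces
protein quantification to sequence counting. `halobc` implements the
computational layer of that read-out: from raw FASTQ reads of the
barcode amplicons to per-protein unique-molecule counts and
positive/negative assay calls, plus a generative simulator that provides
ground truth for every stage.

## Barcode model

The oligo layout is

```
5'-[arm, 31 bp][protein identifier, 8 bp][counting tag, 30 bp][arm, 31 bp]-3'
```

for a 100-bp total; sequencing reads 76 bp covering the 38-bp
identifier+tag region. The counting tag holds 24 random bases and 6
fixed bases (A, C, T, G, A, C in order). The main design gap is *where*
the fixed bases sit within the 30-mer: the published description gives
the mask composition but not the positions. The default here interleaves
one fixed base after every four random bases (positions 4, 9, 14, 19,
24, 29), and the mask is a plain pattern string in the schema config, so
a user with the true oligo sheet can set the real positions. Downstream
logic (filter and clusterer) depends only on the mask, not on the true
positions. Similarly, the 31-bp amplification arms never enter the
counting logic; the defaults are Illumina-adapter-anchored placeholders,
overridable in config.

Schema validation additionally enforces a design floor of pairwise
Hamming distance ≥ 3 between identifier tags. This is a package-level
design rule, not part of the assay description: it guarantees that
1-mismatch demultiplexing can never be ambiguous.

## Demultiplexing and filtering

Each read is reduced to an observation: the first 8 bases of the region
are matched against the identifier table by Hamming distance
(`max_mismatch` 1 by default; an exact-only mode is one flag away, and
with `max_mismatch=0` the operation equals dictionary lookup). A read is
unassigned if no identifier is within range or two tie at the minimum
distance. The 30-base counting tag is then checked against the mask:
**any** mismatched fixed base excludes the read from molecule counting.
This replaces the original pipeline's short-read aligner with direct
table matching — at 8 bp with a distance-3 table, exact Hamming matching
is at least as powerful and fully reproducible. Reads are taken in
sequencing orientation (the amplicon design fixes orientation); quality
strings are parsed but unused, since the described method applies no
quality filter.

## Molecule counting

Filtered tags are collapsed per protein by greedy abundance-ordered
clustering with `distance` 2, `fixed base number` 6, `random base
number` 24. The original in-house clusterizer is unpublished; this
package commits to the standard UMI-literature rule with fully
deterministic tie-breaks:

1. sort distinct tags by read count (desc), then lexicographically;
2. each tag joins the first existing cluster (in creation order) whose
   *representative* is within `distance`, else it seeds a new cluster;
3. clusters are reported sorted by total reads (desc), then
   representative.

The molecule count is the number of clusters. Distance is Hamming by
default (tags are fixed-length and extracted at a fixed register, and
substitutions dominate Illumina errors); Levenshtein (via edlib) and a
single-linkage union-find variant exist behind flags for sensitivity
analysis. Distance is computed over the full 30-mer, but because
filtered tags agree at all six fixed positions this equals distance over
the 24 random bases — the choice is provably irrelevant post-filter. A
literal O(n²) re-implementation with an explicit pairwise distance
matrix ships in the package as a permanent oracle
(`brute_force_cluster`) and is held equal to the fast path in the tests.

## Calling rules

Three positivity criteria are stated for the assay read-out; the package
composes them as a conjunction (most conservative reading), each
individually toggleable and each recorded per call:

* **min_reads** — fewer than 10 reads ⇒ negative;
* **control_exceed** — the prey signal must strictly exceed the matched
  barcoded-HaloTag-only control ("exceeded" is read strictly: a tie is
  negative);
* **noise_floor** — the signal must reach mean + 3 SD of the read counts
  of barcodes with role `unused` (present in the sequencing run's
  background but not in the assay). SD uses the n−1 (sample) denominator,
  stated here so the threshold is reproducible; at least two unused
  identifiers are required or the floor is undefined.

Whether the 10-read threshold applies before or after noise-floor
comparison is ambiguous in the assay description; it is implemented as
an independent conjunct, and the per-call record shows which rule(s)
failed. Rules apply to raw assigned reads by default, with an `on
molecules` flag to apply them to unique-molecule counts instead. A
signal failing only the noise-floor rule is labelled `background_noise`
rather than plain negative.

Screen summaries (positive-reference vs random-reference sets) are
compared with a two-tailed Fisher's exact test using the
point-probability rule — the sum over tables with the observed margins
whose hypergeometric probability does not exceed the observed table's —
via `scipy.stats.fisher_exact`; an independent enumeration oracle in the
test suite checks it over the full margin range used here. The
immunoprecipitation caller sums replicate barcodes per antigen (e.g.
four oligos per protein), calls a dilution step positive when the sum
strictly exceeds the matched background control, divides positive sums
by the human-serum reference reads for a specificity ratio, and reports
the largest dilution still positive as the detection limit.

## Simulator

The generator emulates the physical read-out:

1. every true molecule draws a distinct counting tag (collisions are
   re-drawn; with 4²⁴ random-base states the birthday probability for M
   tags is ≤ M²/2·4⁻²⁴, negligible at any realistic M);
2. PCR is a Galton–Watson branching process: each amplicon duplicates
   with probability `pcr_efficiency` (default 0.6) per cycle (default
   10 cycles), each new copy acquiring substitutions at `pcr_error_rate`
   per base (default 1e-4). Branching, rather than deterministic
   doubling, produces the realistic read-count skew across molecules
   that stresses an abundance-greedy clusterer;
3. `reads_out` amplicons are drawn uniformly with replacement, then
   mutated at `seq_error_rate` per base (default 1e-3); an exhaustive
   mode emits every amplicon exactly once so zero-error limits can be
   asserted without stochastic slack;
4. reads are laid out identifier-first (matching the default
   `read_offset` 0), padded with adapter to 76 bp; a configurable
   fraction of identifiers is scrambled to random 8-mers to emulate
   off-target amplicons. Qualities are constant `I` since nothing
   downstream consumes them.

Errors are substitution-only by default (consistent with
Hamming-metric counting; indels mainly exercise the Levenshtein
option). The cycle count is kept at 10 — far below a real protocol's
~29 — because the amplicon pool is simulated explicitly; the branching
skew and per-lineage error accumulation it produces are the features
under test, not the absolute cycle number.

What the simulator does **not** model: sequencer-specific and
quality-dependent error profiles, indels and chimeric amplicons, jackpot
bias beyond the branching process, carry-over between samples. Passing
recovery tests therefore demonstrate correctness of the counting logic
under substitution noise and amplification skew, not performance on any
particular instrument's error spectrum.

## Verified behaviour and known limitations

At the reference study conditions (true counts 100 and 50, 20× read
depth, substitution rates 1e-3 at both PCR and sequencing stages, seeds
0–19) molecule counts are recovered within 2% of truth, and exactly in
the zero-error exhaustive limit at depth 1. Two residual error
mechanisms remain visible at these conditions and dominate the worst
case over other seed batches (where the error can reach a few percent):

* **dropout** — the branching process gives some molecules small
  lineages, which can receive zero reads at 20× average depth
  (undercount);
* **spurious singletons** — per-cycle PCR errors accumulate along a
  lineage, so a small fraction of reads ends ≥ 3 away from its true tag
  and seeds its own cluster (overcount).

Both shrink with depth and with fewer effective error-accumulating
cycles; neither is an artifact of the clusterer (the brute-force oracle
agrees exactly on every tested instance).

Problem sizes used by the packaged checks: clustering instances up to
200 distinct tags (oracle comparisons), screens of 16+16 simulated
pull-downs at ~1000 reads each, recovery batches of 20 simulated
experiments at 3000 reads each. These sizes are chosen so the whole
verification suite runs on a laptop in well under a minute per module.
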