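# Methods

This note documents the models, algorithms, parameter choices and numerical
conventions behind `vgenotyper`, and what its synthetic benchmarks do and do
not demonstrate about real data.

## Problem setting and assumptions

Immune-receptor V-gene loci (IGKV, IGLV, TRAV, TRBV, TRGV, TRDV and their
kin) consist of many short (~280–300 bp), highly homologous genes, each with
several near-identical alleles, plus orphon copies outside the canonical
locus.  Short reads mapped to such a locus are individually ambiguous; the
method's premise is that the *joint* assignment of all reads is far less so,
provided it is required to respect the depth of coverage the sequencing run
delivers everywhere else in the genome.  The model assumes approximately
uniform coverage (no strong GC bias), reads long enough (~100–150 bp) to
span several inter-allele differences, and a reasonably complete allele
database; reads from sequences absent from the database are handled by an
explicit discard mechanism rather than being forced onto a wrong allele.

## Allele database

Alleles are named `GENE*ALLELE`; the gene is the prefix before `*`.  Two
FASTA header dialects are accepted: bare tokens and pipe-delimited IMGT
headers (field 2 = allele name, field 4 = functionality code, `F` counting
as functional).  Unrecognised headers are skipped with a warning; duplicate
allele ids are an error.

Every allele is padded with `pad_len` flanking `N`s (default 150, one read
length) so that a read overhanging the allele end can still align
end-to-end: the overhang falls on `N`, which costs nothing.  On reload,
flanking `N` runs are recognised as padding, so write/read round-trips
preserve core offsets exactly.

**Landmarks.**  Depth is measured at `G·L` positions per allele (defaults
G = 6 groups × L = 6 landmarks).  Positions are interior-uniform:
`round(k·len/(G·L+1))` for `k = 1..G·L`, excluding the core endpoints, where
alignment-edge effects would otherwise bias coverage; groups are consecutive
runs of L positions.  Cores shorter than the grid fall back to one landmark
per base (with a warning), split into near-equal groups.  Landmark layout is
a function of core length alone.

## Read recruitment and the depth profile

Reads are extracted from an indexed BAM/CRAM over the union of target-locus
and orphon BED regions, deduplicated by (name, mate), with `chr1`/`1` naming
resolved automatically.  Secondary/supplementary alignments trigger
recruitment but the read's primary sequence is used.  Mates are treated as
independent single-end reads: the assignment model works per read and no
pair constraint is used anywhere.

Orphon discovery is the merge of overlapping-or-abutting read placements
into maximal regions, dropping regions shorter than 150 bp (strictly —
length 150 is kept); a SAM adapter derives placements from an external
aligner's output for database-derived simulated reads.  The package does not
bundle an aligner.

The depth profile samples per-base depth at `n_positions` (default 10 000)
uniformly random positions of a user-chosen reference region (classically a
chromosome-1 window), zero-depth positions included — a conservative choice
that also makes accidental exome inputs fail loudly through the zero-mean
error.  The profile records the region's ploidy (2 for an autosome): the
model works with the **per-copy mean** `μ = mean_depth / ploidy`, because a
single allele copy carries haploid coverage.  The tolerance scale `σ` is the
dataset-level per-base SD exactly as measured; it is deliberately not
rescaled by ploidy — the windows are meant to reflect the run's own depth
variability, and the supplementary tolerance factor `s` (below) absorbs any
residual calibration.

## Candidate mapping

The translation of the original all-mapping alignment policy is: end-to-end
placement of the read inside the padded allele, unit-cost substitutions and
indels, reference `N` free, maximum distance 25 (a score floor of −50 at
mismatch penalty 2).  Candidate discovery uses an exact k-mer index (k = 15)
over the padded alleles — k-mers containing `N` are never indexed — and each
seeded pair is verified with banded edit-distance alignment (edlib, infix
mode, `N` equivalences).

Because `N` matches everything, an unconstrained aligner would place any
read wholly inside the padding at distance 0.  A seeded aligner cannot
anchor inside `N`, and the implementation enforces the same physics by
trimming each flank to `read_length − 15` before alignment, so every
placement overlaps the core by at least the seed length.  Reads overlapping
the core by fewer than 15 bases therefore receive no candidates and are
pre-discarded; at default geometry this is ~6% of reads, which depresses
coverage only at the outermost landmark (~4% at the first/last position).

Only the best placement per (read, allele, strand) is kept, tie-broken
toward maximal core overlap and then leftmost; reverse-complement placements
are reported in allele coordinates.  Base qualities are ignored throughout.

## The assignment ILP

Variables: binary `x_{r,a}` per candidate, binary discard `d_r` per read,
binary presence `z_a` and integer copy number `c_a ∈ [0, C_max]` per allele
(C_max default 4; higher amplifications are rare and inflate the model).
Objective: total edit distance plus `P` per discarded read, with
`P = 2·max_distance + 1 = 51` so that discarding is strictly worse than
accepting any single read.  Constraints: each read assigned exactly once or
discarded; `x ≤ z`, `z ≤ c ≤ C_max·z`, and `z_a ≤ Σ_r x_{r,a}` so an allele
cannot be "called" without any assigned read; and per allele and landmark
group the depth window

    c_a (μ − sσ)  ≤  cov_{a,g}  ≤  c_a (μ + sσ),      s = 1.5 by default,

where `cov_{a,g}` is the mean over the group's L landmarks of the number of
assigned reads covering each landmark.  Group means (rather than
per-landmark constraints) smooth edge landmarks; this granularity is the
package's reading of "landmark groups" and is one of the genuinely open
design points.  Reads with no candidates enter the objective as a constant
`P` each.

The model is solved with HiGHS through `scipy.optimize.milp` — open-source,
single-threaded and deterministic for a fixed input (mip gap 10⁻⁶, i.e.
effectively exact on these integral objectives).  All-discard is always
feasible, so the base model can never be infeasible.  Because ties among
co-optimal solutions are solver-internal, nothing downstream depends on
*which* optimum is returned; stability is assessed explicitly by the
confidence machinery instead.  A brute-force enumerator (≤ 10 reads,
enumeration over all assignment/discard combinations with direct window
checking) provides an independent oracle; solver and enumerator agree on the
objective across 100 random instances in the test suite.

## Confidence: prefix consistency

Near-optimal solution bands re-solve the model under the floor
`objective ≥ optimum · (1 + δ)` for δ = 2%, 4%, 6%, 8%, each solved
independently to optimality.  For a degenerate zero optimum the
multiplicative floor collapses; the additive scale `δ·P·n_reads` (one
discarded read ≈ one penalty unit) substitutes.  A band that cannot be made
that much worse is recorded as infeasible with an empty present set.

An allele called in the optimum gets prefix consistency = the count of
consecutive bands (in δ order) still containing it, stopping at the first
absence; present-only-in-the-optimum scores 0, fully stable scores 4.
Threshold calibration computes, per gene and threshold t ∈ [0, 4], the PPV
and passing proportion of labelled calls with prefix consistency ≥ t, and
picks the threshold maximising F-β with β = 0.5 (precision-weighted), ties
toward the lower threshold.  The recall inside F-β uses the call set's own
true-positive total by default; a truth-set denominator is available behind
a switch, since which denominator the original procedure used is not
recoverable from its description.

## Validation machinery

**Mendelian concordance.**  A gene with two called child copies is
concordant iff one copy's allele appears in the maternal calls and the
other's in the paternal (under either pairing); with more than two copies,
some pair of distinct copies must be traceable one to each parent; a single
copy needs either parent.  A required parent with no calls for the gene
yields `parent_missing` (discordant).  The trio concordance is the
concordant fraction over genes with ≥ 1 child call (optionally restricted to
functional genes).  Note the literal two-copy rule makes a homozygous child
discordant when only one parent carries the allele — a deliberate,
documented strictness that penalises uniparental-looking CNV events.

**Precision/recall.**  Allele presence uses set semantics by default
(assembly-contig truth sets have unreliable CNV counts because contigs
overlap); a CNV-sensitive multiset mode exists.  Contig annotation reports
an allele present iff its full core occurs on some contig (either strand)
with at most `max_mismatches` substitutions and no indels (default 0),
collapsing duplicates across contigs.

**Genotype matrix.**  A samples × alleles presence/absence matrix is
exported for downstream association work, with the usual low-prevalence
filter (both presence and absence in ≥ 5% of samples); the regression itself
is out of scope.

## Synthetic data generator

The generator is the package's study-condition definition, not a test dial.
A locus is one random ancestor; genes are the ancestor mutated at
`gene_divergence` (default 0.10, ≈ 80% inter-gene identity — the realistic
regime for V-gene families), alleles the gene mutated at `allele_divergence`
(default 0.01).  Mutations are substitutions only: the ILP consumes edit
distances, and substitutions suffice to create the read-assignment ambiguity
the method must resolve.  Genotypes default to two copies per gene (alleles
uniform with replacement, so ~1/3 of genes are homozygous); trios inherit
one uniformly chosen copy per parent per gene, with optional injected
non-Mendelian events replacing a child copy by an allele absent from both
parents.

Reads are single-end, fixed length (default 150 bp), error rate 0.5%
(uniform substitutions), with per-copy Poisson counts and starts uniform
over every placement overlapping the allele core, so expected per-core-base
depth is flat and equals the per-copy `depth` parameter (default 15×, i.e.
30× diploid WGS); the expected read count per copy is
`depth·(core_len + read_len − 1)/read_len`.  Template `N` positions are
emitted as random bases — the flank is unknown genomic context, not literal
`N`.  Optional per-gene dropout emulates V(D)J-rearrangement read loss.
Downsampling keeps each read independently with probability `fraction`;
using one seed across fractions makes the subsets nested (the same per-read
uniform draws are thresholded), which is how the depth-degradation study is
run.  A BAM emitter lays the genes out on a synthetic contig with a uniform
background contig for depth estimation, so the recruit→estimate→map→solve
pipeline can be exercised end to end from files.

**What passing these benchmarks shows — and does not.**  The generator
reproduces the statistical structure the model assumes: homologous genes,
near-identical alleles, uniform Poisson coverage, uniform errors.  Perfect
or near-perfect recovery there demonstrates the correctness of the
machinery, not field accuracy: real data add GC and mappability bias,
indels and structural variation, database incompleteness, B-cell V(D)J read
dropout, and orphon content beyond the database — all of which degrade
real-world precision/recall below the synthetic ceiling.

## Numerical choices and degenerate inputs

- Solver determinism: fixed model ordering (sorted reads/alleles), single
  thread, node-order-deterministic HiGHS; identical config + seed reproduce
  byte-identical output files (headers carry version, config hash, seed —
  no timestamps).
- Zero-objective optima: see the additive band scale above.
- Landmark ties: co-optimal alignment placements tie-break toward maximal
  core overlap, then leftmost; per-read candidate lists are sorted by
  (distance, allele id).
- Short cores: landmark fallback to one-per-base; empty cores and all-`N`
  records are rejected/skipped at load.
- Empty candidate tables: the model degenerates to all-discard with
  objective `P·n_reads` rather than failing.
- Copy-number reporting: `c_a` does not enter the objective, so among
  feasible copy numbers the solver's choice is arbitrary within the window;
  copy numbers are accordingly noisier than presence calls.

## Problem sizes used in the shipped benchmarks

The recovery study uses 20 genes × 3 alleles at 30× diploid coverage
(~1 700 reads, ~50 000 candidate variables), solved in well under a minute
per depth on one CPU; the solver-vs-enumeration suite uses 100 instances of
≤ 6 reads × ≤ 3 alleles.  These sizes were chosen to exercise every
mechanism (within-gene ambiguity, cross-gene candidates, discards, copy
windows) while keeping the full validation suite fast.

## Known limitations

- No haplotype phasing of copies; no structural-variant breakpoints.
- Copy-number estimates are window-based and coarse (see above).
- No base-quality model and no paired-end constraints.
- Exact Bowtie-2 gap scoring is not emulated; the distance model is unit
  cost with reference-`N` positions free.
- The constraint granularity (per landmark group vs per landmark) and the
  F-β recall denominator are reconstructed design points, each chosen and
  documented here.
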