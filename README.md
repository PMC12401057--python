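# vgenotyper

Germline allele genotyping of multi-copy immune-receptor **variable (V) gene
loci** — the IGKV/IGLV light-chain and TRAV/TRBV/TRGV/TRDV T-cell-receptor
gene families — from standard short-read whole-genome sequencing.

These loci resist conventional reference-based variant calling: each locus
holds tens of highly duplicated genes, each gene has several alleles that
differ by only a few bases over ~280–300 bp, and near-identical *orphon*
copies elsewhere in the genome siphon off read mappings.  A read therefore
rarely identifies its source allele on its own.  `vgenotyper` resolves this
ambiguity jointly, over all reads at once, with an integer linear program
whose constraints force the chosen genotype to be consistent with the
sequencing run's own depth of coverage.  It is aimed at immunogenomics and
statistical-genetics researchers who want germline IG/TR V-gene genotypes
(and presence/absence matrices for association studies) out of ordinary
30× WGS cohorts.

## The model

Reads recruited from the target locus and its orphon regions are aligned
end-to-end against an allele database (IMGT-style `GENE*ALLELE` names, each
sequence padded with flanking `N`s so overhanging reads align at no cost).
Every read–allele pair with edit distance ≤ 25 becomes a candidate
assignment.  The ILP then chooses, for every read *r*, one allele or the
discard option, and for every allele *a* a copy number *c_a*:

```
min   Σ_{r,a} e_{r,a} x_{r,a}  +  P Σ_r d_r

s.t.  Σ_a x_{r,a} + d_r = 1                       every read used once
      x_{r,a} ≤ z_a ,   z_a ≤ c_a ≤ C_max z_a     calls need support
      c_a (μ − sσ) ≤ cov_{a,g} ≤ c_a (μ + sσ)     every landmark group g
```

where `e_{r,a}` is the (N-aware) edit distance, `P = 2·max_distance + 1`
makes discarding a last resort, and `cov_{a,g}` is the mean number of
assigned reads covering the landmarks of group *g* (depth is measured at 6
groups × 6 uniformly spaced landmark positions per allele rather than at
every base).  `μ` is the per-copy (haploid) depth derived from the
genome-wide depth profile, `σ` its per-base SD, and `s = 1.5` the tolerance
scaling.  The model is solved exactly with HiGHS via `scipy.optimize.milp`.

Call confidence is quantified by *prefix consistency*: the model is re-solved
under objective floors 2%, 4%, 6% and 8% above the optimum, and each allele
call is scored by how many consecutive degraded solutions still contain it
(0 = the call vanishes as soon as the solution is perturbed, 4 = fully
stable).  Per-gene PPV/F-β (β = 0.5) threshold calibration is included.

Validation machinery ships with the package: Mendelian trio concordance
(a child's per-gene allele calls must be explainable by one copy from each
parent), allele-presence precision/recall against truth tables or assembly
contigs, and a seeded synthetic-data generator (locus → genotype → trio →
reads → BAM) so the entire pipeline is testable without any downloads.

## Worked example

Simulate a 4-gene locus with a diploid genotype sequenced at 30× (15× per
haplotype copy), then genotype it from the BAM:

```bash
vgenotyper simulate --n-genes 4 --depth 15 --seed 11 --bam -o sim
vgenotyper genotype \
    --bam sim/alignments.bam --allele-db sim/locus.fasta \
    --target-bed sim/targets.bed --depth-region "$(cat sim/depth_region.txt)" \
    --depth-positions 2000 --seed 11 -o out
```

`out/calls.tsv` then contains:

```
# vgenotyper v0.1.0
# config_hash=368a3478e6a5
# seed=11
sample  gene    allele     copy_number  n_reads  mean_edit  prefix_consistency
sample  SYNV1   SYNV1*02   1            43       0.558      4
sample  SYNV1   SYNV1*03   1            36       0.167      4
sample  SYNV2   SYNV2*01   1            32       0.438      4
sample  SYNV2   SYNV2*03   1            39       0.513      4
sample  SYNV3   SYNV3*02   1            37       0.676      4
sample  SYNV3   SYNV3*03   1            41       0.585      4
sample  SYNV4   SYNV4*01   1            48       0.667      4
sample  SYNV4   SYNV4*02   2            49       0.571      4
```

All eight planted alleles are recovered (compare `sim/genotype_truth.tsv`),
each backed by 32–49 assigned reads with mean edit distance well below 1 —
essentially only sequencing errors.  Every call persists through all four
near-optimal solution bands (prefix consistency 4), i.e. the calls are
stable, not artifacts of one particular optimum.  Copy numbers are noisier
than presence: `SYNV4*02` is called at 2 copies where the truth holds one
(its true copy drew extra reads), a known limitation of depth-window copy
estimation.  `trio`, `benchmark`, `discover-orphons`, `calibrate-confidence`
and `export-matrix` subcommands cover the validation and downstream-export
workflows (`vgenotyper --help`).

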