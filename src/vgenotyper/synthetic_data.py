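"""Seeded generators for synthetic loci, genotypes, trios, reads and alignments.

These emulate the statistical structure the genotyper assumes: a locus of N
homologous genes, each with a handful of near-identical alleles (~280-300 bp);
diploid genotypes with optional copy-number variation; trios with Mendelian
inheritance (plus optionally injected non-Mendelian events); and error-bearing
uniform-coverage short reads.  Every generator is a pure function of its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .allele_db import AlleleDatabase, AlleleRecord

BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimRead:
    read_id: str
    sequence: str
    truth_allele_id: str | None = None
    truth_offset: int | None = None  # start on the padded allele


@dataclass
class ReadSet:
    reads: list[SimRead]
    read_length: int
    nominal_depth: float

    def __len__(self) -> int:
        return len(self.reads)

    def __iter__(self):
        return iter(self.reads)

    def truth_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for r in self.reads:
            if r.truth_allele_id is not None:
                out[r.truth_allele_id] = out.get(r.truth_allele_id, 0) + 1
        return out


@dataclass
class SimulatedGenotype:
    """Ground-truth genotype: per gene, a list of (allele_id, haplotype) copies."""

    sample_id: str
    copies: dict[str, list[tuple[str, str]]]  # gene_id -> [(allele_id, 'M'|'P')]

    def allele_multiset(self, gene_id: str) -> list[str]:
        return sorted(a for a, _ in self.copies.get(gene_id, []))

    def present_alleles(self) -> set[str]:
        return {a for cps in self.copies.values() for a, _ in cps}

    def n_copies(self, gene_id: str) -> int:
        return len(self.copies.get(gene_id, []))


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each base independently with probability ``rate``."""
    out = seq.copy()
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    for i in hits:
        choices = BASES[BASES != out[i]]
        out[i] = rng.choice(choices)
    return out


def generate_locus(
    n_genes: int,
    alleles_per_gene: int,
    gene_divergence: float,
    allele_divergence: float,
    length_range: tuple[int, int] = (280, 300),
    seed: int = 0,
    gene_prefix: str = "SYNV",
) -> AlleleDatabase:
    """Generate a homologous gene family as an (un-padded) allele database.

    One random ancestor sequence seeds the locus; each gene is the ancestor
    mutated at ``gene_divergence``, and each allele is its gene mutated at
    ``allele_divergence`` (substitutions only).
    """
    if not (0 <= allele_divergence < gene_divergence < 0.25):
        raise ValueError("require 0 <= allele_divergence < gene_divergence < 0.25")
    lo, hi = length_range
    if not (0 < lo <= hi):
        raise ValueError(f"degenerate length_range {length_range}")
    if n_genes < 1 or alleles_per_gene < 1:
        raise ValueError("n_genes and alleles_per_gene must be >= 1")
    rng = np.random.default_rng(seed)
    length = int(rng.integers(lo, hi + 1))
    ancestor = rng.choice(BASES, size=length)
    records: dict[str, AlleleRecord] = {}
    for g in range(1, n_genes + 1):
        gene_id = f"{gene_prefix}{g}"
        gene_seq = _mutate(ancestor, gene_divergence, rng)
        for a in range(1, alleles_per_gene + 1):
            allele_id = f"{gene_id}*{a:02d}"
            allele_seq = _mutate(gene_seq, allele_divergence, rng)
            seq = "".join(allele_seq)
            records[allele_id] = AlleleRecord(
                allele_id=allele_id,
                gene_id=gene_id,
                sequence=seq,
                core_start=0,
                core_end=len(seq),
            )
    return AlleleDatabase(records=records)


def simulate_genotype(
    db: AlleleDatabase,
    cn_distribution: Mapping[int, float] | None = None,
    seed: int = 0,
    sample_id: str = "sample",
) -> SimulatedGenotype:
    """Draw a genotype: per gene a copy number from ``cn_distribution`` (default:
    always two copies, one per haplotype) and alleles uniform with replacement."""
    if cn_distribution is None:
        cn_distribution = {2: 1.0}
    counts = sorted(cn_distribution)
    probs = np.array([cn_distribution[c] for c in counts], dtype=float)
    if abs(probs.sum() - 1.0) > 1e-9 or (probs < 0).any():
        raise ValueError("cn_distribution probabilities must be >= 0 and sum to 1")
    rng = np.random.default_rng(seed)
    copies: dict[str, list[tuple[str, str]]] = {}
    for gene_id, allele_ids in sorted(db.genes.items()):
        cn = int(rng.choice(counts, p=probs))
        if cn == 0:
            continue
        chosen = [str(rng.choice(allele_ids)) for _ in range(cn)]
        # Copies alternate across haplotypes (maternal first).
        copies[gene_id] = [
            (a, "M" if i % 2 == 0 else "P") for i, a in enumerate(chosen)
        ]
    return SimulatedGenotype(sample_id=sample_id, copies=copies)


def simulate_trio(
    db: AlleleDatabase,
    seed: int = 0,
    n_discordant: int = 0,
    cn_distribution: Mapping[int, float] | None = None,
) -> tuple[SimulatedGenotype, SimulatedGenotype, SimulatedGenotype]:
    """Simulate (mother, father, child) with Mendelian inheritance.

    The child inherits, per gene, one uniformly chosen copy from each parent
    that carries the gene.  ``n_discordant`` randomly chosen child genes then
    have one copy's allele replaced by an allele absent from both parents,
    injecting non-Mendelian events for validation tests.
    """
    rng = np.random.default_rng(seed)
    mother = simulate_genotype(db, cn_distribution, seed=int(rng.integers(2**31)),
                               sample_id="mother")
    father = simulate_genotype(db, cn_distribution, seed=int(rng.integers(2**31)),
                               sample_id="father")
    child_copies: dict[str, list[tuple[str, str]]] = {}
    for gene_id in sorted(set(mother.copies) | set(father.copies)):
        copies: list[tuple[str, str]] = []
        m = mother.copies.get(gene_id, [])
        f = father.copies.get(gene_id, [])
        if m:
            copies.append((m[int(rng.integers(len(m)))][0], "M"))
        if f:
            copies.append((f[int(rng.integers(len(f)))][0], "P"))
        if copies:
            child_copies[gene_id] = copies
    if n_discordant > len(child_copies):
        raise ValueError(
            f"n_discordant={n_discordant} exceeds {len(child_copies)} child genes"
        )
    if n_discordant:
        genes = sorted(child_copies)
        # Only genes with an allele outside both parents can host a discordance.
        eligible = []
        for g in genes:
            parental = {a for a, _ in mother.copies.get(g, [])} | {
                a for a, _ in father.copies.get(g, [])
            }
            if set(db.genes[g]) - parental:
                eligible.append(g)
        if len(eligible) < n_discordant:
            raise ValueError("not enough genes with non-parental alleles available")
        chosen = rng.choice(eligible, size=n_discordant, replace=False)
        for g in sorted(chosen):
            parental = {a for a, _ in mother.copies.get(g, [])} | {
                a for a, _ in father.copies.get(g, [])
            }
            novel = sorted(set(db.genes[g]) - parental)
            new_allele = str(rng.choice(novel))
            i = int(rng.integers(len(child_copies[g])))
            hap = child_copies[g][i][1]
            child_copies[g][i] = (new_allele, hap)
    child = SimulatedGenotype(sample_id="child", copies=child_copies)
    return mother, father, child


def simulate_reads(
    genotype: SimulatedGenotype,
    db: AlleleDatabase,
    depth: float = 15.0,
    read_length: int = 150,
    error_rate: float = 0.005,
    seed: int = 0,
    dropout_genes: set[str] | None = None,
    dropout_rate: float = 0.0,
) -> ReadSet:
    """Simulate single-end reads from every genotype copy.

    ``depth`` is the expected coverage contributed per allele copy (haploid
    depth; a normal two-copy gene sees 2x this).  Read starts are uniform over
    all placements overlapping the allele core, so expected depth is flat
    (= ``depth``) across every core base; reads overhanging the core ends pick
    up randomized flanking sequence (template N positions are emitted as random
    bases — the flank is unknown context, not literal N).  Per-copy read counts
    are Poisson.  Genes in ``dropout_genes`` emit reads at ``dropout_rate``
    times the nominal rate (default 0: full dropout, emulating V(D)J-deleted
    segments).
    """
    if db.pad_len is None or db.pad_len < read_length - 1:
        raise ValueError("database must be padded with pad_len >= read_length - 1")
    rng = np.random.default_rng(seed)
    dropout_genes = dropout_genes or set()
    reads: list[SimRead] = []
    counter = 0
    for gene_id in sorted(genotype.copies):
        rate = dropout_rate if gene_id in dropout_genes else 1.0
        for allele_id, _hap in genotype.copies[gene_id]:
            rec = db[allele_id]
            seq = np.array(list(rec.sequence))
            core_len = rec.core_length
            expected = depth * (core_len + read_length - 1) / read_length * rate
            n = int(rng.poisson(expected)) if expected > 0 else 0
            lo = max(0, rec.core_start - read_length + 1)
            hi = min(len(seq) - read_length, rec.core_end - 1)
            for _ in range(n):
                start = int(rng.integers(lo, hi + 1))
                tmpl = seq[start:start + read_length].copy()
                n_pos = np.nonzero(tmpl == "N")[0]
                if len(n_pos):
                    tmpl[n_pos] = rng.choice(BASES, size=len(n_pos))
                if error_rate > 0:
                    tmpl = _mutate(tmpl, error_rate, rng)
                reads.append(
                    SimRead(
                        read_id=f"r{counter:07d}",
                        sequence="".join(tmpl),
                        truth_allele_id=allele_id,
                        truth_offset=start,
                    )
                )
                counter += 1
    return ReadSet(reads=reads, read_length=read_length, nominal_depth=depth)


def downsample_reads(reads: ReadSet, fraction: float, seed: int = 0) -> ReadSet:
    """Keep each read independently with probability ``fraction`` (seeded).

    Using the same seed for different fractions yields nested subsets (the
    same per-read uniform draws are compared against each threshold).
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    if fraction == 1:
        return ReadSet(list(reads.reads), reads.read_length, reads.nominal_depth)
    rng = np.random.default_rng(seed)
    u = rng.random(len(reads.reads))
    kept = [r for r, keep in zip(reads.reads, u < fraction) if keep]
    return ReadSet(kept, reads.read_length, reads.nominal_depth * fraction)


def random_assignment_instance(
    seed: int,
    max_reads: int = 6,
    max_alleles: int = 3,
    max_distance: int = 5,
):
    """Random tiny (candidate table, database, depth profile) triple.

    Sized for exhaustive enumeration: a handful of reads, up to three alleles
    of one gene, random distances in [0, max_distance] and random contiguous
    landmark coverage.  Used to cross-check the MILP solver against the
    brute-force enumerator.
    """
    from .allele_db import add_landmarks, pad_alleles
    from .candidate_mapping import CandidateAssignment, CandidateTable
    from .recruitment import DepthProfile

    rng = np.random.default_rng(seed)
    db = generate_locus(1, max_alleles, 0.20, 0.05, length_range=(100, 100),
                        seed=seed, gene_prefix="TOY")
    db = pad_alleles(db, 10)
    add_landmarks(db, n_groups=2, per_group=2)
    allele_ids = db.allele_ids()
    n_reads = int(rng.integers(1, max_reads + 1))
    span = 60
    candidates: dict[str, list[CandidateAssignment]] = {}
    zero: set[str] = set()
    for i in range(n_reads):
        rid = f"t{i:03d}"
        n_cand = int(rng.integers(0, len(allele_ids) + 1))
        chosen = rng.choice(allele_ids, size=n_cand, replace=False)
        cands = []
        for aid in sorted(chosen):
            rec = db[aid]
            start = int(rng.integers(0, rec.core_length - span // 2))
            s_abs = rec.core_start + start
            e_abs = s_abs + span
            covered = frozenset(
                (g, p)
                for g, p in db.landmarks_flat(aid)
                if s_abs <= rec.core_start + p < e_abs
            )
            cands.append(
                CandidateAssignment(
                    read_id=rid,
                    allele_id=aid,
                    edit_distance=int(rng.integers(0, max_distance + 1)),
                    start_on_allele=s_abs,
                    end_on_allele=e_abs,
                    strand="+",
                    covered_landmarks=covered,
                )
            )
        if cands:
            candidates[rid] = sorted(cands, key=lambda c: (c.edit_distance, c.allele_id))
        else:
            zero.add(rid)
    table = CandidateTable(candidates=candidates, zero_candidate_reads=zero,
                           read_length=span)
    depth = DepthProfile(mean_depth=2.0, sd_depth=1.0, n_positions_sampled=10,
                         ploidy=1)
    return table, db, depth


# ---------------------------------------------------------------------------
# File emitters (FASTA/FASTQ/TSV) and a synthetic alignment (BAM) writer.
# ---------------------------------------------------------------------------

def write_reads_fasta(reads: ReadSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f">{r.read_id}\n{r.sequence}\n")


def write_reads_fastq(reads: ReadSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{'I' * len(r.sequence)}\n")


def write_truth_tsv(reads: ReadSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\ttruth_allele_id\ttruth_offset\n")
        for r in reads:
            fh.write(f"{r.read_id}\t{r.truth_allele_id}\t{r.truth_offset}\n")


def write_genotype_tsv(genotype: SimulatedGenotype, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tgene_id\tallele_id\thaplotype\n")
        for gene_id in sorted(genotype.copies):
            for allele_id, hap in genotype.copies[gene_id]:
                fh.write(f"{genotype.sample_id}\t{gene_id}\t{allele_id}\t{hap}\n")


def write_alignments(
    reads: ReadSet,
    db: AlleleDatabase,
    bam_path: str | Path,
    seed: int = 0,
    background_depth: float = 30.0,
    background_length: int = 20_000,
    offtarget_reads: int = 0,
    gene_gap: int = 500,
):
    """Write a sorted, indexed BAM emulating a WGS alignment of ``reads``.

    Genes are laid out on a single ``locus_sim`` contig (in sorted gene order,
    separated by ``gene_gap``); each read is placed at its truth position.  A
    ``chr1_sim`` background contig receives uniform coverage at
    ``background_depth`` (diploid-equivalent) for depth estimation, and
    ``offtarget_reads`` random reads land on an ``offtarget_sim`` contig.

    Returns (target_regions, depth_region) where target_regions is a list of
    (chrom, start, end) per gene and depth_region spans the background contig
    interior (read-length margins trimmed).
    """
    import pysam

    rng = np.random.default_rng(seed)
    rl = reads.read_length
    margin = rl + 10
    # Gene layout on locus_sim.
    gene_offsets: dict[str, int] = {}
    pos = margin
    for gene_id, allele_ids in sorted(db.genes.items()):
        gene_offsets[gene_id] = pos
        pos += db[allele_ids[0]].core_length + gene_gap
    locus_len = pos + margin
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [
            {"SN": "locus_sim", "LN": locus_len},
            {"SN": "chr1_sim", "LN": background_length},
            {"SN": "offtarget_sim", "LN": max(background_length, 2 * margin)},
        ],
    }
    entries: list[tuple[int, int, str, str]] = []  # (tid, pos, read_id, seq)
    for r in reads:
        rec = db[r.truth_allele_id]
        p = gene_offsets[rec.gene_id] + (r.truth_offset - rec.core_start)
        entries.append((0, p, r.read_id, r.sequence))
    # Background coverage on chr1_sim.
    n_bg = int(rng.poisson(background_depth * background_length / rl))
    for i in range(n_bg):
        p = int(rng.integers(0, background_length - rl + 1))
        seq = "".join(rng.choice(BASES, size=rl))
        entries.append((1, p, f"bg{i:07d}", seq))
    for i in range(offtarget_reads):
        p = int(rng.integers(0, header["SQ"][2]["LN"] - rl + 1))
        seq = "".join(rng.choice(BASES, size=rl))
        entries.append((2, p, f"ot{i:07d}", seq))
    entries.sort(key=lambda e: (e[0], e[1], e[2]))
    with pysam.AlignmentFile(str(bam_path), "wb", header=header) as bam:
        for tid, p, rid, seq in entries:
            a = pysam.AlignedSegment()
            a.query_name = rid
            a.query_sequence = seq
            a.flag = 0
            a.reference_id = tid
            a.reference_start = p
            a.mapping_quality = 60
            a.cigarstring = f"{len(seq)}M"
            a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
            bam.write(a)
    pysam.index(str(bam_path))
    target_regions = [
        ("locus_sim", off, off + db[db.genes[g][0]].core_length)
        for g, off in sorted(gene_offsets.items(), key=lambda kv: kv[1])
    ]
    depth_region = ("chr1_sim", margin, background_length - margin)
    return target_regions, depth_region
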