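"""Validation machinery: Mendelian trio concordance, allele-presence
precision/recall, and assembly-contig truth annotation.

A gene in a parent-child trio is *concordant* when the child's allele calls
are explainable by Mendelian inheritance: for a two-copy child, one copy's
allele must appear in the maternal calls and the other copy's in the paternal;
for more than two copies, some pair of distinct copies must be traceable one
to each parent; a single-copy child needs its allele in at least one parent.
Missing parental calls for a required parent are counted as discordant.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .allele_db import AlleleDatabase
from .candidate_mapping import reverse_complement

REASONS = (
    "two_copy_match",
    "multi_copy_pair",
    "single_in_parent",
    "unexplained",
    "parent_missing",
)


@dataclass
class TrioCallSet:
    """Per-member gene -> allele multiset (copy-expanded) call tables."""

    child: dict[str, list[str]]
    mother: dict[str, list[str]]
    father: dict[str, list[str]]


@dataclass
class ConcordanceResult:
    per_gene: pd.DataFrame  # gene, concordant, reason
    trio_concordance: float | None  # None when the denominator is empty
    denominator_genes: list[str]


def gene_concordance(
    child: Sequence[str], mother: Sequence[str], father: Sequence[str]
) -> tuple[bool, str]:
    """Mendelian-explainability of one gene's child calls (see module doc)."""
    child = list(child)
    if not child:
        raise ValueError("child multiset must be non-empty (gene excluded upstream)")
    m, f = Counter(mother), Counter(father)
    if len(child) == 1:
        a = child[0]
        if m[a] or f[a]:
            return True, "single_in_parent"
        if not m and not f:
            return False, "parent_missing"
        return False, "unexplained"
    # Two or more copies: need a pair of distinct copies, one per parent.
    for i, a in enumerate(child):
        for j, b in enumerate(child):
            if i != j and m[a] and f[b]:
                return True, "two_copy_match" if len(child) == 2 else "multi_copy_pair"
    if not m or not f:
        return False, "parent_missing"
    return False, "unexplained"


def trio_concordance(
    calls: TrioCallSet,
    functional_genes: set[str] | None = None,
) -> ConcordanceResult:
    """Trio concordance = concordant genes / genes with >=1 child call.

    ``functional_genes``, when given, restricts the denominator (pseudogene
    calls are typically excluded from Mendelian validation).
    """
    denominator = [
        g
        for g in sorted(calls.child)
        if calls.child[g] and (functional_genes is None or g in functional_genes)
    ]
    rows = []
    n_concordant = 0
    for g in denominator:
        ok, reason = gene_concordance(
            calls.child[g], calls.mother.get(g, []), calls.father.get(g, [])
        )
        n_concordant += ok
        rows.append({"gene": g, "concordant": ok, "reason": reason})
    per_gene = pd.DataFrame(rows, columns=["gene", "concordant", "reason"])
    rate = n_concordant / len(denominator) if denominator else None
    return ConcordanceResult(
        per_gene=per_gene, trio_concordance=rate, denominator_genes=denominator
    )


def presence_precision_recall(
    calls: Iterable[str],
    truth: Iterable[str],
    cnv_sensitive: bool = False,
) -> tuple[float | None, float | None]:
    """Allele-presence precision/recall.

    Set semantics by default (copy numbers ignored, matching assembly-contig
    benchmarking where CNV counts are unreliable); ``cnv_sensitive=True`` uses
    multiset intersection counts.  Empty calls leave precision undefined
    (None); empty truth leaves recall undefined.
    """
    if cnv_sensitive:
        c, t = Counter(calls), Counter(truth)
        inter = sum((c & t).values())
        n_calls, n_truth = sum(c.values()), sum(t.values())
    else:
        c_set, t_set = set(calls), set(truth)
        inter = len(c_set & t_set)
        n_calls, n_truth = len(c_set), len(t_set)
    precision = inter / n_calls if n_calls else None
    recall = inter / n_truth if n_truth else None
    return precision, recall


def _hamming_present(contig: np.ndarray, query: str, max_mismatches: int) -> bool:
    """Does ``query`` occur in ``contig`` with <= max_mismatches substitutions
    (no indels)?  Quadratic scan; alleles are short and contigs modest."""
    m = len(query)
    n = len(contig)
    if m > n:
        return False
    q = np.frombuffer(query.encode(), dtype="S1")
    if max_mismatches == 0:
        return query in contig.tobytes().decode()
    for off in range(n - m + 1):
        window = contig[off:off + m]
        if int((window != q).sum()) <= max_mismatches:
            return True
    return False


def annotate_contigs(
    contigs: Mapping[str, str] | Iterable[tuple[str, str]],
    db: AlleleDatabase,
    max_mismatches: int = 0,
) -> set[str]:
    """Derive the truth allele-presence set from assembly contigs.

    An allele is present iff its full core sequence matches somewhere on some
    contig (either strand) with at most ``max_mismatches`` substitutions and
    no indels.  Output is a set: duplicates across overlapping contigs
    collapse (contig CNV counts are not trusted).
    """
    items = list(contigs.items()) if isinstance(contigs, Mapping) else list(contigs)
    if not items:
        raise ValueError("contigs must be non-empty")
    arrs = [
        np.frombuffer(seq.upper().encode(), dtype="S1") for _name, seq in items
    ]
    present: set[str] = set()
    for aid in db.allele_ids():
        core = db[aid].core
        for arr in arrs:
            if _hamming_present(arr, core, max_mismatches) or _hamming_present(
                arr, reverse_complement(core), max_mismatches
            ):
                present.add(aid)
                break
    return present


def genotype_matrix(
    sample_calls: Mapping[str, Iterable[str]],
    min_prevalence: float | None = 0.05,
) -> pd.DataFrame:
    """Samples x alleles presence/absence matrix for downstream association.

    With ``min_prevalence`` set, alleles are kept only when both presence and
    absence occur in at least that fraction of samples (the usual low-variance
    filter before regression); pass None to keep everything.
    """
    samples = sorted(sample_calls)
    alleles = sorted({a for s in samples for a in sample_calls[s]})
    mat = pd.DataFrame(0, index=samples, columns=alleles, dtype=int)
    for s in samples:
        for a in set(sample_calls[s]):
            mat.loc[s, a] = 1
    if min_prevalence is not None and len(samples):
        prev = mat.mean(axis=0)
        keep = (prev >= min_prevalence) & (1 - prev >= min_prevalence)
        mat = mat.loc[:, keep[keep].index]
    return mat


def run_parameter_recovery(
    seed: int,
    n_genes: int = 20,
    alleles_per_gene: int = 3,
    gene_divergence: float = 0.10,
    allele_divergence: float = 0.01,
    depth: float = 30.0,
    read_length: int = 150,
    error_rate: float = 0.005,
    fractions: Sequence[float] = (1.0, 2 / 3, 1 / 3),
    pad_len: int = 150,
) -> list[dict]:
    """Planted-genotype recovery study, optionally across read subsamples.

    Simulates a homologous locus and a diploid genotype, sequences it at
    ``depth`` (diploid WGS coverage), genotypes each read subsample end-to-end
    (map -> ILP -> calls) and scores allele presence against the planted truth.
    All stage seeds derive deterministically from ``seed``.  Returns one row
    per fraction with n_reads, precision and recall.
    """
    from . import ilp_core
    from .candidate_mapping import map_reads_to_alleles
    from .recruitment import DepthProfile
    from .synthetic_data import (
        downsample_reads,
        generate_locus,
        simulate_genotype,
        simulate_reads,
    )
    from .allele_db import add_landmarks, pad_alleles

    base = int(seed) % (2**31 - 10)
    db = generate_locus(n_genes, alleles_per_gene, gene_divergence,
                        allele_divergence, seed=base)
    db = pad_alleles(db, pad_len)
    add_landmarks(db)
    genotype = simulate_genotype(db, seed=base + 1)
    reads = simulate_reads(genotype, db, depth=depth / 2,
                           read_length=read_length, error_rate=error_rate,
                           seed=base + 2)
    truth = genotype.present_alleles()
    rows = []
    for fraction in fractions:
        sub = downsample_reads(reads, fraction, seed=base + 3)
        table = map_reads_to_alleles(sub, db)
        profile = DepthProfile(
            mean_depth=depth * fraction,
            sd_depth=float(np.sqrt(depth * fraction)),
            n_positions_sampled=1,
            ploidy=2,
        )
        params = ilp_core.ModelParams()
        solution = ilp_core.solve(
            ilp_core.build_model(table, db, profile, params), params
        )
        calls = ilp_core.calls_from_solution(solution, db)
        p, r = presence_precision_recall(
            {c.allele_id for c in calls}, truth, cnv_sensitive=False
        )
        rows.append(
            {
                "fraction": fraction,
                "n_reads": len(sub),
                "precision": p,
                "recall": r,
                "n_truth_alleles": len(truth),
                "n_discarded": solution.n_discarded,
            }
        )
    return rows


# ---------------------------------------------------------------------------
# TSV I/O for call tables
# ---------------------------------------------------------------------------

def read_calls_tsv(path: str | Path) -> dict[str, list[str]]:
    """Read a calls TSV (as written by the genotyper) into gene -> allele
    multiset, expanding copy numbers."""
    out: dict[str, list[str]] = {}
    with open(path) as fh:
        header: list[str] | None = None
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                for col in ("gene", "allele"):
                    if col not in header:
                        raise ValueError(
                            f"{path}: line {lineno}: missing column {col!r}"
                        )
                continue
            row = dict(zip(header, fields))
            try:
                cn = int(row.get("copy_number", 1) or 1)
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: bad copy_number") from exc
            out.setdefault(row["gene"], []).extend([row["allele"]] * cn)
    if header is None:
        raise ValueError(f"{path}: empty calls table")
    return out


def write_concordance_tsvs(
    result: ConcordanceResult,
    per_gene_path: str | Path,
    summary_path: str | Path,
    trio_id: str = "trio",
    header_lines: Sequence[str] = (),
) -> None:
    with open(per_gene_path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df = result.per_gene.copy()
        df.insert(0, "trio", trio_id)
        df.to_csv(fh, sep="\t", index=False)
    with open(summary_path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("trio\tn_genes\tn_concordant\tconcordance\n")
        n = len(result.denominator_genes)
        k = int(result.per_gene["concordant"].sum()) if n else 0
        rate = "" if result.trio_concordance is None else f"{result.trio_concordance:.6f}"
        fh.write(f"{trio_id}\t{n}\t{k}\t{rate}\n")
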