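"""All-to-all candidate (read, allele) alignment with N-aware edit distances.

Every recruited read is matched against every plausible allele end-to-end
(both strands).  Candidate alleles are discovered through an exact k-mer index
(k = 15, mirroring a seed-and-extend aligner's seeding step; k-mers containing
N are never indexed, so reads cannot "match" inside the N padding alone) and
verified with banded edit-distance alignment in which positions aligned against
a padded ``N`` cost nothing.  The resulting candidate table, with one best
placement per (read, allele), is the ILP's input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import edlib
import numpy as np
import pandas as pd

from .allele_db import AlleleDatabase
from .synthetic_data import ReadSet, SimRead

#: N in the (padded) reference matches any read base at zero cost.
N_EQUALITIES = [("N", "A"), ("N", "C"), ("N", "G"), ("N", "T")]

_RC = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC)[::-1]


@dataclass(frozen=True)
class CandidateAssignment:
    read_id: str
    allele_id: str
    edit_distance: int
    start_on_allele: int           # 0-based start of the placement on the padded allele
    end_on_allele: int             # half-open end
    strand: str                    # '+' or '-'
    covered_landmarks: frozenset[tuple[int, int]]  # (group, core offset) pairs


@dataclass
class CandidateTable:
    """Per-read candidate lists (sorted by edit distance, then allele id)."""

    candidates: dict[str, list[CandidateAssignment]]
    zero_candidate_reads: set[str]
    read_length: int

    @property
    def read_ids(self) -> list[str]:
        return sorted(self.candidates)

    @property
    def allele_ids(self) -> list[str]:
        return sorted({c.allele_id for cs in self.candidates.values() for c in cs})

    @property
    def n_candidates(self) -> int:
        return sum(len(cs) for cs in self.candidates.values())


def align_read(
    read: str,
    allele_seq: str,
    max_distance: int,
    core_start: int | None = None,
    core_end: int | None = None,
    min_core_overlap: int = 15,
) -> tuple[int, list[tuple[int, int]]] | None:
    """Best end-to-end placement of ``read`` within ``allele_seq``.

    Returns (edit_distance, co-optimal (start, end_inclusive) locations in
    padded-allele coordinates), or None if no placement has distance <=
    ``max_distance``.  Gaps at the allele ends are free (the read is aligned
    end-to-end; the allele is longer) and reference N positions cost nothing.
    Because N matches every base, a placement lying entirely in the N padding
    would trivially score 0; placements are therefore restricted to those
    overlapping the core by at least ``min_core_overlap`` bases (the seed
    length — a seeded aligner cannot anchor inside N either), by trimming each
    flank to ``len(read) - min_core_overlap`` before aligning.
    """
    if core_start is None or core_end is None:
        core_start = len(allele_seq) - len(allele_seq.lstrip("N"))
        core_end = len(allele_seq.rstrip("N"))
    max_flank = max(0, len(read) - min_core_overlap)
    left = max(0, core_start - max_flank)
    right = min(len(allele_seq), core_end + max_flank)
    target = allele_seq[left:right]
    if len(read) > len(target):
        return None
    res = edlib.align(
        read, target, mode="HW", task="locations", k=max_distance,
        additionalEqualities=N_EQUALITIES,
    )
    if res["editDistance"] < 0:
        return None
    locations = [(s + left, e + left) for s, e in res["locations"]]
    return res["editDistance"], locations


def _kmer_index(db: AlleleDatabase, k: int) -> dict[str, set[str]]:
    index: dict[str, set[str]] = {}
    for aid in db.allele_ids():
        seq = db[aid].sequence
        for i in range(len(seq) - k + 1):
            kmer = seq[i:i + k]
            if "N" in kmer:
                continue
            index.setdefault(kmer, set()).add(aid)
    return index


def map_reads_to_alleles(
    reads: ReadSet,
    db: AlleleDatabase,
    max_distance: int = 25,
    k: int = 15,
) -> CandidateTable:
    """Map every read against the padded allele database on both strands.

    For each (read, allele) pair sharing at least one exact k-mer, the best
    end-to-end placement is kept if its distance is <= ``max_distance`` and it
    overlaps the allele core (co-optimal placements tie-break toward maximal
    core overlap, then leftmost).  Reads with no surviving candidate land in
    the zero-candidate set and will be trivially discarded by the ILP.
    """
    if db.pad_len is None:
        raise ValueError("database must be padded before mapping")
    if not db.landmarks:
        raise ValueError("database has no landmarks; call add_landmarks first")
    index = _kmer_index(db, k)
    landmark_abs: dict[str, list[tuple[int, int, int]]] = {
        aid: [(g, p, db[aid].core_start + p) for g, p in db.landmarks_flat(aid)]
        for aid in db.allele_ids()
    }
    table: dict[str, list[CandidateAssignment]] = {}
    zero: set[str] = set()
    for read in reads:
        seqs = {"+": read.sequence, "-": reverse_complement(read.sequence)}
        hits: dict[str, set[str]] = {"+": set(), "-": set()}
        for strand, seq in seqs.items():
            for i in range(len(seq) - k + 1):
                found = index.get(seq[i:i + k])
                if found:
                    hits[strand] |= found
        best: dict[str, CandidateAssignment] = {}
        for strand in "+-":
            for aid in hits[strand]:
                rec = db[aid]
                aln = align_read(
                    seqs[strand], rec.sequence, max_distance,
                    core_start=rec.core_start, core_end=rec.core_end,
                    min_core_overlap=k,
                )
                if aln is None:
                    continue
                dist, locations = aln
                # Prefer the co-optimal placement with maximal core overlap.
                def overlap(loc: tuple[int, int]) -> int:
                    s, e = loc
                    return max(0, min(e + 1, rec.core_end) - max(s, rec.core_start))
                s, e = max(locations, key=lambda l: (overlap(l), -l[0]))
                if overlap((s, e)) <= 0:
                    continue
                prev = best.get(aid)
                if prev is not None and (prev.edit_distance, prev.strand) <= (dist, strand):
                    continue
                covered = frozenset(
                    (g, p) for g, p, ap in landmark_abs[aid] if s <= ap <= e
                )
                best[aid] = CandidateAssignment(
                    read_id=read.read_id,
                    allele_id=aid,
                    edit_distance=dist,
                    start_on_allele=s,
                    end_on_allele=e + 1,
                    strand=strand,
                    covered_landmarks=covered,
                )
        if best:
            table[read.read_id] = sorted(
                best.values(), key=lambda c: (c.edit_distance, c.allele_id)
            )
        else:
            zero.add(read.read_id)
    return CandidateTable(
        candidates=table, zero_candidate_reads=zero, read_length=reads.read_length
    )


def candidate_summary(
    table: CandidateTable,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-allele and per-read diagnostics over the candidate table."""
    per_allele: dict[str, list[int]] = {}
    rows = []
    for rid in table.read_ids:
        cands = table.candidates[rid]
        rows.append(
            {
                "read_id": rid,
                "n_candidates": len(cands),
                "min_distance": min(c.edit_distance for c in cands),
            }
        )
        for c in cands:
            per_allele.setdefault(c.allele_id, []).append(c.edit_distance)
    per_read = pd.DataFrame(rows, columns=["read_id", "n_candidates", "min_distance"])
    allele_rows = [
        {
            "allele_id": aid,
            "n_candidate_reads": len(ds),
            "mean_distance": float(np.mean(ds)),
        }
        for aid, ds in sorted(per_allele.items())
    ]
    per_allele_df = pd.DataFrame(
        allele_rows, columns=["allele_id", "n_candidate_reads", "mean_distance"]
    )
    return per_allele_df, per_read


def write_candidate_tsv(
    table: CandidateTable, path: str | Path, header_lines: Sequence[str] = ()
) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("read_id\tallele_id\tdistance\tstart\tstrand\n")
        for rid in table.read_ids:
            for c in table.candidates[rid]:
                fh.write(
                    f"{c.read_id}\t{c.allele_id}\t{c.edit_distance}"
                    f"\t{c.start_on_allele}\t{c.strand}\n"
                )


def table_from_sam(
    sam_path: str | Path, db: AlleleDatabase, max_distance: int = 25
) -> CandidateTable:
    """Adapter: build a candidate table from an external all-mapping SAM run
    against the padded allele database (e.g. Bowtie 2 with the translated
    parameters).  Distances are recomputed N-aware from the stored sequences."""
    import pysam

    best: dict[str, dict[str, CandidateAssignment]] = {}
    seqs: dict[str, str] = {}
    with pysam.AlignmentFile(str(sam_path), check_sq=False) as fh:
        read_lengths = []
        for aln in fh:
            if aln.is_unmapped or aln.reference_name not in db.records:
                continue
            seq = aln.get_forward_sequence()
            if seq:
                seqs[aln.query_name] = seq.upper()
            read_lengths.append(aln.query_length)
    reads = ReadSet(
        reads=[SimRead(rid, s) for rid, s in sorted(seqs.items())],
        read_length=int(np.median(read_lengths)) if read_lengths else 0,
        nominal_depth=0.0,
    )
    return map_reads_to_alleles(reads, db, max_distance=max_distance)
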