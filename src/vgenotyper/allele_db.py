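"""Allele reference database: loading, validation, N-padding and landmark placement.

The genotyper works against a database of known allele sequences named in the
IMGT style ``GENE*ALLELE`` (e.g. ``IGLV2-14*01``).  Because V genes are short
(~280-300 bp) relative to a read length, every allele is padded with flanking
``N`` runs so that reads overhanging the allele ends can still be aligned
end-to-end (N positions cost nothing during alignment).  Read depth inside the
ILP is only measured at a small set of uniformly spaced "landmark" positions on
each allele, partitioned into contiguous landmark groups.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

VALID_BASES = set("ACGTN")

#: IMGT functionality codes that count as functional.
FUNCTIONAL_CODES = {"F"}


class AlleleDatabaseError(ValueError):
    """Raised for malformed or inconsistent allele databases."""


@dataclass(frozen=True)
class AlleleRecord:
    """One allele sequence, possibly N-padded.

    ``core_start``/``core_end`` are 0-based half-open offsets of the original
    (un-padded) allele within ``sequence``.
    """

    allele_id: str
    gene_id: str
    sequence: str
    core_start: int
    core_end: int
    functional: bool = True

    @property
    def core(self) -> str:
        return self.sequence[self.core_start:self.core_end]

    @property
    def core_length(self) -> int:
        return self.core_end - self.core_start

    def __post_init__(self) -> None:
        if "*" not in self.allele_id:
            raise AlleleDatabaseError(f"allele_id {self.allele_id!r} lacks '*'")
        if not (0 <= self.core_start < self.core_end <= len(self.sequence)):
            raise AlleleDatabaseError(
                f"{self.allele_id}: bad core offsets "
                f"[{self.core_start}, {self.core_end}) for length {len(self.sequence)}"
            )
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise AlleleDatabaseError(f"{self.allele_id}: invalid bases {sorted(bad)}")


@dataclass
class AlleleDatabase:
    """Collection of alleles grouped by gene, with optional landmark positions.

    ``landmarks[allele_id]`` is a list of landmark groups; each group is a list
    of 0-based offsets into the allele *core*, strictly increasing overall.
    """

    records: dict[str, AlleleRecord]
    pad_len: int | None = None
    landmarks: dict[str, list[list[int]]] = field(default_factory=dict)

    @property
    def genes(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for aid in sorted(self.records):
            out.setdefault(self.records[aid].gene_id, []).append(aid)
        return out

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, allele_id: str) -> AlleleRecord:
        return self.records[allele_id]

    def allele_ids(self) -> list[str]:
        return sorted(self.records)

    def landmarks_flat(self, allele_id: str) -> list[tuple[int, int]]:
        """All (group_index, core_offset) landmark pairs for one allele."""
        return [
            (g, p)
            for g, group in enumerate(self.landmarks.get(allele_id, []))
            for p in group
        ]


def _parse_header(header: str) -> tuple[str | None, bool | None]:
    """Extract (allele_id, functional) from a FASTA header.

    Supports bare ``GENE*ALLELE`` tokens and pipe-delimited IMGT headers where
    field 2 is the allele name and field 4 the functionality code (F/ORF/P).
    Returns (None, None) for unrecognised dialects.
    """
    header = header.strip()
    if "|" in header:
        fields = header.split("|")
        allele_id = fields[1].strip() if len(fields) > 1 else ""
        functional = None
        if len(fields) > 3:
            code = fields[3].strip().strip("()[]")
            if code:
                functional = code in FUNCTIONAL_CODES
        if "*" in allele_id:
            return allele_id, functional
        return None, None
    token = header.split()[0] if header else ""
    if "*" in token:
        return token, None
    return None, None


def load_allele_database(
    fasta_path: str | Path,
    functional_ids: set[str] | None = None,
) -> AlleleDatabase:
    """Load an allele database from FASTA.

    Records with unparseable headers are skipped with a warning; duplicate
    allele ids and an empty resulting database are hard errors.  When the
    header does not carry an IMGT functionality code, ``functional_ids``
    (if given) decides functionality; otherwise alleles default to functional.
    """
    records: dict[str, AlleleRecord] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        allele_id, functional = _parse_header(rec.description)
        if allele_id is None:
            logger.warning("skipping record with unrecognised header: %r", rec.description)
            continue
        if allele_id in records:
            raise AlleleDatabaseError(f"duplicate allele_id {allele_id!r}")
        if functional is None:
            functional = allele_id in functional_ids if functional_ids is not None else True
        seq = str(rec.seq).upper()
        # Flanking N runs are padding by construction (pad_alleles), so the
        # core is recovered on reload and write/reload round-trips exactly.
        lead = len(seq) - len(seq.lstrip("N"))
        trail = len(seq) - len(seq.rstrip("N"))
        if lead + trail >= len(seq):
            logger.warning("skipping all-N record %r", allele_id)
            continue
        records[allele_id] = AlleleRecord(
            allele_id=allele_id,
            gene_id=allele_id.split("*")[0],
            sequence=seq,
            core_start=lead,
            core_end=len(seq) - trail,
            functional=functional,
        )
    if not records:
        raise AlleleDatabaseError(f"no usable allele records in {fasta_path}")
    flanks = {
        (r.core_start, len(r.sequence) - r.core_end) for r in records.values()
    }
    pad_len = None
    if len(flanks) == 1:
        a, b = next(iter(flanks))
        if a == b and a > 0:
            pad_len = a
    return AlleleDatabase(records=records, pad_len=pad_len)


def pad_alleles(db: AlleleDatabase, pad_len: int = 150) -> AlleleDatabase:
    """Return a new database with every allele symmetrically N-padded.

    Padding an already-padded database is refused (idempotence contract).
    Landmarks, being core-relative, carry over unchanged.
    """
    if db.pad_len is not None:
        raise AlleleDatabaseError("database is already padded")
    if pad_len < 0:
        raise AlleleDatabaseError("pad_len must be >= 0")
    pad = "N" * pad_len
    new = {
        aid: replace(
            rec,
            sequence=pad + rec.sequence + pad,
            core_start=rec.core_start + pad_len,
            core_end=rec.core_end + pad_len,
        )
        for aid, rec in db.records.items()
    }
    return AlleleDatabase(records=new, pad_len=pad_len, landmarks=dict(db.landmarks))


def compute_landmarks(
    core_length: int, n_groups: int = 6, per_group: int = 6
) -> list[list[int]]:
    """Place ``n_groups * per_group`` uniformly spaced landmarks on a core.

    Positions are interior-uniform: ``round(k * core_length / (G*L + 1))`` for
    ``k = 1..G*L``, grouped into consecutive runs of ``per_group``.  Cores too
    short for the full grid fall back to one landmark per base (with a
    warning), split into ``n_groups`` near-equal consecutive groups.
    """
    if core_length <= 0:
        raise AlleleDatabaseError("core_length must be positive")
    if n_groups < 1 or per_group < 1:
        raise AlleleDatabaseError("n_groups and per_group must be >= 1")
    total = n_groups * per_group
    if core_length > total:
        positions = [round(k * core_length / (total + 1)) for k in range(1, total + 1)]
        if len(set(positions)) == total:
            return [
                positions[g * per_group:(g + 1) * per_group] for g in range(n_groups)
            ]
        positions = sorted(set(positions))
        warnings.warn(
            f"core length {core_length} cannot host {total} distinct landmarks; "
            f"using {len(positions)}"
        )
    else:
        # Saturated (== total) or short core: one landmark per base.
        positions = list(range(core_length))
        if core_length < total:
            warnings.warn(
                f"core length {core_length} < {total} landmarks; "
                f"falling back to {core_length} landmarks"
            )
    # Near-equal consecutive grouping of the reduced landmark set.
    n = len(positions)
    base, extra = divmod(n, n_groups)
    groups, i = [], 0
    for g in range(n_groups):
        size = base + (1 if g < extra else 0)
        if size:
            groups.append(positions[i:i + size])
        i += size
    return groups


def add_landmarks(
    db: AlleleDatabase, n_groups: int = 6, per_group: int = 6
) -> AlleleDatabase:
    """Compute and attach landmark positions for every allele in place."""
    for aid, rec in db.records.items():
        db.landmarks[aid] = compute_landmarks(rec.core_length, n_groups, per_group)
    return db


def write_fasta(db: AlleleDatabase, path: str | Path) -> None:
    """Write the database (padded or not) to FASTA, headers = allele ids."""
    recs = [
        SeqRecord(Seq(db.records[aid].sequence), id=aid, description="")
        for aid in db.allele_ids()
    ]
    SeqIO.write(recs, str(path), "fasta")


def write_landmark_table(db: AlleleDatabase, path: str | Path) -> None:
    """TSV of (allele_id, group, position) landmark placements."""
    with open(path, "w") as fh:
        fh.write("allele_id\tgroup\tposition\n")
        for aid in db.allele_ids():
            for g, p in db.landmarks_flat(aid):
                fh.write(f"{aid}\t{g}\t{p}\n")
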