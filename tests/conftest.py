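import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import vgenotyper as vg

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_locus():
    """A 5-gene, 3-allele padded locus with landmarks (fast pipeline fixture)."""
    db = vg.generate_locus(5, 3, 0.10, 0.01, seed=7)
    padded = vg.pad_alleles(db, 150)
    vg.add_landmarks(padded)
    return padded


@pytest.fixture(scope="session")
def small_pipeline(small_locus):
    """Genotype + reads + candidate table + solved model for the small locus."""
    from vgenotyper.recruitment import DepthProfile

    genotype = vg.simulate_genotype(small_locus, seed=1)
    reads = vg.simulate_reads(genotype, small_locus, depth=15, seed=2)
    table = vg.map_reads_to_alleles(reads, small_locus)
    depth = DepthProfile(30.0, np.sqrt(30.0), 100, ploidy=2)
    model = vg.build_model(table, small_locus, depth)
    solution = vg.solve(model)
    return {
        "db": small_locus,
        "genotype": genotype,
        "reads": reads,
        "table": table,
        "depth": depth,
        "model": model,
        "solution": solution,
    }


def make_db(sequences: dict[str, str], pad_len: int = 0,
            n_groups: int = 6, per_group: int = 6) -> vg.AlleleDatabase:
    """Build a padded, landmarked database from explicit sequences."""
    from vgenotyper.allele_db import AlleleRecord

    records = {
        aid: AlleleRecord(
            allele_id=aid,
            gene_id=aid.split("*")[0],
            sequence=seq,
            core_start=0,
            core_end=len(seq),
        )
        for aid, seq in sequences.items()
    }
    db = vg.AlleleDatabase(records=records)
    db = vg.pad_alleles(db, pad_len)
    vg.add_landmarks(db, n_groups, per_group)
    return db


@pytest.fixture
def db_factory():
    return make_db


def make_table(db, rows, read_length=150):
    """Hand-built candidate table.

    rows: (read_id, allele_id, edit_distance, groups) where groups is None
    (candidate covers every landmark) or a list of group indices to cover.
    """
    from vgenotyper.candidate_mapping import CandidateAssignment, CandidateTable

    candidates = {}
    for read_id, allele_id, dist, groups in rows:
        rec = db[allele_id]
        covered = frozenset(
            (g, p)
            for g, p in db.landmarks_flat(allele_id)
            if groups is None or g in groups
        )
        cand = CandidateAssignment(
            read_id=read_id,
            allele_id=allele_id,
            edit_distance=dist,
            start_on_allele=rec.core_start,
            end_on_allele=rec.core_end,
            strand="+",
            covered_landmarks=covered,
        )
        candidates.setdefault(read_id, []).append(cand)
    for rid in candidates:
        candidates[rid].sort(key=lambda c: (c.edit_distance, c.allele_id))
    return CandidateTable(candidates=candidates, zero_candidate_reads=set(),
                          read_length=read_length)


@pytest.fixture
def table_factory():
    return make_table


def brute_force_regions(placements, min_len):
    """Independent interval-union oracle for orphon discovery."""
    from vgenotyper.recruitment import GenomicRegion

    out = []
    for chrom in sorted({c for c, _, _ in placements}):
        ivs = [(s, e) for c, s, e in placements if c == chrom]
        hi = max(e for _, e in ivs)
        covered = np.zeros(hi + 1, dtype=bool)
        for s, e in ivs:
            covered[s:e] = True
        start = None
        for i in range(hi + 2):
            on = covered[i] if i <= hi else False
            if on and start is None:
                start = i
            elif not on and start is not None:
                if i - start >= min_len:
                    out.append(GenomicRegion(chrom, start, i))
                start = None
    return out


def write_bam(path, entries, contigs):
    """Minimal coordinate-sorted, indexed BAM.

    entries: (contig_idx, pos, name, seq[, flag]); secondary alignments
    (flag 0x100) carry no sequence, as real aligners emit them.
    """
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": n, "LN": l} for n, l in contigs],
    }
    entries = sorted(entries, key=lambda e: (e[0], e[1]))
    with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
        for entry in entries:
            tid, pos, name, seq = entry[:4]
            flag = entry[4] if len(entry) > 4 else 0
            a = pysam.AlignedSegment()
            a.query_name = name
            a.flag = flag
            a.reference_id = tid
            a.reference_start = pos
            a.mapping_quality = 60
            if not flag & 0x100:
                a.query_sequence = seq
            a.cigarstring = f"{len(seq)}M"
            bam.write(a)
    pysam.index(str(path))
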