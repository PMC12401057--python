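import numpy as np
import pytest

import vgenotyper as vg
from vgenotyper.candidate_mapping import (
    align_read,
    candidate_summary,
    map_reads_to_alleles,
    reverse_complement,
)


def dp_semiglobal(query: str, target: str) -> int:
    """Independent quadratic DP oracle: edit distance of query aligned
    end-to-end inside target (free target-end gaps), N in target free."""
    n, m = len(query), len(target)
    prev = [0] * (m + 1)  # free leading target gap
    for i in range(1, n + 1):
        cur = [i] + [0] * m
        for j in range(1, m + 1):
            cost = 0 if target[j - 1] == "N" or query[i - 1] == target[j - 1] else 1
            cur[j] = min(prev[j - 1] + cost, prev[j] + 1, cur[j - 1] + 1)
        prev = cur
    return min(prev)  # free trailing target gap


class TestAlignRead:
    def test_exact_core_substring_distance_zero_correct_offset(self, db_factory):
        db = db_factory({"G*01": "ACGTTGCA" * 40}, pad_len=150)
        rec = db["G*01"]
        read = rec.core[37:37 + 150]
        dist, locs = align_read(read, rec.sequence, 25, rec.core_start, rec.core_end)
        assert dist == 0
        assert (rec.core_start + 37, rec.core_start + 37 + 149) in locs

    def test_overhang_into_n_flank_is_free(self, db_factory):
        db = db_factory({"G*01": "ACGTTGCA" * 40}, pad_len=150)
        rec = db["G*01"]
        # 10 bases of (arbitrary) flank context + 140 exact core bases
        read = "GATTACAGAT" + rec.core[:140]
        dist, locs = align_read(read, rec.sequence, 25, rec.core_start, rec.core_end)
        assert dist == 0

    def test_placement_confined_near_core(self, db_factory):
        # A read unrelated to the core may not sit entirely in the N padding.
        db = db_factory({"G*01": "A" * 300}, pad_len=150)
        rec = db["G*01"]
        res = align_read("CGCG" * 25, rec.sequence, 10, rec.core_start, rec.core_end)
        assert res is None

    @pytest.mark.parametrize("case", range(20))
    def test_distance_matches_dp_oracle(self, case, db_factory):
        rng = np.random.default_rng(100 + case)
        bases = np.array(list("ACGT"))
        core = "".join(rng.choice(bases, size=80))
        db = db_factory({"G*01": core}, pad_len=40)
        rec = db["G*01"]
        start = int(rng.integers(0, 40))
        read = list(core[start:start + 40])
        for _ in range(int(rng.integers(0, 6))):  # mutate a few positions
            i = int(rng.integers(len(read)))
            read[i] = str(rng.choice(bases))
        read = "".join(read)
        got = align_read(read, rec.sequence, 25, rec.core_start, rec.core_end,
                         min_core_overlap=15)
        # Oracle recomputes on the identically trimmed target.
        max_flank = len(read) - 15
        left = max(0, rec.core_start - max_flank)
        right = min(len(rec.sequence), rec.core_end + max_flank)
        expected = dp_semiglobal(read, rec.sequence[left:right])
        assert got is not None and got[0] == expected


class TestMapReads:
    def test_truth_allele_among_minimum_distance_candidates(self, small_pipeline):
        db = small_pipeline["db"]
        gt = small_pipeline["genotype"]
        reads = vg.simulate_reads(gt, db, depth=3, error_rate=0.0, seed=8)
        table = map_reads_to_alleles(reads, db)
        by_id = {r.read_id: r for r in reads}
        for rid, cands in table.candidates.items():
            truth = by_id[rid].truth_allele_id
            dmin = min(c.edit_distance for c in cands)
            best = {c.allele_id for c in cands if c.edit_distance == dmin}
            assert truth in best

    def test_read_order_does_not_change_candidates(self, small_locus):
        gt = vg.simulate_genotype(small_locus, seed=5)
        reads = vg.simulate_reads(gt, small_locus, depth=2, seed=6)
        rev = vg.ReadSet(reads.reads[::-1], reads.read_length, reads.nominal_depth)
        t1 = map_reads_to_alleles(reads, small_locus)
        t2 = map_reads_to_alleles(rev, small_locus)
        assert t1.candidates == t2.candidates

    def test_reverse_complement_reads_found_in_allele_coordinates(self, small_locus):
        gt = vg.simulate_genotype(small_locus, seed=5)
        reads = vg.simulate_reads(gt, small_locus, depth=2, error_rate=0.0, seed=7)
        flipped = vg.ReadSet(
            [
                vg.SimRead(r.read_id, reverse_complement(r.sequence),
                           r.truth_allele_id, r.truth_offset)
                for r in reads.reads[:40]
            ],
            reads.read_length, reads.nominal_depth,
        )
        table = map_reads_to_alleles(flipped, small_locus)
        by_id = {r.read_id: r for r in flipped}
        for rid, cands in table.candidates.items():
            truth = [c for c in cands if c.allele_id == by_id[rid].truth_allele_id]
            assert truth and truth[0].strand == "-"
            assert truth[0].start_on_allele == by_id[rid].truth_offset

    def test_junk_read_lands_in_zero_candidate_set(self, small_locus):
        rng = np.random.default_rng(0)
        junk = "".join(rng.choice(np.array(list("ACGT")), size=150))
        rs = vg.ReadSet([vg.SimRead("junk", junk)], 150, 1.0)
        table = map_reads_to_alleles(rs, small_locus)
        assert table.zero_candidate_reads == {"junk"}

    def test_candidates_sorted_and_within_max_distance(self, small_pipeline):
        table = small_pipeline["table"]
        for cands in table.candidates.values():
            keys = [(c.edit_distance, c.allele_id) for c in cands]
            assert keys == sorted(keys)
            assert all(c.edit_distance <= 25 for c in cands)

    def test_covered_landmarks_within_placement_span(self, small_pipeline):
        db = small_pipeline["db"]
        for cands in small_pipeline["table"].candidates.values():
            for c in cands:
                rec = db[c.allele_id]
                for g, p in c.covered_landmarks:
                    ap = rec.core_start + p
                    assert c.start_on_allele <= ap < c.end_on_allele


class TestSummary:
    def test_counts_equal_brute_force_recount(self, small_pipeline):
        table = small_pipeline["table"]
        per_allele, per_read = candidate_summary(table)
        recount = {}
        for cands in table.candidates.values():
            for c in cands:
                recount[c.allele_id] = recount.get(c.allele_id, 0) + 1
        got = dict(zip(per_allele.allele_id, per_allele.n_candidate_reads))
        assert got == recount
        assert (per_read.n_candidates >= 1).all()

    def test_empty_table(self):
        from vgenotyper.candidate_mapping import CandidateTable

        per_allele, per_read = candidate_summary(
            CandidateTable({}, set(), 150)
        )
        assert per_allele.empty and per_read.empty

    def test_sam_adapter_reproduces_internal_mapping(self, tmp_path, small_locus):
        import pysam

        from vgenotyper.candidate_mapping import table_from_sam

        gt = vg.simulate_genotype(small_locus, seed=5)
        reads = vg.simulate_reads(gt, small_locus, depth=1, seed=6)
        header = {
            "HD": {"VN": "1.6"},
            "SQ": [
                {"SN": aid, "LN": len(small_locus[aid].sequence)}
                for aid in small_locus.allele_ids()
            ],
        }
        sam = tmp_path / "allmap.sam"
        with pysam.AlignmentFile(str(sam), "w", header=header) as fh:
            for r in reads:
                a = pysam.AlignedSegment()
                a.query_name = r.read_id
                a.query_sequence = r.sequence
                a.flag = 0
                a.reference_id = small_locus.allele_ids().index(r.truth_allele_id)
                a.reference_start = r.truth_offset
                a.mapping_quality = 60
                a.cigarstring = f"{len(r.sequence)}M"
                fh.write(a)
        table = table_from_sam(sam, small_locus)
        direct = map_reads_to_alleles(reads, small_locus)
        assert table.candidates == direct.candidates

    def test_single_read_three_candidates(self, db_factory):
        db = db_factory(
            {"G*01": "ACGTTGCA" * 40, "G*02": "ACGTTGCA" * 40,
             "G*03": "ACGTTGCA" * 40},
            pad_len=150,
        )
        read = db["G*01"].core[10:160]
        table = map_reads_to_alleles(
            vg.ReadSet([vg.SimRead("r", read)], 150, 1.0), db
        )
        _, per_read = candidate_summary(table)
        assert per_read.n_candidates.tolist() == [3]
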