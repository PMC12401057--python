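"""Read recruitment: orphon-region discovery, BAM/CRAM read extraction, depth.

Orphons are regions outside the canonical locus with high similarity to locus
genes; reads mis-mapped to them must be recruited alongside reads mapped to the
target locus itself.  The depth profile (genome-wide expected per-base coverage
mean/SD, classically measured on chromosome 1) anchors the ILP's
depth-consistency windows.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pysam

from .synthetic_data import ReadSet, SimRead


class RecruitmentError(ValueError):
    pass


@dataclass(frozen=True)
class GenomicRegion:
    chrom: str
    start: int  # 0-based
    end: int    # half-open

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise RecruitmentError(f"empty region {self.chrom}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class DepthProfile:
    """Expected per-base read depth (mean/SD) of the data set.

    ``ploidy`` records how many genome copies the measured region carries (2
    for an autosomal region); a single allele copy contributes mean/ploidy.
    """

    mean_depth: float
    sd_depth: float
    n_positions_sampled: int
    source_region: GenomicRegion | None = None
    ploidy: int = 2

    def __post_init__(self) -> None:
        if self.mean_depth <= 0:
            raise RecruitmentError("mean_depth must be > 0")
        if self.sd_depth < 0:
            raise RecruitmentError("sd_depth must be >= 0")

    @property
    def copy_mean(self) -> float:
        """Expected depth contributed by a single allele copy."""
        return self.mean_depth / self.ploidy

    @property
    def copy_sd(self) -> float:
        """Depth-tolerance SD: the dataset-level per-base SD, as measured.

        The coverage windows use the sequencing run's own depth variability
        (measured on a diploid reference region) as the tolerance scale for
        each copy; it is deliberately not rescaled by ploidy.
        """
        return self.sd_depth


def discover_orphons(
    mappings: Iterable[tuple[str, int, int]],
    min_region_len: int = 150,
) -> list[GenomicRegion]:
    """Merge contiguous read placements into regions; drop short ones.

    Overlapping or abutting placements merge into maximal regions; regions
    strictly shorter than ``min_region_len`` are removed.  Idempotent when fed
    its own output as degenerate placements.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in mappings:
        if start >= end:
            continue
        by_chrom.setdefault(chrom, []).append((start, end))
    out: list[GenomicRegion] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom])
        cur_s, cur_e = ivs[0]
        merged = []
        for s, e in ivs[1:]:
            if s <= cur_e:  # overlap or abut
                cur_e = max(cur_e, e)
            else:
                merged.append((cur_s, cur_e))
                cur_s, cur_e = s, e
        merged.append((cur_s, cur_e))
        out.extend(
            GenomicRegion(chrom, s, e) for s, e in merged if e - s >= min_region_len
        )
    return out


def orphons_from_sam(sam_path: str | Path, min_region_len: int = 150) -> list[GenomicRegion]:
    """Adapter: derive orphon regions from an external aligner's SAM output."""
    placements = []
    with pysam.AlignmentFile(str(sam_path), check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped:
                continue
            placements.append(
                (aln.reference_name, aln.reference_start, aln.reference_end)
            )
    return discover_orphons(placements, min_region_len)


def _resolve_chrom(name: str, header_names: set[str]) -> str:
    """Map a region chromosome name onto the alignment file's naming (chr1/1)."""
    if name in header_names:
        return name
    alt = name[3:] if name.startswith("chr") else f"chr{name}"
    if alt in header_names:
        return alt
    raise RecruitmentError(
        f"chromosome {name!r} not in alignment header; header has: "
        + ", ".join(sorted(header_names)[:25])
    )


def recruit_reads(
    alignments: pysam.AlignmentFile,
    target_regions: Sequence[GenomicRegion | tuple[str, int, int]],
    orphon_regions: Sequence[GenomicRegion | tuple[str, int, int]] = (),
) -> ReadSet:
    """Extract the union of reads overlapping any target or orphon region.

    Reads are deduplicated by (name, first/second-of-pair); secondary and
    supplementary alignments contribute recruitment but each underlying read
    appears once, with the sequence taken from a primary alignment when seen.
    """
    if not alignments.has_index():
        raise RecruitmentError("alignment file must be indexed (.bai/.crai)")
    header_names = set(alignments.references)
    seen: dict[tuple[str, int], str | None] = {}
    read_lengths: list[int] = []
    regions = [
        r if isinstance(r, GenomicRegion) else GenomicRegion(*r)
        for r in list(target_regions) + list(orphon_regions)
    ]
    for region in regions:
        chrom = _resolve_chrom(region.chrom, header_names)
        for aln in alignments.fetch(chrom, region.start, region.end):
            key = (aln.query_name, 2 if aln.is_read2 else 1)
            seq = None
            if not (aln.is_secondary or aln.is_supplementary):
                seq = aln.get_forward_sequence()
            if key not in seen or (seen[key] is None and seq is not None):
                seen[key] = seq
    reads = []
    for (name, mate), seq in sorted(seen.items()):
        if seq is None:
            continue  # only secondary placements seen; no primary sequence
        rid = name if mate == 1 else f"{name}/2"
        reads.append(SimRead(read_id=rid, sequence=seq.upper()))
        read_lengths.append(len(seq))
    read_length = int(np.median(read_lengths)) if read_lengths else 0
    return ReadSet(reads=reads, read_length=read_length, nominal_depth=0.0)


def estimate_depth(
    alignments: pysam.AlignmentFile,
    region: GenomicRegion | tuple[str, int, int],
    n_positions: int = 10_000,
    seed: int = 0,
    ploidy: int = 2,
) -> DepthProfile:
    """Sample per-base depth at ``n_positions`` random positions in ``region``.

    Zero-depth positions count toward the mean and SD.  A zero mean is a hard
    error (nothing can be genotyped without coverage).
    """
    region = region if isinstance(region, GenomicRegion) else GenomicRegion(*region)
    if len(region) < n_positions:
        raise RecruitmentError(
            f"region length {len(region)} < n_positions {n_positions}"
        )
    chrom = _resolve_chrom(region.chrom, set(alignments.references))
    rng = np.random.default_rng(seed)
    positions = rng.choice(np.arange(region.start, region.end), size=n_positions,
                           replace=False)
    positions.sort()
    depths = np.array(
        [alignments.count(chrom, int(p), int(p) + 1) for p in positions], dtype=float
    )
    mean = float(depths.mean())
    if mean == 0:
        raise RecruitmentError(
            f"zero coverage in {region.chrom}:{region.start}-{region.end}; "
            "cannot genotype (wrong region or exome data?)"
        )
    return DepthProfile(
        mean_depth=mean,
        sd_depth=float(depths.std(ddof=1)) if n_positions > 1 else 0.0,
        n_positions_sampled=n_positions,
        source_region=region,
        ploidy=ploidy,
    )


def read_bed(path: str | Path) -> list[GenomicRegion]:
    """Parse a 0-based half-open BED file into regions."""
    regions = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise RecruitmentError(f"malformed BED line: {line!r}")
            regions.append(GenomicRegion(fields[0], int(fields[1]), int(fields[2])))
    return regions


def write_bed(regions: Sequence[GenomicRegion], path: str | Path,
              header_lines: Sequence[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\n")
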