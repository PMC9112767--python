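"""Candidate mitochondrial read extraction from whole-genome alignments.

Mitochondrial reads in a WGS alignment live in three places: on the chrM
contig itself, misplaced onto nuclear NUMT "sink" regions (two intervals on
chr1 and chr17 attract most of them in hg38), and among unmapped reads whose
mate hit chrM.  This module pulls all three classes out of a SAM/BAM/CRAM
file, reunites mates, and gathers the read-count statistics the copy-number
estimator needs.

Files are streamed in a single pass, which at mitochondrial scale is cheaper
than random access and works identically for plain SAM.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pysam

from .reference import revcomp

#: hg38 NUMT read-sink intervals (1-based inclusive)
HG38_NUMT_SINKS = (
    ("chr1", 629084, 634422),
    ("chr17", 22521366, 22521502),
)


@dataclass(frozen=True)
class ExtractionRegions:
    chrm: str = "chrM"
    numt_sinks: tuple[tuple[str, int, int], ...] = HG38_NUMT_SINKS


@dataclass
class CoverageStats:
    """Read-count inputs for copy-number estimation."""

    chrm_reads: int = 0
    read_len: float = 0.0
    total_mapped_bases: int = 0
    sex: str | None = None  # "F", "M" or None
    metadata_cov: float | None = None
    per_contig: dict[str, int] = field(default_factory=dict)


@dataclass
class ExtractedPair:
    """A mate pair in original sequencing orientation (FASTQ-ready)."""

    read_id: str
    seq1: str = ""
    qual1: str = ""
    seq2: str = ""
    qual2: str = ""


def _original_orientation(read: pysam.AlignedSegment) -> tuple[str, str]:
    seq = read.query_sequence or ""
    qual = (
        "".join(chr(q + 33) for q in read.query_qualities)
        if read.query_qualities is not None
        else "I" * len(seq)
    )
    if read.is_reverse:
        return revcomp(seq), qual[::-1]
    return seq, qual


def _overlaps_sink(read: pysam.AlignedSegment, regions: ExtractionRegions) -> bool:
    if read.is_unmapped or read.reference_name is None:
        return False
    for chrom, start, end in regions.numt_sinks:
        if (
            read.reference_name == chrom
            and read.reference_start < end
            and read.reference_end is not None
            and read.reference_end > start - 1
        ):
            return True
    return False


def extract_candidate_reads(
    bam_path: str, regions: ExtractionRegions | None = None
) -> list[ExtractedPair]:
    """All chrM reads, NUMT-sink reads, and unmapped mates of chrM reads.

    Secondary and supplementary alignments are ignored.  Mates are reunited
    by name; each read is emitted exactly once.  Raises if the file lacks a
    chrM-style contig.
    """
    regions = regions or ExtractionRegions()
    pairs: dict[str, ExtractedPair] = {}
    with pysam.AlignmentFile(bam_path, check_sq=False) as fh:
        if regions.chrm not in (fh.references or ()):
            raise ValueError(f"{bam_path}: contig {regions.chrm!r} not in header")
        for read in fh:
            if read.is_secondary or read.is_supplementary:
                continue
            wanted = (
                (not read.is_unmapped and read.reference_name == regions.chrm)
                or _overlaps_sink(read, regions)
                or (
                    read.is_unmapped
                    and not read.mate_is_unmapped
                    and read.next_reference_name == regions.chrm
                )
            )
            if not wanted:
                continue
            pair = pairs.setdefault(read.query_name, ExtractedPair(read.query_name))
            seq, qual = _original_orientation(read)
            if read.is_read2:
                if not pair.seq2:
                    pair.seq2, pair.qual2 = seq, qual
            else:
                if not pair.seq1:
                    pair.seq1, pair.qual1 = seq, qual
    return [pairs[k] for k in sorted(pairs)]


def collect_coverage_stats(
    bam_path: str,
    regions: ExtractionRegions | None = None,
    sex: str | None = None,
    metadata_cov: float | None = None,
) -> CoverageStats:
    """Count primary mapped non-duplicate reads and aligned bases per contig.

    ``total_mapped_bases`` sums aligned reference-consuming read bases
    (CIGAR M/=/X); soft-clipped tails do not count toward coverage.
    """
    regions = regions or ExtractionRegions()
    stats = CoverageStats(sex=sex, metadata_cov=metadata_cov)
    n_reads = 0
    len_sum = 0
    with pysam.AlignmentFile(bam_path, check_sq=False) as fh:
        if regions.chrm not in (fh.references or ()):
            raise ValueError(f"{bam_path}: contig {regions.chrm!r} not in header")
        for read in fh:
            if (
                read.is_unmapped
                or read.is_secondary
                or read.is_supplementary
                or read.is_duplicate
            ):
                continue
            contig = read.reference_name or ""
            stats.per_contig[contig] = stats.per_contig.get(contig, 0) + 1
            aligned = sum(
                ln for op, ln in (read.cigartuples or ()) if op in (0, 7, 8)
            )
            stats.total_mapped_bases += aligned
            n_reads += 1
            len_sum += read.query_length or aligned
    stats.chrm_reads = stats.per_contig.get(regions.chrm, 0)
    stats.read_len = (len_sum / n_reads) if n_reads else 0.0
    return stats
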