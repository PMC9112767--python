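"""Mitochondrial reference handling: circularization, coordinates, region tracks.

The human mitochondrial genome is a 16,569-bp circle conventionally numbered
1..16569 (rCRS numbering).  Short-read aligners expect linear contigs, so the
working reference is the linear sequence extended past position 16569 by a
copy of its first ``ext_len`` bases; alignments landing on the extension are
wrapped back to canonical coordinates.

This module also owns the region annotations used downstream: interval tracks
(homopolymer, hypervariable, hotspot, genic) and site lists (NUMT, haplogroup
defining, dbSNP), plus the polycytosine homopolymer finder (five or more Cs in
a row, allowing one interior mismatch, padded by 1 bp on each end).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

from intervaltree import IntervalTree

MT_LENGTH = 16569
DEFAULT_EXT_LEN = 300

#: interval-style track kinds (BED on disk) vs site-list kinds (VCF on disk)
INTERVAL_KINDS = ("HP", "HV", "HS", "GENIC")
SITE_KINDS = ("NUMT", "HG", "DBSNP")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_VALID_SEQ = re.compile(r"^[ACGTN]+$")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ReferenceBundle:
    """A linear mitochondrial reference plus its circular extension.

    Attributes
    ----------
    name
        Contig name (``chrM`` for the bundled reference).
    seq
        Uppercase A/C/G/T/N sequence of length ``L``.
    ext_len
        Number of bases from the start of the sequence appended after the
        end to emulate the circle.
    """

    name: str
    seq: str
    ext_len: int = DEFAULT_EXT_LEN

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError("reference sequence is empty")
        if not _VALID_SEQ.match(self.seq):
            raise ValueError("reference contains non-ACGTN characters")
        if not 0 < self.ext_len < len(self.seq):
            raise ValueError(
                f"ext_len must be in (0, {len(self.seq)}), got {self.ext_len}"
            )

    @property
    def L(self) -> int:
        return len(self.seq)

    @property
    def ext_seq(self) -> str:
        """The circularized working sequence, ``seq + seq[:ext_len]``."""
        return self.seq + self.seq[: self.ext_len]

    def base(self, pos: int) -> str:
        """Base at 1-based canonical position ``pos``."""
        if not 1 <= pos <= self.L:
            raise ValueError(f"position {pos} outside [1, {self.L}]")
        return self.seq[pos - 1]


def load_fasta(path: str | Path, ext_len: int = DEFAULT_EXT_LEN) -> ReferenceBundle:
    """Load a single-record FASTA into a :class:`ReferenceBundle`.

    Raises ``ValueError`` for empty files, multi-record files, or sequences
    containing characters outside A/C/G/T/N.
    """
    name = None
    parts: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    raise ValueError(f"{path}: multi-record FASTA not supported")
                name = line[1:].split()[0]
            else:
                if name is None:
                    raise ValueError(f"{path}: sequence before FASTA header")
                parts.append(line.strip().upper())
    if name is None or not parts:
        raise ValueError(f"{path}: empty or headerless FASTA")
    return ReferenceBundle(name=name, seq="".join(parts), ext_len=ext_len)


def bundled_reference_path() -> Path:
    """Path of the packaged synthetic chrM fixture (see its header line)."""
    return Path(resources.files("mitocall").joinpath("data/chrM_synthetic.fa"))


def default_reference(ext_len: int = DEFAULT_EXT_LEN) -> ReferenceBundle:
    """Load the packaged 16,569-bp synthetic chrM stand-in."""
    return load_fasta(bundled_reference_path(), ext_len=ext_len)


def wrap_position(p: int, L: int, ext_len: int = DEFAULT_EXT_LEN) -> int:
    """Map a 1-based position on the extended reference to canonical 1..L.

    Positions 1..L are returned unchanged; position L+1 maps to 1, and so on
    up to L+ext_len.  Idempotent on canonical positions.
    """
    if not 1 <= p <= L + ext_len:
        raise ValueError(f"position {p} outside [1, {L + ext_len}]")
    return p if p <= L else p - L


@dataclass(frozen=True, order=True)
class Interval:
    """1-based inclusive interval with a free-text label."""

    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"bad interval [{self.start}, {self.end}]")

    def __len__(self) -> int:
        return self.end - self.start + 1


class RegionTrack:
    """Either an interval track or a (pos, ref, alt) site list.

    Interval membership is by 1-based position; site membership is by the
    exact (position, ref, alt) triple.
    """

    def __init__(
        self,
        kind: str,
        intervals: Iterable[Interval] = (),
        sites: Iterable[tuple[int, str, str]] = (),
    ):
        self.kind = kind
        self.intervals: list[Interval] = sorted(intervals)
        self.sites: set[tuple[int, str, str]] = {
            (int(p), r.upper(), a.upper()) for p, r, a in sites
        }
        self._tree = IntervalTree()
        for iv in self.intervals:
            # IntervalTree is half-open; store [start, end+1)
            self._tree.addi(iv.start, iv.end + 1, iv.label)

    def __contains__(self, pos: int) -> bool:
        return bool(self._tree[pos])

    def contains(self, pos: int) -> bool:
        return pos in self

    def labels_at(self, pos: int) -> list[str]:
        return sorted(hit.data for hit in self._tree[pos])

    def contains_site(self, pos: int, ref: str, alt: str) -> bool:
        return (int(pos), ref.upper(), alt.upper()) in self.sites

    def nearest_distance(self, pos: int) -> int | None:
        """Distance in bp to the closest interval (0 if inside); None if empty."""
        if not self.intervals:
            return None
        best = None
        for iv in self.intervals:
            if iv.start <= pos <= iv.end:
                return 0
            d = min(abs(pos - iv.start), abs(pos - iv.end))
            best = d if best is None else min(best, d)
        return best

    # ---- BED round trip (0-based half-open on disk) ----

    @classmethod
    def from_bed(cls, kind: str, path: str | Path) -> "RegionTrack":
        ivs = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise ValueError(f"{path}:{lineno}: expected >=3 BED columns")
                try:
                    start0, end0 = int(fields[1]), int(fields[2])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: non-integer BED bounds") from exc
                if end0 <= start0:
                    raise ValueError(f"{path}:{lineno}: empty/inverted BED interval")
                label = fields[3] if len(fields) > 3 else kind
                ivs.append(Interval(start0 + 1, end0, label))
        return cls(kind, intervals=ivs)

    def to_bed(self, path: str | Path, chrom: str = "chrM") -> None:
        with open(path, "w") as fh:
            for iv in self.intervals:
                fh.write(f"{chrom}\t{iv.start - 1}\t{iv.end}\t{iv.label}\n")

    @classmethod
    def from_vcf_sites(cls, kind: str, path: str | Path) -> "RegionTrack":
        """Load a site list from a (possibly header-only) VCF file."""
        from . import vcfio

        sites = [(rec.pos, rec.ref, rec.alt) for rec in vcfio.read_records(path)]
        return cls(kind, sites=sites)


def find_homopolymer_regions(
    seq: str,
    min_run: int = 5,
    base: str = "C",
    max_mismatch: int = 1,
    pad: int = 1,
    scan_reverse_complement: bool = False,
) -> list[Interval]:
    """Locate homopolymer regions: runs of ``base`` with limited interruptions.

    A region is a stretch of ``base`` runs separated by single-character
    mismatches — at most ``max_mismatch`` of them, each flanked by at least
    one ``base`` on both sides — containing ``min_run`` or more copies of
    ``base`` in total.  Maximal such stretches are padded by ``pad`` bp on
    each end, clipped to the sequence, and merged when they overlap.

    With ``scan_reverse_complement`` the complementary base is scanned on the
    same strand as well (a C-tract on the minus strand is a G-tract here).

    Returns 1-based inclusive :class:`Interval` objects labelled ``HP``.
    """
    if min_run < 2:
        raise ValueError(f"min_run must be >= 2, got {min_run}")
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    bases = [base.upper()]
    if scan_reverse_complement:
        bases.append(revcomp(base.upper()))

    candidates: list[tuple[int, int]] = []  # 0-based inclusive
    for b in bases:
        runs = [(m.start(), m.end() - 1) for m in re.finditer(f"{b}+", seq)]
        for i in range(len(runs)):
            total = runs[i][1] - runs[i][0] + 1
            end = runs[i][1]
            j = i
            best_end = end if total >= min_run else None
            while (
                j + 1 < len(runs)
                and runs[j + 1][0] - runs[j][1] == 2  # exactly one mismatch char
                and (j + 1 - i) <= max_mismatch
            ):
                j += 1
                total += runs[j][1] - runs[j][0] + 1
                end = runs[j][1]
                if total >= min_run:
                    best_end = end
            if best_end is not None:
                candidates.append((runs[i][0], best_end))

    if not candidates:
        return []
    # pad, clip, merge overlaps; convert to 1-based
    padded = sorted(
        (max(0, s - pad), min(len(seq) - 1, e + pad)) for s, e in candidates
    )
    merged = [list(padded[0])]
    for s, e in padded[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [Interval(s + 1, e + 1, "HP") for s, e in merged]


def load_region_tracks(paths: Mapping[str, str | Path]) -> dict[str, RegionTrack]:
    """Load tracks from a kind -> path map.

    Interval kinds (HP, HV, HS, GENIC) read 4-column BED; site kinds
    (NUMT, HG, DBSNP) read VCF site lists.  Unknown kinds raise.
    """
    tracks: dict[str, RegionTrack] = {}
    for kind, path in paths.items():
        kind = kind.upper()
        if kind in INTERVAL_KINDS:
            tracks[kind] = RegionTrack.from_bed(kind, path)
        elif kind in SITE_KINDS:
            tracks[kind] = RegionTrack.from_vcf_sites(kind, path)
        else:
            raise ValueError(f"unknown track kind {kind!r}")
    return tracks


def default_track_paths() -> dict[str, Path]:
    root = Path(resources.files("mitocall").joinpath("data/tracks_synthetic"))
    return {
        "HV": root / "hv.bed",
        "HS": root / "hs.bed",
        "GENIC": root / "genic.bed",
        "NUMT": root / "numt_sites.vcf",
        "DBSNP": root / "dbsnp_sites.vcf",
    }


def load_default_tracks(ref: ReferenceBundle | None = None) -> dict[str, RegionTrack]:
    """Bundled synthetic tracks plus an HP track computed from the reference."""
    tracks = load_region_tracks(default_track_paths())
    if ref is None:
        ref = default_reference()
    tracks["HP"] = RegionTrack("HP", intervals=find_homopolymer_regions(ref.seq))
    return tracks
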