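"""Read mapping against the circularized mitochondrial reference.

A deliberately small short-read mapper: exact k-mer seeding over the extended
(circular) reference, candidate placements from seed diagonals, and a windowed
edit-distance extension (edlib) to pick the best placement and produce a
CIGAR.  Alignments landing on the circular extension are wrapped back to
canonical coordinates, and alignments whose reference span crosses the
origin are split into two records so every emitted alignment lies within
[1, L].

Also here: duplicate marking on fragment coordinates and seeded down-sampling
to a target fold-coverage, the two alignment-level preprocessing steps the
variant caller expects.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, replace

import edlib
import numpy as np

from .reference import ReferenceBundle, revcomp, wrap_position
from .simulate import ReadPair

_WINDOW_PAD = 12  # extension window slack around a seed diagonal
_MAX_DIST_FRAC = 0.12  # reject placements above this edit-distance fraction
_HAMMING_MAX = 10  # prefer a pure-substitution placement up to this many mismatches


@dataclass
class Alignment:
    """One placed read on the canonical (1..L) reference frame.

    ``seq``/``quals`` are stored reference-oriented (reverse-complemented for
    minus-strand reads) so pileup can walk the CIGAR directly.
    """

    read_id: str
    ref_name: str
    start: int  # 1-based canonical
    strand: str  # "+" or "-"
    cigar: list[tuple[str, int]]
    seq: str
    quals: str
    mapq: int = 60
    score: int = 0  # edit distance of the placement
    mate_start: int | None = None
    mate_strand: str | None = None
    is_duplicate: bool = False

    @property
    def ref_span(self) -> int:
        return sum(ln for op, ln in self.cigar if op in "MDX=")

    @property
    def end(self) -> int:
        """1-based inclusive end on the (possibly unwrapped) reference frame."""
        return self.start + self.ref_span - 1

    @property
    def query_len(self) -> int:
        return sum(ln for op, ln in self.cigar if op in "MIX=S")


@dataclass
class AlignerIndex:
    k: int
    positions: dict[str, list[int]]  # k-mer -> 0-based offsets in ext_seq
    ref: ReferenceBundle


def build_index(ref: ReferenceBundle, k: int = 21) -> AlignerIndex:
    """Exact k-mer index over the extended reference; k must be >= 11."""
    if k < 11:
        raise ValueError(f"k must be >= 11, got {k}")
    ext = ref.ext_seq
    positions: dict[str, list[int]] = defaultdict(list)
    for i in range(len(ext) - k + 1):
        positions[ext[i : i + k]].append(i)
    return AlignerIndex(k=k, positions=dict(positions), ref=ref)


def _parse_edlib_cigar(text: str) -> list[tuple[str, int]]:
    ops: list[tuple[str, int]] = []
    num = 0
    for ch in text:
        if ch.isdigit():
            num = num * 10 + ord(ch) - 48
        else:
            op = "M" if ch in "=X" else ch
            if ops and ops[-1][0] == op:
                ops[-1] = (op, ops[-1][1] + num)
            else:
                ops.append((op, num))
            num = 0
    # terminal insertions have no reference anchor; report them as softclips
    if ops and ops[0][0] == "I":
        ops[0] = ("S", ops[0][1])
    if ops and ops[-1][0] == "I":
        ops[-1] = ("S", ops[-1][1])
    return ops


def _seed_candidates(seq: str, index: AlignerIndex) -> set[int]:
    k = index.k
    n = len(seq)
    if n < k:
        return set()
    lookup = index.positions.get
    offsets = {0, (n - k) // 3, 2 * (n - k) // 3, n - k}
    cands: set[int] = set()
    for off in offsets:
        hits = lookup(seq[off : off + k])
        if hits:
            for h in hits:
                cands.add(h - off)
    return cands


def _extend(seq: str, diag: int, ext: str, max_dist: int):
    """Align read near a candidate diagonal; return (dist, start0_ext, cigar)."""
    n = len(seq)
    w0 = max(0, diag - _WINDOW_PAD)
    w1 = min(len(ext), diag + n + _WINDOW_PAD)
    window = ext[w0:w1]
    exact_at = diag - w0
    on_diag = window[exact_at : exact_at + n]
    if on_diag == seq:
        return 0, diag, [("M", n)]
    mismatches = None
    if len(on_diag) == n:
        # Prefer the substitution representation when it is close: an
        # edit-distance traceback may tie a terminal mismatch against a
        # clip or a 1-bp gap, which would dilute allele counts at the site.
        mismatches = int(
            np.count_nonzero(
                np.frombuffer(seq.encode(), np.uint8)
                != np.frombuffer(on_diag.encode(), np.uint8)
            )
        )
        if mismatches <= min(2, max_dist):
            return mismatches, diag, [("M", n)]
    res = edlib.align(seq, window, mode="HW", task="path", k=max_dist)
    if res["editDistance"] < 0:
        # no gapped placement within budget; a moderately mismatched
        # diagonal placement may still be the read's true home
        if mismatches is not None and mismatches <= min(_HAMMING_MAX, max_dist):
            return mismatches, diag, [("M", n)]
        return None
    if (
        mismatches is not None
        and mismatches <= min(_HAMMING_MAX, max_dist)
        and res["editDistance"] + 2 > mismatches
    ):
        # a gap buys fewer than 2 edits over pure substitutions: reads with
        # an indel shifted tail switch to the gapped form, reads with plain
        # sequencing errors keep the full-length match
        return mismatches, diag, [("M", n)]
    loc = res["locations"][0]
    cigar = _parse_edlib_cigar(res["cigar"])
    start0 = w0 + loc[0]
    if cigar and cigar[0][0] == "S":
        start0 -= 0  # softclip consumes no reference
    return res["editDistance"], start0, cigar


def map_read(
    read_id: str,
    seq: str,
    quals: str,
    index: AlignerIndex,
    ref: ReferenceBundle,
) -> Alignment | None:
    """Best placement of one read on the circular reference, or None.

    Tries both orientations; candidates come from seed k-mers, the winner is
    the placement with the lowest edit distance.  Ties across distinct
    canonical positions get MAPQ 0 (multi-mapping); placements on the
    extension are wrapped to canonical coordinates.
    """
    max_dist = max(4, int(len(seq) * _MAX_DIST_FRAC))
    ext = ref.ext_seq
    best = None  # (dist, canonical_start0, strand, cigar)
    ties = 0
    for strand, oriented, oquals in (
        ("+", seq, quals),
        ("-", revcomp(seq), quals[::-1]),
    ):
        for diag in _seed_candidates(oriented, index):
            if diag < -_WINDOW_PAD:
                continue
            hit = _extend(oriented, diag, ext, max_dist)
            if hit is None:
                continue
            dist, start0, cigar = hit
            canon0 = start0 % ref.L  # position L+1 on ext is canonical 1
            if best is None or dist < best[0]:
                best = (dist, canon0, strand, cigar, oriented, oquals)
                ties = 0
            elif dist == best[0] and (canon0, strand) != (best[1], best[2]):
                ties += 1
                if canon0 < best[1]:  # deterministic representative placement
                    best = (dist, canon0, strand, cigar, oriented, oquals)
    if best is None:
        return None
    dist, canon0, strand, cigar, oriented, oquals = best
    return Alignment(
        read_id=read_id,
        ref_name=ref.name,
        start=canon0 + 1,
        strand=strand,
        cigar=cigar,
        seq=oriented,
        quals=oquals,
        mapq=0 if ties else 60,
        score=dist,
    )


def map_read_pair(
    pair: ReadPair, index: AlignerIndex, ref: ReferenceBundle
) -> tuple[Alignment | None, Alignment | None]:
    """Map both mates; annotate mate coordinates for duplicate marking.

    Pairs violating proper orientation or exceeding the maximum circular
    insert (1000 bp) keep their individual placements but are flagged by
    MAPQ 0 on neither — improper pairs are rare enough at mitochondrial
    scale that per-read placement evidence dominates.
    """
    a1 = map_read(pair.read_id, pair.seq1, pair.qual1, index, ref)
    a2 = map_read(pair.read_id, pair.seq2, pair.qual2, index, ref)
    if a1 is not None and a2 is not None:
        a1.mate_start, a1.mate_strand = a2.start, a2.strand
        a2.mate_start, a2.mate_strand = a1.start, a1.strand
    return a1, a2


def split_origin_spanning(aln: Alignment, L: int) -> list[Alignment]:
    """Split an alignment whose reference span crosses position L.

    Returns [aln] unchanged when no split is needed; otherwise two alignments
    covering [start..L] and [1..remainder] that together conserve reference
    and read bases.  An insertion sitting exactly on the junction stays with
    the piece containing its anchor base.
    """
    span = aln.ref_span
    if span == 0:
        raise ValueError(f"{aln.read_id}: empty reference span")
    if aln.end <= L:
        return [aln]
    if aln.start > L:
        raise ValueError(f"{aln.read_id}: start beyond reference end")
    boundary = L - aln.start + 1  # reference bases belonging to piece A
    piece_a: list[tuple[str, int]] = []
    piece_b: list[tuple[str, int]] = []
    consumed_ref = 0
    consumed_query_a = 0
    in_a = True
    for op, ln in aln.cigar:
        uses_ref = op in "MD"
        if in_a:
            if not uses_ref:
                piece_a.append((op, ln))
                if op in "IS":
                    consumed_query_a += ln
                continue
            if consumed_ref + ln <= boundary:
                piece_a.append((op, ln))
                consumed_ref += ln
                if op == "M":
                    consumed_query_a += ln
                if consumed_ref == boundary:
                    in_a = False
                continue
            take = boundary - consumed_ref
            if take > 0:
                piece_a.append((op, take))
                if op == "M":
                    consumed_query_a += take
            piece_b.append((op, ln - take))
            consumed_ref += ln
            in_a = False
        elif op == "I" and not piece_b:
            # insertion anchored on the junction base belongs to piece A
            piece_a.append((op, ln))
        else:
            piece_b.append((op, ln))
    if not piece_b:
        return [aln]
    qa = consumed_query_a
    first = replace(aln, cigar=piece_a, seq=aln.seq[:qa], quals=aln.quals[:qa])
    second = replace(
        aln, start=1, cigar=piece_b, seq=aln.seq[qa:], quals=aln.quals[qa:]
    )
    return [first, second]


def mark_duplicates(alignments: list[Alignment]) -> list[Alignment]:
    """Flag duplicate pairs sharing both fragment endpoints.

    The retained pair is the one with the highest summed base quality
    (ties broken by read id).  Operates in place and returns the list.
    """
    by_read: dict[str, list[Alignment]] = defaultdict(list)
    for a in alignments:
        by_read[a.read_id].append(a)
    groups: dict[tuple, list[tuple[float, str]]] = defaultdict(list)
    for read_id, alns in by_read.items():
        key = tuple(sorted((a.start, a.strand) for a in alns))
        qsum = sum(sum(a.quals.encode()) - 33 * len(a.quals) for a in alns)
        groups[key].append((-qsum, read_id))
    dup_ids = set()
    for members in groups.values():
        if len(members) > 1:
            members.sort()
            for _, read_id in members[1:]:
                dup_ids.add(read_id)
    for a in alignments:
        a.is_duplicate = a.read_id in dup_ids
    return alignments


def downsample(
    alignments: list[Alignment],
    target_cov: float = 2000.0,
    L: int = 16569,
    seed: int = 0,
) -> list[Alignment]:
    """Thin read pairs to ~target fold-coverage; identity when already below.

    Whole pairs are kept independently with probability target/observed, so
    the output is a subset of the input and strand balance is preserved.
    """
    if target_cov <= 0:
        raise ValueError("target_cov must be positive")
    total_bases = sum(a.query_len for a in alignments)
    observed = total_bases / L
    if observed <= target_cov:
        return list(alignments)
    p_keep = target_cov / observed
    rng = np.random.default_rng(seed)
    read_ids = sorted({a.read_id for a in alignments})
    keep = {rid for rid in read_ids if rng.random() < p_keep}
    return [a for a in alignments if a.read_id in keep]


def map_reads(
    pairs: list[ReadPair],
    index: AlignerIndex,
    ref: ReferenceBundle,
    split: bool = True,
) -> list[Alignment]:
    """Map all pairs; mark duplicates on raw coordinates; split at the origin."""
    raw: list[Alignment] = []
    for pair in pairs:
        a1, a2 = map_read_pair(pair, index, ref)
        if a1 is not None:
            raw.append(a1)
        if a2 is not None:
            raw.append(a2)
    mark_duplicates(raw)
    if not split:
        return raw
    out: list[Alignment] = []
    for a in raw:
        out.extend(split_origin_spanning(a, ref.L))
    return out
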