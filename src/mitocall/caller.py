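"""Strand-aware pileup and frequency-threshold variant calling.

The caller is intentionally model-free: an allele is called when its allele
fraction reaches ``vaf_min`` (default 3%) with at least ``min_reads_per_strand``
supporting reads on *each* strand, at sites with at least ``min_depth``
usable depth.  Calls at or above ``homoplasmy_vaf`` (default 97%) are
classified homoplasmic, everything in between heteroplasmic.  Bases below
the quality floor are excluded from allele counts (and from the VAF
denominator) but still count toward raw depth.

At ~2000x down-sampled coverage and a 1% sequencing error rate these three
thresholds dominate calling accuracy; there is no mutation-model likelihood,
which keeps every decision enumerable by the brute-force oracle in the test
suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .alleles import normalize_variant, variant_type
from .align import Alignment
from .reference import ReferenceBundle, RegionTrack

_BYTE_TO_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BYTE_TO_CODE[_b] = _i
_BASES = "ACGT"

#: INDEL reliability caveat: flag indels this close to a homopolymer region
HP_ADJACENT_WINDOW = 150


@dataclass(frozen=True)
class CallerConfig:
    vaf_min: float = 0.03
    min_reads_per_strand: int = 2
    homoplasmy_vaf: float = 0.97
    min_baseq: int = 20
    min_depth: int = 10

    def __post_init__(self) -> None:
        if not 0 < self.vaf_min < self.homoplasmy_vaf <= 1:
            raise ValueError("need 0 < vaf_min < homoplasmy_vaf <= 1")


@dataclass
class VariantCall:
    position: int
    ref: str
    alt: str
    vaf: float
    depth: int
    strand_counts: tuple[int, int]
    type: str
    klass: str  # HETEROPLASMY or HOMOPLASMY
    filters: set[str] = field(default_factory=set)
    annotations: dict[str, object] = field(default_factory=dict)
    iteration: int = 1

    def key(self) -> tuple[int, str, str]:
        return (self.position, self.ref, self.alt)

    @property
    def passing(self) -> bool:
        return not self.filters


@dataclass
class PileupColumn:
    """Per-position allele evidence.

    ``allele_counts`` maps allele keys to (fwd, rev) passing-quality counts.
    Keys are single bases for substitutions, ``I:<seq>`` for an insertion
    anchored at this position and ``D:<n>`` for an n-base deletion anchored
    here.  ``depth`` is passing depth (allele counts plus reads spanning this
    position with a deletion); ``raw_depth`` additionally counts low-quality
    bases.
    """

    position: int
    depth: int
    raw_depth: int
    allele_counts: dict[str, tuple[int, int]]
    spanning_deletions: int = 0


class Pileup:
    """Column store over the whole mitochondrial circle."""

    def __init__(self, ref: ReferenceBundle):
        self.ref = ref
        L = ref.L
        self.base_counts = np.zeros((L + 2, 4, 2), dtype=np.int32)
        self.raw_depth = np.zeros(L + 2, dtype=np.int32)
        self.spanning_del = np.zeros(L + 2, dtype=np.int32)
        #: canonical (pos, ref, alt) -> [fwd, rev] support for indel/MNV alleles
        self.indels: dict[tuple[int, str, str], list[int]] = {}

    @property
    def passing_depth(self) -> np.ndarray:
        return self.base_counts.sum(axis=(1, 2)) + self.spanning_del

    def column(self, pos: int) -> PileupColumn:
        counts: dict[str, tuple[int, int]] = {}
        for code in range(4):
            f, r = int(self.base_counts[pos, code, 0]), int(
                self.base_counts[pos, code, 1]
            )
            if f or r:
                counts[_BASES[code]] = (f, r)
        for (p, refa, alta), (f, r) in self.indels.items():
            if p != pos:
                continue
            if len(refa) == 1 and alta.startswith(refa):
                counts[f"I:{alta[1:]}"] = (f, r)
            elif len(alta) == 1 and refa.startswith(alta):
                counts[f"D:{len(refa) - 1}"] = (f, r)
            else:
                counts[f"B:{refa}>{alta}"] = (f, r)
        return PileupColumn(
            position=pos,
            depth=int(self.passing_depth[pos]),
            raw_depth=int(self.raw_depth[pos]),
            allele_counts=counts,
            spanning_deletions=int(self.spanning_del[pos]),
        )


def build_pileup(
    alignments: Iterable[Alignment],
    ref: ReferenceBundle,
    min_baseq: int = 20,
) -> Pileup:
    """Accumulate per-position strand-resolved allele counts from CIGARs.

    Duplicates and MAPQ-0 (multi-mapping) alignments are skipped.  Matched
    stretches are accumulated in bulk; reads containing indels walk their
    CIGAR individually.  Insertions are keyed to the anchor base before the
    inserted sequence; deletions count as spanning events at every deleted
    position plus an anchored deletion allele.
    """
    pile = Pileup(ref)
    L = ref.L
    simple: dict[int, list[tuple[int, str, str, int]]] = {}
    complex_alns: list[Alignment] = []
    for aln in alignments:
        if aln.is_duplicate or aln.mapq == 0:
            continue
        if aln.start < 1 or aln.end > L:
            raise ValueError(
                f"{aln.read_id}: span [{aln.start}, {aln.end}] outside [1, {L}]"
            )
        if len(aln.cigar) == 1 and aln.cigar[0][0] == "M":
            n = aln.cigar[0][1]
            simple.setdefault(n, []).append(
                (aln.start, aln.seq, aln.quals, 0 if aln.strand == "+" else 1)
            )
        else:
            complex_alns.append(aln)

    for n, group in simple.items():
        starts = np.array([g[0] for g in group], dtype=np.int64)
        seqs = np.frombuffer("".join(g[1] for g in group).encode(), np.uint8)
        quals = np.frombuffer("".join(g[2] for g in group).encode(), np.uint8)
        strands = np.array([g[3] for g in group], dtype=np.int64)
        codes = _BYTE_TO_CODE[seqs].reshape(-1, n)
        q = quals.reshape(-1, n).astype(np.int16) - 33
        pos = starts[:, None] + np.arange(n)
        np.add.at(pile.raw_depth, pos.ravel(), 1)
        ok = (codes < 4) & (q >= min_baseq)
        flat = (pos * 8 + codes * 2 + strands[:, None])[ok]
        counts = np.bincount(flat, minlength=(L + 2) * 8)
        pile.base_counts += counts.reshape(L + 2, 4, 2)

    for aln in complex_alns:
        _walk_complex(pile, aln, ref, min_baseq)
    return pile


_INDEL_GROUP_GAP = 6  # merge indel CIGAR ops separated by this many matches


def _walk_complex(
    pile: Pileup, aln: Alignment, ref: ReferenceBundle, min_baseq: int
) -> None:
    """CIGAR walk for reads containing indels or clips.

    Matched bases accumulate as usual.  Indel ops are grouped when separated
    by at most a few matched bases, and each group is re-expressed as ONE
    canonical replacement of the spanned reference by the spanned read
    sequence, normalized (trimmed + left-aligned) against the reference.
    Different edit-distance tracebacks of the same underlying event — e.g. a
    3-bp insertion split into two smaller insertions around a matching base —
    thereby collapse onto a single allele key across reads.
    """
    sidx = 0 if aln.strand == "+" else 1
    rpos = aln.start
    qpos = 0
    ops: list[tuple[str, int, int, int]] = []  # (op, ln, rpos0, qpos0)
    for op, ln in aln.cigar:
        ops.append((op, ln, rpos, qpos))
        if op == "M":
            for i in range(ln):
                pile.raw_depth[rpos + i] += 1
                q = ord(aln.quals[qpos + i]) - 33
                code = _BYTE_TO_CODE[ord(aln.seq[qpos + i])]
                if code < 4 and q >= min_baseq:
                    pile.base_counts[rpos + i, code, sidx] += 1
            rpos += ln
            qpos += ln
        elif op == "I":
            qpos += ln
        elif op == "D":
            rpos += ln
        elif op == "S":
            qpos += ln
        else:
            raise ValueError(f"unsupported CIGAR op {op!r}")

    # group indel ops by reference proximity
    groups: list[list[int]] = []
    for i, (op, ln, r0, q0) in enumerate(ops):
        if op not in "ID":
            continue
        if groups:
            prev = ops[groups[-1][-1]]
            prev_ref_end = prev[2] + (prev[1] if prev[0] == "D" else 0)
            if r0 - prev_ref_end <= _INDEL_GROUP_GAP:
                groups[-1].append(i)
                continue
        groups.append([i])

    for group in groups:
        first = ops[group[0]]
        last = ops[group[-1]]
        if group[0] == 0 or ops[group[0] - 1][0] != "M":
            continue  # no anchoring match base (e.g. piece boundary)
        anchor_r = first[2] - 1
        anchor_q = first[3] - 1
        if anchor_r < 1:
            continue
        ref_end = last[2] + (last[1] if last[0] == "D" else 0) - 1
        q_end = last[3] + (last[1] if last[0] == "I" else 0)
        refa = ref.seq[anchor_r - 1 : ref_end]
        alta = aln.seq[anchor_q:q_end]
        if not refa or not alta:
            continue
        pos, refa, alta = normalize_variant(anchor_r, refa, alta, ref.seq)
        pile.indels.setdefault((pos, refa, alta), [0, 0])[sidx] += 1
        if len(alta) == 1 and len(refa) > 1 and refa[0] == alta:
            pile.spanning_del[pos + 1 : pos + len(refa)] += 1


def _classify(vaf: float, cfg: CallerConfig) -> str:
    return "HOMOPLASMY" if vaf >= cfg.homoplasmy_vaf else "HETEROPLASMY"


def call_site(
    col: PileupColumn,
    ref_base: str,
    cfg: CallerConfig,
    ref_seq: str | None = None,
) -> list[VariantCall]:
    """Threshold calling for one pileup column.

    Emits every non-reference allele whose fraction of passing depth reaches
    ``vaf_min``; alleles failing the per-strand support floor carry a
    STRAND_BIAS filter, and sites below ``min_depth`` carry NO_CALL.  All
    alleles at a site are reported, so multiallelic records survive.
    """
    calls: list[VariantCall] = []
    depth = col.depth
    if depth <= 0:
        return calls
    for allele, (fwd, rev) in sorted(col.allele_counts.items()):
        if allele == ref_base:
            continue
        vaf = (fwd + rev) / depth
        if vaf < cfg.vaf_min:
            continue
        filters: set[str] = set()
        if fwd < cfg.min_reads_per_strand or rev < cfg.min_reads_per_strand:
            filters.add("STRAND_BIAS")
        if depth < cfg.min_depth:
            filters.add("NO_CALL")
        if allele.startswith("I:"):
            ref, alt = ref_base, ref_base + allele[2:]
        elif allele.startswith("D:"):
            dlen = int(allele[2:])
            if ref_seq is not None:
                ref = ref_seq[col.position - 1 : col.position + dlen]
            else:
                ref = ref_base + "N" * dlen
            alt = ref_base
        else:
            ref, alt = ref_base, allele
        calls.append(
            VariantCall(
                position=col.position,
                ref=ref,
                alt=alt,
                vaf=vaf,
                depth=depth,
                strand_counts=(fwd, rev),
                type=variant_type(ref, alt),
                klass=_classify(vaf, cfg),
                filters=filters,
            )
        )
    return calls


def call_sample(
    alignments: Iterable[Alignment],
    ref: ReferenceBundle,
    cfg: CallerConfig | None = None,
    hp_track: RegionTrack | None = None,
    include_filtered: bool = False,
    iteration: int = 1,
) -> list[VariantCall]:
    """Pileup the whole genome and call variants at every position.

    INDEL representations are left-aligned before aggregation so reads
    anchoring the same event differently merge into one record.  When an
    ``hp_track`` is provided, indels within 150 bp of a homopolymer region
    are tagged ``HP_ADJACENT`` (they remain in the output; summary counts
    downstream exclude them from headline SNV statistics).
    """
    cfg = cfg or CallerConfig()
    alignments = list(alignments)
    pile = build_pileup(alignments, ref, min_baseq=cfg.min_baseq)
    if not alignments:
        import warnings

        warnings.warn("no alignments provided; returning empty call list")
        return []

    depth = pile.passing_depth
    counts = pile.base_counts
    L = ref.L
    ref_codes = _BYTE_TO_CODE[np.frombuffer(ref.seq.encode(), np.uint8)]

    calls: list[VariantCall] = []
    totals = counts.sum(axis=2)  # (L+2, 4)
    with np.errstate(divide="ignore", invalid="ignore"):
        vafs = np.where(depth[:, None] > 0, totals / depth[:, None], 0.0)
    cand_pos, cand_code = np.nonzero(vafs[1 : L + 1] >= cfg.vaf_min)
    for p0, code in zip(cand_pos, cand_code):
        pos = int(p0) + 1
        if code == ref_codes[pos - 1]:
            continue
        fwd, rev = int(counts[pos, code, 0]), int(counts[pos, code, 1])
        d = int(depth[pos])
        vaf = (fwd + rev) / d
        filters: set[str] = set()
        if fwd < cfg.min_reads_per_strand or rev < cfg.min_reads_per_strand:
            filters.add("STRAND_BIAS")
        if d < cfg.min_depth:
            filters.add("NO_CALL")
        refb = ref.seq[pos - 1]
        calls.append(
            VariantCall(
                position=pos,
                ref=refb,
                alt=_BASES[code],
                vaf=vaf,
                depth=d,
                strand_counts=(fwd, rev),
                type="SNV",
                klass=_classify(vaf, cfg),
                filters=filters,
                iteration=iteration,
            )
        )

    # indel/MNV alleles are already canonical keys in the pileup
    for (pos, refa, alta), (fwd, rev) in pile.indels.items():
        d = int(depth[pos])
        if d <= 0:
            continue
        vaf = (fwd + rev) / d
        if vaf < cfg.vaf_min:
            continue
        filters = set()
        if fwd < cfg.min_reads_per_strand or rev < cfg.min_reads_per_strand:
            filters.add("STRAND_BIAS")
        if d < cfg.min_depth:
            filters.add("NO_CALL")
        call = VariantCall(
            position=pos,
            ref=refa,
            alt=alta,
            vaf=vaf,
            depth=d,
            strand_counts=(fwd, rev),
            type=variant_type(refa, alta),
            klass=_classify(vaf, cfg),
            filters=filters,
            iteration=iteration,
        )
        if hp_track is not None and hp_track.intervals:
            dist = hp_track.nearest_distance(pos)
            if dist is not None and dist <= HP_ADJACENT_WINDOW:
                call.annotations["HP_ADJACENT"] = True
        calls.append(call)

    calls.sort(key=lambda c: c.key())
    if not include_filtered:
        calls = [c for c in calls if c.passing]
    return calls
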