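"""Per-sample consensus genome, coordinate liftover, and second-iteration calls.

Homoplasmy is inter-individual variation; heteroplasmy is intra-individual.
The first iteration of calling (against the standard reference) therefore
mixes the two.  Building a per-sample consensus — the reference edited with
every homoplasmy and every major (>50%) allele — and re-calling against it
leaves only genuine intra-individual variation, at the cost of a coordinate
liftover back to standard numbering and some allele bookkeeping: where a
consensus edit made the standard-reference base the *minor* allele, the
lifted record is re-expressed against the standard alleles and tagged
``ALLELE_SWITCH``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import align as _align
from .alleles import variant_type
from .caller import CallerConfig, VariantCall, call_sample
from .reference import (
    Interval,
    ReferenceBundle,
    RegionTrack,
    find_homopolymer_regions,
)
from .simulate import ReadPair


@dataclass(frozen=True)
class ConsensusEdit:
    ref_pos: int
    ref_allele: str
    alt_allele: str
    source_vaf: float


class ConsensusMap:
    """A consensus sequence plus an invertible coordinate map to the reference.

    ``to_reference`` maps a 1-based consensus position to its reference
    image; positions inside inserted blocks return their insertion anchor
    with ``in_insertion=True``.  ``to_consensus`` maps reference positions;
    deleted reference positions return their anchor on the consensus.
    """

    def __init__(self, ref: ReferenceBundle, edits: list[ConsensusEdit]):
        self.ref = ref
        self.edits = sorted(edits, key=lambda e: e.ref_pos)
        self._check_overlaps()
        cons_parts: list[str] = []
        L = ref.L
        # cons2ref[i] = reference image of consensus position i (0 = inserted)
        cons2ref: list[int] = [0]
        ref2cons = np.zeros(L + 1, dtype=np.int64)
        self._edited_ref_pos: dict[int, ConsensusEdit] = {}
        cursor = 1
        cpos = 1
        for e in self.edits:
            for rp in range(cursor, e.ref_pos):
                cons_parts.append(ref.seq[rp - 1])
                cons2ref.append(rp)
                ref2cons[rp] = cpos
                cpos += 1
            cons_parts.append(e.alt_allele)
            nref, nalt = len(e.ref_allele), len(e.alt_allele)
            for i in range(nalt):
                rp = e.ref_pos + i if i < nref else 0
                cons2ref.append(rp)
                if rp:
                    ref2cons[rp] = cpos + i
            for i in range(nalt, nref):  # reference bases deleted by the edit
                ref2cons[e.ref_pos + i] = -(cpos + nalt - 1)  # anchor, negated
            for i in range(min(nref, nalt)):
                self._edited_ref_pos[e.ref_pos + i] = e
            cpos += nalt
            cursor = e.ref_pos + nref
        for rp in range(cursor, L + 1):
            cons_parts.append(ref.seq[rp - 1])
            cons2ref.append(rp)
            ref2cons[rp] = cpos
            cpos += 1
        self.consensus_seq = "".join(cons_parts)
        self._cons2ref = np.array(cons2ref, dtype=np.int64)
        self._ref2cons = ref2cons
        assert len(self.consensus_seq) == ref.L + sum(
            len(e.alt_allele) - len(e.ref_allele) for e in self.edits
        )

    def _check_overlaps(self) -> None:
        prev_end = 0
        bad = []
        for e in self.edits:
            if e.ref_pos <= prev_end:
                bad.append(e.ref_pos)
            prev_end = max(prev_end, e.ref_pos + len(e.ref_allele) - 1)
        if bad:
            raise ValueError(f"overlapping consensus edits at positions {bad}")

    def __len__(self) -> int:
        return len(self.consensus_seq)

    def to_reference(self, cons_pos: int) -> tuple[int, bool]:
        """(reference position, in_insertion) for a consensus position."""
        if not 1 <= cons_pos < len(self._cons2ref):
            raise ValueError(f"consensus position {cons_pos} out of bounds")
        rp = int(self._cons2ref[cons_pos])
        if rp > 0:
            return rp, False
        # inside an inserted block: anchor is the nearest mapped position left
        probe = cons_pos
        while probe >= 1 and int(self._cons2ref[probe]) <= 0:
            probe -= 1
        return (int(self._cons2ref[probe]) if probe >= 1 else 1), True

    def to_consensus(self, ref_pos: int) -> int:
        """Consensus image of a reference position (anchor if deleted)."""
        if not 1 <= ref_pos <= self.ref.L:
            raise ValueError(f"reference position {ref_pos} out of bounds")
        cp = int(self._ref2cons[ref_pos])
        return abs(cp)

    def edit_at(self, ref_pos: int) -> ConsensusEdit | None:
        return self._edited_ref_pos.get(ref_pos)

    def bundle(self, name: str = "chrM_consensus", ext_len: int | None = None) -> ReferenceBundle:
        if ext_len is None:
            ext_len = self.ref.ext_len
        return ReferenceBundle(name, self.consensus_seq, ext_len=ext_len)


def build_consensus(ref: ReferenceBundle, calls: list[VariantCall]) -> ConsensusMap:
    """Edit every homoplasmy and every major (>0.5 VAF) allele into the reference.

    At multiallelic sites the highest-VAF qualifying allele wins; a tie at
    exactly 0.5 keeps the reference allele.  Overlapping INDEL edits raise.
    """
    best: dict[int, VariantCall] = {}
    for c in calls:
        if not c.passing:
            continue
        if c.vaf > 0.5:
            cur = best.get(c.position)
            if cur is None or c.vaf > cur.vaf:
                best[c.position] = c
    edits = [
        ConsensusEdit(c.position, c.ref, c.alt, c.vaf)
        for c in sorted(best.values(), key=lambda c: c.position)
    ]
    return ConsensusMap(ref, edits)


def lift_to_reference(call: VariantCall, cmap: ConsensusMap) -> VariantCall:
    """Re-express a consensus-frame call in reference coordinates and alleles.

    Unedited positions lift by offset only.  At an edited position the
    reference allele of the output is the standard-reference allele; when
    the call's alternate IS the standard base the roles invert: the output
    records the consensus allele as ALT with VAF ``1 - vaf`` and the
    ``ALLELE_SWITCH`` tag, keeping first- and second-iteration VCFs directly
    comparable.  Calls inside consensus insertions anchor to the insertion
    point and carry ``IN_CONSENSUS_INS``.
    """
    rp, in_ins = cmap.to_reference(call.position)
    ref_seq = cmap.ref.seq
    ann = dict(call.annotations)
    filters = set(call.filters)
    if in_ins:
        ann["IN_CONSENSUS_INS"] = True
        out_ref = ref_seq[rp - 1]
        return VariantCall(
            position=rp,
            ref=out_ref,
            alt=call.alt,
            vaf=call.vaf,
            depth=call.depth,
            strand_counts=call.strand_counts,
            type=call.type,
            klass=call.klass,
            filters=filters,
            annotations=ann,
            iteration=2,
        )

    edit = cmap.edit_at(rp)
    new_ref = ref_seq[rp - 1 : rp - 1 + len(call.ref)]
    new_alt = call.alt
    vaf = call.vaf
    klass = call.klass
    if edit is not None and call.type == "SNV" and new_ref != call.ref:
        if call.alt == new_ref:
            # second iteration saw the standard base as the minor allele
            new_alt = call.ref  # the consensus (major) allele
            ann["ALLELE_SWITCH"] = True
            ann["MINOR_VAF"] = round(call.vaf, 6)
            vaf = 1.0 - call.vaf
            cfg = CallerConfig()
            klass = "HOMOPLASMY" if vaf >= cfg.homoplasmy_vaf else "HETEROPLASMY"
        # else: third allele at an edited site; REF re-expressed, VAF kept
    return VariantCall(
        position=rp,
        ref=new_ref,
        alt=new_alt,
        vaf=vaf,
        depth=call.depth,
        strand_counts=call.strand_counts,
        type=variant_type(new_ref, new_alt),
        klass=klass,
        filters=filters,
        annotations=ann,
        iteration=2,
    )


def validate_consensus(
    cmap: ConsensusMap | ReferenceBundle,
    alignments: list[_align.Alignment],
    min_merge_overlap: int = 5,
) -> tuple[bool, list[Interval]]:
    """Check the consensus circle is tiled by exact full-length alignments.

    Only perfect placements (edit distance 0, no clipping) count.  Their
    intervals are merged when they overlap by at least ``min_merge_overlap``
    bases; the return value reports whether the merged cover spans the whole
    circle and lists any uncovered intervals.
    """
    Lc = len(cmap.consensus_seq) if isinstance(cmap, ConsensusMap) else cmap.L
    ivs = []
    for a in alignments:
        if a.score == 0 and len(a.cigar) == 1 and a.cigar[0][0] == "M":
            ivs.append((a.start, a.end))
    if not ivs:
        return False, [Interval(1, Lc, "uncovered")]
    ivs.sort()
    merged = [list(ivs[0])]
    for s, e in ivs[1:]:
        overlap = merged[-1][1] - s + 1
        if overlap >= min_merge_overlap:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    uncovered: list[Interval] = []
    cursor = 1
    for s, e in merged:
        if s > cursor:
            uncovered.append(Interval(cursor, s - 1, "uncovered"))
        cursor = max(cursor, e + 1)
    if cursor <= Lc:
        uncovered.append(Interval(cursor, Lc, "uncovered"))
    return not uncovered, uncovered


def second_iteration(
    sample_reads: list[ReadPair],
    first_calls: list[VariantCall],
    ref: ReferenceBundle,
    cfg: CallerConfig | None = None,
    target_cov: float = 2000.0,
    seed: int = 0,
    k: int = 21,
) -> tuple[list[VariantCall], ConsensusMap]:
    """Re-call a sample against its own consensus genome.

    Builds the consensus from first-iteration calls, circularizes it with
    the same extension length as the input reference, re-maps all reads,
    down-samples, calls, and lifts everything back to reference coordinates
    (``iteration=2``).
    """
    cfg = cfg or CallerConfig()
    cmap = build_consensus(ref, first_calls)
    cons = cmap.bundle()
    index = _align.build_index(cons, k=k)
    alns = _align.map_reads(sample_reads, index, cons)
    alns = [a for a in alns if not a.is_duplicate]
    alns = _align.downsample(alns, target_cov=target_cov, L=cons.L, seed=seed)
    hp = RegionTrack("HP", intervals=find_homopolymer_regions(cons.seq))
    cons_calls = call_sample(alns, cons, cfg, hp_track=hp, iteration=2)
    lifted = [lift_to_reference(c, cmap) for c in cons_calls]
    lifted.sort(key=lambda c: c.key())
    return lifted, cmap
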