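"""Allele representation helpers shared by the simulator, caller and scorer.

Variants are VCF-style: 1-based position, REF/ALT allele strings, indels
anchored on the base preceding the event.  Comparing call sets only makes
sense after both sides are reduced to the same canonical form, so everything
funnels through :func:`normalize_variant` (trim shared suffix/prefix, then
left-align against the reference).
"""

from __future__ import annotations


def trim_alleles(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Strip shared trailing then leading bases, keeping a non-empty anchor."""
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def normalize_variant(pos: int, ref: str, alt: str, seq: str) -> tuple[int, str, str]:
    """Canonicalize a variant against reference sequence ``seq`` (1-based pos).

    Trims redundant shared bases and left-aligns indels: while the last bases
    of REF and ALT agree and the event can be shifted left, move the anchor
    one base toward the 5' end.  SNVs pass through unchanged.
    """
    pos, ref, alt = trim_alleles(pos, ref, alt)
    if len(ref) == len(alt):
        return pos, ref, alt
    # pure indel after trimming: one allele is a prefix of the other
    while pos > 1 and ref[-1] == alt[-1]:
        prev = seq[pos - 2]
        ref = prev + ref[:-1]
        alt = prev + alt[:-1]
        pos -= 1
    return trim_alleles(pos, ref, alt)


def variant_type(ref: str, alt: str) -> str:
    if len(ref) == len(alt):
        return "SNV" if len(ref) == 1 else "MNV"
    return "INS" if len(alt) > len(ref) else "DEL"


def apply_edits(seq: str, edits: list[tuple[int, str, str]]) -> str:
    """Apply non-overlapping VCF-style edits (1-based) to a sequence.

    Edits must be sorted by position and each REF must match ``seq`` at its
    position; raises ``ValueError`` otherwise.
    """
    out = []
    cursor = 0  # 0-based index into seq
    last_end = 0
    for pos, ref, alt in edits:
        start = pos - 1
        if start < last_end:
            raise ValueError(f"overlapping edits at position {pos}")
        if seq[start : start + len(ref)] != ref:
            raise ValueError(
                f"reference mismatch at position {pos}: expected {ref!r}, "
                f"sequence has {seq[start:start + len(ref)]!r}"
            )
        out.append(seq[cursor:start])
        out.append(alt)
        cursor = start + len(ref)
        last_end = cursor
    out.append(seq[cursor:])
    return "".join(out)
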