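"""Plain-text VCF 4.2 reading/writing for mitochondrial call sets.

Only the subset needed here: single contig, site records with INFO key=value
pairs, no genotype columns.  Readers report the offending line number on
malformed input so track files can be fixed by hand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

VCF_VERSION = "4.2"


@dataclass
class VcfRecord:
    pos: int
    ref: str
    alt: str
    qual: str = "."
    filter: str = "PASS"
    info: dict[str, object] = field(default_factory=dict)
    id: str = "."


def _format_info(info: dict[str, object]) -> str:
    if not info:
        return "."
    parts = []
    for key, val in info.items():
        if val is True:
            parts.append(key)
        elif val is False or val is None:
            continue
        elif isinstance(val, float):
            parts.append(f"{key}={val:.6g}")
        else:
            parts.append(f"{key}={val}")
    return ";".join(parts) if parts else "."


def write_records(
    records: Iterable[VcfRecord],
    path: str | Path,
    contig: str = "chrM",
    contig_length: int = 16569,
    info_headers: Iterable[str] = (),
    source: str = "mitocall",
) -> None:
    """Write records (sorted by position, then alleles) as uncompressed VCF."""
    recs = sorted(records, key=lambda r: (r.pos, r.ref, r.alt))
    with open(path, "w") as fh:
        fh.write(f"##fileformat=VCFv{VCF_VERSION}\n")
        fh.write(f"##source={source}\n")
        fh.write(f"##contig=<ID={contig},length={contig_length}>\n")
        for line in info_headers:
            fh.write(line.rstrip("\n") + "\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for r in recs:
            fh.write(
                f"{contig}\t{r.pos}\t{r.id}\t{r.ref}\t{r.alt}\t{r.qual}"
                f"\t{r.filter}\t{_format_info(r.info)}\n"
            )


def _parse_info(text: str) -> dict[str, object]:
    info: dict[str, object] = {}
    if text in (".", ""):
        return info
    for item in text.split(";"):
        if "=" in item:
            key, val = item.split("=", 1)
            info[key] = val
        else:
            info[item] = True
    return info


def read_records(path: str | Path) -> Iterator[VcfRecord]:
    """Iterate data lines of an uncompressed VCF; multi-ALT lines are split."""
    with open(path) as fh:
        saw_header = False
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                saw_header = True
                continue
            if line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 8:
                raise ValueError(f"{path}:{lineno}: expected >=8 VCF columns")
            try:
                pos = int(fields[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer POS") from exc
            ref = fields[3].upper()
            if not ref or not all(c in "ACGTN" for c in ref):
                raise ValueError(f"{path}:{lineno}: bad REF allele {fields[3]!r}")
            info = _parse_info(fields[7])
            for alt in fields[4].split(","):
                alt = alt.upper()
                if not alt or not all(c in "ACGTN" for c in alt):
                    raise ValueError(f"{path}:{lineno}: bad ALT allele {alt!r}")
                yield VcfRecord(
                    pos=pos,
                    ref=ref,
                    alt=alt,
                    qual=fields[5],
                    filter=fields[6],
                    info=dict(info),
                    id=fields[2],
                )
        if not saw_header:
            raise ValueError(f"{path}: missing #CHROM header line")
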