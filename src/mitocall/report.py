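"""Truth scoring and the pipeline's three output surfaces.

Outputs mirror what a cohort analyst needs: a per-sample copy-number summary
table, a per-sample variant summary table (haplogroup, homoplasmy and
heteroplasmy counts, SNV/INDEL counts split by homopolymer context), and
per-sample annotated VCFs for both calling iterations.  For simulated data
the scorer matches calls to the injected truth by exact normalized
(position, ref, alt) identity and reports false negatives and positives,
optionally with a +/- window for INDEL positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .annotate import MixtureReport
from .caller import VariantCall
from .copynumber import CNMetrics
from .reference import RegionTrack
from .simulate import TruthVariant
from .vcfio import VcfRecord, write_records

HIGH_HET_COUNT = 5


@dataclass
class TruthComparison:
    true_positives: int
    false_negatives: int
    false_positives: int
    by_type: dict[str, tuple[int, int, int]]
    matched_vafs: list[tuple[float, float]] = field(default_factory=list)


def compare_to_truth(
    calls: list[VariantCall],
    truth: list[TruthVariant],
    match_window: int = 0,
) -> TruthComparison:
    """Score calls against a truth set by allele identity.

    A call matches a truth record when positions and both alleles agree
    (INDEL positions may differ by up to ``match_window`` after
    left-alignment).  Unmatched truth records are false negatives; unmatched
    calls are false positives.
    """
    call_list = sorted(calls, key=lambda c: c.key())
    used = [False] * len(call_list)
    tp = 0
    matched_vafs = []
    per_type = {"SNV": [0, 0, 0], "INDEL": [0, 0, 0]}

    def bucket(t: str) -> str:
        return "SNV" if t == "SNV" else "INDEL"

    for tv in truth:
        hit = None
        for i, c in enumerate(call_list):
            if used[i]:
                continue
            if c.ref == tv.ref and c.alt == tv.alt:
                window = match_window if tv.type != "SNV" else 0
                if abs(c.position - tv.position) <= window:
                    hit = i
                    break
        if hit is not None:
            used[hit] = True
            tp += 1
            per_type[bucket(tv.type)][0] += 1
            matched_vafs.append((tv.vaf, call_list[hit].vaf))
        else:
            per_type[bucket(tv.type)][1] += 1
    for i, c in enumerate(call_list):
        if not used[i]:
            per_type[bucket(c.type)][2] += 1
    fn = sum(v[1] for v in per_type.values())
    fp = sum(v[2] for v in per_type.values())
    return TruthComparison(
        true_positives=tp,
        false_negatives=fn,
        false_positives=fp,
        by_type={k: tuple(v) for k, v in per_type.items()},
        matched_vafs=matched_vafs,
    )


@dataclass
class SampleSummary:
    sample_id: str
    haplogroup: str
    iteration: int
    n_homoplasmic: int
    n_heteroplasmic: int
    n_snv: int
    n_indel: int
    n_heteroplasmic_nonhp: int
    n_heteroplasmic_hp: int
    contamination_flag: bool
    high_het_flag: bool
    outlier_flag: bool = False


def summarize_sample(
    calls: list[VariantCall],
    tracks: dict[str, RegionTrack],
    sample_id: str = "sample",
    haplogroup: str = "",
    contamination: MixtureReport | None = None,
    iteration: int = 1,
    cohort_mean: float | None = None,
    cohort_sd: float | None = None,
) -> SampleSummary:
    """Partition passing calls by class, type and homopolymer context."""
    passing = [c for c in calls if c.passing]
    hp = tracks.get("HP")
    hets = [c for c in passing if c.klass == "HETEROPLASMY"]
    n_het_hp = sum(1 for c in hets if hp is not None and c.position in hp)
    n_het = len(hets)
    summary = SampleSummary(
        sample_id=sample_id,
        haplogroup=haplogroup,
        iteration=iteration,
        n_homoplasmic=sum(1 for c in passing if c.klass == "HOMOPLASMY"),
        n_heteroplasmic=n_het,
        n_snv=sum(1 for c in passing if c.type == "SNV"),
        n_indel=sum(1 for c in passing if c.type != "SNV"),
        n_heteroplasmic_nonhp=n_het - n_het_hp,
        n_heteroplasmic_hp=n_het_hp,
        contamination_flag=bool(contamination and contamination.flagged),
        high_het_flag=n_het > HIGH_HET_COUNT,
    )
    if cohort_mean is not None and cohort_sd is not None:
        summary.outlier_flag = n_het > cohort_mean + 3 * cohort_sd
    return summary


_VCF_INFO_HEADERS = [
    '##INFO=<ID=AF,Number=1,Type=Float,Description="Allele fraction">',
    '##INFO=<ID=DP,Number=1,Type=Integer,Description="Passing depth">',
    '##INFO=<ID=SBF,Number=1,Type=Integer,Description="Forward-strand alt reads">',
    '##INFO=<ID=SBR,Number=1,Type=Integer,Description="Reverse-strand alt reads">',
    '##INFO=<ID=TYPE,Number=1,Type=String,Description="SNV, INS or DEL">',
    '##INFO=<ID=CLASS,Number=1,Type=String,Description="HETEROPLASMY or HOMOPLASMY">',
    '##INFO=<ID=ITER,Number=1,Type=Integer,Description="Calling iteration">',
    '##INFO=<ID=APOGEE,Number=1,Type=String,Description="Reserved for user-supplied pathogenicity scores">',
]


def calls_to_vcf(
    calls: list[VariantCall], path: str | Path, contig: str = "chrM",
    contig_length: int = 16569,
) -> None:
    records = []
    for c in calls:
        info: dict[str, object] = {
            "AF": round(c.vaf, 6),
            "DP": c.depth,
            "SBF": c.strand_counts[0],
            "SBR": c.strand_counts[1],
            "TYPE": c.type,
            "CLASS": c.klass,
            "ITER": c.iteration,
        }
        for key, val in sorted(c.annotations.items()):
            info[key] = val
        records.append(
            VcfRecord(
                pos=c.position,
                ref=c.ref,
                alt=c.alt,
                filter=";".join(sorted(c.filters)) if c.filters else "PASS",
                info=info,
            )
        )
    write_records(
        records, path, contig=contig, contig_length=contig_length,
        info_headers=_VCF_INFO_HEADERS,
    )


def write_outputs(
    summaries: list[SampleSummary],
    cn_metrics: dict[str, CNMetrics],
    vcfs: dict[str, dict[int, list[VariantCall]]],
    outdir: str | Path,
) -> dict[str, Path]:
    """Write the CN summary, variant summary, and per-sample VCFs.

    ``vcfs`` maps sample id -> iteration -> calls.  Sample ids must agree
    across all three inputs; ordering of every output is deterministic.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sum_ids = {s.sample_id for s in summaries}
    mismatched = sum_ids.symmetric_difference(cn_metrics) | sum_ids.symmetric_difference(vcfs)
    if mismatched:
        raise ValueError(f"sample ids disagree across inputs: {sorted(mismatched)}")

    cn_rows = []
    for sid in sorted(cn_metrics):
        m = cn_metrics[sid]
        cn_rows.append(
            {
                "sample": sid,
                "chrm_cov": m.chrm_cov,
                "genome_cov_metadata": m.genome_cov_metadata,
                "genome_cov_recomputed": m.genome_cov_recomputed,
                "genome_cov_sex": m.genome_cov_sex,
                "cn_metadata": m.cn_metadata,
                "cn_recomputed": m.cn_recomputed,
                "cn_sex": m.cn_sex,
                "low_cn_flag": m.low_cn_flag,
            }
        )
    cn_path = outdir / "cn_summary.tsv"
    pd.DataFrame(cn_rows).to_csv(cn_path, sep="\t", index=False)

    var_path = outdir / "variant_summary.tsv"
    rows = [vars(s).copy() for s in sorted(summaries, key=lambda s: (s.sample_id, s.iteration))]
    pd.DataFrame(rows).to_csv(var_path, sep="\t", index=False)

    written = {"cn_summary": cn_path, "variant_summary": var_path}
    for sid in sorted(vcfs):
        for iteration in sorted(vcfs[sid]):
            path = outdir / f"{sid}.iter{iteration}.vcf"
            calls_to_vcf(vcfs[sid][iteration], path)
            written[f"{sid}.iter{iteration}"] = path
    return written
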