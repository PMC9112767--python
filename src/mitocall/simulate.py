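"""Validation simulator: haplogroup genomes, injected heteroplasmies, reads.

The simulator reproduces the study design used to benchmark mitochondrial
heteroplasmy callers: per-sample genomes derived from a haplogroup backbone
(homoplasmic SNVs on the reference), a fixed number of injected heteroplasmic
SNVs and INDELs at 15-20% allele fraction (mean 18%), and 150-bp paired-end
reads drawn uniformly from the *circular* genome with independent per-base
substitution errors (default 1%).  Every sample comes with a machine-readable
truth set so false negatives/positives can be scored exactly.

Haplotype mixing is per-variant: each sequenced fragment carries each
overlapping truth variant independently with probability equal to that
variant's VAF.  This makes the number of alt-supporting reads at a site an
exact binomial draw, which the test suite uses as its oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .alleles import apply_edits, normalize_variant, variant_type
from .reference import ReferenceBundle, RegionTrack, revcomp
from .vcfio import VcfRecord, write_records

#: macro-haplogroup style labels for the default 30-genome panel
PANEL_LABELS = (
    "A B C D E F G H HV I J K L0 L1 L2 L3 L4 L5 L6 M N P Q R T U V W X Y".split()
)

_PANEL_SEED = 1731  # fixture identity of the default panel; never varied
_MIN_VARIANT_SPACING = 10  # bp between injected events, keeps truth unambiguous


@dataclass(frozen=True)
class HaplogroupProfile:
    """A haplogroup backbone: homoplasmic SNV edits relative to the reference."""

    name: str
    snvs: tuple[tuple[int, str, str], ...]

    def __post_init__(self) -> None:
        positions = [p for p, _, _ in self.snvs]
        if len(positions) != len(set(positions)):
            raise ValueError(f"profile {self.name}: duplicate positions")


@dataclass(frozen=True)
class TruthVariant:
    position: int
    ref: str
    alt: str
    vaf: float
    type: str

    def key(self) -> tuple[int, str, str]:
        return (self.position, self.ref, self.alt)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated sample.

    Defaults are the benchmark conditions: 150-bp paired ends, 1% base error,
    35 SNVs + 8 INDELs at VAF 15-20% averaging 18%.
    """

    coverage: float = 2000.0
    read_len: int = 150
    error_rate: float = 0.01
    vaf_low: float = 0.15
    vaf_high: float = 0.20
    vaf_mean: float = 0.18
    n_snv: int = 35
    n_indel: int = 8
    frag_mean: float = 350.0
    frag_sd: float = 50.0
    frag_max: int = 1000
    seed: int = 0
    exclude_hp: bool = True
    duplicate_rate: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must be in [0, 0.5)")
        if not self.vaf_low <= self.vaf_mean <= self.vaf_high:
            raise ValueError("need vaf_low <= vaf_mean <= vaf_high")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if self.read_len * 2 > self.frag_max:
            raise ValueError("frag_max must fit two reads")


@dataclass
class ReadPair:
    """One simulated fragment: two reads plus its ground truth placement."""

    read_id: str
    seq1: str
    qual1: str
    seq2: str
    qual2: str
    pos1: int  # 1-based canonical start of the forward read
    strand1: str
    pos2: int
    strand2: str
    carried: tuple[int, ...] = ()  # indices into the truth list


def default_haplogroup_panel(
    ref: ReferenceBundle, n: int = 30, hp_track: RegionTrack | None = None
) -> list[HaplogroupProfile]:
    """Deterministic synthetic panel of ``n`` haplogroup backbones.

    Profiles carry 5-40 homoplasmic SNVs each at positions disjoint across
    the panel and outside homopolymer regions (where consensus building and
    calling are exercised separately).  A synthetic stand-in for a phylotree
    panel: star-shaped rather than nested, which is all the simplified
    haplogroup matcher requires.
    """
    if n < 1 or n > len(PANEL_LABELS):
        raise ValueError(f"panel size must be 1..{len(PANEL_LABELS)}")
    rng = np.random.default_rng(_PANEL_SEED)
    allowed = np.ones(ref.L + 1, dtype=bool)
    allowed[0] = False
    if hp_track is None:
        from .reference import find_homopolymer_regions

        hp_track = RegionTrack("HP", intervals=find_homopolymer_regions(ref.seq))
    for iv in hp_track.intervals:
        allowed[max(1, iv.start - 2) : min(ref.L, iv.end + 2) + 1] = False
    for pos in range(1, ref.L + 1):
        if ref.seq[pos - 1] == "N":
            allowed[pos] = False

    sizes = [5 + round(35 * i / (len(PANEL_LABELS) - 1)) for i in range(n)]
    pool = np.flatnonzero(allowed)
    chosen = rng.choice(pool, size=sum(sizes), replace=False)
    profiles = []
    offset = 0
    others = "ACGT"
    for label, size in zip(PANEL_LABELS[:n], sizes):
        snvs = []
        for pos in sorted(int(p) for p in chosen[offset : offset + size]):
            refb = ref.seq[pos - 1]
            alt = others[(others.index(refb) + int(rng.integers(1, 4))) % 4]
            snvs.append((pos, refb, alt))
        profiles.append(HaplogroupProfile(label, tuple(snvs)))
        offset += size
    return profiles


def build_sample_genome(ref: ReferenceBundle, profile: HaplogroupProfile) -> str:
    """Apply a profile's homoplasmic SNVs to the reference backbone."""
    edits = sorted(profile.snvs)
    for pos, refb, _ in edits:
        if not 1 <= pos <= ref.L:
            raise ValueError(f"profile {profile.name}: position {pos} out of range")
        if ref.seq[pos - 1] != refb:
            raise ValueError(
                f"profile {profile.name}: ref mismatch at {pos} "
                f"(profile {refb}, reference {ref.seq[pos - 1]})"
            )
    return apply_edits(ref.seq, edits)


def _draw_vafs(rng: np.random.Generator, n: int, cfg: SimConfig) -> np.ndarray:
    """VAFs in [vaf_low, vaf_high] whose sample mean is exactly vaf_mean.

    Draws from a Beta rescaled to the interval with the target mean, then
    nudges sites (one at a time, respecting the bounds) until the mean is
    exact.  A uniform draw cannot average 0.18 on [0.15, 0.20] without this.
    """
    lo, hi = cfg.vaf_low, cfg.vaf_high
    if n == 0:
        return np.empty(0)
    if hi == lo:
        return np.full(n, lo)
    m = (cfg.vaf_mean - lo) / (hi - lo)
    conc = 5.0
    vafs = lo + (hi - lo) * rng.beta(m * conc, (1 - m) * conc, size=n)
    deficit = n * cfg.vaf_mean - vafs.sum()
    order = rng.permutation(n)
    for idx in order:
        if abs(deficit) < 1e-12:
            break
        new = np.clip(vafs[idx] + deficit, lo, hi)
        deficit -= new - vafs[idx]
        vafs[idx] = new
    return vafs


def inject_heteroplasmies(
    genome: str,
    cfg: SimConfig,
    hp_track: RegionTrack | None = None,
    forbidden_positions: set[int] | None = None,
) -> tuple[str, list[TruthVariant]]:
    """Choose heteroplasmic sites and VAFs; return alt haplotype and truth.

    Sites are uniform over the genome, excluding homopolymer regions when
    ``cfg.exclude_hp`` (the default), any ``forbidden_positions`` (e.g. the
    backbone's own edits), and a +/-10 bp exclusion zone around already
    chosen sites so truth records stay independent events.  INDELs are 1-4 bp
    and are redrawn until their VCF representation is already left-aligned,
    so truth and calls compare exactly.
    """
    rng = np.random.default_rng(cfg.seed)
    L = len(genome)
    allowed = np.ones(L + 1, dtype=bool)
    allowed[0] = False
    allowed[: _MIN_VARIANT_SPACING + 1] = False  # keep DEL anchors clear of pos 1
    allowed[L - _MIN_VARIANT_SPACING :] = False
    if cfg.exclude_hp and hp_track is not None:
        for iv in hp_track.intervals:
            lo = max(1, iv.start - _MIN_VARIANT_SPACING)
            hi = min(L, iv.end + _MIN_VARIANT_SPACING)
            allowed[lo : hi + 1] = False
    for pos in forbidden_positions or ():
        lo = max(1, pos - _MIN_VARIANT_SPACING)
        hi = min(L, pos + _MIN_VARIANT_SPACING)
        allowed[lo : hi + 1] = False

    n_total = cfg.n_snv + cfg.n_indel
    if n_total == 0:
        return genome, []
    types = ["SNV"] * cfg.n_snv + ["INDEL"] * cfg.n_indel
    vafs = _draw_vafs(rng, n_total, cfg)
    others = "ACGT"
    truth: list[TruthVariant] = []
    for i, vtype in enumerate(types):
        placed = False
        for _ in range(1000):
            pool = np.flatnonzero(allowed)
            if pool.size == 0:
                raise ValueError("no placeable positions left for injected variants")
            pos = int(rng.choice(pool))
            refb = genome[pos - 1]
            if refb == "N":
                allowed[pos] = False
                continue
            if vtype == "SNV":
                alt = others[(others.index(refb) + int(rng.integers(1, 4))) % 4]
                rec = (pos, refb, alt)
            elif rng.random() < 0.5:  # insertion
                ins = "".join(
                    others[int(b)] for b in rng.integers(0, 4, int(rng.integers(1, 5)))
                )
                rec = (pos, refb, refb + ins)
            else:  # deletion
                dlen = int(rng.integers(1, 5))
                if pos + dlen > L:
                    continue
                rec = (pos, genome[pos - 1 : pos + dlen], refb)
            norm = normalize_variant(rec[0], rec[1], rec[2], genome)
            if norm != rec:
                continue  # not canonical here (e.g. shiftable in repeat context)
            lo = max(1, pos - _MIN_VARIANT_SPACING)
            hi = min(L, pos + len(rec[1]) - 1 + _MIN_VARIANT_SPACING)
            allowed[lo : hi + 1] = False
            truth.append(
                TruthVariant(rec[0], rec[1], rec[2], float(vafs[i]),
                             variant_type(rec[1], rec[2]))
            )
            placed = True
            break
        if not placed:
            raise ValueError("could not place injected variant after 1000 tries")

    truth.sort(key=lambda t: t.position)
    alt_genome = apply_edits(genome, [t.key() for t in truth])
    return alt_genome, truth


_BYTE_TO_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BYTE_TO_CODE[_b] = _i
_CODE_TO_BYTE = np.frombuffer(b"ACGT", dtype=np.uint8)


def _add_errors(reads: list[str], rng: np.random.Generator, rate: float) -> list[str]:
    """Apply i.i.d. substitution errors to equal-length reads, vectorized."""
    if rate == 0 or not reads:
        return reads
    rl = len(reads[0])
    arr = np.frombuffer("".join(reads).encode(), dtype=np.uint8).reshape(-1, rl).copy()
    mask = rng.random(arr.shape) < rate
    idx = np.nonzero(mask)
    codes = _BYTE_TO_CODE[arr[idx]]
    shift = rng.integers(1, 4, size=codes.size)
    arr[idx] = _CODE_TO_BYTE[(codes + shift) % 4]
    flat = arr.tobytes().decode()
    return [flat[i * rl : (i + 1) * rl] for i in range(len(reads))]


def simulate_reads(
    backbone: str,
    alt_genome: str,
    truth: list[TruthVariant],
    cfg: SimConfig,
) -> list[ReadPair]:
    """Draw paired-end fragments from the circular genome.

    Fragment starts are uniform over the circle; lengths are
    Normal(frag_mean, frag_sd) truncated to [2*read_len, frag_max].  Each
    fragment carries each overlapping truth variant independently with
    probability vaf.  The total emitted bases equal coverage x L up to the
    rounding of the fragment count.
    """
    if apply_edits(backbone, [t.key() for t in truth]) != alt_genome:
        raise ValueError("alt_genome is not backbone + truth variants")
    rng = np.random.default_rng(cfg.seed + 1)
    L = len(backbone)
    rl = cfg.read_len
    n_frags = int(round(cfg.coverage * L / (2 * rl)))
    doubled = backbone + backbone[: cfg.frag_max + rl]

    starts = rng.integers(0, L, size=n_frags)
    lens = np.clip(
        np.rint(rng.normal(cfg.frag_mean, cfg.frag_sd, size=n_frags)),
        2 * rl,
        cfg.frag_max,
    ).astype(np.int64)

    # truth positions in doubled coordinates for wrap-aware overlap lookup
    tpos = np.array([t.position for t in truth], dtype=np.int64)
    tidx = np.argsort(tpos)
    tpos_sorted = tpos[tidx]
    dpos = np.concatenate([tpos_sorted, tpos_sorted + L])
    didx = np.concatenate([tidx, tidx])

    lo = np.searchsorted(dpos, starts + 1)
    hi = np.searchsorted(dpos, starts + lens, side="right")

    pairs: list[ReadPair] = []
    r1_list: list[str] = []
    r2_list: list[str] = []
    qual = chr(33 + 30) * rl
    for i in range(n_frags):
        start = int(starts[i])
        flen = int(lens[i])
        carried: list[int] = []
        if hi[i] > lo[i]:
            frag_edits = []
            for j in range(int(lo[i]), int(hi[i])):
                v = truth[int(didx[j])]
                p = int(dpos[j])
                if p + len(v.ref) - 1 > start + flen:
                    continue  # event hangs off the fragment end
                if rng.random() < v.vaf:
                    frag_edits.append((p - start, v.ref, v.alt))
                    carried.append(int(didx[j]))
            if frag_edits:
                frag = apply_edits(doubled[start : start + flen], sorted(frag_edits))
            else:
                frag = doubled[start : start + flen]
        else:
            frag = doubled[start : start + flen]
        r1_list.append(frag[:rl])
        r2_list.append(revcomp(frag[-rl:]))
        pos1 = start % L + 1
        pos2 = (start + flen - rl) % L + 1
        pairs.append(
            ReadPair(
                read_id=f"sim{i}",
                seq1="",
                qual1=qual,
                seq2="",
                qual2=qual,
                pos1=pos1,
                strand1="+",
                pos2=pos2,
                strand2="-",
                carried=tuple(sorted(carried)),
            )
        )

    r1_list = _add_errors(r1_list, rng, cfg.error_rate)
    r2_list = _add_errors(r2_list, rng, cfg.error_rate)
    for pair, s1, s2 in zip(pairs, r1_list, r2_list):
        pair.seq1, pair.seq2 = s1, s2

    if cfg.duplicate_rate > 0:
        n_dup = int(round(cfg.duplicate_rate * n_frags))
        for k, i in enumerate(rng.integers(0, n_frags, size=n_dup)):
            src = pairs[int(i)]
            pairs.append(replace(src, read_id=f"dup{k}"))
    return pairs


def write_fastq(pairs: list[ReadPair], r1_path: str | Path, r2_path: str | Path) -> None:
    with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
        for p in pairs:
            f1.write(f"@{p.read_id}/1\n{p.seq1}\n+\n{p.qual1}\n")
            f2.write(f"@{p.read_id}/2\n{p.seq2}\n+\n{p.qual2}\n")


def write_truth(truth: list[TruthVariant], path: str | Path) -> None:
    """Write the truth set as VCF 4.2 with the intended VAF in INFO/AF."""
    write_records(
        [
            VcfRecord(
                pos=t.position,
                ref=t.ref,
                alt=t.alt,
                info={"AF": round(t.vaf, 6), "TYPE": t.type},
            )
            for t in truth
        ],
        path,
        info_headers=[
            '##INFO=<ID=AF,Number=1,Type=Float,Description="Intended allele fraction">',
            '##INFO=<ID=TYPE,Number=1,Type=String,Description="SNV, INS or DEL">',
        ],
        source="mitocall-simulate",
    )


def read_truth(path: str | Path) -> list[TruthVariant]:
    from .vcfio import read_records

    out = []
    for rec in read_records(path):
        out.append(
            TruthVariant(
                rec.pos,
                rec.ref,
                rec.alt,
                float(rec.info.get("AF", 0.0)),
                str(rec.info.get("TYPE", variant_type(rec.ref, rec.alt))),
            )
        )
    return out
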