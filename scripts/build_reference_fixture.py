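"""Regenerate the bundled synthetic chrM reference and annotation tracks.

The packaged reference (src/mitocall/data/chrM_synthetic.fa) is a SYNTHETIC
16,569-bp stand-in for the human mitochondrial genome, not the rCRS itself.
It is built deterministically so that it reproduces the documented structural
features the toolkit's logic depends on:

* length 16,569 with realistic base composition;
* the two published polycytosine tracts at chrM:300-320
  (AAACCCCCCCTCCCCCGCTTC) and chrM:450-470 (TATTTTCCCCTCCCACTCCCA),
  verbatim, so positions 302/310/460 behave as documented;
* exactly nine homopolymer regions under the definition "five or more Cs in
  a row, one interior mismatch, +/-1 bp on the ends" — the count reported
  for the real rCRS — with no accidental tracts elsewhere;
* fixed bases at positions named in the mitochondrial literature (73A,
  2706A, 3666G, 7028C, 8701A, 10398A, 11719G, 12612G, 12705C, 16092C,
  16093T) so the bundled NUMT/dbSNP site lists carry matching REF alleles.

Run from the repository root:  python scripts/build_reference_fixture.py
"""

from pathlib import Path

import numpy as np

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "src" / "mitocall" / "data"
TRACKS = DATA / "tracks_synthetic"

L = 16569
SEED = 16569  # fixture identity; never varied

# (1-based start, sequence); the first two are verbatim published tracts
TRACTS = [
    (300, "AAACCCCCCCTCCCCCGCTTC"),
    (450, "TATTTTCCCCTCCCACTCCCA"),
    (568, "CCCCCC"),
    (955, "CCCCCCC"),
    (3565, "CCCCC"),
    (5895, "CCCCCC"),
    (8270, "CCCCCCCC"),
    (12418, "CCCCC"),
    (16183, "CCCCCCTCCCCC"),
]

FIXED_BASES = {
    73: "A",
    2706: "A",
    3666: "G",
    7028: "C",
    8701: "A",
    10398: "A",
    11719: "G",
    12612: "G",
    12705: "C",
    16092: "C",
    16093: "T",
}

NUMT_SITES = [
    (2706, "A", "G"),
    (7028, "C", "T"),
    (8701, "A", "G"),
    (10398, "A", "G"),
    (11719, "G", "A"),
    (12612, "G", "A"),
    (12705, "C", "T"),
    (16093, "T", "C"),
]

DBSNP_EXTRA = [
    (73, "A", "G"),
    (302, "A", "AC"),
    (310, "T", "TC"),
    (3666, "G", "A"),
    (3666, "G", "C"),
    (16092, "C", "T"),
]

HV_REGIONS = [(16024, 16383, "HV1"), (57, 372, "HV2"), (438, 574, "HV3")]
HS_POSITIONS = [64, 152, 195, 514, 16093, 16189]
DLOOP = [(16024, 16569, "Dloop"), (1, 576, "Dloop")]
CDS = [
    (3307, 4262, "CDS:MT-ND1"),
    (4470, 5511, "CDS:MT-ND2"),
    (5904, 7445, "CDS:MT-CO1"),
    (7586, 8269, "CDS:MT-CO2"),
    (8366, 8572, "CDS:MT-ATP8"),
    (8527, 9207, "CDS:MT-ATP6"),
    (9208, 9990, "CDS:MT-CO3"),
    (10059, 10404, "CDS:MT-ND3"),
    (10470, 10766, "CDS:MT-ND4L"),
    (10767, 12137, "CDS:MT-ND4"),
    (12337, 14148, "CDS:MT-ND5"),
    (14149, 14673, "CDS:MT-ND6"),
    (14747, 15887, "CDS:MT-CYB"),
]


def build_sequence() -> str:
    rng = np.random.default_rng(SEED)
    alphabet = np.array(list("ACGT"))
    # approximate human mtDNA base composition
    seq = rng.choice(alphabet, size=L, p=[0.309, 0.313, 0.131, 0.247])

    # background must contain no C-run of length >= 3: runs of <=2 joined by a
    # single mismatch total <= 5 Cs only when 3+ are contiguous, so capping
    # pure runs at 2 guarantees no accidental homopolymer region
    for i in range(2, L):
        if seq[i] == "C" and seq[i - 1] == "C" and seq[i - 2] == "C":
            seq[i] = "T"

    for start, tract in TRACTS:
        s0 = start - 1
        seq[s0 : s0 + len(tract)] = list(tract)
        for flank in (s0 - 2, s0 - 1, s0 + len(tract), s0 + len(tract) + 1):
            if 0 <= flank < L and seq[flank] == "C":
                seq[flank] = "A"

    for pos, b in FIXED_BASES.items():
        seq[pos - 1] = b
        if b == "C":  # keep the fixed C isolated so it cannot seed a tract
            for flank in (pos - 2, pos):
                if 0 <= flank < L and seq[flank] == "C":
                    seq[flank] = "A"

    return "".join(seq)


def write_fasta(seq: str, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            ">chrM synthetic mitochondrial reference stand-in "
            "(not rCRS; see scripts/build_reference_fixture.py)\n"
        )
        for i in range(0, len(seq), 70):
            fh.write(seq[i : i + 70] + "\n")


def write_bed(rows, path: Path) -> None:
    with open(path, "w") as fh:
        for start, end, label in rows:
            fh.write(f"chrM\t{start - 1}\t{end}\t{label}\n")


def write_site_vcf(sites, path: Path, source: str) -> None:
    import sys

    sys.path.insert(0, str(ROOT / "src"))
    from mitocall import vcfio

    vcfio.write_records(
        [vcfio.VcfRecord(pos=p, ref=r, alt=a) for p, r, a in sites],
        path,
        source=source,
    )


def main() -> None:
    DATA.mkdir(parents=True, exist_ok=True)
    TRACKS.mkdir(parents=True, exist_ok=True)

    seq = build_sequence()
    assert len(seq) == L
    for start, tract in TRACTS:
        assert seq[start - 1 : start - 1 + len(tract)] == tract, start
    for pos, b in FIXED_BASES.items():
        assert seq[pos - 1] == b, pos

    import sys

    sys.path.insert(0, str(ROOT / "src"))
    from mitocall.reference import find_homopolymer_regions

    regions = find_homopolymer_regions(seq)
    print("homopolymer regions:", [(iv.start, iv.end) for iv in regions])
    assert len(regions) == 9, f"expected 9 regions, finder found {len(regions)}"
    starts = {iv.start for iv in regions}
    assert 302 in starts and 455 in starts  # the published tracts

    write_fasta(seq, DATA / "chrM_synthetic.fa")
    write_bed(HV_REGIONS, TRACKS / "hv.bed")
    write_bed([(p, p, "HS") for p in HS_POSITIONS], TRACKS / "hs.bed")
    write_bed(DLOOP + CDS, TRACKS / "genic.bed")
    write_site_vcf(NUMT_SITES, TRACKS / "numt_sites.vcf", "mitocall-synthetic-numt")
    write_site_vcf(
        sorted(NUMT_SITES + DBSNP_EXTRA),
        TRACKS / "dbsnp_sites.vcf",
        "mitocall-synthetic-dbsnp",
    )
    print("fixture written to", DATA)


if __name__ == "__main__":
    main()
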