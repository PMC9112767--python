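# Methods

This note documents the models, parameter choices and numerical conventions
behind `mitocall`, and what the simulated validation does and does not show
about real data.

## Coordinates and the circular reference

All variant and interval positions are reported 1-based inclusive in
standard mitochondrial numbering (1..16,569); BED files on disk stay
0-based half-open. The working reference for alignment is the linear
sequence plus a 300-bp copy of its start appended after position 16,569
(`ext_len=300`, longer than any read, shorter than any fragment we accept).
Alignments on the extension are wrapped back modulo L, and any alignment
whose reference span crosses position L is split into two records
([start..L] and [1..remainder]); the split conserves reference and read
bases, and an insertion anchored exactly on the junction base stays with
the first piece, where its anchor lives.

The bundled reference is a deterministic **synthetic stand-in** for the
human mitochondrial genome (see `scripts/build_reference_fixture.py`). It
reproduces the structural features the code's logic and fixtures rely on —
length, realistic base composition, the two documented polycytosine tracts
spanning positions 300–320 and 450–470, exactly nine homopolymer regions,
and fixed bases at positions the bundled NUMT/dbSNP site lists name — but
it is not the rCRS, and analyses of real reads must supply one. The
annotation tracks shipped under `data/tracks_synthetic/` are likewise
synthetic fixtures with real-genome-style coordinates.

## Homopolymer regions

A homopolymer region is a stretch of cytosine runs containing at least
`min_run=5` Cs in total, interrupted by at most `max_mismatch=1` single
non-C base that has at least one C on each side, then padded by `pad=1` bp
per side and merged with any overlapping stretch. On the bundled reference
this yields nine regions, including 302–318 (the tract around the
well-known positions 302/310) and 16,182–16,195. G-runs (minus-strand C
tracts) can be included with `scan_reverse_complement=True`; the default
scans C only, which is the convention the nine-region count refers to.
Indel calls within 150 bp of a homopolymer region (one read length) are
tagged `HP_ADJACENT`, reflecting how unreliable indels are near slippage
tracts.

## Simulator

The simulator is the package's study design, not a test utility: its
defaults are the benchmark conditions.

* **Backbones.** 30 synthetic haplogroup profiles (5–40 homoplasmic SNVs
  each, disjoint positions, outside homopolymer regions) stand in for a
  phylotree panel. The panel is star-shaped rather than nested — adequate
  for the simplified panel matcher, not for fine haplogrouping.
* **Heteroplasmies.** Per sample, 35 SNVs and 8 INDELs (1–4 bp) are placed
  uniformly outside homopolymer regions, away from backbone edits and from
  each other (≥10 bp), and redrawn until their VCF representation is
  already left-aligned — so truth and calls compare by exact identity.
* **VAFs.** Drawn on [0.15, 0.20] with sample mean exactly 0.18. A uniform
  draw has mean 0.175 and cannot be nudged to 0.18 by moving a single site
  within the range, so draws come from a Beta rescaled to the interval with
  mean 0.18 (concentration 5), then one or more sites are minimally
  adjusted, within bounds, until the mean is exact.
* **Fragments.** Starts uniform on the circle; lengths
  Normal(350, 50) truncated to [300, 1000] (insert size is a free choice;
  these are typical short-insert WGS values). Each fragment carries each
  overlapping truth variant **independently** with probability equal to its
  VAF. This per-variant mixing makes the alt-read count at a site an exact
  Binomial(depth, vaf) draw — the oracle the tests use — at the cost of not
  modeling linkage between heteroplasmies on one molecule.
* **Errors.** I.i.d. substitutions at 0.01 per base; constant Q30 base
  qualities; no indel sequencing errors and no PCR duplicates by default
  (a duplicate-rate option exists).
* Coverage 2000× (the calling depth) or as configured; total emitted bases
  equal coverage × L up to fragment-count rounding.

## Alignment

A small seed-and-extend mapper: exact 21-mer index over the extended
reference, candidate diagonals from four seeds per read (both
orientations), then a windowed extension. Extension policy:

1. exact diagonal match → full-length match CIGAR;
2. ≤2 mismatches on the diagonal → full-length match CIGAR (this guards
   against edit-distance tracebacks that tie a terminal mismatch against a
   clip or 1-bp gap and would otherwise dilute allele counts);
3. otherwise edlib (banded edit distance, infix mode) against a ±12-bp
   window; its gapped CIGAR is used only when it beats the pure-substitution
   placement by ≥2 edits, which separates genuine indel reads (a gap saves
   many edits) from reads with scattered errors (it saves at most one).

Placements above 12% edit distance are discarded (unmapped). Ties across
distinct canonical positions get MAPQ 0 and are excluded from pileups;
among ties the smallest canonical start is the reported representative.
Edit-distance extension rather than the affine-gap scoring of production
mappers is a deliberate simplification: at 1% substitution error plus short
isolated indels the two select the same placements, and the C edlib kernel
keeps the mapper fast enough to be pure Python elsewhere. Adapter/quality
trimming is a no-op by default (simulated reads are clean).

Duplicate pairs (same fragment endpoints and strands) are marked, keeping
the highest-total-base-quality pair (ties by read id). Down-sampling to the
2000× working coverage keeps whole pairs independently with probability
target/observed, seeded.

## Pileup and calling

Pileups are strand-resolved per-position allele counts from CIGAR walks;
bases below Q20 are excluded from allele counts and VAF denominators but
retained in raw depth. Deletions count as spanning events at each deleted
position and as an anchored allele; insertions anchor on the base before
them. Indel CIGAR ops separated by ≤6 matched bases are re-expressed as a
single replacement of the spanned reference by the spanned read sequence,
normalized (trimmed, left-aligned); this collapses the different
edit-distance tracebacks of one event (e.g. a 3-bp insertion split around
a matching base) onto a single allele key across reads. A consequence of
extension policy (2) is a known small downward bias in indel VAFs: carrier
reads whose indel lies within a few bases of the read end keep the
full-length-match representation and stop supporting the indel allele
(roughly a tenth of carriers at 150-bp reads). Site presence at 2000× is
unaffected; tests bound the bias rather than pretending it is absent.

Calling is pure thresholding — no mutation-model likelihood. An allele is
emitted when VAF ≥ 3% of passing depth with ≥2 passing reads on each
strand, at sites with depth ≥10; strand and depth failures are emitted as
filtered records. Multiallelic sites report every qualifying allele.
Heteroplasmy vs homoplasmy is a VAF classification with the boundary at
97%; the 3%/97% symmetry is a design choice (the heteroplasmy floor
reflected about 1), since any allele at ≥97% leaves its competitors below
the calling floor. `min_depth=10` avoids small-denominator artifacts and
Q20 is a conventional base-quality floor; both are package choices. The
thresholds dominate accuracy at 2000×: an error pileup would need 60 reads
(3%) where errors average ~6.7 per alternate base. At 100×, by contrast,
3% is 3 reads and the threshold caller admits error pileups a
likelihood-based caller would reject — the depth dependence is expected
and is why the pipeline down-samples to 2000× rather than lower.

## Consensus and second iteration

The consensus applies every homoplasmy and every heteroplasmy with VAF
strictly >0.5 (highest-VAF allele at multiallelic sites; a tie at exactly
0.5 keeps the reference allele; overlapping indel edits are an error). The
coordinate map is piecewise and invertible: unedited positions round-trip
exactly, deleted reference positions map to their anchor, and positions
inside inserted blocks lift to the insertion anchor with an
`IN_CONSENSUS_INS` tag. Second-iteration calls are re-expressed against
standard-reference alleles so the two iterations' VCFs are directly
comparable: where a consensus edit made the standard base the minor
allele, the lifted record reports the consensus allele as ALT with VAF
1 − v and an `ALLELE_SWITCH` tag carrying the minor fraction. Consensus
validation follows exact-tiling logic: only perfect full-length alignments
count, and their intervals merge only when overlapping by ≥5 bases (the
interpretation of a negative merge distance), so seams covered by a single
exact read chain are accepted and gaps are reported.

## Copy number

`cn = 2 × chrm_cov / genome_cov` with chrm_cov = reads × mean read length
/ 16,569 (aligned M/=/X bases define mapped bases; duplicates and
secondary/supplementary alignments never count). Genome sizes:
3,031,865,587 (standard), 3,054,815,472 (female), 3,008,915,703 (male).
The synthetic cohort generator draws sex ~ Bernoulli(0.5), true CN ~
LogNormal(meanlog 5, sdlog 0.4) (median ≈148 copies, a realistic blood
range), nuclear depth ~ Normal(30, 3) over the sex-specific genome, and
chrM reads binomially at the success probability implied by the true CN.
Because the recomputed and sex-adjusted metrics differ only by a fixed
±0.8% genome-size factor within sex, their correlation across a cohort
with ~40% CN dispersion is ≥0.98 by construction of the estimator, not of
the test.

## Annotation, haplogroup, contamination

Annotation flags are pure functions of the loaded tracks (hence
idempotent). Haplogroup assignment scores each panel profile as
(matched − unmatched defining SNVs among homoplasmies)/size, preferring
smaller profiles on ties (closest to the reference backbone) and flagging
residual ties `AMBIGUOUS`. The contamination screen looks for a second
profile among heteroplasmies and estimates the mixture as the median VAF of
its matching alleles, flagging at ≥3% with ≥3 supporting sites — a
deliberately simple surrogate for tree-walking contamination tools; the
≥3-site floor keeps coincidental single-allele matches from flagging pure
samples.

## Problem sizes and limitations

The validation benchmark runs 10 of the 30 haplogroup backbones at 2000×
(about half a minute per sample end to end), chosen as a replicate count
that keeps the suite comfortably interactive while averaging over distinct
backbones; the simulator and pipeline accept the full 30 unchanged. The
acceptance script (`scripts/acceptance.py`) reruns exactly this benchmark
plus the 1000-sample CN cohort from a single seed.

What passing does not show: the simulator has uniform coverage, clean
qualities, substitution-only errors and no NUMT-misplaced reads, so it
exercises circularity, consensus logic, thresholds and bookkeeping — not
robustness to real library artifacts (slippage indels in poly-C tracts,
strand-biased error modes, low-CN NUMT contamination). INDEL calling in
homopolymer-adjacent regions is tagged rather than trusted. The extractor
streams whole files, which is the right trade-off at mitochondrial scale
but not for whole-genome-sized workloads.
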