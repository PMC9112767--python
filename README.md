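# mitocall

Mitochondrial DNA copy number and heteroplasmy calling from whole-genome
sequencing alignments.

## The problem

Human cells carry hundreds to thousands of copies of the 16,569-bp circular
mitochondrial genome (mtDNA). Two quantities summarize its state in a WGS
sample: **mtDNA copy number** (mtDNA-CN), the dosage of mitochondrial
relative to nuclear genomes, and **heteroplasmy**, the fraction of mtDNA
molecules carrying a variant allele at a site. Both are linked to aging and
disease, and both are awkward to measure from standard alignments: the
circle's "ends" lose coverage under linear mappers, nuclear-embedded
mitochondrial segments (NUMTs) siphon off chrM reads and inject false
low-level variants, and a sample genetically distant from the reference
shows coverage dips wherever its own homoplasmies pile up.

`mitocall` addresses these with three ideas, implemented end to end:

1. **Circular remapping.** Reads are mapped to the reference extended by a
   300-bp copy of its start; alignments crossing the origin are split into
   two records, restoring uniform coverage through the D-loop.
2. **Per-sample consensus re-calling ("second iteration").** Homoplasmies
   are inter-individual variation; heteroplasmies are intra-individual.
   After a first round of calling against the standard reference, every
   homoplasmy and major (>50%) allele is edited into a per-sample consensus
   genome, reads are re-mapped to it, and variants are re-called and lifted
   back to standard coordinates. What survives is genuine intra-individual
   variation.
3. **Copy number as a coverage ratio.**

   mtDNA-CN = 2 × (chrM coverage) / (genome coverage),

   with chrM coverage = (mapped chrM reads × read length) / 16,569 and the
   nuclear coverage computed from pipeline metadata, from mapped bases over
   a fixed genome size (3,031,865,587 bp), or over a sex-specific size
   (3,054,815,472 bp female / 3,008,915,703 bp male). Samples with CN < 100
   are flagged: at low dosage NUMT reads masquerade as heteroplasmies.

Calling itself is a transparent frequency test on strand-aware pileups
down-sampled to ~2000× coverage: an allele is reported at ≥3% VAF with at
least 2 supporting reads per strand; calls at ≥97% are classified
homoplasmic. Calls are annotated against region tracks (hypervariable,
homopolymer, hotspot, genic/D-loop) and site lists (known NUMT alleles,
haplogroup-defining SNVs, dbSNP), a simplified panel matcher assigns a
haplogroup, and a contamination screen flags samples whose heteroplasmies
trace a second haplogroup at ≥3% mixture.

A built-in simulator generates the validation data: haplogroup-derived
genomes with 43 injected heteroplasmies (35 SNVs + 8 INDELs) at 15–20% VAF
(mean 18%), sequenced as 150-bp pairs with 1% base error, plus a truth VCF
for exact false-negative/false-positive scoring.

**Note on the bundled reference.** The packaged `chrM` FASTA is a clearly
labelled synthetic stand-in, not the rCRS: it has the right length, the
documented polycytosine tracts at 300–320 and 450–470, exactly nine
homopolymer regions, and literature-consistent bases at the positions the
annotation fixtures reference. Point the tools at a real rCRS FASTA for
real data (`load_fasta` / `--ref`).

## Worked example

Simulate one haplogroup-H sample at 60× and call it through both iterations:

```
$ mitocall simulate --coverage 60 --seed 4 --haplogroup H --out-prefix s1
wrote 3314 pairs and 43 truth variants

$ mitocall call --fastq1 s1_R1.fastq --fastq2 s1_R2.fastq --seed 4 --out-prefix s1
iteration 1: 58 calls
iteration 2: 45 calls

$ mitocall evaluate --calls s1.iter2.vcf --truth s1.truth.vcf
{"sites": 45, "true_positives": 43, "false_negatives": 0, "false_positives": 2}
```

All 43 injected sites are recovered; at only 60× coverage two 1%-error
pileups still sneak past the 3% threshold (a 3% VAF needs just 2 reads at
this depth). At the pipeline's working depth of 2000× the same benchmark is
exact — `mitocall benchmark --n-samples 10 --coverage 2000 --seed 1`
reports per-sample and mean FN/FP counts for both iterations:

```
means: fn1 0.00 fp1 0.00 fn2 0.00 fp2 0.00
```

Library use mirrors the CLI; the pieces are importable separately
(`mitocall.simulate`, `mitocall.align`, `mitocall.caller`,
`mitocall.consensus`, `mitocall.copynumber`, ...). See `docs/methods.md`
for the model and its assumptions.

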