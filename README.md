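# cnvrmap

Consensus copy-number-variable-region (CNVR) mapping from multi-algorithm
SNP-array CNV calls, built as a tested, fully offline pipeline:

* **Genotype QC** — SNP call-rate, minor-allele-frequency and exact
  Hardy-Weinberg filters (strict thresholds: call rate < 0.90, MAF < 0.03,
  HWE p < 1e-6), followed by a sample call-rate pass on surviving SNPs.
* **CNVR construction** — per-algorithm call filtering (minimum 3 SNPs per
  segment, recurrence in ≥ 2 individuals), aggregation of overlapping calls
  into CNVRs (1-bp transitive overlap, 1-based inclusive coordinates), and
  assembly-gap screening.
* **Consensus map** — regions recalled by ≥ 2 of the supplied callers,
  with per-algorithm agreement fractions and cross-study overlap counts.
* **Cohort comparison** — separate founder-breed and F2 pipelines,
  breed-unique CNVR identification and cross-generation overlap.
* **Annotation overlap** — interval joins against genes (with biotype
  summaries), QTLs (trait summaries), and genome-wide-significant SNPs.
* **qPCR validation** — 2^-ΔΔCT relative quantification from CT
  replicates, copy-state classification (loss < 0.59, gain ≥ 1.59,
  configurable) and concordance scoring against predicted CNVR status.
* **Synthetic data** — seeded generators for planted-truth CNVR
  landscapes, four emulated caller outputs with distinct error profiles,
  genotype matrices with controllable QC failures, and qPCR CT tables,
  plus truth-matching at 50% reciprocal overlap.

Coordinates are 1-based inclusive everywhere internally; BED converts at
the boundary. The CNVR writer reproduces the published table layout,
including its `Length (Kb) = (end − start) / 1000` convention (distinct
from the inclusive `length_bp` used in interval algebra). The 60-row
published F0-unique CNVR table ships as package data
(`src/cnvrmap/data/f0_unique_cnvrs.tsv`) and is used as a round-trip and
arithmetic fixture.

## CLI

```sh
cnvr simulate --seed 42 --out-dir sim/ --n-cnvrs 100
cnvr io validate sim/gada.calls.tsv --schema calls
cnvr qc --genotypes sim/genotypes.tsv --out qc.tsv
cnvr build --calls sim/gada.calls.tsv --algorithm gada \
    --coords 1-based-inclusive --min-snps 3 --min-carriers 2 --out gada.cnvrs.tsv
cnvr consensus --in gada gada.cnvrs.tsv --in penncnv penn.cnvrs.tsv \
    --min-support 2 --out consensus.tsv --agreement agreement.tsv
cnvr annotate --cnvrs consensus.tsv --genes genes.gff3 --qtls qtls.tsv \
    --out hits.tsv --summary summary.json
cnvr qpcr --assays sim/qpcr_cts.tsv --cnvrs consensus.tsv \
    --out rq.tsv --validation validation.tsv
```

Call tables require an explicit coordinate-convention declaration
(`--coords`); the readers refuse to guess.

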