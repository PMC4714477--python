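# rddcall

Calling high-confidence RNA-DNA differences (RDDs) — A-to-I RNA editing
events — from aligned RNA-seq and whole-genome DNA data, plus the downstream
analyses: genic context and coding consequence, cross-sample sharing,
editing/coverage matrices, splice-junction isoform usage, and per-site
correlation of editing frequency with editing-enzyme expression. A synthetic
study generator with planted ground truth stands in for real sequencing data.

## Pipeline

1. **Read filters** — keep uniquely mapped reads (NH tag, or MAPQ fallback)
   with ≥ 70 % of cycles at Phred ≥ 23.
2. **SNV candidates** — per-sample pileups; a candidate passes with ≥ 10X
   coverage, ≥ 2 unique supporting reads at base quality ≥ 23, and at least
   one supporting read more than 10 bp from both read ends.
3. **Positional exclusions** — homopolymer tracts, repeat-masker /
   multi-mappability / self-chain tracks, and intronic sites within 5 bp of
   an exon-intron boundary.
4. **Strand resolution** — sites must lie in annotated genes; sites in genes
   on both strands are discarded.
5. **Genomic subtraction** — an RNA variant becomes an RDD only when pooled
   DNA shows > 20X coverage and zero reads supporting the edited base.
6. **Classification** — sense A→G (genomic A→G on `+`, T→C on `-`) is the
   canonical A-to-I class; other classes are retained and labelled.

## CLI

```bash
rddcall simulate --preset default --seed 1 --out run/   # synthetic study
rddcall call       --run-dir run/                       # filter cascade + subtraction
rddcall annotate   --run-dir run/                       # context, consequence, motifs
rddcall quantify   --run-dir run/                       # RPKM, junctions, matrices, sharing
rddcall correlate  --run-dir run/                       # enzyme-expression correlation
rddcall report     --run-dir run/                       # plain-text summary
```

Each stage reads the previous stage's outputs from the run directory and
exits non-zero naming any missing artifact. All thresholds are flags
(`--min-cov`, `--min-alt`, `--min-bq`, `--end-excl`, `--splice-buf`,
`--dna-min-cov`, …); reruns with the same seed and configuration are
byte-identical.

## Layout

| module | contents |
| --- | --- |
| `rddcall.io_formats` | FASTA/GFF3/SAM/BED readers and writers, genome and gene-model types, RDD table |
| `rddcall.synthetic_data` | study simulator with planted edits/SNPs, filter-gauntlet fixture |
| `rddcall.snv_calling` | read filters, pileups, candidate SNV calling, positional exclusions |
| `rddcall.rdd_calling` | strand inference, genomic subtraction, edit classification, full cascade |
| `rddcall.annotation` | genic context, codon consequence, sequence-context matrices, category enrichment |
| `rddcall.quantification` | RPKM, junction counting, editing matrices, sharing, enzyme correlation |
| `rddcall.cli` | `rddcall` subcommands |
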