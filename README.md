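# retrofunc

Multi-evidence functional annotation of retrocopies (retroposed gene
copies) from transcriptome-level data. Starting from a retrocopy
catalog, a transcript annotation, a TPM expression matrix, per-base
Ribo-seq/RNA-seq coverage tracks, a peptide list, miRNA target-site
tables, a TSS table and a fusion-breakpoint table, the pipeline calls:

- **expression** — TPM filtering (>= 1 TPM in >= 1% of experiments) and
  expression-pattern classes (ubiquitous / tissue-specific /
  cancer-line-only / other / not expressed);
- **co-expression** — Spearman correlation in two modes (co-expressed
  samples only, or all samples), kept at p < 0.001 and |rho| > 0.25;
- **ribosome association** — per-feature ribosome density (mean
  Ribo-seq / mean RNA-seq coverage), RNA-coverage >= 10 gating, one-pass
  Z-score trimming at ±1.64, and a per-library cutoff at Z = +1.64 of
  the trimmed 3'UTR (negative-control) density distribution;
- **peptide evidence** — six-frame stop-to-stop ORF discovery on the
  retrocopy locus ±500 b (ORFs must overlap the retrocopy by >= 60 b),
  exact full-length peptide matching (>= 10 aa, no mismatches) with a
  decoy-transcriptome uniqueness filter and parental-frame concordance;
- **miRNA sponges** — shared seed-family target sites scored with an
  upper-tail hypergeometric test, Benjamini-Hochberg corrected at
  α = 0.05, intersected with co-expression;
- **cis-NAT / trans-NAT / transcriptional interference / exonization** —
  strand-aware overlap geometry classifiers (antisense overlaps,
  antisense lncRNA / exonized transcripts / near-3'-end antisense TSSs,
  retrocopies <= 1000 bp downstream of a short isoform and inside an
  intron of a long isoform, and UTR/CDS exon-contribution classes);
- **fusions** — retrocopy-related fusion categories (parental x host,
  retro x parental, host x host) and per-breakpoint classes (in-body,
  downstream-near, distant, unrelated).

A synthetic-data module (`retrofunc.synth`) generates genomes,
annotations, expression matrices, coverage tracks, peptides, site
tables, TSSs and fusions with planted, machine-readable ground truth,
so every stage is verifiable end to end without external downloads.

## CLI

```bash
# generate a fixture set with planted signals
retrofunc simulate --outdir fixtures/ --seed 1

# run everything
retrofunc run --indir fixtures/ --outdir calls/

# or a single stage
retrofunc expression --indir fixtures/ --outdir calls/
retrofunc ribo --indir fixtures/ --outdir calls/

# aggregate calls into a per-retrocopy evidence matrix
retrofunc report --indir fixtures/ --outdir calls/ [--plots]
```

`retrofunc run` also accepts `--config config.yaml` with any
`RunConfig` field (thresholds, stage toggles); unknown keys are
rejected.

Outputs are tab-separated files (`expressed_ids.tsv`, `patterns.tsv`,
`correlations.tsv`, `density.tsv`, `ribo_calls.tsv`,
`peptide_hits.tsv`, `sponge_calls.tsv`, `overlaps.tsv`,
`cis_nat_calls.tsv`, `trans_nat_calls.tsv`, `exon_contributions.tsv`,
`interference_calls.tsv`, `fusion_classes.tsv`) plus a
`run_log.json` with parameters and per-stage counts.

## Layout

```
src/retrofunc/
  datamodel.py   core domain types (intervals, transcripts, matrices, tracks)
  io.py          GTF/BED12, catalog TSV, expression TSV, bedGraph, FASTA
  synth.py       synthetic fixtures with planted ground truth
  expression.py  TPM filter, pattern classes, Spearman modes
  ribosome.py    density, Z-trimming, 3'UTR-calibrated calling
  peptides.py    six-frame ORFs, exact peptide matching, frame concordance
  sponge.py      seed-match sites, hypergeometric test, BH, sponge calls
  overlap.py     overlaps, cis/trans-NAT, interference, exonization
  fusion.py      fusion categories and breakpoint classes
  pipeline.py    orchestration, evidence summary, network edges
  cli.py         click-based CLI
```
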