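# ervkit

A tested, reusable pipeline for analyzing the epigenetic interplay between
endogenous retroviruses (ERVs) and nearby genes:

- **Insertion-distance distributions** — expected distributions from uniform
  random-insertion simulation, observed ERV-to-TSS/TTS distance binning,
  per-bin proportion-equality tests, and depletion-zone threshold detection
  (lower boundary of the first non-significant bin).
- **Methylation quantification** — MeDIP-qPCR scores
  (`efficiency ** (Ct_input − Ct_IP)`, spike-in normalized, scores < 0.2
  called unmethylated) and bisulfite clone analysis with strict conversion
  QC (> 95% non-CpG conversion) and PCR-duplicate removal (clones kept when
  their CpG pattern **or** their non-conversion error set is unique).
- **LTR / gene architecture** — proximal-LTR orientation calls for
  full-length elements, orientation-bias and CGI-promoter-association
  tests, differential 5'/3'-LTR methylation (Mann-Whitney, exact for small
  samples), methylation-spreading assessment, and copy-filtering rules.
- **Chromatin profiles** — orientation-normalized signal profiles over
  ERV–gene intervening regions (TE on the left, TSS on the right, ±400 or
  ±200 bp flanks) and ChIP-qPCR enrichment.
- **Synthetic data** — deterministic generators for every input the
  pipeline consumes (genome/genes/CGIs, selection-thinned ERV insertions,
  bisulfite clone reads, Ct tables, bedGraph tracks) with ground-truth
  sidecars, so every stage is testable offline as parameter recovery.

## CLI

One entry point, `ervkit`, with per-stage subcommands:

```bash
ervkit simulate --seed 1 --out sim/                    # synthetic input bundle
ervkit erv-dist --ervs sim/ervs.bed --genes sim/genes.bed \
    --genome sim/genome.chrom.sizes --anchor tss --out dist.tsv
ervkit meth-call --ct-table sim/ct_table.tsv --out calls.tsv
ervkit bisulfite-qc --reference ref.fa --reads reads.fa --out qc.tsv
ervkit ltr-compare --ltr5-ref ... --ltr5-reads ... --ltr3-ref ... \
    --ltr3-reads ... --out ltr.tsv
ervkit cgi-assoc --ervs sim/ervs.bed --genes sim/genes.bed \
    --cgis sim/cgis.bed --out assoc.tsv
ervkit profile --regions regions.tsv --track sim/tracks/h3k4me3.bedgraph \
    --out-matrix matrix.tsv --out-mean mean.tsv
ervkit run-all --seed 1 --out run/                     # full pipeline
```

`run-all` writes report tables under `<out>/reports/` (distance
distributions + thresholds, methylation calls with an evidence ledger,
LTR comparison, orientation/CGI association, spreading assessment, copy
filter, profile matrices) plus `run_log.json` with a config hash; two runs
with the same seed are byte-identical.

## File formats

All coordinates are 0-based half-open (BED convention).

- **Genes / CGIs**: BED6 / BED3. Gene TSS is the left edge on `+`, the
  right edge on `-`.
- **ERVs**: extended BED whose columns 7+ are
  `family element_type ltr5_start ltr5_end ltr3_start ltr3_end polymorphism`
  with `family ∈ {ETn/MusD, IAP}`, `element_type ∈ {solo, full_length}`,
  missing LTR coordinates written as `.`, and
  `polymorphism ∈ {fixed, polymorphic}`.
- **Signal**: 4-column bedGraph (uncovered positions read back as 0).
- **Ct tables / expression / region manifests**: TSV.
- **Bisulfite clones**: FASTA reference + FASTA clone reads (ungapped,
  reference-length).

## Library layout

| module                 | contents                                             |
|------------------------|------------------------------------------------------|
| `ervkit.model`         | domain types, interval arithmetic                    |
| `ervkit.io`            | BED/extended-BED, bedGraph, FASTA, TSV readers/writers |
| `ervkit.stats`         | proportion tests, exact Mann-Whitney, Spearman, stars |
| `ervkit.simulate`      | synthetic-data generators + ground-truth sidecars    |
| `ervkit.distribution`  | expected/observed distance machinery, thresholds     |
| `ervkit.methylation`   | MeDIP scoring, bisulfite QC/dedup/quantification     |
| `ervkit.architecture`  | LTR orientation, CGI association, spreading, filters |
| `ervkit.profiles`      | intervening regions, profile extraction/averaging    |
| `ervkit.pipeline`      | end-to-end orchestration and report tables           |
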