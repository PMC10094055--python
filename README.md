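# epi-impute

Dropout imputation for single-cell RNA-seq using matched single-cell
ATAC-seq.

scRNA-seq count matrices are dominated by zeros, a mixture of biological
silence and technical *dropouts* (expressed transcripts that were simply not
captured). Purely expression-based imputation methods infer the missing
values from the expression matrix itself, which is circular and inflates
gene–gene correlations. This package instead uses an orthogonal signal:
chromatin accessibility of a gene's regulatory elements, measured by
scATAC-seq in the *same annotated cell populations* (not necessarily the
same cells). Open chromatin at a promoter or a linked enhancer marks a gene
as likely expressed, so population-level accessibility can back-fill
dropouts without re-using the expression data.

It is aimed at anyone with matched, cell-type-annotated scRNA-seq and
scATAC-seq of the same biological sample (separate experiments are fine;
matching happens through cell-type labels, never through barcodes).

## Method

For each cell type and gene:

1. **Element counting.** ATAC fragments (MAPQ > 30, Tn5-corrected by
   +4/−5 bp) are counted into windows of the gene's cis-regulatory
   elements — a strand-aware −500/+200 bp window around each TSS, and
   enhancer intervals with links to their target genes — separately for
   promoters and enhancers.
2. **Threshold accessibility vector.** The per-cell noise level θ_c is
   estimated from fragment coverage of blacklist (artefact) regions:
   θ_c = (blacklist fragments per bp) × window length. It is appended to
   the count matrix as a pseudo-element so every transform below applies to
   it too.
3. **Normalization.** Smooth quantile normalization across cells (the
   per-rank reference blends cell-type-specific and global quantiles by the
   between-group variance fraction) followed by a binned GC-content
   correction across elements.
4. **Open calls and gene activity.** An element is *open* in cell c iff its
   normalized value v strictly exceeds θ_c. A gene's accessibility is the
   max over its elements, so the gene is open iff *any* of its elements is
   (an OR rule). The soft version is a sigmoid of the gap,
   `a_gc = σ(k·(v_gc − θ_c))` ∈ (0, 1) — a probability of expression that
   crosses 0.5 exactly at the hard call.
5. **Population activity and imputation.** Per cell type t, the per-cell
   open calls are aggregated by the median into `A_gt` ∈ {0, ½, 1}, and the
   result is added to the raw counts of every RNA cell of that type:

   `imputed(g, c) = raw(g, c) + A_{g, type(c)}`

   Nothing is ever subtracted and the added term is constant within a cell
   type, so expression order among cells of a type is preserved exactly.

The package also ships the full evaluation harness (marker-based TPR/FPR,
pseudo-bulk TPR/FPR, expression-stratified 1−F1 imputation error,
gene-pair correlation preservation) and a synthetic matched-data generator
with known ground truth, so the whole pipeline is testable end to end with
no external downloads.

## Worked example

Simulate a small matched dataset (3 FACS-like cell types × 50 cells, 300
genes, 10 positive + 10 negative markers per type), then benchmark
imputation at 50% and 75% simulated dropout:

```bash
cat > design.yaml <<EOF
n_cell_types: 3
cells_per_type: 50
n_genes: 300
markers_per_type_pos: 10
markers_per_type_neg: 10
genes_per_chrom: 150
EOF

epi-impute simulate --out dataset --config design.yaml --seed 7
epi-impute benchmark --data dataset --rates 0.5,0.75 --report report.json --seed 7
```

`report.json` from this exact invocation contains (abridged):

```
rate 0.50  marker test: TPR 1.000  FPR 0.000   bulk test: TPR 1.000  FPR 0.000
           overall imputation error (1-F1): 0.123
           housekeeping pair r:  raw 0.730  dropout 0.283  imputed 0.424
rate 0.75  marker test: TPR 1.000  FPR 0.000   bulk test: TPR 1.000  FPR 0.000
           overall imputation error (1-F1): 0.086
           housekeeping pair r:  raw 0.730  dropout 0.020  imputed 0.199
```

Reading this: every truly expressed positive-marker entry is non-zero after
imputation (TPR 1) while zero entries of negative markers stay zero
(FPR 0) — the additive term is exactly 0 for genes whose regulatory
elements are closed across a population. The overall 1−F1 error reflects
biological zeros of expressed genes that population-level imputation cannot
distinguish from dropouts. The embedded housekeeping gene pair has true
Pearson r = 0.7; dropout destroys the correlation (0.28 at 50%, 0.02 at
75%) and imputation moves it back toward the truth (0.42 / 0.20).

The imputation itself, on files you provide:

```bash
epi-impute run \
  --rna counts/ --rna-ann rna_annotation.tsv \
  --atac-fragments fragments.tsv.gz --atac-ann atac_annotation.tsv \
  --promoters promoters.bed --enhancers enhancers.bed --links links.tsv \
  --blacklist blacklist.bed --out out/
```

writes `out/imputed/` (MatrixMarket + sidecars, fractional values) and a
`manifest.json` with the config snapshot, input digests and seed; identical
inputs and seed reproduce byte-identical outputs. Every stage is also
available as a library function (`epi_impute.run_pipeline`,
`epi_impute.count_fragments`, `epi_impute.smooth_quantile_normalize`, …).

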