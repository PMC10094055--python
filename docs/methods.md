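# Methods

## Model and assumptions

The pipeline estimates, per gene and cell, a probability that the gene is
expressed, from the chromatin accessibility of its cis-regulatory elements,
and adds the per-cell-type median of that probability to the raw scRNA-seq
counts. The underlying assumptions are:

* cells in both modalities carry a trustworthy cell-type annotation, and the
  label sets overlap (RNA cells whose label has no ATAC population are
  passed through untouched);
* accessibility of a gene's promoter *or* any linked enhancer is evidence of
  expression (an OR rule over elements — hence the max aggregation, the
  unique continuous statistic whose thresholding reproduces OR);
* blacklist-region coverage is a usable per-cell estimate of non-specific
  background, so "open" means *strictly more signal in the window than the
  background would produce*;
* enhancer–gene links are prior knowledge supplied as input, not inferred.

Coordinates are 0-based half-open throughout (BED-native); the TSS of a `+`
record is its `start`, of a `-` record `end − 1`.

## Pipeline stages and parameters

| parameter | default | units | role |
|---|---|---|---|
| `flank_up` / `flank_down` | 500 / 200 | bp | strand-aware promoter window around the TSS |
| `mapq_min` | 30 | — | fragments kept iff MAPQ strictly > 30 (when a MAPQ column exists; 10x-style duplicate-count files skip the filter, logged) |
| `tn5_plus_offset` / `tn5_minus_offset` | +4 / −5 | bp | Tn5 dimer correction of fragment ends; the two adaptor insertions are 9 bp apart |
| `count_mode` | `overlap` | — | a fragment counts in every window it overlaps by ≥ 1 bp; `insertion` counts each corrected endpoint instead |
| `gc_bins` | 10 | — | equal-frequency GC bins for the conditional correction |
| `sigmoid_k` | auto | 1/normalized-count | steepness of the soft open call |
| `lhs_strata` | 10 | — | rank strata of the dropout simulator |
| `scale_activity` | 1.0 | — | multiplier on the additive term (escape hatch; the method's statement is scale 1) |

Enhancer windows: enhancers have no strand or TSS, so an enhancer shorter
than `flank_up + flank_down` (700 bp) is recentred to a 700 bp window on its
midpoint; longer enhancers are counted over their annotated interval as is.

### Threshold accessibility vector

θ_c = (blacklist fragments per bp in cell c) × 700 bp is the expected number
of background fragments in one window. The vector is appended to the element
count matrix as a pseudo-element and carried through both normalizations, so
threshold and signal stay on one scale. Because the transforms are
rank-based, only the threshold's rank matters: any θ in (0, 1) separates
zero-count elements from elements with at least one fragment, which makes
the open call robust to the Poisson noise of the blacklist estimate.

### Smooth quantile normalization

Per rank q, the reference for cell group g is
`w(q)·Q_g(q) + (1 − w(q))·Q(q)` with `w(q) = SSB(q)/SST(q)` clamped to
[0, 1] — the fraction of the across-cell variance of the q-th sorted values
explained by the groups. Indistinguishable groups collapse to classical
quantile normalization; disjoint groups keep their own distributions.
Groups with a single cell fall back to the global reference.

### GC correction

Elements are binned on GC-fraction value quantiles (ties always share a
bin — rank-splitting tied GC values can isolate a bin of empty elements and
inflate it to the global mean, which is why binning is by value). Bins with
fewer than 5 elements merge with the nearest bin. Within each bin, values
are rescaled per cell so the bin mean equals the cell's mean over
GC-annotated elements. This is an explicit, testable binned stand-in for a
spline-based conditional-quantile correction: the correctness surface here
is rank/threshold behaviour, not spline internals. Elements without GC
annotation (including the threshold pseudo-element) pass through unscaled.

### From activity to imputation

Gene activity is `σ(k·(v − θ))` with `k = 4 / median positive (v − θ) gap`
by default, so the median open entry sits near activity 0.98 regardless of
sequencing depth; a fixed `k` can be set in the config. Activities are
clipped infinitesimally inside (0, 1).

Aggregation to cell types **binarizes first** by default: each cell's
activity becomes its open call (activity > 0.5), and the per-type median of
the calls is the additive term (0, ½ or 1; the median of an even number of
cells is the mean of the two middle values). Rationale: the additive design
treats any positive imputed value as an expression call, so a continuous
median — strictly positive even for closed genes — would mark every gene in
every cell as expressed. Binarizing makes the term exactly 0 for genes
closed across a population: closed genes are never touched, which is what
gives the method its specificity on negative markers. The continuous median
is available (`binarize_before_median: false`) for analyses that want a
graded term.

## Synthetic data generator

The generator emulates FACS-sorted populations: per type, 20 positive
markers (NB mean 5 in the type, 0 elsewhere) and 20 negative markers (the
next type's positives, hence 0 in this type), background genes at NB mean 3
everywhere, dispersion 3 (variance = μ + μ²/3 — moderate overdispersion,
plausible for homogeneous sorted populations). ATAC is concordant by
construction: every element of a gene with non-zero mean in a type receives
Poisson(2) fragments per cell, placed uniformly in the element window, plus
uniform background of 0.02 fragments/kb/cell across a synthetic genome (one
chromosome per 500 genes, genes every 10 kb, one 400 bp enhancer 3 kb
downstream of each TSS, two 10 kb blacklist regions per chromosome tail).

A housekeeping gene pair with an exact population Pearson correlation can be
embedded. With the pair Poisson(μ)-expressed in k of T types and zero in the
rest, the within-type correlation needed for an overall target r is
`ρ_w = r·(1 + (1−p)·μ) − (1−p)·μ` with `p = k/T`; the pair is then built by
the shared-component construction (x = u₀ + u₁, y = u₀ + u₂ with
u₀ ~ Pois(ρ_w μ)), which hits both marginals and ρ_w exactly. The default
(μ = 4, 2 of 3 types, target 0.7) gives ρ_w = 0.3. The zero type matters: an
imputer that adds a per-type constant cannot change within-type Pearson
correlation at all — only the between-type structure it restores moves the
overall correlation back toward the truth.

Dropout injection: per cell type, exactly `round(rate × nnz)` non-zero
entries are zeroed; entries are ranked by value, split into 10 equal-rank
strata, and each stratum loses an equal share (±1) of the quota, sampled
uniformly without replacement — a Latin-hypercube scheme that spreads
dropouts evenly over the expression range. The mask is exactly invertible.

What the generator does **not** emulate: doublets, batch effects, ambient
RNA, trajectory/continuum structure, distance-dependent enhancer effects,
discordant chromatin (primed-but-silent genes), and depth variation between
cells. Passing tests therefore demonstrate correctness of the machinery and
recoverability under concordant accessibility, not performance on tissues
where chromatin and expression decouple.

## Evaluation protocols

* **Marker test** — over entries (g, c) with g a positive marker of
  type(c) and ground truth non-zero: TPR = recovered fraction; over entries
  with g a negative marker and ground truth zero: FPR = imputed-non-zero
  fraction. "Non-zero" is strict (tolerance exactly 0). Empty classes
  report as missing, never 0.
* **Bulk test** — same rates with classes from a per-type bulk profile: top
  10% genes positive, zero-bulk genes negative (the synthetic truth provides
  a pseudo-bulk as the per-type mean of pre-dropout expression).
* **Stratified 1−F1** — masked entries are stratified by their true value
  (default: quartiles); each false positive (true-zero entry imputed
  non-zero) is assigned to the stratum containing its *gene's* mean true
  expression, since a zero has no entry-level value. This places the FP cost
  of population-level imputation on the expression level of the gene that
  caused it, and a pooled "overall" row aggregates everything.
* **Correlation preservation** — Pearson r per gene pair per matrix over
  all cells (a filtered convention using only cells with a non-zero in the
  pair is available behind a flag), reported with |r − reference|.

## Numerical choices

* Threshold pseudo-element floored at 1e−9 so that a cell with zero
  observed blacklist coverage still ranks its threshold strictly above
  exact-zero counts (a zero-coverage element is never "open").
* Ties in quantile normalization receive the mean reference over the tied
  ranks. This convention costs exact idempotency on tied data; on tie-free
  data both normalizations are idempotent to 1e−9 and this is tested.
* Open call is strictly `v > θ`; activity exactly 0.5 rounds to closed.
* Median convention: even counts average the two middle values.
* Dropout quota rounding is round-half-up; per-stratum remainders are
  assigned to uniformly chosen strata.
* Imputed matrices keep fractional values; nothing is rounded to integers.
* All randomness flows from `numpy.random.SeedSequence` spawns of a single
  seed; identical seeds and inputs give byte-identical output files.

## Problem sizes

The stochastic checks (test suite and `scripts/acceptance.py`) use the
default design — 3 types × 200 cells × 1500 genes, ≈ 3.7 M fragments — over
ten seeds, with 50% dropout for the recovery metrics and 75% for the
correlation protocol; unit tests run a 3 × 30 × 150 version of the same
design. These sizes keep a full multi-seed evaluation in the minutes range
on a single CPU while leaving every per-type statistic well resolved
(≥ 200 cells per median, ≥ 10⁵ masked entries per error estimate).

## Known limitations

* The additive term is population-level: within a cell type it cannot
  distinguish a dropout from a biological zero of an expressed gene, which
  is exactly the residual 1−F1 error the benchmark reports.
* The GC correction is a binned conditional-mean adjustment, not a spline
  fit; strong, narrow GC effects would be smoothed over.
* Enhancer windows for unstranded short enhancers use a midpoint
  convention; a different convention shifts counts by at most the flank
  asymmetry.
* With very few elements (tens), equal-frequency GC bins become noisy;
  bins under 5 elements are merged, but small panels are better run with
  `skip_gc_norm`.
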