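# scbinary

Analyses of binarized single-cell RNA-seq data: how much of a sparse
count matrix's signal survives when every non-zero count is replaced by
a one, and what that buys in storage and simplicity.

As scRNA-seq datasets grow they get sparser, and the 0/1 *detection
pattern* (zero stays zero, every non-zero value becomes a one) carries an
increasing share of the usable signal. This project implements, end to
end, the analyses that make that case quantitative:

* **Binary/count concordance.** For each cell, the point-biserial
  correlation *p* between its log-normalized expression vector and its
  detection vector, its predictor *q* = detection rate × variance of the
  non-zero values, and the dataset statistic *α* = corr(*p*, *q*).
* **Binary embeddings.** PCA on the 0/1 matrix, and eigenvectors of the
  Jaccard cell–cell similarity matrix
  S<sub>ij</sub> = |D<sub>i</sub> ∩ D<sub>j</sub>| / |D<sub>i</sub> ∪ D<sub>j</sub>|
  over detected gene sets, compared with count-based PCA via per-cell-type
  silhouettes, a fixed-*k* inverse Simpson mixing index (iLISI), and the
  correlation of pairwise cell distances.
* **Marker-detection annotation.** Cells labelled by the fraction of each
  type's markers they detect; agreement scored by median F1.
* **Pseudobulk differential expression.** Per-sample aggregation by mean
  log-normalized expression versus per-sample *detection rate*; a Welch
  t-test on detection rates versus a moderated count test with
  empirical-Bayes variance shrinkage toward an intensity trend
  (s̃² = (d₀s₀² + d·s²)/(d₀ + d)); both benchmarked on a multi-sample NB
  simulator with known DE truth over a 96-setting grid.
* **Zero-inflation model selection.** Per-gene maximum likelihood for
  Poisson, NB, ZIP and ZINB (EM over the structural-zero indicator),
  BIC selection, and a Fisher exact test — probability-ordering two-sided
  p, conditional-MLE log odds ratio under the noncentral hypergeometric
  likelihood, exact test-inversion CI — for enrichment of zero-inflated
  fits among differentially detected versus stably detected genes.
* **Bit-packed storage (BBM)** — one bit per matrix entry, LSB-first,
  gene-major with a 24-byte header — plus byte accounting against dense
  float64 and sparse-triplet storage.
* **Expression recovery.** A gene's relative expression in a cell
  re-estimated as its detection rate among the cell's *k* nearest
  neighbours in a binary-only embedding.

All inputs are synthetic: `scbinary.simulate` generates multi-sample
two-condition NB counts with per-sample variability and known DE genes,
and multi-population counts with marker, housekeeping and background
genes.

## Worked example

The numbered scripts under `analysis/` run the whole story on synthetic
data and write tables under `results/`. For example:

```sh
$ python analysis/02_concordance.py --seed 0
cells: 600
mean per-cell binary/normalized correlation p = 0.981
mean detection rate = 0.355
alpha (corr of p against q) = -0.996
```

On a dataset with 35% detection rate, a cell's 0/1 detection vector
correlates at 0.98 with its log-normalized expression — the counts add
little — and *p* is almost perfectly (negatively) predicted by *q*.

```sh
$ python analysis/05_zero_inflation.py --seed 0
model selection among ranked genes (zero-inflated / not):
  differentially detected: 100 / 0
  stably detected:         12 / 88
Fisher exact: p = 9.76e-44, logOR = inf, 95% CI (5.064, inf)
```

Genes expressed in only one cell population are overwhelmingly assigned
zero-inflated models, stably detected genes are not: zero-inflation here
is a signature of biological heterogeneity, not of the technology.

The same Fisher machinery on a published 2×2 enrichment table:

```sh
$ scbinary fisher --table 99,1,35,65
p = 3.03e-25, logOR = 5.1887, 95% CI (3.3584, 8.8662)
```

`analysis/04_pseudobulk_benchmark.py` reproduces the benchmark
directions: the count route yields more false positives at every design
size, the detection-rate route more false negatives at small designs
(concentrated in genes with detection > 0.9), and the F1 gap
(binary − counts) moves from −0.06 at 2 samples × 30 cells to +0.02 at
8 samples × 200 cells.

A `scbinary` command-line interface wraps the library
(`simulate`, `binarize`, `diagnose`, `embed`, `annotate`,
`pseudobulk-de`, `fit-models`, `fisher`, `zi-enrichment`, `reconstruct`,
`run`); see `scbinary --help`.

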