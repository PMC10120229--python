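# Methods

This note documents the models, estimators and numerical conventions
implemented in `scbinary`, the design choices made where several
reasonable options existed, and what the synthetic data do and do not
establish.

## Representations and normalization

A count matrix is genes × cells with non-negative integers. Binarization
maps every non-zero entry to one; it is idempotent and commutes with any
zero-preserving transform. Normalization is fixed to log CP10K,
`ln(1 + 10⁴ · count / cell_total)`: it is deterministic, dependency-free
and preserves the zero pattern exactly, so detection rates are identical
before and after. Cells with zero total count are rejected (no
normalization is defined for them). The shuffled-counts control permutes,
independently per gene, the multiset of non-zero counts among that gene's
detected cells: the binary matrix, each gene's detection pattern and its
count marginal are all invariant, so any analysis that changes under the
shuffle is using count magnitudes, and any that does not is using
detection only.

### BBM storage

The bit-packed format stores a 24-byte header (`BBM1`, 4 reserved zero
bytes, `n_genes` and `n_cells` as little-endian uint64) followed by one
padded byte row per gene, bits LSB-first within each byte. Storage
accounting compares G·C·8 bytes (dense float64), 12·nnz bytes (sparse
triplets at int32 + int32 + float32 — the accounting convention, not a
specific library's layout) and G·⌈C/8⌉ + 24 bytes (BBM, equal to the
written file size by construction). The fold reductions are
dataset-dependent; against sparse storage the fold grows with the
detection rate, since sparse cost is proportional to nnz while the bit
cost is constant.

## Per-cell concordance (p, q, α)

For cell *c* with normalized vector x and detection vector y,
p(c) = Pearson corr(x, y) across genes (the point-biserial correlation;
x is zero exactly where y is zero). q(c) = detection rate × var of the
non-zero values of x, using the unbiased (n−1) variance, defined as 0 for
a single detected gene. α = Pearson corr of p against q across cells with
defined p (constant cells yield a missing p with a warning; α needs ≥3
usable cells). q is used on its natural scale, not log-transformed. On
sparse data p is high when detection is low and the detected values are
homogeneous; α is strongly negative because q orders cells by exactly the
two quantities that degrade p.

## Embeddings and quality metrics

PCA centers genes and does not scale, for both normalized values and 0/1
indicators; components come from the SVD of the centered cells × genes
matrix (equivalently the eigendecomposition of the covariance), scores
are the centered data projected on them, and each component's sign is
fixed so that its largest-magnitude gene loading is positive. Requests
beyond the matrix rank are truncated with a warning. No highly-variable
gene selection is performed anywhere — it would add a tuning axis without
changing any qualitative comparison.

The Jaccard eigenmap computes S over detected gene sets (symmetric,
diagonal 1, entries in [0,1]; undefined for cells with no detections,
which must be removed), takes the top-k eigenvectors of the raw
similarity matrix and scales them by √λ with negative eigenvalues
truncated to zero. Using the raw similarity rather than a centered or
Laplacian form is a declared choice; the leading (Perron) eigenvector is
then a within-block-constant "size" direction and separation of disjoint
populations appears from the first component onward.

kNN graphs are exact Euclidean with ties broken by lower cell index and
self excluded. Silhouettes are standard Euclidean silhouettes
(singleton-cluster cells get 0), reported per label and overall. iLISI is
a simplified fixed-k inverse Simpson index: for each cell, the batch
proportions among its k neighbours give a score 1/Σpᵢ², averaged over
cells; the range is [1, #batches]. The original LISI weights neighbours
by a perplexity kernel; the fixed-k variant keeps the interpretation
while removing a bandwidth parameter. Distance correlation between two
embeddings is the Pearson correlation of their condensed pairwise
Euclidean distance vectors, invariant to isometries of either embedding.

## Marker-detection annotation

score(cell, type) = fraction of the type's markers detected in the cell;
the label is the unique argmax with positive score, otherwise
"unassigned". Ties and all-zero scores are never broken arbitrarily.
Markers absent from the matrix are dropped with a warning; a type losing
all markers is an error. Per-type F1 treats "unassigned" as a wrong
prediction for the cell's true type and never as a true positive; the
summary is the unweighted median over types present in the reference.
The procedure depends on the binary pattern only, so it is exactly
invariant under the shuffled-counts control.

## Pseudobulk differential expression

Aggregation is per sample: `mean` averages log CP10K values, and
`detection_rate` averages detection indicators (identically the mean of
the binarized matrix). The two test routes between two conditions are:

* **detection_t** — per-gene two-sided Welch t-test on the per-sample
  detection rates. Welch rather than pooled is the robust default where
  only "a t-test" is specified; when exactly one group is constant the
  pooled statistic is substituted with a warning; when both groups are
  constant the test is undefined and the gene receives p = 1 (no call) —
  with two samples per group, assigning p = 0 to such genes would
  manufacture false positives out of coincidentally equal rates.
* **moderated_trend** — per-gene effect on mean aggregates with
  empirical-Bayes shrinkage. With groups of n₁, n₂ samples,
  d = n₁ + n₂ − 2, pooled variance s², and abundance A = overall mean,
  the prior log-variance is a quadratic least-squares fit of log s² on A
  (genes with s² > 0), bias-corrected by ψ(d/2) − log(d/2) so s₀² sits on
  the variance scale; the prior df d₀ solves
  ψ′(d₀/2) = Var(residual log s²) − ψ′(d/2) (moment matching on the
  log-variance residuals; if the residual spread is below sampling noise
  d₀ is effectively infinite and shrinkage is complete). The posterior
  variance is s̃² = (d₀s₀² + d·s²)/(d₀ + d) and the moderated t uses
  d₀ + d degrees of freedom. Forcing d₀ = 0 recovers the ordinary pooled
  t-test exactly.

Mean aggregation is on the log scale because the trend model assumes
roughly homoskedastic inputs. Both routes are Benjamini–Hochberg
adjusted; calls use FDR 0.05 by default. Evaluation against simulation
truth reports the confusion counts, precision/recall/F1 and false
negatives binned on the gene's overall detection rate (default bin edges
0, 0.1, …, 1.0).

## Count-model selection and exact 2×2 inference

Per gene, four models are fit by maximum likelihood: Poisson (λ̂ = mean),
NB in mean/size form (variance μ + μ²/θ; μ̂ = mean, θ̂ from a bounded 1-D
profile search on log θ, capped at 10⁶ where the data are Poisson-like),
and ZIP/ZINB by EM over the latent structural-zero indicator.
Initialization: π₀ = max(0, (observed zero fraction − base-model zero
probability)/(1 − that probability)), base parameters from the
non-inflated fit; E-step assigns structural-zero responsibilities to zero
observations; M-step updates π and the (weighted) base model; convergence
at log-likelihood gain < 10⁻⁸ or 500 iterations. Zero-inflated fits are
constrained never to fall below their nested non-inflated counterparts
(the π = 0 solution is substituted if the EM ends lower), so the nesting
inequalities hold exactly. All likelihoods are computed on unique count
values weighted by multiplicity. Selection is by
BIC = −2·loglik + k·ln(n) with k = 1, 2, 2, 3; BIC rather than a Bayesian
expected-log-predictive comparison keeps the procedure deterministic and
dependency-free while preserving the candidate set; ties go to the
simpler model. A gene is "zero-inflated" when ZIP or ZINB is selected.

Gene ranking between two cell populations uses the two-proportion
z-statistic on detection rates with the pooled-proportion standard error;
"DE" mode takes the largest |z|, "stable" mode the smallest |z| among
genes detected in ≥10% of the cells of both groups (the floor keeps
never-expressed genes, which are trivially "stable", out of the
reference set). Ties break by gene index.

Fisher exact inference conditions on both margins of the 2×2 table. The
two-sided p sums central hypergeometric probabilities of all tables no
more probable than the observed one, with a (1 + 10⁻⁷) guard against
ties lost to floating-point rounding. The point estimate is the
conditional MLE: the odds ratio ψ at which the mean of the noncentral
hypergeometric distribution equals the observed count. The 95% CI inverts
the one-sided conditional tests at 0.025 per tail; boundary tables give
0 or ∞. Root-finding follows the convention of standard exact-test
software — solved on the odds-ratio scale (reciprocal scale for roots
above 1) with tolerance eps^¼ — so reported logOR/CI values are directly
comparable with published ones; the probability sums themselves are exact
to double precision (verified against rational-arithmetic enumeration).

## Expression recovery

recovered(g, c) = detection rate of gene g among cell c's k nearest
neighbours (optionally including c itself; default excluded, k = 15),
with neighbours found in a Jaccard eigenmap of the binary matrix by
default so the whole path is count-free. Recovery is evaluated by Pearson
correlation against log-normalized expression, per gene (across cells)
or per cell (across genes), summarized by the median over defined
correlations. Recovered values track relative expression only within the
neighbourhood structure; genes with no between-population differences
carry no recoverable signal, which bounds the median per-gene correlation
well below 1 on data where most genes are background.

## Synthetic data

`simulate_multisample` draws gene baseline means from
LogNormal(−1, 1.5) (median ≈ 0.37 counts/cell — a realistically
zero-rich regime; ≈ 6–9% of genes exceed 0.9 detection at 100+ cells),
dispersions θ ~ Uniform(0.5, 3), per-sample gene factors
LogNormal(0, 0.2) for inter-individual variability, and a Bernoulli(p_de)
subset of genes with condition-2 means multiplied by 2^±lfc (random
sign). Counts are gamma–Poisson (NB with mean μ·f and size θ) per cell.
Defaults: 1,000 genes, 5 samples per group, 100 cells per sample,
p_de = 0.1, lfc = 1. The benchmark grid crosses samples/group
{2, 3, 5, 8} × cells/sample {25, 50, 100, 200} × p_de {0.05, 0.1} ×
lfc {0.5, 1, 2} — 96 settings; ten seeds per setting give 960 datasets.
The corner benchmark (smallest vs largest designs) is run at lfc = 2, the
grid's strongest effect, because at lfc = 1 the 2 × 30 design has
essentially zero power for both routes and route comparisons there are
comparisons of noise.

`simulate_celltypes` builds marker genes whose NB means are solved from
target detection rates (0.9 in the own type, 0.05 elsewhere;
μ = θ((1−d)^{−1/θ} − 1)), housekeeping genes with one NB shared by all
types (per-gene detection drawn in [0.5, 0.9]) and uniformly low
background genes (detection in [0.05, 0.4]); θ ~ Uniform(1, 3).
Defaults: 3 types × 200 cells, 10 markers/type, 50 housekeeping,
140 background.

What the generators do not emulate: batch effects, doublets, ambient
RNA, UMI saturation, library-size gradients within samples, and the
correlated gene–gene structure of real tissue. Passing tests therefore
show that the implementations behave as specified under the stated
hierarchical NB conditions — not that binarization is safe for any given
real dataset; in particular the detection route's blindness to genes at
detection ≈ 1 is a structural limitation that no sample size repairs.

## Numerical conventions and degenerate inputs

Duplicate MTX coordinates are an error (silent summation hides corrupt
input). All-zero genes are unfittable and rejected by the model-selection
step; all-zero cells are rejected by normalization and by the Jaccard
map. Eigen/SVD sign ambiguity is fixed by the largest-magnitude-loading
rule; kNN ties break by index; ranking ties break by gene index — all
outputs are deterministic given a seed. BH adjustment enforces
monotonicity and caps at 1. Welch degrees of freedom follow the
Satterthwaite formula; moderated degrees of freedom are d₀ + d.

## Problem sizes

Tests and the acceptance script use 10²–10³ genes and 10²–10³ cells per
dataset, 20 replicates per benchmark corner and 2,000 null gene-tests for
calibration; these sizes give stable summaries (binomial/SE arguments in
the tests) while keeping any single analysis in the seconds-to-a-minute
range.
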