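# Methods

## Model and rationale

A gene's co-expression context in one condition is summarized by its
*correlation profile*: the vector of Spearman rank correlations between that
gene and every other gene, computed across the samples of the condition.
Differential co-expression of gene *i* between conditions A and B is any
change between the two profiles **a**ᵢ and **b**ᵢ. Spearman correlation is
used throughout because expression data are only rank-stable across
platforms and normalizations; any strictly monotone per-gene transformation
of the data leaves every result unchanged.

Profiles exclude the self-correlation, so with G genes the profile length is
n = G − 1. The self-entry is 1 in both conditions and would contribute
nothing to any difference while distorting the 1/n scaling of the Euclidean
metric.

## The metrics

Six scores condense a profile change into a nonnegative number (labels
append the threshold where one is needed, e.g. M1.3 = M1 at 0.3):

- **M1** counts correlations exceeding a threshold th₁ in each condition and
  reports the absolute difference of the counts. By default correlations
  are compared in absolute value, treating strong negative co-expression as
  co-expression; a flag restores the signed reading, since which of the two
  the original count-based methods intended is ambiguous. "Exceeds" is
  strict, which is immaterial for continuous data.
- **M2** is the two-sample Kolmogorov–Smirnov statistic between the two
  profiles treated as empirical distributions.
- **M3** counts per-partner absolute differences above th₃, treating small
  correlation differences as noise.
- **M4** is the Euclidean distance between profiles scaled by 1/n, bounded
  by 2/√n, so values are comparable across gene-set sizes.
- **M5** is the symmetrized Kullback–Leibler divergence (sum of both
  directions, as in the Jensen–Shannon construction) between histogram
  estimates of the two profile distributions, natural logarithm. See
  "M5 estimation choices" below.
- **M6** is the per-gene sum of soft-thresholded adjacency differences
  (√(½|sign(a)a² − sign(b)b²|))^β with β = 2.5 by default; β up-weights
  large differences. This is the gene-level score of the adjacency-difference
  approach used by differential-network clustering methods; the clustering
  step itself is out of scope here.

All six are symmetric under swapping A and B, and all are computed for every
gene from two aligned correlation matrices in one pass
(`compute_all_metrics`). User metrics are callables `(a, b, spec) -> float`
validated to return finite nonnegative values.

### M5 estimation choices

As a symmetrized KL between histograms, M5 needs a binning rule and a policy
for empty bins.

- *Bins.* The per-profile histogram uses equal-width bins on [−1, 1]. A
  fixed 100-bin grid is appropriate for profiles of several thousand genes
  (≳ 20 values per bin) but becomes sparse on short profiles, where empty
  tail bins dominate the estimate. `MetricSpec(bins=None)` therefore selects
  an occupancy-matched count: ~24 values per bin, capped at 100 and floored
  at 10. The benchmark default (`default_metric_specs`) uses this adaptive
  rule.
- *Empty bins.* The strict rule skips any bin in which either histogram is
  empty. That rule has a degenerate consequence: the divergence of two
  completely disjoint histograms is 0, and more generally a gene whose
  correlation changes are confined to sparsely populated tail bins — exactly
  the signature of a small injected network — scores at the background
  level, and larger changes can *lower* the score by emptying more bins.
  The benchmark default therefore adds a pseudocount of 1/(2n) to every bin
  before normalizing, which preserves the zero at identical profiles (both
  histograms shift identically) while keeping localized tail changes
  visible. `metric_m5` itself defaults to the strict skip rule so the
  documented degenerate behavior is reproducible; the two options are
  explicit in `MetricSpec`.

## Significance

The null hypothesis per gene is "no profile change". Permuting condition
labels among the pooled samples of the two conditions (group sizes
preserved) and recomputing correlation matrices and metrics from scratch
yields null metric values; no shortcut or approximation is used in the
permuted recomputation.

- *Pooled vs per-gene null.* By default the permuted values of all genes
  are pooled into one null distribution, giving p-value resolution
  ~1/(G × permutations) from as few as 10 permutations. This assumes the
  null metric distribution is exchangeable across genes; when genes are
  heterogeneous the pooled p-values are conservative for quiet genes and
  floored for loud ones. The strictly per-gene mode is available
  (`pooling="per_gene"`) but needs many more permutations for useful
  resolution (minimum p is 1/(permutations + 1)).
- *Estimator.* p = (1 + #{null ≥ observed}) / (1 + N). The add-one
  smoothing keeps p in (0, 1], which Benjamini–Hochberg requires; the raw
  proportion-larger estimator is available unsmoothed.
- *Multiple conditions.* All unordered condition pairs are analyzed; per
  gene, the pairwise p-values are combined with Fisher's method
  (X² = −2Σ ln p on χ² with 2K df — the identity map when K = 1), then BH
  adjusted across genes. Pairwise permutation seeds derive deterministically
  from the master seed and the comparison index, so one seed reproduces an
  entire run.

## Controlled datasets

The simulator builds benchmarks in which the differentially co-expressed
genes are known and no gene is differentially expressed:

1. sample the background genes from a normal dataset and standardize each
   gene to mean 0, sd 1 (n−1 convention);
2. find the noise level *s* whose addition to the normal data makes its
   pair-correlation distribution best match a target (tumor) distribution —
   a grid search scored by the two-sample KS distance on sampled gene pairs
   (default grid 0.0–3.0, step 0.1; ties break to the smaller *s*);
3. *noised positives* receive cumulative stage noise:
   T1 = N + 𝒩(0, s/3), T2 = T1 + 𝒩(0, s/3), T3 = T2 + 𝒩(0, s/3);
4. *negatives* receive the same construction at sd s/10, preserving
   sample-level variability while leaving their correlations nearly intact;
5. *network blocks* are appended as new genes: each block of 10 genes is
   drawn per stage from a multivariate normal with equicorrelation *v*
   (loss blocks: v ∈ {0.9, 0.75, 0.6, 0.45, 0.3} stepping −0.05/−0.10/−0.15
   across stages; gain blocks: v ∈ {0.15, 0.3, 0.45, 0.6, 0.75} stepping
   +0.05/+0.10/+0.15), sampled independently per stage via Cholesky
   factorization and standardized per gene.

At the default scale (counts 3000/300/20/10) this yields 3200 genes with
500 positives. Scaled-down builds in the same proportions are first-class.
Noised stages are *not* re-standardized: the stated variance relations
(Var(T3 − N) = 3(s/divisor)²) then hold exactly, and the
differential-expression-free property is a genuine statistical check
(per-gene means stay at 0 in expectation) rather than an artifact of
rescaling. Note the cumulative recipe gives T3 a total added noise sd of
s/√3 < s, so T3 approaches but does not exactly reach the matched tumor
noise level; the recipe is implemented literally.

Stages are treated as independent sample groups (fresh stage-specific sample
ids, one condition label per stage); the number of samples per stage equals
the base sample count, since nothing in the construction constrains it
otherwise.

### Synthetic base data

`generate_synthetic_base` replaces real normal-tissue data so the entire
pipeline runs offline. Independent standardized Gaussian genes alone are a
poor stand-in: adding noise to uncorrelated genes does not change their
(null) correlation distribution, so noised positives would be undetectable
and noise-level matching impossible. Two structure options fix this:

- *equicorrelated blocks* `(size, correlation)` for explicit co-expression
  modules;
- *latent factors* (`n_factors`, default loading sd 0.5): every gene loads
  on shared expression programs, giving all genes broad, heavy-tailed
  correlation profiles. With 10 factors the pairwise Spearman sd is ≈ 0.25,
  comparable to tissue expression data.

What the generator does **not** emulate: count-based noise (negative
binomial mean–variance coupling), batch effects, outlier samples, skewed
correlation distributions, and biologically modular (scale-free) network
topology. Passing benchmarks on this generator therefore demonstrates
correctness of the machinery and relative metric behavior under controlled
alterations, not performance guarantees on any particular real dataset.

## Evaluation accounting

Metric performance on a controlled dataset is the number of truth positives
in the top N genes ranked by descending metric value (N defaults to the
number of positives; ties break by stable input gene order, a measure-zero
concern for continuous metrics). The six stage comparisons are summarized
as sensitivity at 33% (mean of N-T1, T1-T2, T2-T3 over positives), 66%
(N-T2, T1-T3), 100% (N-T3), global (all six) and relative (global over the
best global). Sensitivities are rounded half-up to two decimals, and the
relative sensitivity is a ratio of the *rounded* globals — printed summary
tables are then exactly reproducible from their printed counts.

The differential-expression-free validation uses a per-gene Welch t-test
(the safer default when stage variances differ slightly by construction)
with BH correction; a correct build yields zero genes at FDR < 0.1.

## Benchmark study conditions

Fixed-seed test and acceptance runs use: a full-scale build from a
3000-gene × 60-sample factor base (10 factors), and a scaled benchmark of
600 background genes, 60 noised positives and 8 blocks (680 genes, 140
positives), both at s = 1.5 — a matched-noise level at which the T3
correlation distribution is visibly flattened (attenuation ≈ 0.76 for
positives) while negatives lose almost nothing (≈ 0.97). The permutation
calibration check uses 600 iid genes in two groups of 30 with 20 pooled
permutations; the noise-recovery check plants s = 0.8 on a 400-gene factor
base with a 0.1-step grid. These sizes keep a full run in seconds while
leaving every qualitative conclusion of the full-scale setting intact
(dominance of M4/M5/M6 and low-threshold counts, growth of detection with
accumulated alteration, flatness of M6 across stages).

## Numerical choices and degenerate inputs

- Sample standard deviation (n−1) everywhere, matching the t-test
  convention; zero-variance genes are rejected at standardization with the
  offending genes named.
- A gene constant within a condition would have undefined correlations; its
  row/column are set to 0 with a warning so matrices stay total.
- Correlation matrices are symmetrized ((C + Cᵀ)/2), clipped to [−1, 1],
  and given an exact unit diagonal to absorb floating-point asymmetry.
- Missing values are rejected by default; a pairwise-complete mode is the
  declared extension point but correlations currently require complete data.
- Condition pairs are processed in first-appearance order of the annotation
  file for determinism.

## Known limitations

- The pooled permutation null trades per-gene exactness for resolution; on
  strongly heterogeneous gene sets the per-gene mode (with many more
  permutations) is the safer but slower choice.
- Permutation recomputation of full Spearman matrices is quadratic in genes
  per permutation; at 10⁴ genes and many permutations this is hours, not
  seconds.
- M5's histogram estimate remains the least stable of the six metrics on
  short profiles even with adaptive binning.
- The simulator models correlation *loss* for noised positives only;
  correlation gain exists only through network blocks.
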