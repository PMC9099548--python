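# Methods

`nodalsig` re-implements, as a tested library and CLI, a complete bulk
RNA-seq workflow for discovering a lymph-node-metastasis (N+ vs N−)
gene-expression signature in endometrioid endometrial carcinoma (EEC).
The cohort that motivates the design — 28 analyzable FFPE tumors, 16 N+
and 12 N−, 1:1 matched on tumor size, grade and myometrial invasion — is
not publicly available, so the package ships a synthetic-data generator
with the statistical structure the analysis assumes, and every stage is
validated on that synthetic world plus closed-form oracles.

## Pipeline model

1. **Merged-read splitting** (`fastq`). Adapter-removal tools merge
   overlapping R1/R2 mates into single-end reads. To keep those fragments
   usable by a paired-end aligner, each merged read of length L is split at
   ⌈L/2⌉: R1 keeps the first half unchanged; R2 is the reverse complement
   of the rest with reversed qualities, restoring FR orientation. The
   midpoint is a package choice (the split point is otherwise unspecified);
   it maximizes the shorter mate and makes the partition identity
   `merge(R1, revcomp(R2)) == merged` exact.

2. **Sample QC** (`qc`). A sample enters analysis iff its aligned total
   exceeds 5,000,000 fragments AND it has fewer than 3,500 zero-count
   genes — both strict inequalities. "Aligned total" is operationalized as
   the count-matrix column sum, with an optional explicit override column.

3. **Differential expression** (`dge`). logCPM is
   `log2((c + 0.5) / (R + 1) * 1e6)`. The mean-variance trend is fitted by
   lowess (span 0.5) of sqrt residual SD against average log2 count under a
   group-means model; each observation's weight is the trend value at its
   fitted log-count to the power −4, clamped to the fitted range and
   floored at 1e-4 so constant genes keep finite weight. Per gene, weighted
   least squares estimates the two-group log2 fold change; the
   empirical-Bayes prior (d0, s0²) is estimated by moment matching on
   log s² (digamma/trigamma; Newton inversion of the trigamma), falling
   back to d0 = ∞ when variances carry no excess spread; the moderated
   variance is (d0·s0² + dg·s²)/(d0 + dg) and t has d0 + dg df (normal
   tail at d0 = ∞). BH is the step-up cumulative-minimum formula. A gene
   is called DE iff adjusted p < 0.05 and |log2FC| ≥ 1 (fold change 2).
   No normalization factors beyond library size are used (none are part of
   the method), so grossly compositionally imbalanced designs will show a
   shift in estimated fold changes; at a realistic module-to-transcriptome
   ratio (~2% of library mass) the recovery is unbiased to within ±0.3.

4. **Unsupervised clustering** (`clustering`). Samples are clustered by
   average linkage on 1 − Pearson correlation. Expression is **gene-mean
   centered** before correlations: raw logCPM columns all correlate near
   +1 through the shared abundance profile, and the anti-correlation
   criterion below is only meaningful on deviation profiles. The SD cutoff
   is chosen by sweeping 40 evenly spaced SD quantiles; at each cutoff the
   retained genes are clustered, the two top-level groups are extracted,
   and A(σ) = mean cross-group pairwise sample correlation is recorded;
   the chosen cutoff minimizes A(σ) subject to A(σ) < 0 and ≥ 3,000 genes
   retained. A(σ) is the mean over all cross-group sample pairs (the least
   parametric estimator; the sweep is recorded so centroid-correlation
   alternatives can be compared). If no cutoff achieves negative
   anti-correlation, the stage reports "no structure" instead of returning
   a chance grouping. Consensus clustering subsamples 60% of samples
   (without replacement) for 10,000 iterations by default, clusters each
   subsample, and sets consensus(i,j) = co-cluster count / co-sample
   count; the final assignment clusters 1 − consensus (average linkage,
   cut at k). k defaults to 3; a CDF delta-area summary over a k range is
   available. Because a column pair's Pearson correlation does not depend
   on the other columns in the subsample, the full distance matrix is
   computed once and subset per iteration — exact, not an approximation.

5. **Cluster naming and refinement** (`pipeline`). Clusters are renamed
   A, B, C… by descending N+ fraction (the N+-enriched cluster is "A", the
   most N−-enriched the last letter) — programmatic where the original
   analysis assigned them by inspection. The refinement step removes from
   the N−-enriched cluster the samples whose node label disagrees with the
   cluster majority (C → C′) before the signature contrast.

6. **Signature discovery** (`classifier`). Nearest shrunken centroids:
   d_ik = (x̄_ik − x̄_i)/(m_k (s_i + s0)) with m_k = sqrt(1/n_k − 1/n) and
   s0 the median pooled SD; soft-threshold |d_ik| by Δ; discriminant
   δ_k(x) = Σ (x_i − x̄′_ik)²/(s_i + s0)² − 2 log π_k with frequency
   priors (uniform optional). Δ is chosen by stratified cross-validation
   (10-fold, falling back to leave-one-out when the smallest class has
   fewer members than folds — the operative branch at 7 vs 8 samples),
   minimizing CV error with ties broken toward larger Δ (smaller
   signature). Accuracy/sensitivity/specificity are cross-validated with
   N+ as the positive class.

7. **Centroid validation** (`classifier.centroid_validator`). Group
   centroids are mean expression of each signature gene over the training
   samples of that group; a validation sample is assigned to the group with
   the smallest mean squared error, ties to the first label in sorted
   order (flagged). Significance per sample: permute the sample's
   expression values across the signature genes, recompute the best MSE,
   and report the add-one estimate (r+1)/(B+1) with B = 1,000 by default
   (exhaustive enumeration available for small signatures). What exactly is
   randomized was an open choice; within-sample permutation across
   signature genes preserves the sample's value distribution and tests
   gene-assignment specificity. The pipeline applies the validator
   leave-one-out over the signature cohort.

8. **Over-representation** (`enrichment`). Hypergeometric upper tail
   P(X ≥ k) per GMT set over the post-QC gene universe, BH across sets.
   Ranked GSEA is out of scope.

9. **Clinical statistics** (`clinical`). Categorical covariates: exact
   two-sided Fisher, generalized to r×c by full Freeman–Halton enumeration
   with log-factorial probabilities; "two-sided" = total probability of
   tables (same margins) with probability ≤ observed × (1 + 1e-7), the
   de-facto reference convention. All-zero rows/columns are dropped
   (provably p-invariant); totals over 200 are rejected — the enumeration
   is for small matched-series tables. Continuous covariates: Welch t from
   per-group mean/SD/n with Satterthwaite df. Display rounding is tiered
   (3 dp below 0.05, 2 dp below 0.2, 1 dp otherwise, "<0.001" floor),
   which reproduces the published table roundings.

## Synthetic cohort generator

`SimConfig` defaults *are* the emulated cohort: 18,000 genes; three
latent clusters of 7/10/11 samples with N+ compositions 7/0, 6/4, 3/8
(16 N+ / 12 N−); one DE module per cluster (400/400/300 genes,
log2FC = 2 — the analysis' own fold-change floor); library sizes
log-uniform on [5e6, 2e7], straddling the QC threshold so both inclusion
branches occur.

Counts are negative binomial with mean q_g·R_s·2^fc and variance
μ + φμ²; relative abundances q_g are log-normal (meanlog 3.0, sdlog 1.6,
normalized), dispersions φ_g log-normal (median 0.15, sdlog 0.5) — FFPE
material is noisier than frozen tissue, hence the high median. DE-module
genes draw abundance above the median (config
`de_min_abundance_quantile = 0.5`): an "informative" gene must be
expressed to carry its nominal effect. Dropout is independent Bernoulli
per entry with probability `zero_inflation` (default 0.05) decaying
logistically in log2 mean expression (midpoint 32 counts, shape 1):
degradation zeros concentrate in low-abundance genes. A uniform dropout
rate was rejected during development because it silences well-expressed
genes at a rate real libraries never show and makes the small-n
classifier fail on data where the real-data analysis demonstrably
succeeded. Clinical covariates are drawn per node-status arm at the
published cohort table frequencies (`datasets.py`); tumor size is normal
with the published per-arm mean/SD. One seed governs everything through
deterministically spawned per-stage substreams.

What the generator does **not** model: unexpressed genes (every gene has
positive expected expression, so per-sample zero-gene counts are lower
than in real FFPE exome captures — the QC zero-gene branch is exercised
with constructed fixtures); isoforms, sequencing error, alignment
artifacts, batch effects, gene-gene correlation beyond the block modules,
and survival outcomes. A green structure-recovery test therefore shows
the method chain works under the assumed generative model, not that it
would succeed on an arbitrary real cohort.

## Numerical choices and degenerate inputs

- voom trend floored at 1e-4 (sqrt-SD) → finite weights for constant genes.
- Trigamma inversion by Newton from y0 = 0.5 + 1/x, 50-iteration cap,
  asymptotic starts for extreme arguments.
- BH uses a stable mergesort so tied p-values keep input order.
- Fisher enumeration uses a relative tolerance 1 + 1e-7 when comparing
  table probabilities, absorbing round-off at the two-sided boundary.
- Consensus entries with zero co-sampling are reported as 0 (no evidence).
- NSC ties in the discriminant and validator MSE resolve to the first
  class in sorted order; validator ties are flagged per sample.
- Welch t with both SDs zero: t = 0, p = 1 when means agree, else p = 0.

## Known limitations

- Pairwise two-group fits only; no joint design matrix or covariate
  adjustment in the DE model.
- The r×c Fisher enumeration is exponential in table size; it is guarded
  at n ≤ 200 and intended for small clinical tables.
- The signature stage assumes the refined contrast keeps ≥ 2 samples per
  node class; degenerate refinements surface as stage errors rather than
  silent fallbacks.
- Default consensus iterations (10,000) follow the method description;
  tests and the bundled pipeline configs use 200–2,000, which is
  empirically indistinguishable at n = 28.
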