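# Methods

## Conditional-MVN imputation

For each gene, its Z-score vector across the m phenotypes is modeled as
multivariate normal with mean zero and covariance Σ, the inter-phenotype
correlation matrix, as holds asymptotically under the null of no
gene–phenotype association. Missing entries are replaced by their
conditional expectation given the measured entries; the conditional
covariance is the Schur complement of the observed block. The diagonal of
I − Σ₁|₂ ("imputation information") equals, under the model, both the
variance of the imputed estimate and its covariance with the truth, which
yields two testable laws used throughout the test suite:

- **Information law.** Over cells with information value I, the correlation
  between imputed and true scores is √I. Because information is discrete —
  one value per (missingness pattern, position) pair — a 0.05-wide
  information bin is checked against √(mean information of its cells);
  the bin midpoint is an adequate proxy only up to half the bin's
  sqrt-width, and the tests account for exactly that displacement, no more.
- **Residual calibration.** The variance of (truth − imputed) at a fixed
  missingness pattern equals diag(Σ₁|₂).

Strong signals (true associations) make individual genes non-null, but the
conditional-expectation weights depend only on Σ, so imputation remains a
linear projection; the MVN(0, Σ) model is the calibration reference for the
information score.

### Numerical choices

- The observed-block system (Σ₂₂ + λI) is solved via Cholesky
  factorization; explicit inversion is never performed. A singular system
  (possible only at λ = 0 with rank-deficient Σ₂₂) raises a named error
  advising a larger ridge rather than silently pseudo-inverting.
- The ridge λ = 0.01 is applied unconditionally by default: it is small
  enough to perturb imputed scores by ≲ 1% (the bivariate closed form is
  ρZ/(1 + λ)) while making the solve unconditionally well-posed. λ = 0 is
  available and used by the closed-form and calibration tests.
- Genes are grouped by missingness pattern and each pattern's factorization
  is computed once; with m ≤ a few hundred phenotypes and thousands of
  genes, patterns repeat heavily and this dominates runtime. Results are
  identical (to 1e-10) to gene-by-gene solves.
- Information is clipped to [0, 1]; an excursion beyond 1e-6 (symptomatic
  of a numerically non-PSD Σ) triggers a warning.
- Measured cells carry sentinel information 1.0 so a single threshold
  filters the whole matrix; gene columns with no measured phenotype are
  reported as non-imputable and left missing; cells under the reliability
  threshold (default 0.8) are flagged, never removed.

## Correlation estimation from control phenotypes

Σ is approximated by the phenotypic correlation of control animals
(Cheverud's conjecture). Technical contamination is handled in three steps:

1. **PVCA.** Phenotypes are standardized, principal components retained to
   90% cumulative variance, and for each retained component all candidate
   factors are fit jointly as random effects (crossed variance components
   via REML; the Powell optimizer is used because gradient-based optimizers
   in this setting stall at spurious non-zero variance components without
   reporting convergence — a fit that does not converge falls back to a
   one-way ANOVA method-of-moments estimate). Per-component variance shares
   are averaged with eigenvalue weights. Pairwise interactions are off by
   default (flag to enable). PVCA uses subjects complete on the phenotype
   set, falling back to per-phenotype mean imputation when fewer than half
   are complete.
2. **Confounder selection.** Factors with a variance share ≥ 0.1 (default,
   configurable) are removed — a conservative cutoff that flags only
   dominant technical factors.
3. **ComBat.** Parametric empirical-Bayes location/scale adjustment, with
   phenotypes as the "features" shrunk toward a common prior and subjects
   as samples. Preserved covariates stay in the design. Implementation
   detail follows the standard parametric algorithm and agrees with the
   Bioconductor reference implementation to ~1e-5 on complete data (tested
   via Rscript when available). Batches need ≥ 2 subjects; phenotypes
   constant within every batch pass through with a warning; a single batch
   is a no-op. Adjustment equalizes batches at the pooled scale, so
   between-batch variance ratios — not absolute variances — are the
   meaningful check, and each carries sampling noise ~√(4/n).
4. **Pearson + PSD repair.** Pairwise-complete correlations; pairs sharing
   fewer than 30 subjects are zeroed with a warning. Pairwise completion
   can produce an indefinite matrix; it is repaired by eigenvalue clipping
   at zero followed by diagonal rescaling — deterministic and adequate for
   the m ≤ ~300 matrices this package targets, in place of the full
   alternating-projections nearest-correlation algorithm.

## SVD matrix-completion baseline

Classic hard-impute: fill missing cells (zero or column-mean start),
truncate to rank r by SVD, restore observed cells, iterate until the
missing block's relative Frobenius change falls below 1e-5 or 100
iterations. The method yields no per-cell certainty, so its info matrix is
NaN at imputed cells. The truncation rank is either user-fixed or chosen by
holding out 10% of observed cells (drawn coverage-preservingly, so no row
or column is emptied) and minimizing holdout RMSE over candidate ranks.

## Benchmark design and synthetic data

The benchmark simulates replicate Z-score matrices gene-wise from
MVN(0, Σ), masks an exact fraction of cells uniformly at random, imputes
with each method, and scores the Pearson correlation between held-out truth
and imputations. Defaults mirror the full study design (10 000 genes × 8
phenotypes, 100 replicates, 20/40/60% masking, information threshold 0.8);
tests and the acceptance script run a desk-scale version (2000 genes, 20
replicates) whose Monte-Carlo error is small relative to every gap they
assert, plus a 10-replicate run at the full 10 000 genes for the
rep-to-rep-stability check.

- **Fixture correlation.** The benchmark's default fixture is AR(1) with
  ρ = 0.9. The choice is constrained by the information threshold: with an
  AR(1) correlation the largest attainable information is 2ρ²/(1 + ρ²)
  (interior phenotype, all others observed), which is 0.78 at ρ = 0.8 —
  below the 0.8 filter, leaving the filtered method with nothing — and 0.90
  at ρ = 0.9, giving a non-degenerate spread of information values on both
  sides of the threshold. The information-law test itself uses ρ = 0.8,
  where no cell needs to clear the threshold. Any user-supplied correlation
  matrix file can replace the fixture to emulate a specific phenotype
  domain.
- **Fixed comparator per report cell.** With per-replicate holdout rank
  selection the SVD baseline's chosen rank can flip between replicates,
  inflating rep-to-rep SD with selection noise; the benchmark therefore
  resolves an "auto" rank once per mask fraction (on the first replicate)
  and holds it fixed, so the reported SD measures sampling variability of
  one fixed algorithm.
- **Cells without a conditioning set.** Random masking occasionally empties
  a whole gene column; such cells are excluded from scoring for every
  method symmetrically (neither method can constrain them) and their count
  is reported.
- **Seeding.** One master seed; per-replicate, per-fraction streams are
  derived via SeedSequence spawn keys, independent and reproducible.

### What the generator does and does not emulate

Synthetic Z-scores are exactly null MVN draws with a known Σ: they contain
no true associations (heavy-tailed signal cells), no misspecification of Σ
(the benchmark hands the generating matrix to the imputer), and no
structured missingness (real availability is strongly blockwise by
phenotyping pipeline, not uniform). Passing benchmarks therefore
demonstrate correctness and calibration of the method under its own model,
and the ordering of methods under equal conditions — not field performance
on any particular consortium release. The sensitivity of the method to a
wrong Σ is documented by a test feeding the identity matrix, which destroys
recovery entirely (imputations collapse to zero).

## Known limitations

- Phenotypic correlation is a proxy for genetic correlation; where the two
  diverge, the information score is miscalibrated even though imputation
  remains well-defined.
- PVCA variance shares for factors with very few levels (e.g. two) are
  noisy; the 0.1 selection cutoff absorbs this only partly.
- The nonparametric ComBat variant is out of scope; heavy-tailed phenotype
  distributions may violate the parametric prior.
- The SVD baseline fixes one family of completion algorithms (hard-impute
  with truncated SVD); nuclear-norm variants may differ.
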