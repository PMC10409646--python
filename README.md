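# kompute

Direct imputation of missing gene–phenotype association Z-scores.

High-throughput knockout phenotyping programs (the International Mouse
Phenotyping Consortium being the canonical example) test each knockout line
against a battery of phenotypes, but most gene–phenotype pairs are never
measured: lethal knockouts, staggered pipelines, and resource limits leave
the genes × phenotypes matrix of association summary statistics largely
empty. This package fills those gaps *directly at the summary-statistic
level* — no per-animal phenotype data is needed for the genes being imputed
— which is useful to anyone mining such matrices for candidate
associations, enrichment, or cross-phenotype structure.

## The model

Write a gene's Z-scores across *m* phenotypes as Z = (Z₁, Z₂), with Z₁ the
*k* unmeasured and Z₂ the *l = m − k* measured entries. Under the null of no
association, Z ~ MVN(0, Σ), where Σ is the inter-phenotype genetic
correlation matrix (unit diagonal). Partitioning Σ conformably, the missing
scores are imputed by the conditional expectation

    Ẑ₁ = Σ₁₂ (Σ₂₂ + λI)⁻¹ Z₂

with conditional covariance (Schur complement)

    Σ₁|₂ = Σ₁₁ − Σ₁₂ (Σ₂₂ + λI)⁻¹ Σ₂₁ .

The small ridge λ (default 0.01) guarantees invertibility. The diagonal of
I − Σ₁|₂ is the per-cell **imputation information** in [0, 1]: the fraction
of a missing score's variance explained by the measured ones. Filtering
imputed cells at information > 0.8 keeps only high-confidence estimates.

Σ is not observed; by Cheverud's conjecture it is approximated by the
phenotypic correlation of control animals. The estimation pipeline
quantifies nonbiological variance with principal variance component
analysis (PVCA), removes dominant technical factors with empirical-Bayes
ComBat, and takes pairwise-complete Pearson correlations, repaired to a
valid (PSD, unit-diagonal) correlation matrix.

An iterative truncated-SVD matrix-completion baseline and a mask-and-recover
simulation benchmark (simulate MVN(0, Σ) Z-scores, mask 20/40/60% of cells,
impute, score by Pearson correlation against the held-out truth) round out
the package.

## Worked example

```python
import numpy as np
from kompute import RidgeConfig, ZScoreMatrix, impute_matrix, make_sigma_fixture

sigma = make_sigma_fixture(4, "ar1", 0.8)   # neighboring phenotypes correlate 0.8
values = np.array(
    [
        [1.8, np.nan, 0.3],
        [2.1, -0.9, np.nan],
        [np.nan, -1.2, 0.1],
        [1.2, np.nan, -0.4],
    ]
)
z = ZScoreMatrix(values, sigma.phenotype_ids, ["geneA", "geneB", "geneC"])
result = impute_matrix(z, sigma, RidgeConfig(0.01), info_min=0.8)
print(np.round(result.z_full, 3))
print(np.round(result.info, 3))
```

prints

```
[[ 1.8   -0.721  0.3  ]
 [ 2.1   -0.9    0.189]
 [ 1.601 -1.2    0.1  ]
 [ 1.2   -0.95  -0.4  ]]
[[1.    0.634 1.   ]
 [1.    1.    0.776]
 [0.776 1.    1.   ]
 [1.    0.634 1.   ]]
```

Measured cells pass through verbatim (information 1.0). geneB's missing
scores on the outer phenotypes are pulled toward its strong negative
measured scores, with information 0.634 — below the 0.8 threshold, so
`result.below_threshold` flags them (they are flagged, never deleted). The
`examples/` directory has one short script per capability: imputation,
correlation estimation, SVD completion, and the benchmark.

A thin CLI mirrors the library (`kompute impute`, `kompute estimate-cor`,
`kompute svd-complete`, `kompute simulate`, `kompute benchmark`) for
file-based workflows; matrices are plain CSV/TSV with phenotype rows, gene
columns and `NA`/empty missing cells.

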