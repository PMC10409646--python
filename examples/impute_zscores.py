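"""Impute missing association Z-scores for a handful of genes.

Builds a tiny phenotypes-by-genes Z-score matrix with missing cells, an
AR(1) phenotype correlation matrix, and fills the gaps with conditional
multivariate-normal expectations.
"""

import numpy as np

from kompute import RidgeConfig, ZScoreMatrix, impute_matrix, make_sigma_fixture

sigma = make_sigma_fixture(4, "ar1", 0.8)  # neighboring phenotypes correlate 0.8

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

print("imputed Z-score matrix (measured values kept verbatim):")
print(np.round(result.z_full, 3))
print("\nimputation information (1.0 = measured cell):")
print(np.round(result.info, 3))
print("\ncells flagged below info 0.8:", result.below_threshold)

# The imputed entries are weighted combinations of the gene's measured
# Z-scores, weights set by the phenotype correlations; the info value in
# [0, 1] says how much of each missing score's variance the measured
# phenotypes explain — cells flagged above are too uncertain to trust at
# the 0.8 reliability threshold.
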