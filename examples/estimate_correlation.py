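"""Estimate a phenotype correlation matrix from noisy control data.

Synthesizes control-animal phenotype measurements whose true correlation is
AR(1) with rho = 0.7, contaminated by additive phenotyping-center offsets,
then runs the estimation pipeline: PVCA to find the confounding factor,
ComBat to remove it, Pearson correlation on the adjusted values.
"""

import numpy as np
import pandas as pd

from kompute import (
    PhenotypeTable,
    combat_adjust,
    estimate_correlation,
    make_sigma_fixture,
    pvca,
    select_confounders,
)

rng = np.random.default_rng(0)
m, n = 5, 1000
truth = make_sigma_fixture(m, "ar1", 0.7).values
base = rng.multivariate_normal(np.zeros(m), truth, size=n)
center = rng.choice(["lab1", "lab2", "lab3"], n)
offsets = {"lab1": 0.0, "lab2": 1.5, "lab3": -1.0}
values = base + np.array([offsets[c] for c in center])[:, None]

rows = [
    {
        "subject_id": f"s{i:04d}",
        "phenotype_id": f"p{j}",
        "value": values[i, j],
        "center": center[i],
    }
    for i in range(n)
    for j in range(m)
]
table = PhenotypeTable(pd.DataFrame(rows))

report = pvca(table, ["center"])
print("PVCA variance shares:", {k: round(float(v), 3) for k, v in report.proportions.items()})

confounders = select_confounders(report, 0.1)
print("factors selected for removal:", confounders)

adjusted = table
for factor in confounders:
    adjusted = combat_adjust(adjusted, factor)

sigma = estimate_correlation(adjusted)
print("\nestimated correlation matrix:")
print(np.round(sigma.values, 3))
print("\nmax entry error vs the generating AR(1) 0.7 matrix:",
      round(float(np.max(np.abs(sigma.values - truth))), 4))

# The PVCA share quantifies how much phenotypic variance the center effect
# explains; after ComBat removes it, the Pearson matrix of adjusted values
# recovers the generating correlations to within sampling error.
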