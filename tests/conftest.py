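import numpy as np
import pandas as pd
import pytest

from kompute import CorrelationMatrix, PhenotypeTable


@pytest.fixture
def sigma3() -> CorrelationMatrix:
    """Small correlation matrix with a hand-checkable conditional structure."""
    return CorrelationMatrix(
        np.array([[1.0, 0.8, 0.5], [0.8, 1.0, 0.5], [0.5, 0.5, 1.0]]),
        ["p0", "p1", "p2"],
    )


def random_correlation(m: int, rng: np.random.Generator) -> CorrelationMatrix:
    """Well-conditioned random correlation matrix via a factor model."""
    load = rng.normal(size=(m, m))
    cov = load @ load.T + 0.5 * np.eye(m)
    d = np.sqrt(np.diag(cov))
    return CorrelationMatrix(cov / np.outer(d, d), [f"p{i}" for i in range(m)])


def long_table(
    values: np.ndarray, covariates: dict[str, np.ndarray] | None = None
) -> PhenotypeTable:
    """Build a long-format PhenotypeTable from a subjects x phenotypes array."""
    n, m = values.shape
    rows = []
    for i in range(n):
        for j in range(m):
            if np.isnan(values[i, j]):
                continue
            row = {
                "subject_id": f"s{i:05d}",
                "phenotype_id": f"p{j}",
                "value": values[i, j],
            }
            for name, arr in (covariates or {}).items():
                row[name] = arr[i]
            rows.append(row)
    return PhenotypeTable(pd.DataFrame(rows))
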