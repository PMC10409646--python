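"""Core containers for Z-score matrices, correlation matrices, and results.

The central object of study is an ``m x n`` matrix of signed two-sided
association Z-scores: ``m`` phenotypes in rows, ``n`` genes in columns.
Under the null of no gene-phenotype association a gene's Z-score vector is
multivariate normal with mean zero and covariance equal to the inter-phenotype
(genetic) correlation matrix, which is what makes conditional-expectation
imputation of missing entries possible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ZScoreMatrix",
    "CorrelationMatrix",
    "MissingSplit",
    "ConditionalResult",
    "RidgeConfig",
    "ImputationResult",
    "nearest_psd_correlation",
]

#: eigenvalue tolerance below which a correlation matrix is considered non-PSD
PSD_TOL = 1e-8


def _check_unique(labels: Sequence[str], what: str) -> list[str]:
    labels = [str(x) for x in labels]
    seen: set[str] = set()
    dupes = {x for x in labels if x in seen or seen.add(x)}
    if dupes:
        raise ValueError(f"duplicate {what} labels: {sorted(dupes)}")
    return labels


@dataclass
class ZScoreMatrix:
    """Phenotypes-by-genes matrix of signed Z-scores with explicit missingness.

    Parameters
    ----------
    values
        Real matrix of shape ``(m, n)``; entries at masked cells are ignored
        (conventionally NaN).
    phenotype_ids, gene_ids
        Unique row / column labels.
    mask
        Boolean matrix of the same shape; ``True`` marks a *missing* cell.
        If omitted it is inferred from NaNs in ``values``.
    """

    values: np.ndarray
    phenotype_ids: list[str]
    gene_ids: list[str]
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if self.mask is None:
            self.mask = np.isnan(self.values)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.values.shape:
            raise ValueError(
                f"mask shape {self.mask.shape} != values shape {self.values.shape}"
            )
        self.phenotype_ids = _check_unique(self.phenotype_ids, "phenotype")
        self.gene_ids = _check_unique(self.gene_ids, "gene")
        m, n = self.values.shape
        if len(self.phenotype_ids) != m or len(self.gene_ids) != n:
            raise ValueError("label lengths do not match matrix shape")
        if not np.all(np.isfinite(self.values[~self.mask])):
            raise ValueError("non-finite value at an unmasked cell")

    @property
    def n_phenotypes(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "ZScoreMatrix":
        return ZScoreMatrix(
            self.values.copy(),
            list(self.phenotype_ids),
            list(self.gene_ids),
            self.mask.copy(),
        )


@dataclass
class CorrelationMatrix:
    """Symmetric unit-diagonal phenotype correlation matrix.

    Stands in for the genetic correlation matrix Sigma in the imputation
    model; in practice estimated as the phenotypic correlation of adjusted
    control-animal measurements (Cheverud's conjecture).
    """

    values: np.ndarray
    phenotype_ids: list[str]

    #: symmetry / unit-diagonal tolerance used at validation
    atol: float = 1e-8

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("correlation matrix must be square")
        self.phenotype_ids = _check_unique(self.phenotype_ids, "phenotype")
        if len(self.phenotype_ids) != v.shape[0]:
            raise ValueError("label length does not match matrix dimension")
        if not np.all(np.isfinite(v)):
            raise ValueError("correlation matrix has non-finite entries")
        if np.max(np.abs(v - v.T)) > self.atol:
            raise ValueError(
                f"correlation matrix asymmetric beyond tolerance {self.atol:g}"
            )
        if np.max(np.abs(np.diag(v) - 1.0)) > self.atol:
            raise ValueError("correlation matrix diagonal is not 1")
        if np.max(np.abs(v)) > 1.0 + 1e-10:
            raise ValueError("correlation entries outside [-1, 1]")
        w = np.linalg.eigvalsh((v + v.T) / 2.0)
        if w.min() < -PSD_TOL:
            raise ValueError(
                f"correlation matrix is not PSD (min eigenvalue {w.min():.3e}); "
                "repair it first (see nearest_psd_correlation)"
            )

    @property
    def m(self) -> int:
        return self.values.shape[0]


def nearest_psd_correlation(values: np.ndarray) -> np.ndarray:
    """Repair a symmetric matrix to a valid correlation matrix.

    Eigenvalues are clipped at zero and the result rescaled back to unit
    diagonal. Deterministic and adequate for the small (m <= a few hundred)
    matrices this package handles; not the full alternating-projections
    nearest-correlation algorithm.
    """
    v = np.asarray(values, dtype=float)
    v = (v + v.T) / 2.0
    w, q = np.linalg.eigh(v)
    w = np.clip(w, 0.0, None)
    out = (q * w) @ q.T
    d = np.sqrt(np.clip(np.diag(out), np.finfo(float).tiny, None))
    out = out / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    out = np.clip((out + out.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(out, 1.0)
    return out


@dataclass
class MissingSplit:
    """Partition of one gene's phenotype axis into unmeasured / measured.

    ``missing_idx`` (length k) indexes the unmeasured phenotypes, whose
    Z-scores Z1 are to be imputed; ``observed_idx`` (length l = m - k)
    indexes the measured ones with Z-scores ``z_observed`` (Z2). Original
    phenotype order is preserved via the indices themselves.
    """

    missing_idx: np.ndarray
    observed_idx: np.ndarray
    z_observed: np.ndarray

    def __post_init__(self) -> None:
        self.missing_idx = np.asarray(self.missing_idx, dtype=np.intp)
        self.observed_idx = np.asarray(self.observed_idx, dtype=np.intp)
        self.z_observed = np.asarray(self.z_observed, dtype=float)
        m = self.m
        combined = np.concatenate([self.missing_idx, self.observed_idx])
        if len(np.unique(combined)) != m or (m and combined.max() != m - 1):
            raise ValueError("missing_idx and observed_idx must partition 0..m-1")
        if self.z_observed.shape != (len(self.observed_idx),):
            raise ValueError("z_observed length must equal len(observed_idx)")

    @property
    def k(self) -> int:
        return len(self.missing_idx)

    @property
    def l(self) -> int:  # noqa: E741 - matches the field's notation
        return len(self.observed_idx)

    @property
    def m(self) -> int:
        return self.k + self.l


@dataclass
class RidgeConfig:
    """Ridge penalty added to the diagonal of the observed-block correlation.

    A small positive ``lam`` guarantees invertibility of Sigma22 with
    negligible impact on the imputed scores; ``lam = 0`` recovers the exact
    conditional-expectation formulas and is useful for closed-form checks.
    """

    lam: float = 0.01

    def __post_init__(self) -> None:
        if not (np.isfinite(self.lam) and self.lam >= 0):
            raise ValueError("ridge penalty must be a nonnegative real")


@dataclass
class ConditionalResult:
    """Conditional-MVN result for one missingness pattern.

    ``info = 1 - diag(cond_cov)`` is the per-cell imputation information:
    1 means the conditional distribution is degenerate at the imputed value
    (perfectly reliable), 0 means imputation adds nothing over the null.
    """

    z_imputed: np.ndarray
    cond_cov: np.ndarray
    info: np.ndarray


@dataclass
class ImputationResult:
    """Completed Z-score matrix plus per-cell reliability bookkeeping.

    ``z_full`` keeps measured cells bit-identical to the input and fills
    previously-missing cells with imputed values (NaN where not imputable).
    ``info`` holds the imputation information at imputed cells, sentinel 1.0
    at measured cells, and NaN where no certainty measure exists.
    ``imputed_mask`` equals the input missing mask. ``non_imputable`` lists
    gene columns with no measured phenotype; ``below_threshold`` flags
    imputed cells whose information fell under the caller's threshold
    (flagged, never deleted).
    """

    z_full: np.ndarray
    info: np.ndarray
    imputed_mask: np.ndarray
    phenotype_ids: list[str]
    gene_ids: list[str]
    non_imputable: list[str] = field(default_factory=list)
    below_threshold: list[tuple[str, str, float]] = field(default_factory=list)


def clip_info(info: np.ndarray, warn_tol: float = 1e-6) -> np.ndarray:
    """Clip information values to [0, 1], warning on large excursions.

    Numerically non-PSD inputs can push ``diag(Sigma_1|2)`` slightly outside
    [0, 1]; tiny excursions are silently clipped, anything beyond ``warn_tol``
    is logged as a warning.
    """
    info = np.asarray(info, dtype=float)
    excess = max(
        float(np.max(info - 1.0, initial=0.0)),
        float(np.max(-info, initial=0.0)),
    )
    if excess > warn_tol:
        warnings.warn(
            f"imputation information outside [0, 1] by {excess:.3e}; clipped "
            "(input correlation matrix may not be PSD)",
            RuntimeWarning,
            stacklevel=2,
        )
    return np.clip(info, 0.0, 1.0)
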