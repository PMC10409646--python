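"""Conditional multivariate-normal imputation of missing association Z-scores.

For one gene, write its m-vector of Z-scores as (Z1, Z2) with Z1 the k
unmeasured and Z2 the l measured entries. Under the null, Z ~ MVN(0, Sigma)
with Sigma the inter-phenotype correlation matrix, so

    E[Z1 | Z2] = Sigma12 Sigma22^{-1} Z2
    Cov[Z1 | Z2] = Sigma11 - Sigma12 Sigma22^{-1} Sigma21   (Schur complement)

The diagonal of ``I - Cov[Z1|Z2]`` is the per-cell imputation information in
[0, 1]. A small ridge penalty ``lam`` on the diagonal of Sigma22 guarantees
invertibility. All linear systems are solved through a Cholesky factorization
of ``Sigma22 + lam I`` — never an explicit inverse — and genes sharing a
missingness pattern reuse one factorization.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.linalg import cho_factor, cho_solve, LinAlgError

from .types import (
    ConditionalResult,
    CorrelationMatrix,
    ImputationResult,
    MissingSplit,
    RidgeConfig,
    ZScoreMatrix,
    clip_info,
)

__all__ = [
    "SingularConditioningError",
    "split_by_missingness",
    "conditional_impute",
    "impute_matrix",
]

logger = logging.getLogger(__name__)


class SingularConditioningError(np.linalg.LinAlgError):
    """The observed-block matrix Sigma22 + lam*I is singular."""


def split_by_missingness(z_column: np.ndarray) -> MissingSplit:
    """Partition one gene's Z-score vector into missing and observed parts.

    NaN entries are treated as missing. ``k = 0`` (nothing missing) and
    ``k = m`` (everything missing) are both legal outputs; the caller's data
    is never reordered in place.
    """
    z = np.asarray(z_column, dtype=float)
    if z.ndim != 1 or z.size < 1:
        raise ValueError("z_column must be a 1-D vector of length >= 1")
    miss = np.isnan(z)
    missing_idx = np.flatnonzero(miss)
    observed_idx = np.flatnonzero(~miss)
    return MissingSplit(missing_idx, observed_idx, z[observed_idx])


def _factor_observed_block(
    sigma22: np.ndarray, lam: float
) -> tuple[np.ndarray, bool]:
    """Cholesky factor of Sigma22 + lam*I, raising a named error if singular."""
    a = sigma22 + lam * np.eye(sigma22.shape[0])
    try:
        return cho_factor(a, lower=True)
    except LinAlgError as exc:
        raise SingularConditioningError(
            "singular conditioning matrix, increase ridge"
        ) from exc


def conditional_impute(
    split: MissingSplit,
    sigma: CorrelationMatrix,
    ridge: RidgeConfig = RidgeConfig(),
) -> ConditionalResult:
    """Impute one gene's missing Z-scores given its measured ones.

    Returns the conditional mean ``z_imputed`` (length k), the conditional
    covariance ``cond_cov`` (k x k Schur complement with the ridge applied),
    and ``info = 1 - diag(cond_cov)`` clipped to [0, 1].

    Requires at least one missing and one observed phenotype; with zero
    correlation between the blocks the imputed scores and information are
    exactly zero.
    """
    if split.k < 1:
        raise ValueError("nothing to impute (k = 0)")
    if split.l < 1:
        raise ValueError("no measured phenotypes to condition on (l = 0)")
    if sigma.m != split.m:
        raise ValueError(
            f"sigma dimension {sigma.m} does not match split m = {split.m}"
        )
    s = sigma.values
    mi, oi = split.missing_idx, split.observed_idx
    sigma11 = s[np.ix_(mi, mi)]
    sigma12 = s[np.ix_(mi, oi)]
    sigma22 = s[np.ix_(oi, oi)]
    factor = _factor_observed_block(sigma22, ridge.lam)
    # W = (Sigma22 + lam I)^{-1} Sigma21, solved via the factorization
    w = cho_solve(factor, sigma12.T)
    z_imputed = w.T @ split.z_observed
    cond_cov = sigma11 - sigma12 @ w
    info = clip_info(1.0 - np.diag(cond_cov))
    return ConditionalResult(z_imputed=z_imputed, cond_cov=cond_cov, info=info)


def impute_matrix(
    z: ZScoreMatrix,
    sigma: CorrelationMatrix,
    ridge: RidgeConfig = RidgeConfig(),
    info_min: float | None = None,
) -> ImputationResult:
    """Impute every gene column of a Z-score matrix.

    Genes are grouped by missingness pattern so each distinct observed block
    is factorized once; with m phenotypes and thousands of genes the patterns
    repeat heavily and this dominates runtime. Columns with no missing cells
    pass through; columns with no measured cells cannot be imputed and are
    reported in ``non_imputable``. If ``info_min`` is given, imputed cells
    with information below it are listed in ``below_threshold`` — flagged,
    not deleted, so the caller chooses what to drop.
    """
    if sigma.phenotype_ids != z.phenotype_ids:
        mism = [
            (a, b)
            for a, b in zip(sigma.phenotype_ids, z.phenotype_ids)
            if a != b
        ]
        raise ValueError(
            "phenotype labels of sigma do not match the Z-score matrix "
            f"(first mismatches: {mism[:5]})"
        )
    if z.n_genes < 1:
        raise ValueError("Z-score matrix has no genes")
    if info_min is not None and not (0.0 <= info_min <= 1.0):
        raise ValueError("info_min must lie in [0, 1]")

    m, n = z.values.shape
    z_full = np.where(z.mask, np.nan, z.values)
    info_mat = np.full((m, n), np.nan)
    info_mat[~z.mask] = 1.0  # sentinel at measured cells
    non_imputable: list[str] = []
    below: list[tuple[str, str, float]] = []

    # group gene columns by missingness pattern (bytes key is hash-cheap)
    patterns: dict[bytes, list[int]] = {}
    for j in range(n):
        patterns.setdefault(z.mask[:, j].tobytes(), []).append(j)

    s = sigma.values
    for key, cols in patterns.items():
        pattern = np.frombuffer(key, dtype=bool)
        k = int(pattern.sum())
        if k == 0:
            continue
        if k == m:
            non_imputable.extend(z.gene_ids[j] for j in cols)
            continue
        mi = np.flatnonzero(pattern)
        oi = np.flatnonzero(~pattern)
        sigma12 = s[np.ix_(mi, oi)]
        factor = _factor_observed_block(s[np.ix_(oi, oi)], ridge.lam)
        w = cho_solve(factor, sigma12.T)  # (l, k)
        info = clip_info(1.0 - (np.diag(s)[mi] - np.sum(sigma12 * w.T, axis=1)))
        z2 = z.values[np.ix_(oi, cols)]  # (l, n_cols)
        z_full[np.ix_(mi, cols)] = w.T @ z2
        info_mat[np.ix_(mi, cols)] = info[:, None]
        if info_min is not None:
            low = np.flatnonzero(info < info_min)
            for j in cols:
                for i in low:
                    below.append(
                        (z.phenotype_ids[mi[i]], z.gene_ids[j], float(info[i]))
                    )
    if non_imputable:
        logger.info(
            "%d gene column(s) with zero measured phenotypes left unimputed",
            len(non_imputable),
        )
    return ImputationResult(
        z_full=z_full,
        info=info_mat,
        imputed_mask=z.mask.copy(),
        phenotype_ids=list(z.phenotype_ids),
        gene_ids=list(z.gene_ids),
        non_imputable=non_imputable,
        below_threshold=below,
    )
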