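"""Iterative low-rank SVD matrix completion (benchmark baseline).

Classic hard-impute: fill missing cells from the current estimate, take a
rank-r truncated SVD, restore the observed cells, repeat until the missing
block stops moving. Provides no per-cell certainty measure — the info matrix
of its result is NaN at imputed cells.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .types import ImputationResult, ZScoreMatrix

__all__ = ["SvdConfig", "svd_complete", "choose_rank"]

logger = logging.getLogger(__name__)


@dataclass
class SvdConfig:
    """Configuration of the iterative SVD completion.

    rank
        Truncation rank, or ``"auto"`` to pick it by holdout (see
        :func:`choose_rank`).
    max_iter, tol
        Stopping rule: iterate until the relative Frobenius change of the
        missing-cell block falls below ``tol`` or ``max_iter`` is reached.
    init
        Initial fill of missing cells: ``"zero"`` or ``"column_mean"``.
    """

    rank: int | str = "auto"
    max_iter: int = 100
    tol: float = 1e-5
    init: str = "zero"

    def __post_init__(self) -> None:
        if isinstance(self.rank, str):
            if self.rank != "auto":
                raise ValueError('rank must be a positive integer or "auto"')
        elif self.rank < 1:
            raise ValueError("rank must be >= 1")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.init not in ("zero", "column_mean"):
            raise ValueError('init must be "zero" or "column_mean"')


def _check_coverage(mask: np.ndarray, z: ZScoreMatrix) -> None:
    empty_rows = np.flatnonzero(mask.all(axis=1))
    empty_cols = np.flatnonzero(mask.all(axis=0))
    if empty_rows.size or empty_cols.size:
        rows = [z.phenotype_ids[i] for i in empty_rows]
        cols = [z.gene_ids[j] for j in empty_cols]
        raise ValueError(
            "SVD completion needs at least one observed entry per row and "
            f"column; empty rows: {rows[:10]}, empty columns: {cols[:10]}"
        )


def _truncate(x: np.ndarray, rank: int) -> np.ndarray:
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    r = min(rank, s.size)
    return (u[:, :r] * s[:r]) @ vt[:r]


def _complete_array(
    values: np.ndarray, mask: np.ndarray, config: SvdConfig, rank: int
) -> np.ndarray:
    x = values.copy()
    if config.init == "zero":
        x[mask] = 0.0
    else:
        col_mean = np.nanmean(np.where(mask, np.nan, values), axis=0)
        x[mask] = np.broadcast_to(col_mean, values.shape)[mask]
    if not mask.any():
        return x
    for it in range(config.max_iter):
        low = _truncate(x, rank)
        new_missing = low[mask]
        denom = max(np.linalg.norm(x[mask]), 1.0)
        delta = np.linalg.norm(new_missing - x[mask]) / denom
        x[mask] = new_missing
        if delta < config.tol:
            logger.debug("SVD completion converged after %d iterations", it + 1)
            break
    else:
        warnings.warn(
            f"SVD completion did not converge in {config.max_iter} iterations "
            f"(last relative change {delta:.3e}); returning current iterate",
            RuntimeWarning,
            stacklevel=2,
        )
    return x


def svd_complete(
    z: ZScoreMatrix, config: SvdConfig = SvdConfig(rank="auto"), seed: int = 0
) -> ImputationResult:
    """Complete a Z-score matrix by iterative truncated SVD.

    Observed cells in the output are bit-identical to the input. ``seed`` is
    used only when ``config.rank == "auto"`` (holdout rank selection over
    ranks 1..min(m, n, 8)).
    """
    mask = z.mask
    _check_coverage(mask, z)
    rank = config.rank
    if rank == "auto":
        cap = min(z.n_phenotypes, z.n_genes, 8)
        candidates = list(range(1, max(cap, 2) + 1))
        rank = choose_rank(z, candidates, seed=seed, config=config)
        logger.info("auto-selected SVD rank %d", rank)
    if rank > min(z.values.shape):
        raise ValueError(
            f"rank {rank} exceeds min(m, n) = {min(z.values.shape)}"
        )
    x = _complete_array(z.values, mask, config, int(rank))
    info = np.where(mask, np.nan, 1.0)
    return ImputationResult(
        z_full=np.where(mask, x, z.values),
        info=info,
        imputed_mask=mask.copy(),
        phenotype_ids=list(z.phenotype_ids),
        gene_ids=list(z.gene_ids),
    )


def choose_rank(
    z: ZScoreMatrix,
    candidate_ranks: list[int],
    holdout_frac: float = 0.1,
    seed: int = 0,
    config: SvdConfig | None = None,
) -> int:
    """Pick the truncation rank by masking extra observed cells and scoring.

    A fraction ``holdout_frac`` of the observed cells is additionally masked;
    each candidate rank completes the matrix and the rank with the smallest
    holdout RMSE wins. Deterministic given ``seed``.
    """
    if len(candidate_ranks) < 2:
        raise ValueError("need at least 2 candidate ranks")
    cap = min(z.values.shape)
    bad = [r for r in candidate_ranks if r > cap]
    if bad:
        raise ValueError(f"candidate ranks {bad} exceed min(m, n) = {cap}")
    if not (0.0 < holdout_frac < 1.0):
        raise ValueError("holdout_frac must lie in (0, 1)")
    base = config or SvdConfig(rank=candidate_ranks[0])
    rng = np.random.default_rng(seed)
    obs = np.flatnonzero(~z.mask.ravel())
    n_hold = max(1, int(round(holdout_frac * obs.size)))
    # greedy coverage-preserving holdout: never empty a row or column
    m, n = z.mask.shape
    row_left = (~z.mask).sum(axis=1)
    col_left = (~z.mask).sum(axis=0)
    hold_list: list[int] = []
    for flat in rng.permutation(obs):
        r, c = divmod(int(flat), n)
        if row_left[r] > 1 and col_left[c] > 1:
            hold_list.append(int(flat))
            row_left[r] -= 1
            col_left[c] -= 1
            if len(hold_list) >= n_hold:
                break
    hold = np.array(hold_list, dtype=np.intp)
    if hold.size < 1:
        raise ValueError("cannot hold out any cell without emptying a row/column")
    mask2 = z.mask.copy().ravel()
    mask2[hold] = True
    mask2 = mask2.reshape(z.mask.shape)
    truth = z.values.ravel()[hold]
    z2 = ZScoreMatrix(
        np.where(mask2, np.nan, z.values),
        list(z.phenotype_ids),
        list(z.gene_ids),
        mask2,
    )
    _check_coverage(mask2, z2)
    best_rank, best_rmse = None, np.inf
    for r in candidate_ranks:
        x = _complete_array(z2.values, mask2, base, int(r))
        rmse = float(np.sqrt(np.mean((x.ravel()[hold] - truth) ** 2)))
        logger.debug("rank %d holdout RMSE %.4f", r, rmse)
        if rmse < best_rmse:
            best_rank, best_rmse = int(r), rmse
    return best_rank
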