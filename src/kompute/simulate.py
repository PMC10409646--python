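"""Mask-and-recover benchmark: simulate Z-score matrices, mask, impute, score.

The evaluation design simulates association Z-score matrices gene-by-gene
from MVN(0, Sigma_p), randomly masks a fraction of cells, imputes them with
each method, and scores recovery as the Pearson correlation between the
held-out true values and the imputed ones — optionally restricted to cells
whose imputation information exceeds a threshold.

Fixture correlation matrices (AR(1), block, random factor-model) stand in
for phenotype-domain correlation matrices estimated from real control data;
any user-supplied correlation matrix file can be used instead to replicate a
specific study.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .impute import impute_matrix
from .svd import SvdConfig, choose_rank, svd_complete
from .types import CorrelationMatrix, RidgeConfig, ZScoreMatrix

__all__ = [
    "SimConfig",
    "TruthRecord",
    "BenchmarkReport",
    "make_sigma_fixture",
    "simulate_z",
    "mask_random",
    "score_recovery",
    "run_benchmark",
]

logger = logging.getLogger(__name__)

KNOWN_METHODS = ("svd", "kompute", "kompute_filtered")


@dataclass
class SimConfig:
    """Study conditions of the benchmark.

    Defaults mirror the full-scale design: 10 000 genes, 100 replicate
    matrices, mask fractions 20/40/60%, information threshold 0.8. A single
    master ``seed`` drives everything; per-replicate streams are derived
    deterministically.
    """

    sigma: CorrelationMatrix
    n_genes: int = 10_000
    n_reps: int = 100
    mask_fractions: tuple[float, ...] = (0.2, 0.4, 0.6)
    info_min: float = 0.8
    ridge: RidgeConfig = field(default_factory=RidgeConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_reps < 1:
            raise ValueError("n_genes and n_reps must be positive")
        if any(not (0.0 < f < 1.0) for f in self.mask_fractions):
            raise ValueError("mask fractions must lie strictly inside (0, 1)")
        if not (0.0 <= self.info_min <= 1.0):
            raise ValueError("info_min must lie in [0, 1]")


@dataclass
class TruthRecord:
    """Held-out values of masked cells (row/col indices + true Z-scores)."""

    rows: np.ndarray
    cols: np.ndarray
    values: np.ndarray


def make_sigma_fixture(
    m: int, kind: str = "ar1", strength: float = 0.8, seed: int = 0
) -> CorrelationMatrix:
    """Deterministic synthetic phenotype correlation matrices.

    ``"ar1"`` gives ``strength**|i-j|`` (a banded structure typical of
    related phenotypes ordered by similarity); ``"block"`` gives two equal
    blocks with ``strength`` inside and 0 between; ``"random"`` blends a
    random factor-model correlation with the identity so that ``strength``
    scales the overall correlation level. ``strength = 0`` always yields the
    identity.
    """
    if m < 2:
        raise ValueError("need m >= 2 phenotypes")
    if not (0.0 <= strength < 1.0):
        raise ValueError("strength must lie in [0, 1)")
    idx = np.arange(m)
    if kind == "ar1":
        values = strength ** np.abs(idx[:, None] - idx[None, :])
    elif kind == "block":
        half = m // 2
        block = (idx[:, None] < half) == (idx[None, :] < half)
        values = np.where(block, strength, 0.0)
        np.fill_diagonal(values, 1.0)
    elif kind == "random":
        rng = np.random.default_rng(seed)
        load = rng.normal(size=(m, max(1, m // 2)))
        cov = load @ load.T + 0.5 * np.eye(m)
        d = np.sqrt(np.diag(cov))
        base = cov / np.outer(d, d)
        values = strength * base + (1.0 - strength) * np.eye(m)
        np.fill_diagonal(values, 1.0)
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    ids = [f"p{i}" for i in range(m)]
    return CorrelationMatrix(values, ids)


def simulate_z(config: SimConfig, rep_index: int = 0) -> ZScoreMatrix:
    """Draw one replicate Z-score matrix, gene columns iid MVN(0, sigma).

    Streams are independent across ``rep_index`` and reproducible given
    ``(seed, rep_index)``.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(0, rep_index))
    )
    sigma = config.sigma.values
    m = sigma.shape[0]
    # eigen-based factor tolerates exactly-PSD (rank-deficient) sigma
    w, q = np.linalg.eigh(sigma)
    factor = q * np.sqrt(np.clip(w, 0.0, None))
    z = factor @ rng.standard_normal(size=(m, config.n_genes))
    ids = config.sigma.phenotype_ids
    genes = [f"g{j:06d}" for j in range(config.n_genes)]
    return ZScoreMatrix(z, list(ids), genes, np.zeros_like(z, dtype=bool))


def mask_random(
    z: ZScoreMatrix, fraction: float, seed: int = 0
) -> tuple[ZScoreMatrix, TruthRecord]:
    """Mask exactly ``round(fraction * cells)`` cells uniformly at random.

    Returns the masked matrix and a record of the held-out truth. Masking an
    entire gene column can happen by chance and is legal — the conditional
    imputation reports such columns non-imputable and the benchmark excludes
    them from scoring for every method symmetrically.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must lie in (0, 1)")
    m, n = z.values.shape
    already = z.mask.any()
    if already:
        raise ValueError("mask_random expects a fully observed matrix")
    rng = np.random.default_rng(seed)
    n_mask = int(round(fraction * m * n))
    flat = rng.choice(m * n, size=n_mask, replace=False)
    rows, cols = np.unravel_index(flat, (m, n))
    mask = np.zeros((m, n), dtype=bool)
    mask[rows, cols] = True
    masked = ZScoreMatrix(
        np.where(mask, np.nan, z.values),
        list(z.phenotype_ids),
        list(z.gene_ids),
        mask,
    )
    return masked, TruthRecord(rows, cols, z.values[rows, cols])


def score_recovery(
    truth: np.ndarray,
    imputed: np.ndarray,
    info: np.ndarray | None = None,
    info_min: float | None = None,
) -> tuple[float, int, float]:
    """Pearson correlation between held-out truth and imputed values.

    Cells failing the information filter (when given) and cells without an
    imputed value (NaN) are dropped; returns ``(correlation, n_used,
    retention)`` with ``retention = n_used / len(truth)``. Fewer than two
    usable cells yields NaN with a warning.
    """
    truth = np.asarray(truth, dtype=float)
    imputed = np.asarray(imputed, dtype=float)
    if truth.shape != imputed.shape:
        raise ValueError("truth and imputed must have equal length")
    keep = ~np.isnan(imputed) & ~np.isnan(truth)
    if info is not None and info_min is not None:
        keep &= np.nan_to_num(np.asarray(info, dtype=float), nan=-1.0) >= info_min
    n_total = truth.size
    n_used = int(keep.sum())
    if n_used < 2:
        warnings.warn(
            "fewer than 2 cells pass the filter; correlation undefined",
            RuntimeWarning,
            stacklevel=2,
        )
        return float("nan"), n_used, n_used / max(n_total, 1)
    r = float(np.corrcoef(truth[keep], imputed[keep])[0, 1])
    return r, n_used, n_used / n_total


def _rep_seed(master: int, rep: int, frac_index: int) -> int:
    # distinct, reproducible, and < 2**31
    return int(
        np.random.SeedSequence(
            master, spawn_key=(1, rep, frac_index)
        ).generate_state(1)[0] % (2**31 - 1)
    )


@dataclass
class BenchmarkReport:
    """Recovery-correlation table: one row per (method, mask fraction)."""

    table: pd.DataFrame

    def to_tsv(self, path: str) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_benchmark(
    config: SimConfig,
    methods: tuple[str, ...] = KNOWN_METHODS,
    svd_config: SvdConfig | None = None,
) -> BenchmarkReport:
    """Run the full reps x fractions x methods recovery benchmark.

    For each replicate and mask fraction the same masked matrix is handed to
    every method; KOMPUTE uses ``config.sigma`` as its correlation matrix
    (supply an estimated one to emulate realistic conditions).
    ``kompute_filtered`` scores the same imputation restricted to cells with
    information >= ``config.info_min``. Cells in gene columns that lost all
    observations are excluded from scoring for every method symmetrically;
    their count is reported. A replicate failing for one method is logged
    and does not abort the others.
    """
    unknown = [mth for mth in methods if mth not in KNOWN_METHODS]
    if unknown:
        raise ValueError(f"unknown methods {unknown}; choose from {KNOWN_METHODS}")
    svd_config = svd_config or SvdConfig(rank="auto")
    need_kompute = bool({"kompute", "kompute_filtered"} & set(methods))
    rows = []
    for fi, frac in enumerate(config.mask_fractions):
        per_method: dict[str, list[tuple[float, float]]] = {mth: [] for mth in methods}
        excluded_counts = []
        # one fixed SVD configuration per fraction: with rank="auto" the rank
        # is chosen on the first replicate and reused, so rep-to-rep spread
        # measures sampling noise of a fixed algorithm, not selection noise
        frac_svd_config = svd_config
        for rep in range(config.n_reps):
            seed = _rep_seed(config.seed, rep, fi)
            z_true = simulate_z(config, rep_index=rep * len(config.mask_fractions) + fi)
            masked, truth = mask_random(z_true, frac, seed=seed)
            # columns left with zero observations: excluded for all methods
            dead_cols = np.flatnonzero(masked.mask.all(axis=0))
            scoreable = ~np.isin(truth.cols, dead_cols)
            excluded_counts.append(int((~scoreable).sum()))
            t_vals = truth.values[scoreable]
            t_rows, t_cols = truth.rows[scoreable], truth.cols[scoreable]

            imp = None
            if need_kompute:
                try:
                    imp = impute_matrix(masked, config.sigma, config.ridge)
                except Exception:
                    logger.exception("conditional imputation failed (rep %d)", rep)
            for mth in methods:
                try:
                    if mth == "svd":
                        if dead_cols.size:
                            # drop unconstrained columns, complete the rest
                            keep = np.setdiff1d(
                                np.arange(masked.n_genes), dead_cols
                            )
                            sub = ZScoreMatrix(
                                masked.values[:, keep],
                                list(masked.phenotype_ids),
                                [masked.gene_ids[j] for j in keep],
                                masked.mask[:, keep],
                            )
                        else:
                            sub, keep = masked, None
                        if frac_svd_config.rank == "auto":
                            cap = min(sub.n_phenotypes, sub.n_genes, 8)
                            rank = choose_rank(
                                sub, list(range(1, max(cap, 2) + 1)), seed=seed
                            )
                            frac_svd_config = replace(frac_svd_config, rank=rank)
                            logger.info(
                                "fraction %g: fixed SVD rank %d", frac, rank
                            )
                        res = svd_complete(sub, frac_svd_config, seed=seed)
                        if keep is None:
                            full = res.z_full
                        else:
                            full = np.full(masked.values.shape, np.nan)
                            full[:, keep] = res.z_full
                        r, n_used, ret = score_recovery(
                            t_vals, full[t_rows, t_cols]
                        )
                    elif imp is None:
                        continue
                    else:
                        pred = imp.z_full[t_rows, t_cols]
                        if mth == "kompute":
                            r, n_used, ret = score_recovery(t_vals, pred)
                        else:
                            r, n_used, ret = score_recovery(
                                t_vals,
                                pred,
                                info=imp.info[t_rows, t_cols],
                                info_min=config.info_min,
                            )
                    per_method[mth].append((r, ret))
                except Exception:
                    logger.exception("method %s failed (rep %d, frac %g)", mth, rep, frac)
        for mth in methods:
            got = np.array(per_method[mth], dtype=float)
            rows.append(
                {
                    "method": mth,
                    "mask_fraction": frac,
                    "n_reps": len(got),
                    "mean_corr": float(np.nanmean(got[:, 0])) if len(got) else np.nan,
                    "sd_corr": float(np.nanstd(got[:, 0], ddof=1))
                    if len(got) > 1
                    else np.nan,
                    "mean_retention": float(np.nanmean(got[:, 1]))
                    if len(got)
                    else np.nan,
                    "mean_cells_excluded": float(np.mean(excluded_counts)),
                }
            )
    return BenchmarkReport(pd.DataFrame(rows))
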