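"""Estimate the phenotype correlation matrix from control-animal data.

The imputation model needs the inter-phenotype genetic correlation matrix
Sigma. Following Cheverud's conjecture, the phenotypic correlation of
control animals (Sigma_p) is used as its proxy. Raw control phenotypes are
contaminated by nonbiological factors (phenotyping center, batch, ...), so
the pipeline is:

1. :func:`pvca` — principal variance component analysis to quantify how much
   phenotypic variance each candidate covariate explains;
2. :func:`select_confounders` — keep the dominant technical factors;
3. :func:`combat_adjust` — parametric empirical-Bayes location/scale batch
   adjustment (the classic ComBat algorithm) removing those factors;
4. :func:`estimate_correlation` — pairwise-complete Pearson correlation of
   the adjusted values, repaired to a valid (PSD, unit-diagonal)
   correlation matrix if needed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import CorrelationMatrix, nearest_psd_correlation, PSD_TOL

__all__ = [
    "PhenotypeTable",
    "PvcaReport",
    "BatchAdjustedTable",
    "pvca",
    "select_confounders",
    "combat_adjust",
    "estimate_correlation",
]

logger = logging.getLogger(__name__)

_RESERVED = ("subject_id", "phenotype_id", "value")


@dataclass
class PhenotypeTable:
    """Long-format control-animal phenotype measurements with covariates.

    ``data`` holds one row per (subject, phenotype) measurement with columns
    ``subject_id``, ``phenotype_id``, ``value`` plus one column per
    categorical covariate (e.g. center, batch, sex). Covariates are
    properties of the subject and must be constant across a subject's rows.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _RESERVED if c not in self.data.columns]
        if missing:
            raise ValueError(f"phenotype table lacks required columns {missing}")
        dup = self.data.duplicated(subset=["subject_id", "phenotype_id"])
        if dup.any():
            pairs = self.data.loc[dup, ["subject_id", "phenotype_id"]].head(5)
            raise ValueError(
                f"multiple values for (subject, phenotype) pairs, e.g.\n{pairs}"
            )
        for cov in self.covariate_names:
            per_subj = self.data.groupby("subject_id", sort=False)[cov].nunique(
                dropna=False
            )
            if (per_subj > 1).any():
                bad = per_subj[per_subj > 1].index.tolist()[:5]
                raise ValueError(
                    f"covariate {cov!r} varies within subjects {bad}"
                )
        if self.data[self.covariate_names].isna().any().any():
            raise ValueError("covariate labels must be complete for every subject")

    @property
    def covariate_names(self) -> list[str]:
        return [c for c in self.data.columns if c not in _RESERVED]

    @property
    def phenotype_ids(self) -> list[str]:
        return sorted(self.data["phenotype_id"].astype(str).unique())

    def to_wide(self) -> pd.DataFrame:
        """Subjects-by-phenotypes value matrix (NaN where unmeasured)."""
        wide = self.data.pivot(
            index="subject_id", columns="phenotype_id", values="value"
        )
        return wide[sorted(wide.columns)]

    def covariates(self) -> pd.DataFrame:
        """One row per subject with its covariate labels."""
        return (
            self.data.drop_duplicates("subject_id")
            .set_index("subject_id")[self.covariate_names]
        )


@dataclass
class BatchAdjustedTable(PhenotypeTable):
    """Phenotype table after batch adjustment; records the removed factors."""

    removed_factors: list[str] = field(default_factory=list)


@dataclass
class PvcaReport:
    """Per-factor proportions of phenotypic variance, summing to 1.

    ``proportions`` maps each factor (and ``"residual"``) to its
    eigenvalue-weighted average variance share across the retained principal
    components.
    """

    proportions: dict[str, float]
    n_components: int = 0

    def __post_init__(self) -> None:
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"variance proportions sum to {total}, not 1")
        if any(not (-1e-9 <= p <= 1 + 1e-9) for p in self.proportions.values()):
            raise ValueError("variance proportions must lie in [0, 1]")


# ---------------------------------------------------------------------------
# PVCA


def _variance_components_mixedlm(
    score: np.ndarray, covs: pd.DataFrame, factors: list[str]
) -> dict[str, float]:
    """Random-effects variance components of one PC score, one per factor."""
    import statsmodels.api as sm

    df = covs[factors].astype(str).copy()
    df["score"] = score
    df["_g"] = 1  # single group: all factors enter as crossed variance components
    vc = {f: f"0 + C({f})" for f in factors}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM.from_formula(
            "score ~ 1", groups="_g", vc_formula=vc, re_formula="0", data=df
        )
        # powell is the reliable optimizer here; gradient methods stall on
        # near-zero variance components
        res = model.fit(reml=True, method="powell", maxiter=500)
    if not res.converged:
        raise RuntimeError("variance-components fit did not converge")
    out = {name: max(float(v), 0.0) for name, v in zip(model.exog_vc.names, res.vcomp)}
    out["residual"] = max(float(res.scale), 0.0)
    return out


def _variance_components_anova(
    score: np.ndarray, covs: pd.DataFrame, factors: list[str]
) -> dict[str, float]:
    """Method-of-moments fallback: per-factor one-way ANOVA components."""
    total_var = float(np.var(score, ddof=1))
    out: dict[str, float] = {}
    for f in factors:
        groups = covs[f].astype(str).to_numpy()
        levels, counts = np.unique(groups, return_counts=True)
        n = score.size
        means = np.array([score[groups == lv].mean() for lv in levels])
        grand = score.mean()
        msb = float(np.sum(counts * (means - grand) ** 2) / (len(levels) - 1))
        msw = float(
            sum(np.sum((score[groups == lv] - mu) ** 2) for lv, mu in zip(levels, means))
            / (n - len(levels))
        )
        n0 = (n - np.sum(counts**2) / n) / (len(levels) - 1)
        out[f] = max((msb - msw) / n0, 0.0)
    out["residual"] = max(total_var - sum(out.values()), 0.0)
    return out


def pvca(
    data: PhenotypeTable,
    factors: list[str],
    pc_var_threshold: float = 0.9,
    interactions: bool = False,
) -> PvcaReport:
    """Principal variance component analysis of candidate covariates.

    Each phenotype is standardized; the leading principal components covering
    ``pc_var_threshold`` of total variance are extracted; for each retained
    component every factor is fit as a random effect (jointly, via a
    variance-components mixed model) and the per-component variance shares
    are averaged weighted by the component eigenvalues.

    Set ``interactions=True`` to also include pairwise factor interactions as
    additional random effects.
    """
    covs = data.covariates()
    for f in factors:
        if f not in covs.columns:
            raise ValueError(f"unknown covariate {f!r}")
        if covs[f].astype(str).nunique() < 2:
            raise ValueError(f"factor {f!r} has a single level")
    wide = data.to_wide()
    if wide.shape[1] < 2:
        raise ValueError("PVCA needs at least 2 phenotypes")
    complete = wide.dropna()
    if len(complete) < 0.5 * len(wide):
        logger.info(
            "only %d/%d subjects complete; mean-imputing sporadic gaps",
            len(complete),
            len(wide),
        )
        complete = wide.fillna(wide.mean())
    if len(complete) < 3:
        raise ValueError("PVCA needs at least 3 subjects with phenotype data")
    covs = covs.loc[complete.index]

    x = complete.to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [c for c, s in zip(complete.columns, sd) if s == 0]
        raise ValueError(f"zero-variance phenotypes: {bad}")
    x = (x - x.mean(axis=0)) / sd

    evals, evecs = np.linalg.eigh(np.cov(x, rowvar=False))
    order = np.argsort(evals)[::-1]
    evals, evecs = np.clip(evals[order], 0, None), evecs[:, order]
    cum = np.cumsum(evals) / evals.sum()
    n_pc = int(np.searchsorted(cum, pc_var_threshold) + 1)
    scores = x @ evecs[:, :n_pc]

    fit_factors = list(factors)
    if interactions:
        for i, a in enumerate(factors):
            for b in factors[i + 1 :]:
                name = f"{a}:{b}"
                covs[name] = covs[a].astype(str) + ":" + covs[b].astype(str)
                fit_factors.append(name)

    weights = evals[:n_pc] / evals[:n_pc].sum()
    acc = {f: 0.0 for f in fit_factors + ["residual"]}
    for i in range(n_pc):
        try:
            comp = _variance_components_mixedlm(scores[:, i], covs, fit_factors)
        except Exception:  # singular fits on degenerate PCs
            comp = _variance_components_anova(scores[:, i], covs, fit_factors)
        total = sum(comp.values())
        if total <= 0:
            comp = {k: (1.0 if k == "residual" else 0.0) for k in comp}
            total = 1.0
        for k in acc:
            acc[k] += weights[i] * comp[k] / total
    total = sum(acc.values())
    return PvcaReport(
        proportions={k: v / total for k, v in acc.items()}, n_components=n_pc
    )


def select_confounders(
    report: PvcaReport, proportion_min: float = 0.1
) -> list[str]:
    """Factors whose variance share reaches ``proportion_min``, descending."""
    items = [
        (name, p)
        for name, p in report.proportions.items()
        if name != "residual" and p >= proportion_min
    ]
    return [name for name, _ in sorted(items, key=lambda kv: -kv[1])]


# ---------------------------------------------------------------------------
# ComBat


def _aprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (2 * s2 + m**2) / s2


def _bprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (m * s2 + m**3) / s2


def _it_sol(
    sdat: np.ndarray,
    g_hat: np.ndarray,
    d_hat: np.ndarray,
    g_bar: float,
    t2: float,
    a: float,
    b: float,
    conv: float = 1e-4,
) -> tuple[np.ndarray, np.ndarray]:
    """EB shrinkage iteration for one batch (features x in-batch samples)."""
    n = np.sum(~np.isnan(sdat), axis=1).astype(float)
    g_old, d_old = g_hat.copy(), d_hat.copy()
    change = 1.0
    while change > conv:
        g_new = (t2 * n * g_hat + d_old * g_bar) / (t2 * n + d_old)
        sum2 = np.nansum((sdat - g_new[:, None]) ** 2, axis=1)
        d_new = (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)
        change = max(
            np.max(np.abs(g_new - g_old) / np.abs(g_old).clip(min=1e-12)),
            np.max(np.abs(d_new - d_old) / np.abs(d_old).clip(min=1e-12)),
        )
        g_old, d_old = g_new, d_new
    return g_old, d_old


def _design_matrix(
    covs: pd.DataFrame, batch_factor: str, preserve: list[str]
) -> tuple[np.ndarray, np.ndarray, list]:
    batch = covs[batch_factor].astype(str)
    levels = sorted(batch.unique())
    batch_onehot = np.stack(
        [(batch == lv).to_numpy(dtype=float) for lv in levels], axis=1
    )
    parts = [batch_onehot]
    for cov in preserve:
        d = pd.get_dummies(covs[cov].astype(str), drop_first=True)
        parts.append(d.to_numpy(dtype=float))
    return np.concatenate(parts, axis=1), batch_onehot, levels


def combat_adjust(
    data: PhenotypeTable,
    batch_factor: str,
    covariates_to_preserve: list[str] | None = None,
) -> BatchAdjustedTable:
    """Remove batch effects with parametric empirical-Bayes ComBat.

    Per-phenotype location and scale batch parameters are estimated on
    standardized data, shrunk toward their across-phenotype prior by
    parametric empirical Bayes, and removed; effects of
    ``covariates_to_preserve`` are kept in the design and restored.

    Phenotypes play the role of ComBat's "features" and subjects its
    "samples". Sporadically missing measurements are tolerated (estimates use
    the observed cells; missing cells stay missing). A phenotype that is
    constant within every batch passes through unadjusted with a warning.
    With a single batch the data is returned unchanged.
    """
    preserve = list(covariates_to_preserve or [])
    covs = data.covariates()
    if batch_factor not in covs.columns:
        raise ValueError(f"unknown batch factor {batch_factor!r}")
    wide = data.to_wide()
    covs = covs.loc[wide.index]
    batch = covs[batch_factor].astype(str)
    levels, counts = np.unique(batch, return_counts=True)
    if len(levels) < 2:
        logger.info("single batch level; nothing to adjust")
        return BatchAdjustedTable(data.data.copy(), removed_factors=[])
    singletons = [lv for lv, c in zip(levels, counts) if c < 2]
    if singletons:
        raise ValueError(
            f"batch level(s) with a single subject: {singletons} "
            "(ComBat needs >= 2 subjects per batch)"
        )

    y = wide.to_numpy(dtype=float).T  # features (phenotypes) x samples
    design, batch_onehot, levels = _design_matrix(covs, batch_factor, preserve)
    n_batch = batch_onehot.shape[1]
    n_samples = y.shape[1]
    batch_sizes = batch_onehot.sum(axis=0)
    batch_props = batch_sizes / n_samples

    # per-feature OLS of Y on [batch indicators, preserved covariates]
    b_hat = np.full((design.shape[1], y.shape[0]), np.nan)
    for g in range(y.shape[0]):
        ok = ~np.isnan(y[g])
        b_hat[:, g], *_ = np.linalg.lstsq(design[ok], y[g, ok], rcond=None)

    grand_mean = batch_props @ b_hat[:n_batch]  # per feature
    stand_mean = grand_mean[:, None] + (design[:, n_batch:] @ b_hat[n_batch:]).T
    resid = y - (design @ b_hat).T
    var_pooled = np.nanmean(resid**2, axis=1)

    constant = var_pooled <= 1e-12
    if constant.any():
        names = [str(wide.columns[i]) for i in np.flatnonzero(constant)]
        warnings.warn(
            f"phenotype(s) constant within every batch pass through "
            f"unadjusted: {names}",
            RuntimeWarning,
            stacklevel=2,
        )

    active = ~constant
    z = np.full_like(y, np.nan)
    z[active] = (y[active] - stand_mean[active]) / np.sqrt(
        var_pooled[active, None]
    )

    bayes = y.copy()
    n_feat = int(active.sum())
    for bi, lv in enumerate(levels):
        in_batch = batch_onehot[:, bi].astype(bool)
        sdat = z[np.ix_(active, in_batch)]
        g_hat = np.nanmean(sdat, axis=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            d_hat = np.nanvar(sdat, axis=1, ddof=1)
        d_hat = np.where(np.isnan(d_hat) | (d_hat <= 0), 1.0, d_hat)
        if n_feat >= 2 and d_hat.var(ddof=1) > 0 and g_hat.var(ddof=1) >= 0:
            g_bar, t2 = g_hat.mean(), g_hat.var(ddof=1)
            if t2 <= 0:
                g_star, d_star = g_hat, d_hat
            else:
                a, b = _aprior(d_hat), _bprior(d_hat)
                g_star, d_star = _it_sol(sdat, g_hat, d_hat, g_bar, t2, a, b)
        else:  # too few features for empirical-Bayes pooling
            g_star, d_star = g_hat, d_hat
        adj = (sdat - g_star[:, None]) / np.sqrt(d_star[:, None])
        bayes[np.ix_(active, in_batch)] = (
            adj * np.sqrt(var_pooled[active, None])
            + stand_mean[np.ix_(active, in_batch)]
        )

    adjusted_wide = pd.DataFrame(bayes.T, index=wide.index, columns=wide.columns)
    out = data.data.copy()
    lookup = adjusted_wide.stack()
    keys = list(zip(out["subject_id"], out["phenotype_id"]))
    out["value"] = [lookup.get(k, np.nan) for k in keys]
    return BatchAdjustedTable(out, removed_factors=[batch_factor])


# ---------------------------------------------------------------------------
# Pearson correlation with PSD repair


def estimate_correlation(
    data: PhenotypeTable, min_pairs: int = 30
) -> CorrelationMatrix:
    """Pairwise-complete Pearson correlation of (adjusted) phenotype values.

    Pairs sharing fewer than ``min_pairs`` subjects are set to 0 with a
    warning. If the pairwise-complete matrix is indefinite it is repaired by
    eigenvalue clipping and diagonal rescaling; the result always satisfies
    the correlation-matrix invariants (symmetry, unit diagonal, PSD).
    """
    wide = data.to_wide()
    if wide.shape[1] < 2:
        raise ValueError("need at least 2 phenotypes")
    var = wide.var(ddof=1)
    zero_var = var.index[var.fillna(0.0) == 0].tolist()
    if zero_var:
        raise ValueError(f"zero-variance phenotype(s): {zero_var}")
    corr = wide.corr(method="pearson", min_periods=2).to_numpy()
    present = wide.notna().to_numpy(dtype=float)
    n_pairs = present.T @ present
    low = (n_pairs < min_pairs) & ~np.eye(len(var), dtype=bool)
    if low.any() or np.isnan(corr).any():
        n_low = int(low.sum() // 2 + np.isnan(corr).sum() // 2)
        warnings.warn(
            f"{n_low} phenotype pair(s) share fewer than {min_pairs} subjects; "
            "their correlations are set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
        corr[low] = 0.0
        corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 1.0)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    if np.linalg.eigvalsh(corr).min() < -PSD_TOL:
        logger.info("pairwise-complete correlation indefinite; applying PSD repair")
        corr = nearest_psd_correlation(corr)
    return CorrelationMatrix(corr, [str(c) for c in wide.columns])
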