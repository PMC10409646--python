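"""PVCA, ComBat batch adjustment and Pearson correlation estimation."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from kompute import (
    PhenotypeTable,
    PvcaReport,
    combat_adjust,
    estimate_correlation,
    make_sigma_fixture,
    pvca,
    select_confounders,
)
from conftest import long_table


def test_phenotype_table_rejects_duplicate_measurements():
    df = pd.DataFrame(
        {
            "subject_id": ["s1", "s1"],
            "phenotype_id": ["p0", "p0"],
            "value": [1.0, 2.0],
        }
    )
    with pytest.raises(ValueError, match="multiple values"):
        PhenotypeTable(df)


def test_phenotype_table_rejects_inconsistent_covariates():
    df = pd.DataFrame(
        {
            "subject_id": ["s1", "s1"],
            "phenotype_id": ["p0", "p1"],
            "value": [1.0, 2.0],
            "batch": ["A", "B"],
        }
    )
    with pytest.raises(ValueError, match="varies within subjects"):
        PhenotypeTable(df)


# ---------------------------------------------------------------------------
# PVCA


def _one_way_anova_components(score, groups):
    """From-scratch balanced one-way variance-components fit (oracle)."""
    levels = np.unique(groups)
    n = score.size
    means = np.array([score[groups == lv].mean() for lv in levels])
    msb = np.sum(
        [np.sum(groups == lv) * (mu - score.mean()) ** 2 for lv, mu in zip(levels, means)]
    ) / (len(levels) - 1)
    msw = np.sum(
        [np.sum((score[groups == lv] - mu) ** 2) for lv, mu in zip(levels, means)]
    ) / (n - len(levels))
    n0 = (n - np.sum([(groups == lv).sum() ** 2 for lv in levels]) / n) / (
        len(levels) - 1
    )
    var_b = max((msb - msw) / n0, 0.0)
    return var_b / (var_b + msw)


def test_pvca_detects_a_dominant_batch_factor():
    rng = np.random.default_rng(10)
    n, m = 200, 5
    batch = np.repeat(["b1", "b2"], n // 2)
    sex = rng.choice(["f", "m"], n)
    values = rng.normal(size=(n, m))
    values[batch == "b2"] += 2.0  # 2-SD shift of every phenotype
    tbl = long_table(values, {"batch": batch, "sex": sex})
    report = pvca(tbl, ["batch", "sex"])
    props = report.proportions
    assert props["batch"] > props["sex"]
    assert props["batch"] == max(
        v for k, v in props.items() if k != "residual"
    )
    # oracle: one-way variance components on the first principal component
    x = (values - values.mean(0)) / values.std(0, ddof=1)
    evals, evecs = np.linalg.eigh(np.cov(x, rowvar=False))
    pc1 = x @ evecs[:, -1]
    oracle_share = _one_way_anova_components(pc1, batch)
    assert props["batch"] > 0.5 * oracle_share * (evals[-1] / evals.sum())
    assert abs(sum(props.values()) - 1.0) < 1e-6


def test_pvca_null_covariates_get_tiny_shares():
    rng = np.random.default_rng(11)
    n, m = 500, 6
    values = rng.normal(size=(n, m))
    covs = {
        "batch": rng.permutation(np.repeat(["a", "b", "c"], n // 3 + 1)[:n]),
        "sex": rng.permutation(np.repeat(["f", "m"], n // 2)),
    }
    report = pvca(long_table(values, covs), ["batch", "sex"])
    assert report.proportions["batch"] < 0.05
    assert report.proportions["sex"] < 0.05


def test_pvca_degenerate_inputs_error():
    rng = np.random.default_rng(12)
    one_pheno = long_table(
        rng.normal(size=(50, 1)), {"batch": np.repeat(["a", "b"], 25)}
    )
    with pytest.raises(ValueError, match="at least 2 phenotypes"):
        pvca(one_pheno, ["batch"])
    single_level = long_table(
        rng.normal(size=(50, 3)), {"batch": np.repeat("a", 50)}
    )
    with pytest.raises(ValueError, match="single level"):
        pvca(single_level, ["batch"])


@pytest.mark.parametrize(
    "proportions, minimum, expected",
    [
        ({"center": 0.4, "sex": 0.05, "residual": 0.55}, 0.1, ["center"]),
        ({"center": 0.05, "sex": 0.03, "residual": 0.92}, 0.1, []),
        (
            {"center": 0.4, "sex": 0.05, "residual": 0.55},
            0.0,
            ["center", "sex"],
        ),
    ],
)
def test_select_confounders_threshold(proportions, minimum, expected):
    report = PvcaReport(proportions=proportions)
    assert select_confounders(report, minimum) == expected


# ---------------------------------------------------------------------------
# ComBat


def test_pure_location_batch_effect_removed():
    # noise-free batch offset: standardize each batch exactly, then shift one;
    # empirical-Bayes shrinkage is then an exact no-op and the offset is
    # removed completely
    rng = np.random.default_rng(20)
    n, m = 100, 4
    batch = np.repeat(["b1", "b2"], n // 2)
    values = rng.normal(size=(n, m))
    for b in ("b1", "b2"):
        sel = batch == b
        values[sel] -= values[sel].mean(axis=0)
        values[sel] /= values[sel].std(axis=0)
    values[batch == "b2"] += 3.0
    adj = combat_adjust(long_table(values, {"batch": batch}), "batch")
    wide = adj.to_wide()
    means = wide.groupby(batch).mean()
    assert np.max(np.abs(means.iloc[0] - means.iloc[1]).to_numpy()) < 1e-6


def test_single_batch_passes_through():
    rng = np.random.default_rng(21)
    values = rng.normal(size=(30, 3))
    tbl = long_table(values, {"batch": np.repeat("only", 30)})
    adj = combat_adjust(tbl, "batch")
    pd.testing.assert_frame_equal(adj.to_wide(), tbl.to_wide())


def test_scale_batch_effect_removed():
    rng = np.random.default_rng(22)
    n_per, m = 2000, 5
    batch = np.repeat(["b1", "b2"], n_per)
    values = rng.normal(size=(2 * n_per, m))
    values[batch == "b2"] *= 2.0  # known multiplicative batch effect
    adj = combat_adjust(long_table(values, {"batch": batch}), "batch")
    wide = adj.to_wide()
    v1 = wide.groupby(batch).var()
    # ComBat equalizes batches at the pooled scale: compare across batches.
    # each feature's variance ratio carries sampling noise ~sqrt(4/n)
    ratio = (v1.iloc[0] / v1.iloc[1]).to_numpy()
    se = np.sqrt(2.0 / (n_per - 1) + 2.0 / (n_per - 1))
    assert np.all(np.abs(ratio - 1.0) < 3 * se)
    assert abs(ratio.mean() - 1.0) < 0.05


def test_singleton_batch_is_an_error():
    rng = np.random.default_rng(23)
    batch = np.array(["b1"] * 29 + ["lonely"])
    with pytest.raises(ValueError, match="lonely"):
        combat_adjust(long_table(rng.normal(size=(30, 3)), {"batch": batch}), "batch")


def test_constant_phenotype_passes_through_with_warning():
    rng = np.random.default_rng(24)
    values = rng.normal(size=(40, 3))
    values[:, 1] = 7.0
    batch = np.repeat(["b1", "b2"], 20)
    with pytest.warns(RuntimeWarning, match="constant"):
        adj = combat_adjust(long_table(values, {"batch": batch}), "batch")
    assert np.allclose(adj.to_wide()["p1"].to_numpy(), 7.0)


def test_combat_idempotent_on_location_effects():
    rng = np.random.default_rng(25)
    n, m = 200, 4
    batch = np.repeat(["b1", "b2"], n // 2)
    values = rng.normal(size=(n, m))
    values[batch == "b2"] += 2.0
    once = combat_adjust(long_table(values, {"batch": batch}), "batch")
    twice = combat_adjust(once, "batch")
    diff = np.abs(once.to_wide().to_numpy() - twice.to_wide().to_numpy())
    assert np.nanmax(diff) < 0.05


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript not available")
def test_combat_matches_reference_implementation(tmp_path):
    """Dual-route check against the Bioconductor sva::ComBat implementation."""
    rng = np.random.default_rng(7)
    n, m = 60, 6
    batch = np.repeat(["b1", "b2", "b3"], n // 3)
    sex = rng.choice(["f", "m"], n)
    base = rng.multivariate_normal(
        np.zeros(m), 0.5 * np.ones((m, m)) + 0.5 * np.eye(m), size=n
    )
    offs = {"b1": 0.0, "b2": 1.5, "b3": -1.0}
    scale = {"b1": 1.0, "b2": 2.0, "b3": 0.7}
    values = np.array(
        [
            [
                base[i, j] * scale[batch[i]]
                + offs[batch[i]]
                + (0.3 if sex[i] == "m" else 0.0)
                for j in range(m)
            ]
            for i in range(n)
        ]
    )
    adj = combat_adjust(
        long_table(values, {"batch": batch, "sex": sex}), "batch", ["sex"]
    )
    subj = [f"s{i:05d}" for i in range(n)]
    pd.DataFrame(values, index=subj, columns=[f"p{j}" for j in range(m)]).to_csv(
        tmp_path / "raw.csv"
    )
    pd.DataFrame({"batch": batch, "sex": sex}).to_csv(
        tmp_path / "covs.csv", index=False
    )
    script = tmp_path / "combat.R"
    script.write_text(
        "suppressMessages(library(sva))\n"
        f"raw <- as.matrix(read.csv('{tmp_path}/raw.csv', row.names=1))\n"
        f"covs <- read.csv('{tmp_path}/covs.csv')\n"
        "mod <- model.matrix(~sex, data=covs)\n"
        "out <- ComBat(dat=t(raw), batch=covs$batch, mod=mod, par.prior=TRUE)\n"
        f"write.csv(t(out), '{tmp_path}/ref.csv')\n"
    )
    proc = subprocess.run(
        ["Rscript", str(script)], capture_output=True, text=True, timeout=300
    )
    if proc.returncode != 0:
        pytest.skip(f"reference ComBat unavailable: {proc.stderr[-200:]}")
    ref = pd.read_csv(tmp_path / "ref.csv", index_col=0)
    ours = adj.to_wide()
    diff = np.abs(ours.to_numpy() - ref[ours.columns].loc[ours.index].to_numpy())
    assert np.max(diff) < 1e-3


# ---------------------------------------------------------------------------
# correlation estimation


def test_perfectly_correlated_phenotypes_give_unit_offdiagonal():
    x = np.linspace(-2, 2, 50)
    sigma = estimate_correlation(long_table(np.column_stack([x, 2 * x + 1])))
    assert sigma.values[0, 1] == pytest.approx(1.0, abs=1e-12)


def test_independent_phenotypes_within_sampling_error():
    rng = np.random.default_rng(30)
    sigma = estimate_correlation(long_table(rng.normal(size=(10_000, 4))))
    off = sigma.values[~np.eye(4, dtype=bool)]
    assert np.max(np.abs(off)) < 0.03  # |r| < 3/sqrt(n)


def test_disjoint_subsets_indefinite_matrix_is_repaired():
    # pairwise-complete correlations over disjoint subject subsets can be
    # jointly infeasible (indefinite); construction below forces r(0,1)=r(0,2)=1
    # and r(1,2)=-1
    rng = np.random.default_rng(31)
    n = 120
    x = rng.normal(size=n)
    values = np.full((n, 3), np.nan)
    values[:40, 0] = x[:40]
    values[:40, 1] = x[:40]
    values[40:80, 0] = x[40:80]
    values[40:80, 2] = x[40:80]
    values[80:, 1] = x[80:]
    values[80:, 2] = -x[80:]
    raw = long_table(values).to_wide().corr().to_numpy()
    assert np.linalg.eigvalsh(raw).min() < -1e-8  # genuinely indefinite input
    sigma = estimate_correlation(long_table(values), min_pairs=10)
    assert np.linalg.eigvalsh(sigma.values).min() >= -1e-8
    assert np.allclose(np.diag(sigma.values), 1.0)


def test_sparse_pairs_zeroed_with_warning():
    rng = np.random.default_rng(32)
    values = np.full((100, 3), np.nan)
    values[:, 0] = rng.normal(size=100)
    values[:, 1] = rng.normal(size=100)
    values[:5, 2] = rng.normal(size=5)  # only 5 subjects share p2
    with pytest.warns(RuntimeWarning, match="fewer than"):
        sigma = estimate_correlation(long_table(values), min_pairs=30)
    assert sigma.values[0, 2] == 0.0
    assert sigma.values[1, 2] == 0.0


def test_zero_variance_phenotype_named_in_error():
    values = np.column_stack([np.arange(20.0), np.full(20, 3.0)])
    with pytest.raises(ValueError, match="p1"):
        estimate_correlation(long_table(values))


def test_pipeline_recovers_known_correlation():
    """End-to-end: PVCA -> confounder selection -> ComBat -> Pearson."""
    rng = np.random.default_rng(33)
    m, n = 6, 1500
    truth = make_sigma_fixture(m, "ar1", 0.6).values
    base = rng.multivariate_normal(np.zeros(m), truth, size=n)
    batch = rng.choice(["A", "B", "C"], n)
    offsets = {"A": 0.0, "B": 1.8, "C": -1.2}
    values = base + np.array([offsets[b] for b in batch])[:, None]
    tbl = long_table(values, {"batch": batch})
    confounders = select_confounders(pvca(tbl, ["batch"]))
    assert confounders == ["batch"]
    adjusted = combat_adjust(tbl, "batch")
    sigma = estimate_correlation(adjusted)
    assert np.max(np.abs(sigma.values - truth)) < 0.05
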