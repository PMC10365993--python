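"""Weighted scan estimator oracles, QC, standardization, comparison, clumping."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from wgwas import gwas
from wgwas.synthetic import GenotypeSet


def _geno(dosages: np.ndarray) -> GenotypeSet:
    n, m = dosages.shape
    meta = pd.DataFrame(
        {
            "snp": [f"rs{j}" for j in range(m)],
            "chrom": 1,
            "pos": 1 + 1000 * np.arange(m, dtype=np.int64),
            "a1": "A",
            "a2": "G",
        }
    )
    return GenotypeSet(dosages=dosages.astype(np.int8), snp_meta=meta)


def _dense_wls(Xf: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Direct evaluation of the printed WLS and sandwich formulas."""
    W = np.diag(w)
    A_inv = np.linalg.inv(Xf.T @ W @ Xf)
    beta = A_inv @ Xf.T @ W @ y
    resid = y - Xf @ beta
    D = np.diag(resid**2)
    V = A_inv @ Xf.T @ W @ D @ W @ Xf @ A_inv
    return beta, V


def test_estimator_matches_dense_formulas_no_covariates():
    """Vectorized closed-form scan equals the printed matrix formulas."""
    rng = np.random.default_rng(0)
    for rep in range(20):
        n = 60
        dos = rng.integers(0, 3, size=(n, 3))
        y = rng.normal(size=n)
        w = rng.uniform(0.2, 3.0, size=n)
        g = _geno(dos)
        ss = gwas.run_scan(g, y, weights=w)
        for j in range(3):
            Xf = np.column_stack([dos[:, j].astype(float), np.ones(n)])
            beta, V = _dense_wls(Xf, y, w)
            assert ss["BETA"].iloc[j] == pytest.approx(beta[0], abs=1e-10)
            assert ss["SE"].iloc[j] == pytest.approx(np.sqrt(V[0, 0]), abs=1e-10)


def test_estimator_matches_dense_formulas_with_covariates():
    rng = np.random.default_rng(1)
    for rep in range(20):
        n = 50
        dos = rng.integers(0, 3, size=(n, 2))
        C = rng.normal(size=(n, 2))
        y = rng.normal(size=n)
        w = rng.uniform(0.5, 2.0, size=n)
        g = _geno(dos)
        ss = gwas.run_scan(g, y, covariates=C, weights=w)
        for j in range(2):
            Xf = np.column_stack([dos[:, j].astype(float), C, np.ones(n)])
            beta, V = _dense_wls(Xf, y, w)
            assert ss["BETA"].iloc[j] == pytest.approx(beta[0], abs=1e-10)
            assert ss["SE"].iloc[j] == pytest.approx(np.sqrt(V[0, 0]), abs=1e-10)


def test_unit_weights_equal_ols_and_hc0():
    rng = np.random.default_rng(2)
    n = 80
    dos = rng.integers(0, 3, size=(n, 4))
    y = rng.normal(size=n)
    g = _geno(dos)
    ss_w = gwas.run_scan(g, y, weights=np.ones(n))  # robust by default
    ss_u = gwas.run_scan(g, y)  # OLS, classical
    for j in range(4):
        Xf = sm.add_constant(dos[:, j].astype(float))
        ols = sm.OLS(y, Xf).fit()
        assert ss_u["BETA"].iloc[j] == pytest.approx(ols.params[1], abs=1e-10)
        assert ss_u["SE"].iloc[j] == pytest.approx(ols.bse[1], abs=1e-10)
        hc0 = ols.get_robustcov_results(cov_type="HC0")
        assert ss_w["BETA"].iloc[j] == pytest.approx(ols.params[1], abs=1e-10)
        assert ss_w["SE"].iloc[j] == pytest.approx(hc0.bse[1], abs=1e-10)


def test_missing_dosages_drop_individuals_per_snp():
    rng = np.random.default_rng(3)
    n = 100
    dos = rng.integers(0, 3, size=(n, 2))
    dos[:30, 0] = -1
    y = rng.normal(size=n)
    g = _geno(dos)
    ss = gwas.run_scan(g, y)
    keep = dos[:, 0] >= 0
    Xf = sm.add_constant(dos[keep, 0].astype(float))
    ols = sm.OLS(y[keep], Xf).fit()
    assert ss["BETA"].iloc[0] == pytest.approx(ols.params[1], abs=1e-10)


def test_weighted_scan_reports_effective_n():
    rng = np.random.default_rng(4)
    n = 50
    g = _geno(rng.integers(0, 3, size=(n, 2)))
    w = np.ones(n)
    w[0] = 4.0  # n_eff = (n+3)^2 / (n-1+16)
    ss = gwas.run_scan(g, rng.normal(size=n), weights=w)
    w_in = w / w.mean()
    assert ss["N"].iloc[0] == pytest.approx(w_in.sum() ** 2 / np.sum(w_in**2))


def test_standardize_effects_formula():
    Z, p, n = 2.0, 0.3, 10_000.0
    b, se = gwas.standardize_effects(Z, p, n)
    denom = np.sqrt(2 * p * (1 - p) * (n + Z**2))
    assert se == pytest.approx(1 / denom, rel=1e-12)
    assert b == pytest.approx(Z / denom, rel=1e-12)
    with pytest.raises(ValueError):
        gwas.standardize_effects(1.0, 0.0, 100)
    with pytest.raises(ValueError):
        gwas.standardize_effects(1.0, 0.5, 0)


def test_qc_filter_removes_failing_snps():
    rng = np.random.default_rng(5)
    n = 500
    maf_ok = rng.binomial(2, 0.3, size=(n, 1))
    maf_low = rng.binomial(2, 0.002, size=(n, 1))
    call_low = rng.binomial(2, 0.3, size=(n, 1))
    call_low[: int(0.2 * n)] = -1
    hwe_bad = np.ones((n, 1), dtype=int)  # all hets: gross HWE violation
    dos = np.hstack([maf_ok, maf_low, call_low, hwe_bad])
    g = _geno(dos)
    filtered, report = gwas.qc_filter(g)
    assert report["kept"].tolist() == [True, False, False, False]
    assert bool(report["fail_maf"].iloc[1])
    assert bool(report["fail_call_rate"].iloc[2])
    assert bool(report["fail_hwe"].iloc[3])
    assert filtered.n_snps == 1


def test_hwe_pvalues_uniform_under_hwe(small_genotypes):
    p = gwas.hwe_pvalues(small_genotypes)
    assert (p > 1e-6).mean() >= 0.9999  # HWE-by-construction panel


def test_compare_scans_classes():
    base = pd.DataFrame(
        {
            "SNP": ["a", "b", "c", "d"],
            "CHR": 1,
            "BP": [1, 2, 3, 4],
            "BETA": [1.0, 1.0, 1.0, 0.1],
            "P": [1e-9, 1e-9, 0.5, 0.9],
        }
    )
    ss_w = base.copy()
    ss_w["BETA"] = [0.7, -1.0, 1.0, 0.1]  # reduced 30%, sign flip, -, -
    ss_w["P"] = [1e-9, 0.5, 1e-9, 0.9]
    hits, summary = gwas.compare_scans(base, ss_w, threshold=5e-8)
    assert summary["n_significant_either"] == 3
    assert summary["n_both"] == 1
    assert summary["n_gwa_only"] == 1
    assert summary["n_wgwa_only"] == 1
    a_row = hits[hits["SNP"] == "a"].iloc[0]
    assert a_row["change_class"] == "reduced"
    assert bool(hits[hits["SNP"] == "b"]["sign_flip"].iloc[0])


def test_compare_scans_requires_same_snps():
    ss = pd.DataFrame({"SNP": ["a"], "CHR": 1, "BP": [1], "BETA": [1.0], "P": [0.5]})
    ss2 = ss.copy()
    ss2["SNP"] = ["b"]
    with pytest.raises(ValueError, match="same SNPs"):
        gwas.compare_scans(ss, ss2)


def test_clump_removes_correlated_neighbours(small_genotypes):
    g = small_genotypes
    m = g.n_snps
    rng = np.random.default_rng(6)
    P = rng.uniform(0.5, 1.0, size=m)
    P[10] = 1e-10  # lead in block 3 (SNPs 10-14 correlated, rho=0.3)
    P[11] = 1e-9  # same block: should be absorbed if r2 > 0.1
    P[40] = 1e-12  # distant lead
    ss = pd.DataFrame(
        {
            "SNP": g.snp_meta["snp"],
            "CHR": g.snp_meta["chrom"],
            "BP": g.snp_meta["pos"],
            "P": P,
        }
    )
    leads = gwas.clump(ss, g, window_kb=1e6, r2_max=0.05, threshold=1e-5)
    assert leads[0] == g.snp_meta["snp"].iloc[40]
    assert g.snp_meta["snp"].iloc[10] in leads
    X = g.dosage_float()
    r = np.corrcoef(X[:, 10], X[:, 11])[0, 1]
    if r**2 > 0.05:
        assert g.snp_meta["snp"].iloc[11] not in leads


def test_clump_empty_when_nothing_significant(small_genotypes):
    ss = pd.DataFrame(
        {
            "SNP": small_genotypes.snp_meta["snp"],
            "CHR": small_genotypes.snp_meta["chrom"],
            "BP": small_genotypes.snp_meta["pos"],
            "P": 1.0,
        }
    )
    assert gwas.clump(ss, small_genotypes) == []


def test_sex_scan_returns_both_arms(small_genotypes):
    rng = np.random.default_rng(7)
    n = small_genotypes.n_individuals
    sex = rng.integers(0, 2, size=n).astype(float)
    w = rng.uniform(0.5, 2.0, size=n)
    ss, ss_w = gwas.sex_scan(small_genotypes, sex, weights=w)
    assert not ss.attrs["weighted"] and ss_w.attrs["weighted"]
    assert len(ss) == small_genotypes.n_snps


def test_participation_liability_scan_rejects_constant(small_genotypes):
    n = small_genotypes.n_individuals
    with pytest.raises(ValueError, match="constant"):
        gwas.participation_liability_scan(
            small_genotypes, np.full(n, 0.5), weights=np.ones(n)
        )


def test_compute_pcs_shape_and_determinism(small_genotypes):
    pcs1 = gwas.compute_pcs(small_genotypes, n_components=3, seed=1)
    pcs2 = gwas.compute_pcs(small_genotypes, n_components=3, seed=1)
    assert pcs1.shape == (small_genotypes.n_individuals, 3)
    np.testing.assert_array_equal(pcs1, pcs2)
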