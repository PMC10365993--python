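"""LD-score regression: heritability, genetic correlation, difference tests.

Under a polygenic model, the expected association chi-square of SNP j is
E[chi2_j] = 1 + n h2 l_j / M, where l_j is the LD score (the sum of squared
correlations of SNP j with its neighbours, itself included) and M the
number of SNPs.  Regressing chi2 on n l / M therefore separates polygenic
signal (the slope, h2) from confounding (the intercept).  The cross-trait
analogue regresses Z1*Z2 on sqrt(n1 n2) l / M to estimate the genetic
covariance, and r_g = cov_g / sqrt(h2_1 h2_2).

Standard errors come from a delete-one-block jackknife over contiguous SNP
blocks; the same delete-one series yields the correlation between paired
(weighted vs unweighted) estimates needed by the difference test

    Z = (est_a - est_b) / sqrt(se_a^2 + se_b^2 - 2 r se_a se_b).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import norm

from wgwas.synthetic import GenotypeSet

__all__ = [
    "LdScores",
    "LdscFit",
    "RgFit",
    "DiffTest",
    "compute_ld_scores",
    "estimate_h2",
    "estimate_rg",
    "liability_conversion",
    "jackknife_correlation",
    "difference_test",
]


@dataclass
class LdScores:
    """Per-SNP LD scores and the SNP count M."""

    table: pd.DataFrame  # columns: SNP, L2
    M: int


@dataclass
class LdscFit:
    h2: float
    intercept: float
    se: float
    intercept_se: float
    blocks: np.ndarray  # delete-one-block h2 estimates
    M: int
    n_blocks: int
    h2_liability: Optional[float] = None


@dataclass
class RgFit:
    rg: float
    se: float
    blocks: np.ndarray  # delete-one-block r_g estimates
    gencov: float
    h2_1: float
    h2_2: float
    n_blocks: int
    flag: str = ""


@dataclass
class DiffTest:
    diff: float
    se_diff: float
    r: float
    z: float
    p: float
    p_fdr: Optional[float] = None


# ---------------------------------------------------------------------------
# LD scores
# ---------------------------------------------------------------------------


def compute_ld_scores(g: GenotypeSet, window_kb: float = 1_000.0) -> LdScores:
    """LD scores from a genotype panel.

    l_j = sum over SNPs k within ``window_kb`` of j (same chromosome, self
    included) of the bias-adjusted squared correlation
    r2_adj = r2 - (1 - r2) / (n - 2).
    """
    X = g.dosage_float(imputed=True)
    n = X.shape[0]
    X -= X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    X /= sd

    meta = g.snp_meta
    pos = meta["pos"].to_numpy()
    chrom = meta["chrom"].to_numpy()
    window_bp = window_kb * 1_000.0
    m = g.n_snps
    l2 = np.zeros(m)

    block = 256
    for a in range(0, m, block):
        b = min(a + block, m)
        lo = np.searchsorted(pos, pos[a] - window_bp)
        hi = np.searchsorted(pos, pos[b - 1] + window_bp, side="right")
        R = (X[:, a:b].T @ X[:, lo:hi]) / n
        r2 = R**2
        r2_adj = r2 - (1.0 - r2) / max(n - 2, 1)
        in_window = (
            (np.abs(pos[lo:hi][None, :] - pos[a:b][:, None]) <= window_bp)
            & (chrom[lo:hi][None, :] == chrom[a:b][:, None])
        )
        l2[a:b] = np.where(in_window, r2_adj, 0.0).sum(axis=1)

    return LdScores(table=pd.DataFrame({"SNP": meta["snp"].to_numpy(), "L2": l2}), M=m)


# ---------------------------------------------------------------------------
# Weighted regression with block jackknife (shared machinery)
# ---------------------------------------------------------------------------


def _wls_sufficient(x, y, v):
    return np.array(
        [v.sum(), (v * x).sum(), (v * x * x).sum(), (v * y).sum(), (v * x * y).sum()]
    )


def _wls_from_stats(S):
    """Slope and intercept from (Sv, Svx, Svxx, Svy, Svxy); vectorized."""
    Sv, Svx, Svxx, Svy, Svxy = S[..., 0], S[..., 1], S[..., 2], S[..., 3], S[..., 4]
    denom = Sv * Svxx - Svx**2
    slope = (Sv * Svxy - Svx * Svy) / denom
    intercept = (Svy - slope * Svx) / Sv
    return slope, intercept


def _wls_slope_only(S, intercept: float):
    """Slope with the intercept constrained: Sum v x (y - c) / Sum v x^2."""
    Svx, Svxx, Svxy = S[..., 1], S[..., 2], S[..., 4]
    return (Svxy - intercept * Svx) / Svxx


def _block_stats(x, y, v, n_blocks):
    idx_blocks = np.array_split(np.arange(len(x)), n_blocks)
    stats = np.stack([_wls_sufficient(x[i], y[i], v[i]) for i in idx_blocks])
    return stats


def _jackknife_se(estimates: np.ndarray) -> float:
    B = len(estimates)
    mean = estimates.mean()
    return float(np.sqrt((B - 1) / B * np.sum((estimates - mean) ** 2)))


def _resolve_blocks(m: int, n_blocks: int) -> int:
    if m < n_blocks:
        warnings.warn(
            f"only {m} SNPs for {n_blocks} jackknife blocks; using {m} blocks",
            stacklevel=3,
        )
        return m
    return n_blocks


# ---------------------------------------------------------------------------
# Heritability
# ---------------------------------------------------------------------------


def estimate_h2(
    ss: pd.DataFrame,
    ld: LdScores,
    n: Optional[float] = None,
    n_blocks: int = 200,
    fixed_intercept: Optional[float] = None,
) -> LdscFit:
    """Univariate LD-score regression.

    Regresses chi2 = Z^2 on n l / M with a free intercept, using
    heteroskedasticity weights 1 / max(l, 1).  The slope is the observed-
    scale h2; the intercept is ~1 absent confounding.  SEs come from a
    200-block delete-one jackknife over contiguous SNP blocks.

    ``fixed_intercept`` constrains the intercept to the given value (the
    analogue of LDSC's --intercept-h2 constraint): the slope becomes a
    regression of chi2 - intercept through the origin, which sharpens the
    slope SE considerably when confounding is known to be absent — e.g. in
    simulation studies or when the polygenic signal is weak relative to
    the free-intercept sampling noise of a small SNP panel.
    """
    merged = ss.merge(ld.table, on="SNP", how="inner")
    if merged.empty:
        raise ValueError("no shared SNPs between summary stats and LD scores")
    z = merged["Z"].to_numpy(dtype=float)
    l2 = merged["L2"].to_numpy(dtype=float)
    n_vec = np.full(len(merged), float(n)) if n is not None else merged["N"].to_numpy(dtype=float)

    x = n_vec * l2 / ld.M
    y = z**2
    v = 1.0 / np.maximum(l2, 1.0)

    n_blocks = _resolve_blocks(len(x), n_blocks)
    stats = _block_stats(x, y, v, n_blocks)
    total = stats.sum(axis=0)
    del_stats = total[None, :] - stats
    if fixed_intercept is None:
        slope, intercept = _wls_from_stats(total)
        slopes_d, intercepts_d = _wls_from_stats(del_stats)
        intercept_se = _jackknife_se(intercepts_d)
    else:
        slope, intercept = _wls_slope_only(total, fixed_intercept), fixed_intercept
        slopes_d = _wls_slope_only(del_stats, fixed_intercept)
        intercept_se = 0.0

    return LdscFit(
        h2=float(slope),
        intercept=float(intercept),
        se=_jackknife_se(slopes_d),
        intercept_se=intercept_se,
        blocks=slopes_d,
        M=ld.M,
        n_blocks=n_blocks,
    )


def liability_conversion(h2_obs: float, K: float, P_sample: float) -> float:
    """Observed-scale to liability-scale heritability for a binary trait.

    h2_liab = h2_obs * K^2 (1 - K)^2 / (P (1 - P) z^2) where K is the
    population prevalence, P the (weighted) sample prevalence and z the
    standard normal density at the K-quantile threshold.  The weighted arm
    passes the weighted prevalence as K.
    """
    if not (0.0 < K < 1.0) or not (0.0 < P_sample < 1.0):
        raise ValueError("prevalences must lie strictly in (0, 1)")
    z = norm.pdf(norm.ppf(1.0 - K))
    return h2_obs * K**2 * (1.0 - K) ** 2 / (P_sample * (1.0 - P_sample) * z**2)


# ---------------------------------------------------------------------------
# Genetic correlation
# ---------------------------------------------------------------------------


def _align(ss1: pd.DataFrame, ss2: pd.DataFrame) -> pd.DataFrame:
    merged = ss1.merge(ss2, on="SNP", suffixes=("_1", "_2"))
    same = (merged["A1_1"] == merged["A1_2"]) & (merged["A2_1"] == merged["A2_2"])
    flipped = (merged["A1_1"] == merged["A2_2"]) & (merged["A2_1"] == merged["A1_2"])
    if not (same | flipped).all():
        bad = merged.loc[~(same | flipped), "SNP"].head().tolist()
        raise ValueError(f"allele mismatch between summary stats, e.g. {bad}")
    merged.loc[flipped, "Z_2"] = -merged.loc[flipped, "Z_2"]
    return merged


def estimate_rg(
    ss1: pd.DataFrame,
    ss2: pd.DataFrame,
    ld: LdScores,
    n1: Optional[float] = None,
    n2: Optional[float] = None,
    n_blocks: int = 200,
) -> RgFit:
    """Cross-trait LD-score regression genetic correlation.

    The product Z1*Z2 is regressed on sqrt(n1 n2) l / M to estimate the
    genetic covariance; r_g = cov_g / sqrt(h2_1 h2_2).  The delete-one-block
    series recomputes all three regressions per deletion, so the jackknife
    SE and the paired-estimate correlation reflect the full estimator.
    """
    merged = _align(ss1, ss2).merge(ld.table, on="SNP", how="inner")
    if merged.empty:
        raise ValueError("no shared SNPs")
    z1 = merged["Z_1"].to_numpy(dtype=float)
    z2 = merged["Z_2"].to_numpy(dtype=float)
    l2 = merged["L2"].to_numpy(dtype=float)
    n1v = np.full(len(merged), float(n1)) if n1 is not None else merged["N_1"].to_numpy(float)
    n2v = np.full(len(merged), float(n2)) if n2 is not None else merged["N_2"].to_numpy(float)

    v = 1.0 / np.maximum(l2, 1.0)
    x1 = n1v * l2 / ld.M
    x2 = n2v * l2 / ld.M
    xc = np.sqrt(n1v * n2v) * l2 / ld.M

    n_blocks = _resolve_blocks(len(l2), n_blocks)
    s1 = _block_stats(x1, z1**2, v, n_blocks)
    s2 = _block_stats(x2, z2**2, v, n_blocks)
    sc = _block_stats(xc, z1 * z2, v, n_blocks)

    h2_1, _ = _wls_from_stats(s1.sum(axis=0))
    h2_2, _ = _wls_from_stats(s2.sum(axis=0))
    gencov, _ = _wls_from_stats(sc.sum(axis=0))

    flag = ""
    if h2_1 <= 0 or h2_2 <= 0:
        return RgFit(
            rg=np.nan, se=np.nan, blocks=np.full(n_blocks, np.nan),
            gencov=float(gencov), h2_1=float(h2_1), h2_2=float(h2_2),
            n_blocks=n_blocks, flag="non-positive heritability",
        )

    d1 = s1.sum(axis=0)[None, :] - s1
    d2 = s2.sum(axis=0)[None, :] - s2
    dc = sc.sum(axis=0)[None, :] - sc
    h1_d, _ = _wls_from_stats(d1)
    h2_d, _ = _wls_from_stats(d2)
    gc_d, _ = _wls_from_stats(dc)
    with np.errstate(invalid="ignore"):
        rg_d = gc_d / np.sqrt(h1_d * h2_d)
    rg = float(gencov / np.sqrt(h2_1 * h2_2))
    if not -1.0 <= rg <= 1.0:
        flag = "r_g outside [-1, 1] (sampling noise)"
    valid = np.isfinite(rg_d)
    if not valid.all():
        flag = (flag + "; " if flag else "") + "non-positive h2 in some jackknife blocks"
    se = _jackknife_se(rg_d[valid]) if valid.sum() >= 2 else np.nan
    return RgFit(
        rg=rg, se=se, blocks=rg_d, gencov=float(gencov),
        h2_1=float(h2_1), h2_2=float(h2_2), n_blocks=n_blocks, flag=flag,
    )


# ---------------------------------------------------------------------------
# Paired difference test
# ---------------------------------------------------------------------------


def jackknife_correlation(est_blocks_a: np.ndarray, est_blocks_b: np.ndarray) -> float:
    """Correlation between paired estimates from delete-one-block series.

    Computed directly on the delete-one estimates (for equal block sizes
    this is invariant to the affine pseudovalue transform).  Zero variance
    in either series yields 0 with a warning.
    """
    a = np.asarray(est_blocks_a, dtype=float)
    b = np.asarray(est_blocks_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired series must have equal length")
    valid = np.isfinite(a) & np.isfinite(b)
    a, b = a[valid], b[valid]
    if len(a) < 2 or a.std() == 0.0 or b.std() == 0.0:
        warnings.warn("zero variance in jackknife series; correlation set to 0", stacklevel=2)
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def difference_test(
    est_a: float, est_b: float, se_a: float, se_b: float, r: float
) -> DiffTest:
    """Z-test of a paired difference with jackknife-derived correlation.

    diff = est_a - est_b with
    se_diff = sqrt(se_a^2 + se_b^2 - 2 r se_a se_b); the correlation r
    between the two estimates comes from their shared-data jackknife.
    """
    for val in (est_a, est_b, se_a, se_b, r):
        if not np.isfinite(val):
            raise ValueError("difference test requires finite inputs")
    if not -1.0 <= r <= 1.0:
        raise ValueError("r must lie in [-1, 1]")
    var_diff = se_a**2 + se_b**2 - 2.0 * r * se_a * se_b
    if var_diff <= 0.0:
        if est_a == est_b:
            return DiffTest(diff=0.0, se_diff=0.0, r=r, z=0.0, p=1.0)
        raise ValueError("non-positive variance of the difference: inconsistent inputs")
    se_diff = float(np.sqrt(var_diff))
    diff = est_a - est_b
    z = diff / se_diff
    return DiffTest(diff=float(diff), se_diff=se_diff, r=float(r), z=float(z),
                    p=float(2.0 * norm.sf(abs(z))))
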