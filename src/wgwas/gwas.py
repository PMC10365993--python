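"""Weighted and unweighted per-SNP association scans.

The weighted estimator is weighted least squares on X = [snp, covariates,
intercept]:

    beta_w = (X' W X)^-1 X' W Y

with W the diagonal matrix of participation weights.  Because weighting
breaks homoskedasticity, the variance is the Huber–White sandwich

    Var(beta_w) = (X' W X)^-1 (X' W D W X) (X' W X)^-1,
    D = diag[(Y - X beta_w)^2].

The unweighted scan is ordinary least squares with the classical
homoskedastic variance (a flag switches both arms to robust variance).
Binary outcomes are scanned with the same linear model so that effects can
be standardized and compared across arms.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from wgwas.synthetic import GenotypeSet

__all__ = [
    "qc_filter",
    "run_scan",
    "standardize_effects",
    "compare_scans",
    "participation_liability_scan",
    "sex_scan",
    "clump",
    "compute_pcs",
    "hwe_pvalues",
]

SUMMARY_COLUMNS = [
    "SNP", "CHR", "BP", "A1", "A2", "FREQ",
    "BETA", "SE", "Z", "P", "N", "BETA_STD", "SE_STD",
]


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------


def hwe_pvalues(g: GenotypeSet) -> np.ndarray:
    """Chi-square Hardy–Weinberg equilibrium P per SNP (1 d.f.)."""
    from scipy.stats import chi2

    dos = g.dosages
    present = dos >= 0
    n = present.sum(axis=0).astype(float)
    n0 = ((dos == 0) & present).sum(axis=0).astype(float)
    n1 = ((dos == 1) & present).sum(axis=0).astype(float)
    n2 = ((dos == 2) & present).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = (n1 + 2.0 * n2) / (2.0 * n)
        e0 = n * (1.0 - p) ** 2
        e1 = n * 2.0 * p * (1.0 - p)
        e2 = n * p**2
        stat = np.zeros(g.n_snps)
        for obs, exp in ((n0, e0), (n1, e1), (n2, e2)):
            term = np.where(exp > 0, (obs - exp) ** 2 / np.where(exp > 0, exp, 1.0), 0.0)
            stat += term
        pvals = chi2.sf(stat, df=1)
    # monomorphic SNPs: HWE trivially satisfied
    mono = (p <= 0.0) | (p >= 1.0)
    pvals = np.where(mono, 1.0, pvals)
    return pvals


def qc_filter(
    g: GenotypeSet,
    maf_min: float = 0.01,
    call_rate_min: float = 0.90,
    hwe_p_min: float = 1e-6,
) -> tuple[GenotypeSet, pd.DataFrame]:
    """Standard per-SNP quality control.

    Keeps SNPs with minor allele frequency > ``maf_min``, call rate >
    ``call_rate_min`` and Hardy–Weinberg chi-square P > ``hwe_p_min``.
    Returns the filtered set and a per-SNP report of removal reasons.
    """
    present = g.dosages >= 0
    call_rate = present.mean(axis=0)
    freq = g.allele_frequencies()
    maf = np.minimum(freq, 1.0 - freq)
    hwe_p = hwe_pvalues(g)

    fail_maf = ~(maf > maf_min)
    fail_call = ~(call_rate > call_rate_min)
    fail_hwe = ~(hwe_p > hwe_p_min)
    keep = ~(fail_maf | fail_call | fail_hwe)

    report = pd.DataFrame(
        {
            "snp": g.snp_meta["snp"].to_numpy(),
            "maf": maf,
            "call_rate": call_rate,
            "hwe_p": hwe_p,
            "fail_maf": fail_maf,
            "fail_call_rate": fail_call,
            "fail_hwe": fail_hwe,
            "kept": keep,
        }
    )
    if not keep.any():
        warnings.warn("QC removed every SNP", stacklevel=2)
    filtered = g.subset(snps=np.flatnonzero(keep))
    return filtered, report


# ---------------------------------------------------------------------------
# Effect standardization
# ---------------------------------------------------------------------------


def standardize_effects(Z, p, n):
    """Standardized SNP effect and its standard error from (Z, freq, n).

    beta_STD = Z / sqrt(2 p (1 - p) (n + Z^2)) and
    s.e.(beta_STD) = 1 / sqrt(2 p (1 - p) (n + Z^2)); the weighted arm
    passes the effective sample size and weighted allele frequency.
    """
    Z = np.asarray(Z, dtype=float)
    p = np.asarray(p, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any((p <= 0.0) | (p >= 1.0)):
        raise ValueError("allele frequency must lie strictly in (0, 1)")
    if np.any(n <= 0):
        raise ValueError("sample size must be positive")
    se = 1.0 / np.sqrt(2.0 * p * (1.0 - p) * (n + Z**2))
    return Z * se, se


# ---------------------------------------------------------------------------
# Association scans
# ---------------------------------------------------------------------------


def _scan_no_covariates(X_int, present, y, w, robust):
    """Closed-form simple weighted regression, vectorized over SNP chunks.

    X_int: int8 dosages (missing < 0); returns beta, se, freq arrays.
    Missing dosages drop the individual for that SNP only (the per-SNP
    effective weight is zero).
    """
    n, m = X_int.shape
    beta = np.empty(m)
    se = np.empty(m)
    freq = np.empty(m)
    chunk = max(1, int(2**22 // max(n, 1)))  # ~32 MB float64 residual blocks
    for a in range(0, m, chunk):
        b = min(a + chunk, m)
        Xc = X_int[:, a:b].astype(np.float64)
        pres = present[:, a:b]
        Xc[~pres] = 0.0
        wm = w[:, None] * pres  # per-(i, snp) effective weights
        S0 = wm.sum(axis=0)
        Sx = (w @ np.where(pres, Xc, 0.0))
        Sxx = (w @ np.where(pres, Xc**2, 0.0))
        Sy = ((w * y) @ pres)
        Sxy = ((w * y) @ Xc)
        denom = S0 * Sxx - Sx**2
        slope = (S0 * Sxy - Sx * Sy) / denom
        alpha = (Sy - slope * Sx) / S0
        freq[a:b] = Sx / (2.0 * S0)

        R = (y[:, None] - alpha[None, :] - Xc * slope[None, :]) * pres
        if robust:
            # sandwich (X'WX)^-1 (X'WDWX) (X'WX)^-1, slope element
            w2r2 = (w[:, None] ** 2) * R**2
            m11 = (w2r2 * Xc**2).sum(axis=0)
            m12 = (w2r2 * Xc).sum(axis=0)
            m22 = w2r2.sum(axis=0)
            # (A^-1 M A^-1)[slope, slope] with A = [[Sxx, Sx], [Sx, S0]]
            var = (S0**2 * m11 - 2.0 * S0 * Sx * m12 + Sx**2 * m22) / denom**2
        else:
            n_eff = pres.sum(axis=0).astype(float)
            rss = (wm * R**2).sum(axis=0)
            sigma2 = rss / np.maximum(n_eff - 2.0, 1.0)
            var = sigma2 * S0 / denom
        beta[a:b] = slope
        se[a:b] = np.sqrt(np.maximum(var, 0.0))
    return beta, se, freq


def _scan_with_covariates(X_int, present, y, w, C, robust):
    """Per-SNP dense solve of the printed WLS + sandwich formulas."""
    n, m = X_int.shape
    k = C.shape[1] + 2  # snp + covariates + intercept
    beta = np.full(m, np.nan)
    se = np.full(m, np.nan)
    freq = np.full(m, np.nan)
    skipped = []
    ones = np.ones(n)
    for j in range(m):
        pres = present[:, j]
        x = X_int[pres, j].astype(np.float64)
        Xf = np.column_stack([x, C[pres], ones[pres]])
        wj = w[pres]
        yj = y[pres]
        A = Xf.T @ (wj[:, None] * Xf)
        bvec = Xf.T @ (wj * yj)
        try:
            Ainv = np.linalg.inv(A)
        except np.linalg.LinAlgError:
            skipped.append((j, "rank-deficient design"))
            continue
        if np.linalg.cond(A) > 1e12:
            skipped.append((j, "rank-deficient design"))
            continue
        coefs = Ainv @ bvec
        resid = yj - Xf @ coefs
        if robust:
            meat = Xf.T @ ((wj**2 * resid**2)[:, None] * Xf)
            V = Ainv @ meat @ Ainv
        else:
            sigma2 = np.sum(wj * resid**2) / max(len(yj) - k, 1)
            V = sigma2 * Ainv
        beta[j] = coefs[0]
        se[j] = np.sqrt(max(V[0, 0], 0.0))
        freq[j] = np.sum(wj * x) / (2.0 * np.sum(wj))
    return beta, se, freq, skipped


def run_scan(
    g: GenotypeSet,
    y: np.ndarray,
    covariates: Optional[np.ndarray] = None,
    weights: Optional[np.ndarray] = None,
    robust: Optional[bool] = None,
) -> pd.DataFrame:
    """Per-SNP (weighted) least-squares association scan.

    ``weights`` are the per-individual participation weights (any positive
    scale); when absent the scan is ordinary least squares.  ``robust``
    defaults to True for weighted scans (Huber–White sandwich) and False
    for unweighted scans (classical variance).  Individuals with missing
    phenotype are dropped for every SNP; individuals with a missing call
    are dropped for that SNP only.  Two-sided P-values use the normal
    approximation; N reports the effective sample size for weighted scans.
    """
    y = np.asarray(y, dtype=float)
    if len(y) != g.n_individuals:
        raise ValueError("phenotype length must match individuals")
    weighted = weights is not None
    if robust is None:
        robust = weighted
    w = np.ones(len(y)) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")

    keep = np.isfinite(y) & (w > 0)
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        keep &= np.all(np.isfinite(C), axis=1)
    y_k = y[keep]
    w_k = w[keep]
    dos = g.dosages[keep]
    present = dos >= 0

    skipped: list = []
    if covariates is None:
        beta, se, freq = _scan_no_covariates(dos, present, y_k, w_k, robust)
    else:
        beta, se, freq, skipped = _scan_with_covariates(
            dos, present, y_k, w_k, C[keep], robust
        )
    for j, reason in skipped:
        warnings.warn(f"SNP {g.snp_meta['snp'].iloc[j]} skipped: {reason}", stacklevel=2)

    with np.errstate(invalid="ignore", divide="ignore"):
        Z = beta / se
    P = 2.0 * norm.sf(np.abs(Z))

    if weighted:
        w_in = w_k / w_k.mean()
        n_rep = float(w_in.sum() ** 2 / np.sum(w_in**2))
    else:
        n_rep = float(len(y_k))

    ok = np.isfinite(Z) & (freq > 0.0) & (freq < 1.0)
    beta_std = np.full_like(beta, np.nan)
    se_std = np.full_like(beta, np.nan)
    if ok.any():
        beta_std[ok], se_std[ok] = standardize_effects(Z[ok], freq[ok], n_rep)

    out = pd.DataFrame(
        {
            "SNP": g.snp_meta["snp"].to_numpy(),
            "CHR": g.snp_meta["chrom"].to_numpy(),
            "BP": g.snp_meta["pos"].to_numpy(),
            "A1": g.snp_meta["a1"].to_numpy(),
            "A2": g.snp_meta["a2"].to_numpy(),
            "FREQ": freq,
            "BETA": beta,
            "SE": se,
            "Z": Z,
            "P": P,
            "N": n_rep,
            "BETA_STD": beta_std,
            "SE_STD": se_std,
        }
    )
    out.attrs["weighted"] = weighted
    out.attrs["robust"] = robust
    return out


def participation_liability_scan(
    g: GenotypeSet,
    P: np.ndarray,
    weights: np.ndarray,
    covariates: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Weighted scan with the participation probability as the outcome.

    A standard (unweighted) scan of participation is impossible because the
    analysis sample is itself conditioned on participating; the weighted
    scan of the fitted liability P_i is the feasible proxy.
    """
    P = np.asarray(P, dtype=float)
    if np.nanstd(P) == 0:
        raise ValueError("participation probability is constant")
    ss = run_scan(g, P, covariates=covariates, weights=weights)
    ss.attrs["outcome"] = "participation_liability"
    return ss


def sex_scan(
    g: GenotypeSet,
    sex: np.ndarray,
    weights: np.ndarray,
    covariates: Optional[np.ndarray] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Autosomal scans of biological sex (0/1), unweighted and weighted.

    Autosomal SNP effects on sex can only arise from artefacts such as
    sex-differential participation, so attenuation under weighting is the
    expected signature of bias correction.
    """
    sex = np.asarray(sex, dtype=float)
    ss = run_scan(g, sex, covariates=covariates, weights=None)
    ss_w = run_scan(g, sex, covariates=covariates, weights=weights)
    return ss, ss_w


# ---------------------------------------------------------------------------
# Comparison of scans
# ---------------------------------------------------------------------------


def compare_scans(
    ss: pd.DataFrame, ss_w: pd.DataFrame, threshold: float = 5e-8
) -> tuple[pd.DataFrame, dict]:
    """Classify SNPs significant in either arm by discovery and effect change.

    Discovery class: GWA-only / wGWA-only / both at ``threshold``.
    Relative change (|beta| - |beta_w|) / |beta| is classed ``reduced`` when
    >= 0.2, ``increased`` when <= -0.2, else ``stable``; sign flips are
    flagged separately.
    """
    if not ss["SNP"].equals(ss_w["SNP"]):
        raise ValueError("scans must cover the same SNPs in the same order")
    merged = ss[["SNP", "CHR", "BP", "BETA", "P"]].merge(
        ss_w[["SNP", "BETA", "P"]], on="SNP", suffixes=("", "_w")
    )
    sig = merged["P"] < threshold
    sig_w = merged["P_w"] < threshold
    hits = merged[sig | sig_w].copy()
    sig_h = hits["P"] < threshold
    sig_wh = hits["P_w"] < threshold
    hits["discovery"] = np.select(
        [sig_h & sig_wh, sig_h & ~sig_wh, ~sig_h & sig_wh],
        ["both", "GWA-only", "wGWA-only"],
        default="",  # unreachable: every row is significant in some arm
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = (hits["BETA"].abs() - hits["BETA_w"].abs()) / hits["BETA"].abs()
    hits["relative_change"] = rel
    hits["change_class"] = np.select(
        [rel >= 0.2, rel <= -0.2], ["reduced", "increased"], default="stable"
    )
    hits["sign_flip"] = np.sign(hits["BETA"]) != np.sign(hits["BETA_w"])

    n_hits = len(hits)
    summary = {
        "n_significant_either": n_hits,
        "n_both": int((hits["discovery"] == "both").sum()),
        "n_gwa_only": int((hits["discovery"] == "GWA-only").sum()),
        "n_wgwa_only": int((hits["discovery"] == "wGWA-only").sum()),
        "n_reduced": int((hits["change_class"] == "reduced").sum()),
        "n_increased": int((hits["change_class"] == "increased").sum()),
        "n_stable": int((hits["change_class"] == "stable").sum()),
        "n_sign_flips": int(hits["sign_flip"].sum()),
    }
    if n_hits:
        summary["prop_reduced"] = summary["n_reduced"] / n_hits
        summary["prop_increased"] = summary["n_increased"] / n_hits
        summary["prop_wgwa_only"] = summary["n_wgwa_only"] / n_hits
    return hits.reset_index(drop=True), summary


# ---------------------------------------------------------------------------
# Clumping and PCs
# ---------------------------------------------------------------------------


def clump(
    ss: pd.DataFrame,
    g: GenotypeSet,
    window_kb: float = 250.0,
    r2_max: float = 0.1,
    threshold: float = 5e-8,
) -> list[str]:
    """Greedy LD clumping of significant SNPs.

    Repeatedly takes the smallest-P unassigned SNP below ``threshold`` as a
    lead SNP and removes all SNPs on the same chromosome within
    ``window_kb`` kilobases whose squared correlation with the lead exceeds
    ``r2_max``.  Returns lead SNP identifiers in selection order.
    """
    meta = g.snp_meta
    pos = meta["pos"].to_numpy()
    for chrom, grp in meta.groupby("chrom", sort=False):
        if np.any(np.diff(grp["pos"].to_numpy()) <= 0):
            raise ValueError("positions must be sorted and unique for clumping")
    order = {s: i for i, s in enumerate(meta["snp"])}
    sig = ss[ss["P"] < threshold].sort_values("P")
    if sig.empty:
        return []
    X = g.dosage_float(imputed=True)
    Xc = X - X.mean(axis=0)
    sd = Xc.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = Xc / sd
    n = X.shape[0]

    window_bp = window_kb * 1_000.0
    available = set(sig["SNP"])
    leads: list[str] = []
    chrom_arr = meta["chrom"].to_numpy()
    for snp in sig["SNP"]:
        if snp not in available:
            continue
        leads.append(snp)
        available.discard(snp)
        j = order[snp]
        near = np.flatnonzero(
            (chrom_arr == chrom_arr[j]) & (np.abs(pos - pos[j]) <= window_bp)
        )
        if near.size:
            r = (Xs[:, near].T @ Xs[:, j]) / n
            for idx, r2 in zip(near, r**2):
                name = meta["snp"].iloc[idx]
                if name in available and r2 > r2_max:
                    available.discard(name)
    return leads


def compute_pcs(g: GenotypeSet, n_components: int = 5, seed: int = 0) -> np.ndarray:
    """Leading principal components of the standardized dosage matrix."""
    from sklearn.utils.extmath import randomized_svd

    X = g.dosage_float(imputed=True)
    X -= X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    X /= sd
    U, S, _ = randomized_svd(X, n_components=n_components, random_state=seed)
    return U * S
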