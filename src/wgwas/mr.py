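"""Inverse-variance-weighted Mendelian randomization with selection correction.

Instruments are LD-independent SNPs reaching genome-wide significance in
either the standard or the weighted scan of the exposure (the union rule).
The IVW estimator combines per-SNP ratio estimates
alpha_j = beta_out_j / beta_exp_j with weights (beta_exp_j / se_out_j)^2,
equivalent to weighted through-origin regression of outcome on exposure
effects.  Because IVW treats exposure effects as noise-free, instruments
selected in one arm but evaluated in the other suffer regression dilution;
the correction rescales by S^2 / sigma2_hat, the ratio of the observed
exposure-effect variance to its noise-free part:

    S^2     = (1 / (m - 1)) sum (beta_exp_j - mean)^2
    sigma2  = S^2 - (1 / m) sum Var(beta_exp_j)
    alpha_corrected = alpha_IVW * S^2 / sigma2
    Var(alpha_corrected) = Var(alpha_IVW) * S^2 / sigma2.

Weighted vs standard MR estimates are compared with a Z-test whose paired
correlation comes from a leave-one-SNP-out jackknife.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import norm, t as student_t
from statsmodels.stats.multitest import multipletests

from wgwas.gwas import clump
from wgwas.ldsc import jackknife_correlation
from wgwas.synthetic import GenotypeSet

__all__ = [
    "InsufficientInstruments",
    "MrFit",
    "MrComparison",
    "select_instruments",
    "harmonize_instruments",
    "ivw",
    "corrected_ivw",
    "mr_difference",
    "fdr_adjust",
]


class InsufficientInstruments(ValueError):
    """Raised when an exposure yields fewer instruments than the minimum."""


@dataclass
class MrFit:
    alpha: float
    var_alpha: float
    m: int
    ratio_estimates: np.ndarray
    alpha_corrected: Optional[float] = None
    var_alpha_corrected: Optional[float] = None
    S2: Optional[float] = None
    sigma2: Optional[float] = None
    correction_flag: str = ""

    @property
    def se(self) -> float:
        return float(np.sqrt(self.var_alpha))

    @property
    def se_corrected(self) -> Optional[float]:
        if self.var_alpha_corrected is None:
            return None
        return float(np.sqrt(self.var_alpha_corrected))


@dataclass
class MrComparison:
    alpha: float
    alpha_w: float
    diff: float
    se_diff: float
    r: float
    z: float
    p: float
    se_jk: Optional[float] = None
    se_w_jk: Optional[float] = None
    p_fdr: Optional[float] = None


# ---------------------------------------------------------------------------
# Instrument selection
# ---------------------------------------------------------------------------


def select_instruments(
    ss_exp: pd.DataFrame,
    ss_exp_w: pd.DataFrame,
    g: GenotypeSet,
    threshold: float = 5e-8,
    window_kb: float = 10_000.0,
    r2_max: float = 0.001,
    min_instruments: int = 10,
    allow_few: bool = False,
) -> pd.DataFrame:
    """Union-rule instrument selection with greedy clumping.

    SNPs genome-wide significant in either arm are pooled and clumped
    greedily on the smaller of the two arms' P-values.  Each retained lead
    SNP carries a discovery flag (``GWA``, ``wGWA`` or ``both``).  Fewer
    than ``min_instruments`` leads raises :class:`InsufficientInstruments`
    unless ``allow_few`` is set.
    """
    if not ss_exp["SNP"].equals(ss_exp_w["SNP"]):
        raise ValueError("exposure scans must cover the same SNP universe")
    pooled = ss_exp[["SNP", "CHR", "BP", "P"]].merge(
        ss_exp_w[["SNP", "P"]], on="SNP", suffixes=("", "_w")
    )
    pooled["P_min"] = pooled[["P", "P_w"]].min(axis=1)
    sig = pooled["P"] < threshold
    sig_w = pooled["P_w"] < threshold
    pooled["discovery"] = np.select(
        [sig & sig_w, sig & ~sig_w, ~sig & sig_w],
        ["both", "GWA", "wGWA"],
        default="none",
    )
    clump_input = pooled.rename(columns={"P_min": "P_clump"})[
        ["SNP", "CHR", "BP", "P_clump", "discovery"]
    ].rename(columns={"P_clump": "P"})
    leads = clump(clump_input, g, window_kb=window_kb, r2_max=r2_max, threshold=threshold)
    out = clump_input[clump_input["SNP"].isin(leads)].reset_index(drop=True)
    if len(out) < min_instruments and not allow_few:
        raise InsufficientInstruments(
            f"{len(out)} instruments found; minimum is {min_instruments}"
        )
    return out


def harmonize_instruments(
    instruments: pd.DataFrame,
    ss_exp: pd.DataFrame,
    ss_out: pd.DataFrame,
    ss_exp_w: pd.DataFrame,
    ss_out_w: pd.DataFrame,
) -> pd.DataFrame:
    """Attach standardized exposure/outcome effects from both arms.

    Effects are taken on the standardized (BETA_STD / SE_STD) scale so
    weighted and unweighted estimates are directly comparable.
    """
    out = instruments[["SNP", "discovery"]].copy()
    for tag, ss in (
        ("exp", ss_exp),
        ("out", ss_out),
        ("exp_w", ss_exp_w),
        ("out_w", ss_out_w),
    ):
        sub = ss[["SNP", "BETA_STD", "SE_STD"]].rename(
            columns={"BETA_STD": f"beta_{tag}", "SE_STD": f"se_{tag}"}
        )
        out = out.merge(sub, on="SNP", how="inner")
    return out


# ---------------------------------------------------------------------------
# Estimators
# ---------------------------------------------------------------------------


def ivw(beta_exp, se_exp, beta_out, se_out) -> MrFit:
    """Fixed-effect inverse-variance-weighted MR estimate.

    alpha = sum u_j alpha_j / sum u_j with alpha_j = beta_out_j /
    beta_exp_j and u_j = (beta_exp_j / se_out_j)^2; Var = 1 / sum u_j.
    SNPs with a zero exposure effect are dropped with a warning.
    """
    beta_exp = np.asarray(beta_exp, dtype=float)
    se_exp = np.asarray(se_exp, dtype=float)
    beta_out = np.asarray(beta_out, dtype=float)
    se_out = np.asarray(se_out, dtype=float)
    keep = beta_exp != 0.0
    if not keep.all():
        warnings.warn(f"dropping {np.sum(~keep)} instruments with zero exposure beta",
                      stacklevel=2)
        beta_exp, se_exp, beta_out, se_out = (
            beta_exp[keep], se_exp[keep], beta_out[keep], se_out[keep]
        )
    m = len(beta_exp)
    if m == 0:
        raise ValueError("no usable instruments")
    u = (beta_exp / se_out) ** 2
    ratios = beta_out / beta_exp
    alpha = float(np.sum(u * ratios) / np.sum(u))
    var = float(1.0 / np.sum(u))
    return MrFit(alpha=alpha, var_alpha=var, m=m, ratio_estimates=ratios)


def corrected_ivw(
    fit: MrFit, beta_exp, se_exp, as_printed: bool = False
) -> MrFit:
    """Selection (regression-dilution) correction of an IVW fit.

    The attenuation factor S^2 / sigma2 rescales both the estimate and its
    variance (``as_printed=True`` instead divides the estimate by the
    standard deviation sigma rather than the variance sigma2, for audit).
    With noise-free exposure effects the factor is 1.  When the noise
    variance exceeds the observed spread (sigma2 <= 0) the correction is
    undefined and the uncorrected fit is returned flagged.
    """
    beta_exp = np.asarray(beta_exp, dtype=float)
    se_exp = np.asarray(se_exp, dtype=float)
    m = len(beta_exp)
    if m < 2:
        raise ValueError("correction needs at least 2 instruments")
    S2 = float(np.var(beta_exp, ddof=1))
    sigma2 = S2 - float(np.mean(se_exp**2))
    out = MrFit(
        alpha=fit.alpha, var_alpha=fit.var_alpha, m=fit.m,
        ratio_estimates=fit.ratio_estimates, S2=S2, sigma2=sigma2,
    )
    if sigma2 <= 0.0:
        warnings.warn("sigma2 <= 0: correction undefined, returning uncorrected fit",
                      stacklevel=2)
        out.alpha_corrected = fit.alpha
        out.var_alpha_corrected = fit.var_alpha
        out.correction_flag = "sigma2 <= 0"
        return out
    factor = S2 / sigma2
    if as_printed:
        out.alpha_corrected = fit.alpha * S2 / np.sqrt(sigma2)
    else:
        out.alpha_corrected = fit.alpha * factor
    out.var_alpha_corrected = fit.var_alpha * factor
    return out


def _fit_arm(tbl: pd.DataFrame, arm: str, corrected: bool) -> MrFit:
    suffix = "_w" if arm == "weighted" else ""
    be = tbl[f"beta_exp{suffix}"].to_numpy()
    se_e = tbl[f"se_exp{suffix}"].to_numpy()
    bo = tbl[f"beta_out{suffix}"].to_numpy()
    se_o = tbl[f"se_out{suffix}"].to_numpy()
    fit = ivw(be, se_e, bo, se_o)
    if corrected:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = corrected_ivw(fit, be, se_e)
    return fit


def mr_difference(
    instruments: pd.DataFrame,
    corrected: bool = True,
) -> tuple[MrFit, MrFit, MrComparison]:
    """Weighted vs standard MR difference test on a shared instrument set.

    ``instruments`` is a harmonized table (see :func:`harmonize_instruments`)
    with standardized effects from both arms.  A leave-one-SNP-out jackknife
    produces paired (alpha, alpha_w) series;
    se(alpha_DIFF) = sqrt(se^2 + se_w^2 - 2 r se se_w) with all three
    ingredients (both standard errors and the correlation r) taken from the
    same delete-one series, so se(alpha_DIFF) is exactly the jackknife
    standard error of the paired difference.  Mixing analytic per-arm
    variances with a jackknife r would destabilize the difference variance
    whenever r is close to 1, and the analytic variance ignores the
    sampling noise of the dilution-correction factor; the all-jackknife
    form avoids both problems.  The P-value uses the jackknife-t reference
    with m - 1 degrees of freedom, the standard small-m calibration for a
    jackknife-studentized statistic.
    """
    m = len(instruments)
    if m < 3:
        raise ValueError("leave-one-out jackknife needs at least 3 instruments")
    fit_std = _fit_arm(instruments, "standard", corrected)
    fit_w = _fit_arm(instruments, "weighted", corrected)

    loo_std = np.empty(m)
    loo_w = np.empty(m)
    for j in range(m):
        sub = instruments.drop(instruments.index[j])
        f1 = _fit_arm(sub, "standard", corrected)
        f2 = _fit_arm(sub, "weighted", corrected)
        loo_std[j] = f1.alpha_corrected if corrected else f1.alpha
        loo_w[j] = f2.alpha_corrected if corrected else f2.alpha
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r = jackknife_correlation(loo_std, loo_w)
    scale = (m - 1.0) / m
    se_a = float(np.sqrt(scale * np.sum((loo_std - loo_std.mean()) ** 2)))
    se_w = float(np.sqrt(scale * np.sum((loo_w - loo_w.mean()) ** 2)))

    if corrected:
        a, aw = fit_std.alpha_corrected, fit_w.alpha_corrected
    else:
        a, aw = fit_std.alpha, fit_w.alpha
    diff = a - aw
    var_diff = se_a**2 + se_w**2 - 2.0 * r * se_a * se_w
    if var_diff <= 0.0:
        se_diff, z, p = 0.0, 0.0, 1.0
        if diff != 0.0:
            raise ValueError("non-positive variance of alpha_DIFF")
    else:
        se_diff = float(np.sqrt(var_diff))
        z = diff / se_diff
        p = float(2.0 * student_t.sf(abs(z), df=m - 1))
    comp = MrComparison(alpha=float(a), alpha_w=float(aw), diff=float(diff),
                        se_diff=se_diff, r=float(r), z=float(z), p=p,
                        se_jk=se_a, se_w_jk=se_w)
    return fit_std, fit_w, comp


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted P-values (FDR at the given level)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
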