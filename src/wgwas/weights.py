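"""Participation-probability models and inverse-probability weights.

The participation probability P_i of each selected individual — the
probability of appearing in the selected (biobank) sample rather than the
representative reference sample — is estimated by L1-penalized (LASSO)
logistic regression on the stacked samples, using all auxiliary main
effects (continuous variables as-is, one indicator per categorical level)
plus every pairwise product.  The inverse-probability weight
``w_i = (1 - P_i) / P_i`` up-weights individuals who resemble the target
population more than the volunteers; normalized weights ``w_in`` average 1.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.model_selection import StratifiedKFold, train_test_split

from wgwas.synthetic import AUX_VARIABLES, CATEGORICAL_AUX_LEVELS, CONTINUOUS_AUX

__all__ = [
    "DesignMatrix",
    "WeightFit",
    "ProbabilityWeights",
    "build_design",
    "fit_participation_model",
    "compute_weights",
    "effective_sample_size",
    "weighted_moments",
    "weighted_correlation",
    "bias_reduction",
    "bias_report",
    "crossvalidate_weights",
    "weighted_logistic_check",
]


# ---------------------------------------------------------------------------
# Design matrix
# ---------------------------------------------------------------------------


@dataclass
class DesignMatrix:
    """Main-effect + all-pairwise-product design for the participation model."""

    X: np.ndarray
    columns: list[str]

    @property
    def shape(self) -> tuple[int, int]:
        return self.X.shape


def build_design(
    cohort: pd.DataFrame,
    continuous: Sequence[str] = CONTINUOUS_AUX,
    categorical_levels: Mapping[str, Sequence[str]] = CATEGORICAL_AUX_LEVELS,
) -> DesignMatrix:
    """Build the participation design matrix from a stacked cohort table.

    Main effects: continuous variables as-is, then one {0,1} indicator per
    level of each categorical variable (all levels retained — no reference
    level is dropped).  Interaction terms: the product of every unordered
    pair of distinct main-effect columns, including pairs of indicators of
    the same categorical variable (those products are identically zero and
    are retained for the penalized fit to discard).  With 5 continuous
    variables and categorical level counts (7, 2, 6, 3, 4, 5, 4, 3, 3) this
    yields 42 mains + C(42, 2) = 903 columns.

    Product columns involving a continuous variable are formed from its
    z-scored values (indicator columns enter products as-is).  A product
    of raw-scale columns is dominated by the means of its factors — it is
    almost collinear with the two main effects, and the genuine
    interaction contrast carries only a small share of the column's
    variance — which makes the L1 penalty on interaction structure depend
    on arbitrary measurement units.  Centering restores the
    scale-equivariance that per-column standardization alone cannot.

    Raises ``ValueError`` naming the variable and level when a categorical
    value outside the declared level set is encountered, and when any
    auxiliary value is missing (rows with missingness must be dropped
    upstream; no imputation is performed).
    """
    n = len(cohort)
    mains: list[np.ndarray] = []
    prod_inputs: list[np.ndarray] = []  # z-scored for continuous mains
    names: list[str] = []

    for var in continuous:
        col = cohort[var].to_numpy(dtype=float)
        if np.isnan(col).any():
            raise ValueError(f"missing values in continuous variable {var!r}")
        mains.append(col)
        sd = col.std()
        prod_inputs.append((col - col.mean()) / sd if sd > 0 else np.zeros(n))
        names.append(var)

    for var, levels in categorical_levels.items():
        values = cohort[var].astype(str).to_numpy()
        level_set = set(map(str, levels))
        seen = set(values)
        bad = seen - level_set
        if bad:
            raise ValueError(
                f"variable {var!r} has unseen level(s): {sorted(bad)}; "
                f"declared levels are {list(levels)}"
            )
        for level in levels:
            ind = (values == str(level)).astype(float)
            mains.append(ind)
            prod_inputs.append(ind)
            names.append(f"{var}={level}")

    k = len(mains)
    total = k + k * (k - 1) // 2
    X = np.empty((n, total), dtype=np.float64)
    for j, col in enumerate(mains):
        X[:, j] = col
    col_names = list(names)
    j = k
    for a, b in itertools.combinations(range(k), 2):
        X[:, j] = prod_inputs[a] * prod_inputs[b]
        col_names.append(f"{names[a]}*{names[b]}")
        j += 1
    return DesignMatrix(X=X, columns=col_names)


# ---------------------------------------------------------------------------
# LASSO participation model
# ---------------------------------------------------------------------------


@dataclass
class WeightFit:
    """Fitted LASSO participation model."""

    lambda_: float
    coefficients: pd.Series  # original (unstandardized) scale, sparse-ish
    intercept: float
    P: np.ndarray  # fitted participation probability of selected rows
    P_all: np.ndarray  # fitted probability for every stacked row
    n_retained_predictors: int
    cv_deviance: pd.DataFrame  # lambda path with mean CV deviance


def _weighted_deviance(y, p, w) -> float:
    eps = 1e-12
    p = np.clip(p, eps, 1.0 - eps)
    ll = y * np.log(p) + (1.0 - y) * np.log(1.0 - p)
    return float(-2.0 * np.sum(w * ll) / np.sum(w))


def _sigmoid(eta: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(eta, -30.0, 30.0)))


def _lasso_logistic_path(
    Xs: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    lambdas: np.ndarray,
    tol: float = 1e-7,
    max_outer: int = 50,
    max_inner: int = 200,
) -> tuple[np.ndarray, np.ndarray]:
    """Coordinate-descent path solver for L1-penalized logistic regression.

    Minimizes ``(1/W) sum_i w_i BCE(y_i, sigmoid(b + x_i beta)) +
    lambda ||beta||_1`` for each lambda on the (descending) path, warm
    starting each fit from the previous solution.  The smooth loss is
    handled by iteratively reweighted least squares; each quadratic
    subproblem is solved by cyclic coordinate descent with active-set
    iteration (full sweeps only to verify the KKT conditions), as in
    glmnet.  Returns ``(B, b)`` with one coefficient row and intercept per
    lambda.  Deterministic: no randomness is involved.
    """
    n, p = Xs.shape
    X = np.asfortranarray(Xs)
    X2 = np.asfortranarray(X * X)
    wbar = w / w.sum()  # observation weights summing to 1
    beta = np.zeros(p)
    b = float(np.log(np.clip(wbar @ y, 1e-12, 1 - 1e-12) /
                     np.clip(1.0 - wbar @ y, 1e-12, 1 - 1e-12)))
    eta = np.full(n, b)
    B_out = np.zeros((len(lambdas), p))
    b_out = np.zeros(len(lambdas))

    for li, lam in enumerate(lambdas):
        for _outer in range(max_outer):
            prob = _sigmoid(eta)
            v = wbar * np.clip(prob * (1.0 - prob), 1e-10, None)
            d = X2.T @ v  # curvature per coordinate
            v_sum = v.sum()
            # working residual of z = eta + (y - prob)/(prob') around (b, beta)
            t = wbar * (y - prob)  # equals v * s where s is the residual

            def _sweep(indices: np.ndarray) -> float:
                nonlocal b, t
                delta_max = 0.0
                db = t.sum() / v_sum
                if db != 0.0:
                    b += db
                    t -= db * v
                    delta_max = v_sum * db * db
                for j in indices:
                    dj = d[j]
                    if dj <= 0.0:
                        continue
                    xj = X[:, j]
                    rho = xj @ t + dj * beta[j]
                    bj = np.sign(rho) * max(abs(rho) - lam, 0.0) / dj
                    diff = bj - beta[j]
                    if diff != 0.0:
                        beta[j] = bj
                        t -= diff * (v * xj)
                        delta_max = max(delta_max, dj * diff * diff)
                return delta_max

            changed = _sweep(np.arange(p))  # full sweep: lets predictors enter
            active = np.flatnonzero(beta)
            for _inner in range(max_inner):
                if changed < tol or active.size == 0:
                    break
                changed = _sweep(active)
                active = np.flatnonzero(beta)
            eta_new = b + X @ beta
            if np.max(np.abs(eta_new - eta)) < 1e-4:
                eta = eta_new
                break
            eta = eta_new
        B_out[li] = beta
        b_out[li] = b
    return B_out, b_out


def fit_participation_model(
    design: DesignMatrix,
    labels: np.ndarray,
    sample_weight: Optional[np.ndarray] = None,
    n_folds: int = 5,
    seed: int = 0,
    n_lambda: int = 30,
    lambda_min_ratio: float = 1e-4,
    standardize: bool = True,
    tol: float = 1e-7,
) -> WeightFit:
    """Cross-validated logistic LASSO for participation probability.

    ``labels`` are 1 for selected-sample rows and 0 for reference rows;
    ``sample_weight`` carries the reference survey design weights (selected
    rows get weight 1) and enters the penalized deviance as observation
    weights.  The penalty ``lambda`` is chosen on a descending log-spaced
    path from the coefficient-killing ``lambda_max`` by ``n_folds``-fold
    stratified cross-validation minimizing the weighted deviance; ties
    resolve to the larger (sparser) lambda.  Fits descend the path with
    warm starts (glmnet-style coordinate descent).  Predictors are
    internally standardized for the penalty when ``standardize`` is True
    and coefficients are reported on the original scale.
    """
    y = np.asarray(labels, dtype=float)
    classes = np.unique(y)
    if not np.isin(classes, [0.0, 1.0]).all() or classes.size < 2:
        raise ValueError("labels must contain both classes {0, 1}")
    X = design.X
    n = len(y)
    w = np.ones(n) if sample_weight is None else np.asarray(sample_weight, dtype=float)

    # drop zero-variance columns from the fit (coefficients stay 0)
    sd = X.std(axis=0)
    active = sd > 0
    if not active.any():
        raise ValueError("zero-variance design: no usable predictors")
    mu = X.mean(axis=0)
    if standardize:
        Xs = (X[:, active] - mu[active]) / sd[active]
    else:
        Xs = X[:, active]

    # lambda path, glmnet-style: lambda_max kills every coefficient
    p0 = np.sum(w * y) / np.sum(w)
    grad = Xs.T @ (w * (y - p0)) / np.sum(w)
    lam_max = max(np.abs(grad).max(), 1e-6)
    lambdas = np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambda)

    W_sum = np.sum(w)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    dev = np.zeros(n_lambda)
    for train, test in skf.split(Xs, y):
        B, b0 = _lasso_logistic_path(Xs[train], y[train], w[train], lambdas, tol=tol)
        eta_test = Xs[test] @ B.T + b0  # (n_test, n_lambda)
        for i in range(n_lambda):
            p = _sigmoid(eta_test[:, i])
            dev[i] += _weighted_deviance(y[test], p, w[test]) * np.sum(w[test])
    dev /= W_sum
    # ties -> larger lambda (path is descending, so first index at minimum)
    best = int(np.flatnonzero(dev <= dev.min() + 1e-12)[0])
    lam = float(lambdas[best])

    B, b0 = _lasso_logistic_path(Xs, y, w, lambdas[: best + 1], tol=tol)
    coef_std, intercept_std = B[best], float(b0[best])
    p_all = _sigmoid(Xs @ coef_std + intercept_std)

    coef = np.zeros(X.shape[1])
    if standardize:
        coef[active] = coef_std / sd[active]
        intercept = intercept_std - float(np.sum(coef_std * mu[active] / sd[active]))
    else:
        coef[active] = coef_std
        intercept = intercept_std

    return WeightFit(
        lambda_=lam,
        coefficients=pd.Series(coef, index=design.columns),
        intercept=intercept,
        P=p_all[y == 1.0],
        P_all=p_all,
        n_retained_predictors=int(np.count_nonzero(coef)),
        cv_deviance=pd.DataFrame({"lambda": lambdas, "cv_deviance": dev}),
    )


# ---------------------------------------------------------------------------
# Weights
# ---------------------------------------------------------------------------


@dataclass
class ProbabilityWeights:
    """Inverse-probability participation weights for the selected sample."""

    P: np.ndarray
    w: np.ndarray  # (1 - P) / P
    w_in: np.ndarray  # w / mean(w), averages 1
    W: float  # sum of raw weights
    n_effective: float

    def __len__(self) -> int:
        return len(self.w)


def compute_weights(P: np.ndarray) -> ProbabilityWeights:
    """Build w = (1 - P) / P and its normalized form from probabilities.

    Probabilities outside the open interval (0, 1) raise — weights are
    never silently clipped.
    """
    P = np.asarray(P, dtype=float)
    if P.size == 0:
        raise ValueError("empty probability vector")
    if np.any(~np.isfinite(P)) or np.any(P <= 0.0) or np.any(P >= 1.0):
        raise ValueError("participation probabilities must lie strictly in (0, 1)")
    w = (1.0 - P) / P
    w_in = w / w.mean()
    return ProbabilityWeights(
        P=P, w=w, w_in=w_in, W=float(w.sum()), n_effective=effective_sample_size(w)
    )


def effective_sample_size(w: np.ndarray) -> float:
    """Effective number of equally weighted observations.

    ``(sum w_in)^2 / sum w_in^2`` over the normalized weights, which is
    scale invariant and identical to ``n / (Var_pop(w_in) + 1)`` where the
    variance uses the divide-by-n convention.  Equals n iff all weights are
    equal.
    """
    w = np.asarray(w, dtype=float)
    if w.size == 0:
        raise ValueError("empty weight vector")
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    w_in = w / w.mean()
    return float(w_in.sum() ** 2 / np.sum(w_in**2))


def weighted_moments(x: np.ndarray, w: np.ndarray) -> float:
    """Weighted mean (1/W) sum w_i x_i; proportions are means of indicators."""
    x = np.asarray(x, dtype=float)
    w = np.asarray(w, dtype=float)
    if x.shape != w.shape:
        raise ValueError("x and w must have the same length")
    W = w.sum()
    if W == 0:
        raise ValueError("weights sum to zero")
    return float(np.sum(w * x) / W)


def weighted_correlation(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    """Weighted Pearson correlation."""
    mx = weighted_moments(x, w)
    my = weighted_moments(y, w)
    cov = np.sum(w * (x - mx) * (y - my))
    vx = np.sum(w * (x - mx) ** 2)
    vy = np.sum(w * (y - my) ** 2)
    if vx <= 0 or vy <= 0:
        return np.nan
    return float(cov / np.sqrt(vx * vy))


def bias_reduction(r_ref: float, r_sel: float, r_sel_weighted: float) -> float:
    """Fraction of participation bias removed by weighting.

    ``(|r_ref - r_sel| - |r_ref - r_sel_weighted|) / |r_ref - r_sel|``:
    1 means weighting fully eliminated the bias, 0 means no change.  When
    the selected and reference correlations already agree the quantity is
    undefined and NaN is returned (callers exclude such pairs from
    summaries).
    """
    for r in (r_ref, r_sel, r_sel_weighted):
        if not -1.0 - 1e-9 <= r <= 1.0 + 1e-9:
            raise ValueError("correlations must lie in [-1, 1]")
    denom = abs(r_ref - r_sel)
    if denom == 0.0:
        return np.nan
    return (denom - abs(r_ref - r_sel_weighted)) / denom


def _numeric_encoding(df: pd.DataFrame, variables: Sequence[str]) -> pd.DataFrame:
    out = {}
    for var in variables:
        col = df[var]
        if var in CATEGORICAL_AUX_LEVELS:
            levels = list(CATEGORICAL_AUX_LEVELS[var])
            out[var] = col.astype(str).map({lv: i for i, lv in enumerate(levels)})
        else:
            out[var] = col.astype(float)
    return pd.DataFrame(out, index=df.index)


def bias_report(
    selected: pd.DataFrame,
    reference: pd.DataFrame,
    w_in: np.ndarray,
    reference_weights: Optional[np.ndarray] = None,
    variables: Sequence[str] = AUX_VARIABLES,
) -> pd.DataFrame:
    """Per-variable-pair bias and bias reduction.

    For every unordered pair of auxiliary variables (numeric-encoded), the
    reference correlation ``r_ref`` (design-weighted), the unweighted
    selected-sample correlation ``r_sel``, the weighted selected-sample
    correlation ``r_sel_weighted``, ``r_diff = |r_ref - r_sel|`` and the
    bias-reduction fraction.
    """
    sel_num = _numeric_encoding(selected, variables)
    ref_num = _numeric_encoding(reference, variables)
    w_sel = np.asarray(w_in, dtype=float)
    w_ref = (
        np.ones(len(reference))
        if reference_weights is None
        else np.asarray(reference_weights, dtype=float)
    )
    rows = []
    ones = np.ones(len(selected))
    for a, b in itertools.combinations(variables, 2):
        r_ref = weighted_correlation(ref_num[a].to_numpy(), ref_num[b].to_numpy(), w_ref)
        r_sel = weighted_correlation(sel_num[a].to_numpy(), sel_num[b].to_numpy(), ones)
        r_w = weighted_correlation(sel_num[a].to_numpy(), sel_num[b].to_numpy(), w_sel)
        if np.isnan(r_ref) or np.isnan(r_sel) or np.isnan(r_w):
            br = np.nan
            r_diff = np.nan
        else:
            r_diff = abs(r_ref - r_sel)
            br = bias_reduction(r_ref, r_sel, r_w)
        rows.append(
            {
                "var_a": a,
                "var_b": b,
                "r_ref": r_ref,
                "r_sel": r_sel,
                "r_sel_weighted": r_w,
                "r_diff": r_diff,
                "bias_reduction": br,
            }
        )
    return pd.DataFrame(rows)


def summarize_bias_reduction(
    report: pd.DataFrame, r_diff_min: float = 0.05
) -> dict[str, float]:
    """Median / mean / range of bias reduction over materially biased pairs."""
    sub = report[(report["r_diff"] > r_diff_min) & report["bias_reduction"].notna()]
    if len(sub) == 0:
        return {"median": np.nan, "mean": np.nan, "min": np.nan, "max": np.nan, "n_pairs": 0}
    br = sub["bias_reduction"]
    return {
        "median": float(br.median()),
        "mean": float(br.mean()),
        "min": float(br.min()),
        "max": float(br.max()),
        "n_pairs": int(len(sub)),
    }


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------


def crossvalidate_weights(
    stacked: pd.DataFrame,
    test_fraction: float = 0.2,
    n_splits: int = 5,
    n_folds: int = 5,
    seed: int = 0,
    r_diff_min: float = 0.05,
    **fit_kwargs,
) -> dict:
    """Out-of-sample check of the participation model (overfitting audit).

    For each of ``n_splits`` stratified 80:20 train–test splits, the LASSO
    is refit on the training portion and probabilities are predicted for
    the held-out selected individuals; the bias-reduction summary from
    those out-of-sample weights is compared with the full-sample summary.
    """
    labels = stacked["participation"].to_numpy()
    dw = stacked["design_weight"].to_numpy(dtype=float)
    design = build_design(stacked)

    full_fit = fit_participation_model(
        design, labels, sample_weight=dw, n_folds=n_folds, seed=seed, **fit_kwargs
    )
    reference = stacked[stacked["participation"] == 0]
    selected = stacked[stacked["participation"] == 1]
    full_w = compute_weights(full_fit.P)
    in_sample = summarize_bias_reduction(
        bias_report(
            selected,
            reference,
            full_w.w_in,
            reference_weights=reference["design_weight"].to_numpy(),
        ),
        r_diff_min=r_diff_min,
    )

    rng = np.random.default_rng(seed)
    out_rows = []
    for s in range(n_splits):
        split_seed = int(rng.integers(2**31))
        idx_train, idx_test = train_test_split(
            np.arange(len(stacked)),
            test_size=test_fraction,
            stratify=labels,
            random_state=split_seed,
        )
        if len(np.unique(labels[idx_train])) < 2 or len(np.unique(labels[idx_test])) < 2:
            raise ValueError("degenerate split: a class is missing")
        sub_design = DesignMatrix(X=design.X[idx_train], columns=design.columns)
        fit = fit_participation_model(
            sub_design,
            labels[idx_train],
            sample_weight=dw[idx_train],
            n_folds=n_folds,
            seed=split_seed,
            **fit_kwargs,
        )
        # out-of-sample probabilities for the held-out selected rows
        lp = design.X[idx_test] @ fit.coefficients.to_numpy() + fit.intercept
        p_test = 1.0 / (1.0 + np.exp(-lp))
        sel_mask = labels[idx_test] == 1
        p_sel = np.clip(p_test[sel_mask], 1e-12, 1 - 1e-12)
        w_oos = compute_weights(p_sel)
        test_selected = stacked.iloc[idx_test[sel_mask]]
        rep = bias_report(
            test_selected,
            reference,
            w_oos.w_in,
            reference_weights=reference["design_weight"].to_numpy(),
        )
        out_rows.append(summarize_bias_reduction(rep, r_diff_min=r_diff_min))

    oos = pd.DataFrame(out_rows)
    out_of_sample = {
        "median": float(oos["median"].median()),
        "mean": float(oos["mean"].mean()),
        "min": float(oos["min"].min()),
        "max": float(oos["max"].max()),
        "n_splits": n_splits,
    }
    return {
        "in_sample": in_sample,
        "out_of_sample": out_of_sample,
        "per_split": out_rows,
        "full_fit": full_fit,
    }


def weighted_logistic_check(
    stacked: pd.DataFrame,
    w_in: np.ndarray,
    variables: Sequence[str] = AUX_VARIABLES,
) -> pd.DataFrame:
    """Univariate logistic audit of balance before and after weighting.

    Each auxiliary variable (z-scored numeric encoding) predicts the
    participation label in a logistic model with robust standard errors,
    twice: unweighted, and with selected rows carrying their normalized
    probability weight while reference rows keep weight 1.  With perfect
    weights every post-weighting coefficient is ~0.
    """
    y = stacked["participation"].to_numpy(dtype=float)
    num = _numeric_encoding(stacked, variables)
    obs_w = np.ones(len(stacked))
    obs_w[y == 1.0] = np.asarray(w_in, dtype=float)

    rows = []
    for var in variables:
        x = num[var].to_numpy(dtype=float)
        sd = x.std()
        if sd == 0:
            rows.append({"variable": var, "flag": "constant"})
            continue
        z = (x - x.mean()) / sd
        X = sm.add_constant(z)
        rec: dict = {"variable": var, "flag": ""}
        for tag, fw in (("pre", np.ones(len(y))), ("post", obs_w)):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = sm.GLM(y, X, family=sm.families.Binomial(), freq_weights=fw).fit(
                        cov_type="HC0"
                    )
                rec[f"coef_{tag}"] = float(res.params[1])
                rec[f"se_{tag}"] = float(res.bse[1])
                rec[f"p_{tag}"] = float(res.pvalues[1])
            except Exception:  # perfect separation or non-convergence
                rec[f"coef_{tag}"] = np.nan
                rec[f"se_{tag}"] = np.nan
                rec[f"p_{tag}"] = np.nan
                rec["flag"] = "separation"
        rows.append(rec)
    return pd.DataFrame(rows)
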