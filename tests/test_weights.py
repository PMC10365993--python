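"""Design matrix, LASSO participation model, weights and bias metrics."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from wgwas import weights as wmod
from wgwas import synthetic as syn


# ---------------------------------------------------------------------------
# Design matrix
# ---------------------------------------------------------------------------


def test_design_has_903_columns(tiny_cohort):
    design = wmod.build_design(tiny_cohort)
    assert design.shape == (len(tiny_cohort), 903)
    assert len(design.columns) == 903
    # 42 mains then all C(42,2) products
    assert design.columns[0] == "age"
    assert "*" not in "".join(design.columns[:42])
    assert all("*" in c for c in design.columns[42:])


def test_design_same_variable_products_identically_zero(tiny_cohort):
    design = wmod.build_design(tiny_cohort)
    X = design.X
    for j, name in enumerate(design.columns):
        if "*" not in name:
            continue
        a, b = name.split("*")
        if "=" in a and "=" in b and a.split("=")[0] == b.split("=")[0]:
            assert not X[:, j].any(), name


def test_design_deterministic_order(tiny_cohort):
    d1 = wmod.build_design(tiny_cohort)
    d2 = wmod.build_design(tiny_cohort)
    assert d1.columns == d2.columns
    np.testing.assert_array_equal(d1.X, d2.X)


def test_design_unseen_level_raises(tiny_cohort):
    bad = tiny_cohort.copy()
    bad["smoking"] = bad["smoking"].astype(object)
    bad.loc[bad.index[0], "smoking"] = "vaping"
    with pytest.raises(ValueError, match="smoking.*vaping"):
        wmod.build_design(bad)


def test_design_missing_value_raises(tiny_cohort):
    bad = tiny_cohort.copy()
    bad.loc[bad.index[0], "age"] = np.nan
    with pytest.raises(ValueError, match="age"):
        wmod.build_design(bad)


# ---------------------------------------------------------------------------
# Weights arithmetic
# ---------------------------------------------------------------------------


def test_compute_weights_formula_and_normalization():
    P = np.array([0.2, 0.5, 0.8])
    pw = wmod.compute_weights(P)
    np.testing.assert_allclose(pw.w, (1 - P) / P)
    assert pw.w_in.mean() == pytest.approx(1.0, abs=1e-15)
    assert pw.W == pytest.approx(pw.w.sum())


def test_compute_weights_rejects_degenerate_p():
    for bad in ([0.0, 0.5], [0.5, 1.0], [np.nan, 0.5], []):
        with pytest.raises(ValueError):
            wmod.compute_weights(np.array(bad))


def test_effective_sample_size_identity_random_vectors():
    rng = np.random.default_rng(0)
    for _ in range(1_000):
        n = int(rng.integers(2, 50))
        w = rng.uniform(0.01, 10.0, size=n)
        w_in = w / w.mean()
        lhs = w_in.sum() ** 2 / np.sum(w_in**2)
        rhs = n / (np.var(w_in) + 1.0)
        assert abs(lhs - rhs) < 1e-10
        assert wmod.effective_sample_size(w) == pytest.approx(lhs, abs=1e-10)


def test_effective_sample_size_examples():
    assert wmod.effective_sample_size(np.ones(7)) == pytest.approx(7.0)
    assert wmod.effective_sample_size(np.array([1.0, 1.0, 4.0])) == pytest.approx(2.0)
    with pytest.raises(ValueError):
        wmod.effective_sample_size(np.array([1.0, -1.0]))


def test_weighted_moments_examples():
    assert wmod.weighted_moments(np.array([0.0, 1.0, 1.0]), np.array([2.0, 1.0, 1.0])) == 0.5
    x = np.array([3.0, 5.0])
    assert wmod.weighted_moments(x, np.ones(2)) == pytest.approx(4.0)
    with pytest.raises(ValueError):
        wmod.weighted_moments(x, np.ones(3))


def test_weighted_moments_scale_invariance():
    rng = np.random.default_rng(1)
    x = rng.normal(size=30)
    w = rng.uniform(0.1, 5.0, size=30)
    m1 = wmod.weighted_moments(x, w)
    m2 = wmod.weighted_moments(x, 17.3 * w)
    assert m1 == pytest.approx(m2, rel=1e-12)
    r1 = wmod.weighted_correlation(x, x**2, w)
    r2 = wmod.weighted_correlation(x, x**2, 17.3 * w)
    assert r1 == pytest.approx(r2, rel=1e-12)


def test_bias_reduction_formula_and_flags():
    assert wmod.bias_reduction(0.5, 0.2, 0.5) == pytest.approx(1.0)
    assert wmod.bias_reduction(0.5, 0.2, 0.2) == pytest.approx(0.0)
    assert wmod.bias_reduction(0.5, 0.2, 0.35) == pytest.approx(0.5)
    # weighting that overshoots past the reference is a negative reduction
    assert wmod.bias_reduction(0.5, 0.2, 0.05) == pytest.approx(-0.5)
    assert np.isnan(wmod.bias_reduction(0.3, 0.3, 0.1))  # flagged, not thrown
    with pytest.raises(ValueError):
        wmod.bias_reduction(1.5, 0.0, 0.0)


def test_bias_report_shape_and_summary(tiny_cohort):
    sel = tiny_cohort[tiny_cohort["participation"] == 1]
    ref = tiny_cohort[tiny_cohort["participation"] == 0]
    w_in = np.ones(len(sel))
    rep = wmod.bias_report(sel, ref, w_in)
    n_pairs = 14 * 13 // 2
    assert len(rep) == n_pairs
    # unit weights: weighted equals unweighted selected correlation
    np.testing.assert_allclose(rep["r_sel_weighted"], rep["r_sel"], atol=1e-12)
    summ = wmod.summarize_bias_reduction(rep, r_diff_min=2.0)
    assert summ["n_pairs"] == 0 and np.isnan(summ["median"])


# ---------------------------------------------------------------------------
# LASSO participation model (small, fast settings)
# ---------------------------------------------------------------------------


def test_lasso_intercept_only_when_labels_independent(tiny_cohort):
    rng = np.random.default_rng(3)
    labels = rng.permutation(tiny_cohort["participation"].to_numpy())
    design = wmod.build_design(tiny_cohort)
    fit = wmod.fit_participation_model(
        design, labels, n_folds=3, n_lambda=4, lambda_min_ratio=0.3, seed=0
    )
    # shuffled labels: CV keeps a heavy penalty and P ~ base rate
    base = labels.mean()
    assert np.allclose(fit.P_all, base, atol=0.05)


def test_lasso_lambda_max_kills_all_coefficients(tiny_cohort):
    design = wmod.build_design(tiny_cohort)
    labels = tiny_cohort["participation"].to_numpy()
    fit = wmod.fit_participation_model(
        design, labels, n_folds=3, n_lambda=1, lambda_min_ratio=1.0, seed=0
    )
    assert fit.n_retained_predictors == 0
    assert np.allclose(fit.P_all, fit.P_all[0], atol=1e-6)


def test_lasso_recovers_selection_signal_sign():
    # needs more rows than the tiny fixture for CV to retain any predictor
    rng = np.random.default_rng(9)
    n = 4_000
    traits = pd.DataFrame(
        {"health": rng.normal(size=n), "ses": rng.normal(size=n)}
    )
    aux = syn.simulate_auxiliary(traits, syn.HEALTHY_VOLUNTEER_LOADINGS, seed=10)
    pop = syn.apply_participation(
        aux,
        syn.ParticipationModel(syn.HEALTHY_VOLUNTEER_SELECTION, target_fraction=0.3),
        seed=11,
    )
    sel = pop[pop["participation"] == 1]
    ref = syn.draw_reference_sample(pop, n_ref=600, seed=12)
    cohort = syn.stack_cohorts(sel, ref)
    design = wmod.build_design(cohort)
    labels = cohort["participation"].to_numpy()
    fit = wmod.fit_participation_model(
        design, labels, n_folds=3, n_lambda=8, lambda_min_ratio=1e-3, seed=0
    )
    assert fit.n_retained_predictors > 0
    assert fit.coefficients["education"] >= 0.0  # generator selects on education
    # probabilities valid and higher on average for selected rows
    assert np.all((fit.P_all > 0) & (fit.P_all < 1))
    assert fit.P.mean() > fit.P_all[labels == 0].mean()


def test_lasso_deterministic(tiny_cohort):
    design = wmod.build_design(tiny_cohort)
    labels = tiny_cohort["participation"].to_numpy()
    kw = dict(n_folds=3, n_lambda=4, lambda_min_ratio=0.05, seed=42)
    f1 = wmod.fit_participation_model(design, labels, **kw)
    f2 = wmod.fit_participation_model(design, labels, **kw)
    assert f1.lambda_ == f2.lambda_
    np.testing.assert_array_equal(f1.P_all, f2.P_all)


def test_lasso_rejects_single_class(tiny_cohort):
    design = wmod.build_design(tiny_cohort)
    with pytest.raises(ValueError, match="both classes"):
        wmod.fit_participation_model(design, np.ones(len(tiny_cohort)))


def test_weighted_logistic_check_balance(tiny_cohort):
    rng = np.random.default_rng(4)
    sel_mask = tiny_cohort["participation"] == 1
    w_in = rng.uniform(0.5, 2.0, size=int(sel_mask.sum()))
    tbl = wmod.weighted_logistic_check(tiny_cohort, w_in, variables=("age", "education"))
    assert set(tbl["variable"]) == {"age", "education"}
    assert {"coef_pre", "coef_post", "p_pre", "p_post"} <= set(tbl.columns)
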