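"""Generator oracles: HWE, LD, trait h2, auxiliaries, participation, reference."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from wgwas import synthetic as syn
from wgwas.gwas import hwe_pvalues


def test_population_config_validation():
    with pytest.raises(ValueError):
        syn.PopulationConfig(n_population=0, n_snps=10)
    with pytest.raises(ValueError):
        syn.PopulationConfig(n_population=10, n_snps=10, maf_range=(0.0, 0.5))
    with pytest.raises(ValueError):
        syn.PopulationConfig(n_population=10, n_snps=10, ld_rho=1.0)


def test_genotypes_hwe_property():
    g = syn.simulate_genotypes(
        syn.PopulationConfig(n_population=5_000, n_snps=400, seed=1)
    )
    p = hwe_pvalues(g)
    assert (p > 1e-6).mean() >= 0.9999


def test_genotypes_symmetric_maf_mean_dosage():
    g = syn.simulate_genotypes(
        syn.PopulationConfig(n_population=20_000, n_snps=50, maf_range=(0.5, 0.5), seed=2)
    )
    assert np.allclose(g.dosages.mean(axis=0), 1.0, atol=0.05)


def test_genotypes_dosage_variance_matches_binomial():
    g = syn.simulate_genotypes(
        syn.PopulationConfig(n_population=50_000, n_snps=60, seed=3)
    )
    p = g.allele_frequencies()
    var = g.dosages.astype(float).var(axis=0)
    expect = 2 * p * (1 - p)
    # binomial(2, p) variance within 3 standard errors of the sample variance
    se = np.sqrt(2.0) * expect / np.sqrt(g.n_individuals - 1)
    assert np.all(np.abs(var - expect) < 5 * se)


def test_genotypes_ld_structure():
    g = syn.simulate_genotypes(
        syn.PopulationConfig(
            n_population=8_000, n_snps=60, ld_block_size=5, ld_rho=0.35, seed=4
        )
    )
    X = g.dosage_float()
    within, across = [], []
    for j in range(0, 55):
        r = np.corrcoef(X[:, j], X[:, j + 1])[0, 1]
        (within if (j % 5) != 4 else across).append(abs(r))
    assert np.mean(within) > 0.15
    assert np.mean(across) < 0.05


def test_genotypes_no_ld_when_block_one():
    g = syn.simulate_genotypes(
        syn.PopulationConfig(n_population=5_000, n_snps=40, ld_block_size=1, seed=5)
    )
    X = g.dosage_float()
    r = [abs(np.corrcoef(X[:, j], X[:, j + 1])[0, 1]) for j in range(39)]
    assert np.mean(r) < 0.03


def test_genotypes_deterministic():
    cfg = dict(n_population=500, n_snps=30, seed=9)
    g1 = syn.simulate_genotypes(syn.PopulationConfig(**cfg))
    g2 = syn.simulate_genotypes(syn.PopulationConfig(**cfg))
    np.testing.assert_array_equal(g1.dosages, g2.dosages)


def test_phenotype_null_has_no_signal(small_genotypes):
    model = syn.TraitModel(
        causal_effects=np.ones(small_genotypes.n_snps), h2_target=0.0
    )
    y = syn.simulate_phenotype(small_genotypes, model, seed=1)
    x = small_genotypes.dosages[:, 0].astype(float)
    r = np.corrcoef(x, y)[0, 1]
    assert abs(r) < 0.15  # pure noise at n=400


def test_phenotype_realized_h2():
    g = syn.simulate_genotypes(syn.PopulationConfig(n_population=20_000, n_snps=300, seed=6))
    rng = np.random.default_rng(0)
    beta = np.zeros(300)
    idx = rng.choice(300, size=200, replace=False)
    beta[idx] = rng.standard_normal(200) / np.sqrt(200)
    model = syn.TraitModel(causal_effects=beta, h2_target=0.5)
    y, genetic, _ = syn.simulate_phenotype(g, model, seed=7, return_components=True)
    r2 = np.corrcoef(genetic, y)[0, 1] ** 2
    assert abs(r2 - 0.5) < 0.03


def test_phenotype_binary_case_fraction():
    g = syn.simulate_genotypes(syn.PopulationConfig(n_population=4_000, n_snps=50, seed=8))
    beta = np.ones(50) * 0.05
    model = syn.TraitModel(
        causal_effects=beta, h2_target=0.3, liability_threshold_prevalence=0.5
    )
    y = syn.simulate_phenotype(g, model, seed=9)
    assert set(np.unique(y)) <= {0.0, 1.0}
    assert abs(y.mean() - 0.5) < 0.02


def test_trait_model_validation():
    with pytest.raises(ValueError):
        syn.TraitModel(causal_effects=np.ones(3), h2_target=1.5)
    with pytest.raises(ValueError):
        syn.TraitModel(
            causal_effects=np.ones(3), h2_target=0.5, liability_threshold_prevalence=0.0
        )


def test_auxiliary_level_counts_and_types():
    rng = np.random.default_rng(1)
    traits = pd.DataFrame({"health": rng.normal(size=2_000), "ses": rng.normal(size=2_000)})
    aux = syn.simulate_auxiliary(traits, syn.HEALTHY_VOLUNTEER_LOADINGS, seed=2)
    counts = [len(syn.CATEGORICAL_AUX_LEVELS[v]) for v in syn.CATEGORICAL_AUX_LEVELS]
    assert counts == [7, 2, 6, 3, 4, 5, 4, 3, 3]
    for var, levels in syn.CATEGORICAL_AUX_LEVELS.items():
        assert set(aux[var].astype(str)) <= set(levels)
    for var in syn.CONTINUOUS_AUX:
        assert np.issubdtype(aux[var].dtype, np.floating)


def test_auxiliary_zero_loadings_independent():
    rng = np.random.default_rng(2)
    traits = pd.DataFrame({"health": rng.normal(size=5_000)})
    aux = syn.simulate_auxiliary(traits, {}, seed=3)
    r = np.corrcoef(aux["bmi"], traits["health"])[0, 1]
    assert abs(r) < 0.04


def test_auxiliary_positive_loading_positive_correlation():
    rng = np.random.default_rng(3)
    traits = pd.DataFrame({"ses": rng.normal(size=5_000)})
    aux = syn.simulate_auxiliary(traits, {"education": {"ses": 0.9}}, seed=4)
    assert np.corrcoef(aux["education"], traits["ses"])[0, 1] > 0.3


def test_auxiliary_unknown_trait_raises():
    traits = pd.DataFrame({"ses": np.zeros(10) + np.arange(10)})
    with pytest.raises(KeyError, match="unknown trait"):
        syn.simulate_auxiliary(traits, {"education": {"wealth": 1.0}}, seed=0)


def _population(n=20_000, seed=0):
    rng = np.random.default_rng(seed)
    traits = pd.DataFrame({"health": rng.normal(size=n), "ses": rng.normal(size=n)})
    return syn.simulate_auxiliary(traits, syn.HEALTHY_VOLUNTEER_LOADINGS, seed=seed + 1)


def test_participation_zero_coefficients_hits_target_fraction():
    aux = _population()
    pm = syn.ParticipationModel(logit_coefficients={}, target_fraction=0.055)
    pop = syn.apply_participation(aux, pm, seed=5)
    assert np.allclose(pop["true_P"], 0.055)
    share = pop["participation"].mean()
    assert abs(share - 0.055) < 3 * np.sqrt(0.055 * 0.945 / len(pop))


def test_participation_positive_coefficient_shifts_mean():
    aux = _population(seed=10)
    pm = syn.ParticipationModel({"education": 1.0}, target_fraction=0.1)
    pop = syn.apply_participation(aux, pm, seed=6)
    sel = pop[pop["participation"] == 1]
    assert sel["education"].mean() > pop["education"].mean()


def test_participation_constant_p_means_agree():
    aux = _population(seed=11)
    pm = syn.ParticipationModel({}, target_fraction=0.2)
    pop = syn.apply_participation(aux, pm, seed=7)
    sel = pop[pop["participation"] == 1]
    w = (1 - sel["true_P"]) / sel["true_P"]
    assert np.average(sel["age"], weights=w) == pytest.approx(sel["age"].mean())


def test_participation_interaction_distorts_selected_correlation():
    """A product term in the logit shifts the selected-sample correlation."""
    rng = np.random.default_rng(12)
    n = 40_000
    traits = pd.DataFrame({"health": rng.normal(size=n), "ses": rng.normal(size=n)})
    aux = syn.simulate_auxiliary(traits, {}, seed=13)  # independent auxiliaries
    pm = syn.ParticipationModel({("age", "bmi"): 0.4}, target_fraction=0.2)
    pop = syn.apply_participation(aux, pm, seed=14)
    sel = pop[pop["participation"] == 1]
    r_pop = np.corrcoef(pop["age"], pop["bmi"])[0, 1]
    r_sel = np.corrcoef(sel["age"], sel["bmi"])[0, 1]
    assert abs(r_pop) < 0.03
    assert r_sel - r_pop > 0.15


def test_participation_model_validation():
    with pytest.raises(ValueError, match="unknown auxiliary"):
        syn.ParticipationModel({"wealth": 1.0})
    with pytest.raises(ValueError, match="distinct"):
        syn.ParticipationModel({("age", "age"): 0.5})
    with pytest.raises(ValueError, match="target_fraction"):
        syn.ParticipationModel({}, target_fraction=1.5)


def test_oracle_weights_recover_population_means():
    """Horvitz–Thompson oracle: (1-P)/P weighting reproduces population means."""
    aux = _population(n=50_000, seed=20)
    pm = syn.ParticipationModel(syn.HEALTHY_VOLUNTEER_SELECTION, target_fraction=0.1)
    pop = syn.apply_participation(aux, pm, seed=21)
    sel = pop[pop["participation"] == 1]
    w = ((1 - sel["true_P"]) / sel["true_P"]).to_numpy()
    from wgwas.weights import _numeric_encoding

    enc_pop = _numeric_encoding(pop, syn.AUX_VARIABLES)
    enc_sel = _numeric_encoding(sel, syn.AUX_VARIABLES)
    W = w.sum()
    for var in syn.AUX_VARIABLES:
        x = enc_sel[var].to_numpy(dtype=float)
        mw = np.sum(w * x) / W
        # linearized (ratio-estimator) Monte-Carlo SE of the weighted mean
        se = np.sqrt(np.sum(w**2 * (x - mw) ** 2)) / W
        assert abs(mw - enc_pop[var].mean()) < 4 * se, var


def test_reference_sample_srs_weights_one():
    aux = _population(seed=30)
    pop = syn.apply_participation(aux, syn.ParticipationModel({}, 0.1), seed=31)
    ref = syn.draw_reference_sample(pop, n_ref=500, seed=32)
    assert len(ref) == 500
    assert (ref["design_weight"] == 1.0).all()
    assert (ref["participation"] == 0).all()


def test_reference_sample_stratified_weights():
    aux = _population(seed=33)
    pop = syn.apply_participation(aux, syn.ParticipationModel({}, 0.1), seed=34)
    scheme = {"column": "sex", "rates": {"male": 0.5, "female": 1.0}}
    ref = syn.draw_reference_sample(pop, n_ref=1_000, design_scheme=scheme, seed=35)
    dw = ref.groupby(ref["sex"].astype(str), observed=True)["design_weight"].first()
    # male stratum sampled at half rate -> design weight ~2x female's
    assert dw["male"] / dw["female"] == pytest.approx(2.0, rel=0.15)
    # Horvitz-Thompson: design-weighted reference means track population means
    for var in ("age", "education"):
        m = np.average(ref[var], weights=ref["design_weight"])
        se = pop[var].std() / np.sqrt(len(ref))
        assert abs(m - pop[var].mean()) < 5 * se


def test_reference_sample_validation():
    aux = _population(seed=36).head(100)
    pop = syn.apply_participation(aux, syn.ParticipationModel({}, 0.1), seed=37)
    with pytest.raises(ValueError):
        syn.draw_reference_sample(pop, n_ref=0)
    with pytest.raises(ValueError):
        syn.draw_reference_sample(pop, n_ref=101)


def test_generate_scenario_determinism_and_shapes():
    sc = syn.healthy_volunteer_scenario(seed=123, n_population=2_000, n_snps=100,
                                        n_reference=200)
    d1 = syn.generate_scenario(sc)
    sc2 = syn.healthy_volunteer_scenario(seed=123, n_population=2_000, n_snps=100,
                                         n_reference=200)
    d2 = syn.generate_scenario(sc2)
    np.testing.assert_array_equal(d1["genotypes"].dosages, d2["genotypes"].dosages)
    pd.testing.assert_frame_equal(d1["population"], d2["population"])
    assert len(d1["reference"]) == 200
    assert d1["selected"]["participation"].eq(1).all()
    assert set(d1["traits"].columns) == {"health", "ses"}


def test_stack_cohorts_labels():
    sel = pd.DataFrame({"id": ["a"], "age": [50.0]})
    ref = pd.DataFrame({"id": ["b"], "age": [60.0]})
    stacked = syn.stack_cohorts(sel, ref)
    assert stacked["participation"].tolist() == [1, 0]
    assert (stacked["design_weight"] == 1.0).all()
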