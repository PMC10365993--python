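"""Shared fixtures for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from wgwas import synthetic as syn


@pytest.fixture(scope="session")
def small_genotypes() -> syn.GenotypeSet:
    """400 individuals x 60 SNPs with block LD, deterministic."""
    cfg = syn.PopulationConfig(
        n_population=400, n_snps=60, ld_block_size=5, ld_rho=0.3, seed=11
    )
    return syn.simulate_genotypes(cfg)


@pytest.fixture(scope="session")
def tiny_cohort() -> pd.DataFrame:
    """Small stacked cohort with both labels, for design/weights tests."""
    rng = np.random.default_rng(5)
    n = 600
    traits = pd.DataFrame(
        {"health": rng.normal(size=n), "ses": rng.normal(size=n)}
    )
    aux = syn.simulate_auxiliary(traits, syn.HEALTHY_VOLUNTEER_LOADINGS, seed=6)
    pop = syn.apply_participation(
        aux,
        syn.ParticipationModel(syn.HEALTHY_VOLUNTEER_SELECTION, target_fraction=0.3),
        seed=7,
    )
    sel = pop[pop["participation"] == 1]
    ref = syn.draw_reference_sample(pop, n_ref=150, seed=8)
    return syn.stack_cohorts(sel, ref)
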