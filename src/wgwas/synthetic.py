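"""Synthetic cohorts with a known participation mechanism.

The generator emulates the structure of a volunteer biobank study: a large
target population with genotypes in Hardy–Weinberg proportions (optionally
with local LD), polygenic traits with chosen heritability, a 14-variable
auxiliary profile (5 continuous, 9 categorical) derived from the traits,
a logistic participation mechanism acting on the auxiliary variables
(which creates the collider structure that biases naive analyses), and a
small representative reference sample with optional survey design weights.

Because the participation probability of every individual is stored
(``true_P``), oracle inverse-probability weights ``(1 - P) / P`` are
available as ground truth for every downstream stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import norm

# ---------------------------------------------------------------------------
# Auxiliary-variable schema
# ---------------------------------------------------------------------------

#: Continuous auxiliary variables (as-is columns in the participation design).
CONTINUOUS_AUX: tuple[str, ...] = ("age", "bmi", "weight", "height", "education")

#: Categorical auxiliary variables and their ordered level sets.  The level
#: counts are (7, 2, 6, 3, 4, 5, 4, 3, 3); together with the 5 continuous
#: variables this yields 42 main-effect columns under all-level dummy coding.
CATEGORICAL_AUX_LEVELS: dict[str, tuple[str, ...]] = {
    "household_size": ("1", "2", "3", "4", "5", "6", "7plus"),
    "sex": ("male", "female"),
    "alcohol_freq": ("never", "yearly", "monthly", "weekly_1_2", "weekly_3_4", "daily"),
    "smoking": ("never", "previous", "current"),
    "employment": ("employed", "inactive", "retired", "unemployed"),
    "income": ("lt_18k", "18_31k", "31_52k", "52_100k", "gt_100k"),
    "obesity": ("underweight", "healthy", "overweight", "obese"),
    "overall_health": ("poor", "fair", "good"),
    "urbanisation": ("village", "town", "urban"),
}

AUX_VARIABLES: tuple[str, ...] = CONTINUOUS_AUX + tuple(CATEGORICAL_AUX_LEVELS)

# Marginal level probabilities used when discretizing categorical latents.
# Chosen as plausible mid-life general-population frequencies; the joint
# distribution is induced by the latent trait loadings, not matched to any
# real survey.
_CATEGORICAL_MARGINALS: dict[str, tuple[float, ...]] = {
    "household_size": (0.14, 0.33, 0.16, 0.20, 0.09, 0.05, 0.03),
    "sex": (0.49, 0.51),
    "alcohol_freq": (0.15, 0.10, 0.10, 0.25, 0.20, 0.20),
    "smoking": (0.50, 0.30, 0.20),
    "employment": (0.60, 0.10, 0.22, 0.08),
    "income": (0.25, 0.30, 0.25, 0.15, 0.05),
    "obesity": (0.02, 0.35, 0.38, 0.25),
    "overall_health": (0.10, 0.25, 0.65),
    "urbanisation": (0.20, 0.15, 0.65),
}

# Location / scale used to place continuous auxiliaries on a natural scale.
_CONTINUOUS_LOC_SCALE: dict[str, tuple[float, float]] = {
    "age": (56.0, 8.0),
    "bmi": (27.0, 4.5),
    "weight": (78.0, 15.0),
    "height": (169.0, 9.0),
    "education": (17.0, 2.5),
}


# ---------------------------------------------------------------------------
# Configuration types
# ---------------------------------------------------------------------------


@dataclass
class PopulationConfig:
    """Size and genotype structure of the simulated target population."""

    n_population: int
    n_snps: int
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 1
    ld_rho: float = 0.0
    seed: int = 0
    bp_spacing: int = 5_000  # base pairs between adjacent SNPs

    def __post_init__(self) -> None:
        if self.n_population <= 0 or self.n_snps <= 0:
            raise ValueError("n_population and n_snps must be positive")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError(f"maf_range must lie within (0, 1), got {self.maf_range}")
        if self.ld_block_size < 1:
            raise ValueError("ld_block_size must be >= 1")
        if not (0.0 <= self.ld_rho < 1.0):
            raise ValueError("ld_rho must be in [0, 1)")


@dataclass
class TraitModel:
    """Additive polygenic trait.

    ``causal_effects`` holds one additive effect per SNP (zeros allowed).
    The environmental noise is scaled so the realized genetic variance share
    equals ``h2_target``.  If ``liability_threshold_prevalence`` (K) is set,
    the continuous liability is dichotomized at the 1 - K quantile.
    """

    causal_effects: np.ndarray
    h2_target: float
    liability_threshold_prevalence: Optional[float] = None

    def __post_init__(self) -> None:
        self.causal_effects = np.asarray(self.causal_effects, dtype=float)
        if not (0.0 <= self.h2_target <= 1.0):
            raise ValueError("h2_target must be in [0, 1]")
        K = self.liability_threshold_prevalence
        if K is not None and not (0.0 < K < 1.0):
            raise ValueError("liability_threshold_prevalence must be in (0, 1)")


@dataclass
class ParticipationModel:
    """Logistic participation mechanism on standardized auxiliary scores.

    ``logit_coefficients`` maps auxiliary-variable names — or unordered
    pairs of distinct names, written as 2-tuples — to coefficients on the
    logit scale.  Each variable enters as a z-score (continuous variables
    standardized directly, categorical variables through their standardized
    level index); a pair key contributes the product of the two z-scores.
    The intercept is solved numerically so that the expected selected
    fraction equals ``target_fraction``.

    Interaction (pair) terms are what make participation a genuine collider
    for variable *pairs*: a purely additive logistic tilt of jointly
    Gaussian-latent auxiliaries shifts their means but leaves pairwise
    correlations almost unchanged, whereas a product term with coefficient
    ``b`` shifts the selected-sample correlation of that pair by ≈ ``b``.
    """

    logit_coefficients: Mapping[str | tuple[str, str], float]
    target_fraction: float = 0.10

    def __post_init__(self) -> None:
        if not (0.0 < self.target_fraction < 1.0):
            raise ValueError("target_fraction must be in (0, 1)")
        for key in self.logit_coefficients:
            if isinstance(key, tuple):
                if len(key) != 2 or key[0] == key[1]:
                    raise ValueError(
                        f"interaction key must pair two distinct variables: {key!r}"
                    )
                names = key
            else:
                names = (key,)
            unknown = set(names) - set(AUX_VARIABLES)
            if unknown:
                raise ValueError(f"unknown auxiliary variables: {sorted(unknown)}")


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------


@dataclass
class GenotypeSet:
    """Individuals x SNPs dosage matrix with per-SNP metadata.

    Dosages are stored as ``int8`` counts of the A1 allele in {0, 1, 2},
    with ``-1`` marking a missing call.  ``snp_meta`` has one row per SNP
    with columns ``snp, chrom, pos, a1, a2, freq`` where ``freq`` is the A1
    allele frequency among non-missing calls.
    """

    dosages: np.ndarray
    snp_meta: pd.DataFrame

    MISSING: int = field(default=-1, repr=False)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (individuals x SNPs)")
        if len(self.snp_meta) != self.dosages.shape[1]:
            raise ValueError("snp_meta rows must match number of SNP columns")
        for chrom, grp in self.snp_meta.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(
                    f"positions must be strictly increasing within chromosome {chrom}"
                )

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def dosage_float(self, imputed: bool = False) -> np.ndarray:
        """Dosages as float64 with missing calls as NaN (or mean-imputed)."""
        X = self.dosages.astype(np.float64)
        miss = self.dosages < 0
        if miss.any():
            X[miss] = np.nan
            if imputed:
                col_mean = np.nanmean(X, axis=0)
                idx = np.where(miss)
                X[idx] = col_mean[idx[1]]
        return X

    def allele_frequencies(self) -> np.ndarray:
        """A1 allele frequency per SNP over non-missing calls."""
        X = self.dosages.astype(np.float64)
        present = self.dosages >= 0
        with np.errstate(invalid="ignore"):
            return np.where(present, X, 0.0).sum(axis=0) / (2.0 * present.sum(axis=0))

    def subset(self, individuals=None, snps=None) -> "GenotypeSet":
        dos = self.dosages
        meta = self.snp_meta
        if individuals is not None:
            dos = dos[np.asarray(individuals)]
        if snps is not None:
            snps = np.asarray(snps)
            dos = dos[:, snps]
            meta = meta.iloc[snps].reset_index(drop=True)
        meta = meta.copy()
        g = GenotypeSet(dosages=dos.copy(), snp_meta=meta)
        g.snp_meta["freq"] = g.allele_frequencies()
        return g


def simulate_genotypes(config: PopulationConfig) -> GenotypeSet:
    """Draw genotypes in Hardy–Weinberg proportions with optional block LD.

    Each SNP's minor allele frequency is drawn uniformly from
    ``config.maf_range``.  A Gaussian copula with block-equicorrelation
    ``ld_rho`` (blocks of ``ld_block_size`` adjacent SNPs) is thresholded at
    the Hardy–Weinberg cumulative genotype probabilities, so the marginal
    genotype distribution at each SNP is exactly HWE while adjacent SNPs in
    a block share tunable LD.  Cross-block LD is zero by construction.
    """
    rng = np.random.default_rng(config.seed)
    n, m = config.n_population, config.n_snps
    maf = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)

    # HWE cumulative cut points on the latent normal scale:
    # P(g=0) = (1-p)^2, P(g<=1) = (1-p)^2 + 2p(1-p)
    q0 = (1.0 - maf) ** 2
    q1 = q0 + 2.0 * maf * (1.0 - maf)
    c0 = norm.ppf(q0).astype(np.float32)
    c1 = norm.ppf(q1).astype(np.float32)

    dosages = np.empty((n, m), dtype=np.int8)
    rho = config.ld_rho
    bs = config.ld_block_size
    # chunk whole LD blocks together; transient float arrays stay ~100 MB
    snps_per_chunk = max(bs, (256 * bs) if bs > 1 else 512)
    snps_per_chunk = min(snps_per_chunk, max(bs, int(2**21 * 64 // max(n, 1))))
    snps_per_chunk = max(bs, (snps_per_chunk // bs) * bs)
    for start in range(0, m, snps_per_chunk):
        stop = min(start + snps_per_chunk, m)
        width = stop - start
        z = rng.standard_normal((n, width), dtype=np.float32)
        if rho > 0.0 and bs > 1:
            n_blocks = -(-width // bs)
            shared = rng.standard_normal((n, n_blocks), dtype=np.float32)
            shared = np.repeat(shared, bs, axis=1)[:, :width]
            z *= np.float32(np.sqrt(1.0 - rho))
            z += np.float32(np.sqrt(rho)) * shared
        chunk = (
            (z > c0[start:stop]).astype(np.int8) + (z > c1[start:stop]).astype(np.int8)
        )
        dosages[:, start:stop] = chunk

    meta = pd.DataFrame(
        {
            "snp": [f"rs{j + 1}" for j in range(m)],
            "chrom": np.ones(m, dtype=int),
            "pos": 1 + config.bp_spacing * np.arange(m, dtype=np.int64),
            "a1": "A",
            "a2": "G",
        }
    )
    g = GenotypeSet(dosages=dosages, snp_meta=meta)
    g.snp_meta["freq"] = g.allele_frequencies()
    return g


# ---------------------------------------------------------------------------
# Phenotypes and auxiliaries
# ---------------------------------------------------------------------------


def simulate_phenotype(
    g: GenotypeSet,
    model: TraitModel,
    seed: int = 0,
    return_components: bool = False,
):
    """Additive polygenic phenotype with heritability ``model.h2_target``.

    The genetic value is the centered dosage matrix times the causal
    effects; Gaussian noise is added with variance chosen so the realized
    genetic variance share equals the target.  With ``h2_target == 0`` the
    phenotype is pure standard-normal noise.  Binary traits threshold the
    liability at the ``1 - K`` quantile of its realized distribution, so the
    case fraction is ~K by construction.
    """
    if len(model.causal_effects) != g.n_snps:
        raise ValueError("causal_effects length must equal the number of SNPs")
    rng = np.random.default_rng(seed)
    n = g.n_individuals

    causal = np.flatnonzero(model.causal_effects)
    genetic = np.zeros(n)
    if causal.size and model.h2_target > 0:
        X = g.dosages[:, causal].astype(np.float64)
        X[X < 0] = np.nan
        X = np.where(np.isnan(X), np.nanmean(X, axis=0), X)
        X -= X.mean(axis=0)
        genetic = X @ model.causal_effects[causal]

    var_g = genetic.var()
    h2 = model.h2_target
    if h2 <= 0 or var_g == 0.0:
        phen = rng.standard_normal(n)
        genetic = np.zeros(n)
    else:
        noise_sd = np.sqrt(var_g * (1.0 - h2) / h2) if h2 < 1.0 else 0.0
        phen = genetic + noise_sd * rng.standard_normal(n)

    K = model.liability_threshold_prevalence
    if K is not None:
        threshold = np.quantile(phen, 1.0 - K)
        binary = (phen > threshold).astype(float)
        if return_components:
            return binary, genetic, phen
        return binary
    if return_components:
        return phen, genetic, phen
    return phen


def simulate_auxiliary(
    phenotypes: pd.DataFrame,
    loadings: Mapping[str, Mapping[str, float]],
    seed: int = 0,
    noise_sd: float = 1.0,
) -> pd.DataFrame:
    """Derive the 14 auxiliary variables from latent traits.

    Each auxiliary variable is built from a latent score: the weighted sum
    of the z-scored traits named in ``loadings[aux]`` plus independent
    Gaussian noise with standard deviation ``noise_sd``.  Continuous
    auxiliaries rescale the standardized latent to a natural location and
    scale; categorical ones are discretized at the Gaussian quantiles of
    fixed marginal level probabilities, preserving the declared ordered
    level sets.
    """
    rng = np.random.default_rng(seed)
    n = len(phenotypes)
    zs = {
        c: (phenotypes[c] - phenotypes[c].mean()) / phenotypes[c].std(ddof=0)
        for c in phenotypes.columns
    }

    out = {}
    for aux in AUX_VARIABLES:
        latent = noise_sd * rng.standard_normal(n)
        for trait, coef in loadings.get(aux, {}).items():
            if trait not in zs:
                raise KeyError(f"loading for {aux!r} names unknown trait {trait!r}")
            latent = latent + coef * zs[trait].to_numpy()
        sd = latent.std()
        if sd > 0:
            latent = (latent - latent.mean()) / sd
        if aux in CONTINUOUS_AUX:
            loc, scale = _CONTINUOUS_LOC_SCALE[aux]
            out[aux] = loc + scale * latent
        else:
            levels = CATEGORICAL_AUX_LEVELS[aux]
            probs = _CATEGORICAL_MARGINALS[aux]
            cuts = norm.ppf(np.cumsum(probs[:-1]))
            codes = np.searchsorted(cuts, latent, side="left")
            out[aux] = pd.Categorical.from_codes(codes, categories=list(levels))
    df = pd.DataFrame(out)
    df.insert(0, "id", [f"ind_{i}" for i in range(n)])
    return df


# ---------------------------------------------------------------------------
# Participation and reference sampling
# ---------------------------------------------------------------------------


def _numeric_aux_scores(cohort: pd.DataFrame) -> pd.DataFrame:
    """Standardized numeric encoding of all auxiliary variables."""
    scores = {}
    for aux in AUX_VARIABLES:
        col = cohort[aux]
        if aux in CONTINUOUS_AUX:
            x = col.to_numpy(dtype=float)
        else:
            if isinstance(col.dtype, pd.CategoricalDtype):
                x = col.cat.codes.to_numpy(dtype=float)
            else:
                levels = list(CATEGORICAL_AUX_LEVELS[aux])
                x = col.map({lv: i for i, lv in enumerate(levels)}).to_numpy(dtype=float)
        sd = x.std()
        scores[aux] = (x - x.mean()) / sd if sd > 0 else np.zeros(len(x))
    return pd.DataFrame(scores, index=cohort.index)


def apply_participation(
    cohort: pd.DataFrame, pm: ParticipationModel, seed: int = 0
) -> pd.DataFrame:
    """Select individuals with probability expit(intercept + sum coef*aux).

    The intercept is calibrated by root finding so the mean selection
    probability equals ``pm.target_fraction``.  Adds columns ``true_P``
    (the individual participation probability) and ``participation``
    (the realized Bernoulli label).
    """
    scores = _numeric_aux_scores(cohort)
    lp = np.zeros(len(cohort))
    for key, coef in pm.logit_coefficients.items():
        if isinstance(key, tuple):
            a, b = key
            lp += coef * scores[a].to_numpy() * scores[b].to_numpy()
        else:
            lp += coef * scores[key].to_numpy()
    if not np.all(np.isfinite(lp)):
        raise ValueError("non-finite linear predictor in participation model")

    def mean_gap(c: float) -> float:
        return expit(c + lp).mean() - pm.target_fraction

    intercept = brentq(mean_gap, -40.0, 40.0, xtol=1e-12)
    true_p = expit(intercept + lp)

    rng = np.random.default_rng(seed)
    out = cohort.copy()
    out["true_P"] = true_p
    out["participation"] = (rng.random(len(cohort)) < true_p).astype(int)
    out["design_weight"] = 1.0
    return out


def draw_reference_sample(
    population: pd.DataFrame,
    n_ref: int,
    design_scheme: Optional[Mapping] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw a representative reference sample from the target population.

    With ``design_scheme=None`` the sample is a simple random sample and
    all design weights are 1.  Otherwise ``design_scheme`` is a mapping
    with keys ``column`` (a categorical auxiliary) and ``rates`` (relative
    inclusion rates per level); allocation is proportional to stratum size
    times rate, and each sampled row receives the Horvitz–Thompson design
    weight N_stratum / n_sampled_in_stratum.
    """
    if n_ref <= 0:
        raise ValueError("n_ref must be positive")
    if n_ref > len(population):
        raise ValueError("n_ref exceeds population size")
    rng = np.random.default_rng(seed)

    if design_scheme is None:
        idx = rng.choice(len(population), size=n_ref, replace=False)
        ref = population.iloc[np.sort(idx)].copy()
        ref["design_weight"] = 1.0
    else:
        column = design_scheme["column"]
        rates = design_scheme["rates"]
        levels = population[column].astype(str)
        parts = []
        alloc = {
            lv: len(grp) * float(rates.get(lv, 1.0))
            for lv, grp in population.groupby(levels, sort=True, observed=True)
        }
        total = sum(alloc.values())
        for lv, grp in population.groupby(levels, sort=True, observed=True):
            n_h = max(1, int(round(n_ref * alloc[lv] / total)))
            n_h = min(n_h, len(grp))
            take = rng.choice(len(grp), size=n_h, replace=False)
            sub = grp.iloc[np.sort(take)].copy()
            sub["design_weight"] = len(grp) / n_h
            parts.append(sub)
        ref = pd.concat(parts).sort_index()

    ref["participation"] = 0
    return ref


def stack_cohorts(selected: pd.DataFrame, reference: pd.DataFrame) -> pd.DataFrame:
    """Stack the selected sample (label 1) on the reference sample (label 0)."""
    sel = selected.copy()
    sel["participation"] = 1
    if "design_weight" not in sel.columns:
        sel["design_weight"] = 1.0
    ref = reference.copy()
    ref["participation"] = 0
    if "design_weight" not in ref.columns:
        ref["design_weight"] = 1.0
    return pd.concat([sel, ref], ignore_index=True)


# ---------------------------------------------------------------------------
# Canned scenarios
# ---------------------------------------------------------------------------

#: Trait loadings of the default healthy-volunteer scenario.  Two latent
#: traits drive the auxiliaries: ``health`` (overall physical health) and
#: ``ses`` (socio-economic standing).  Education, income and health status
#: load positively; smoking and adiposity load negatively on health.
HEALTHY_VOLUNTEER_LOADINGS: dict[str, dict[str, float]] = {
    "education": {"ses": 0.9},
    "income": {"ses": 0.8},
    "overall_health": {"health": 0.9},
    "smoking": {"health": -0.5, "ses": -0.4},
    "bmi": {"health": -0.6},
    "weight": {"health": -0.4},
    "obesity": {"health": -0.7},
    "employment": {"ses": -0.3, "health": -0.3},
    "alcohol_freq": {"ses": 0.3},
    "household_size": {"ses": 0.2},
    "age": {"health": -0.2},
}

#: Participation coefficients of the default scenario: positive selection on
#: education, health and income analogues, negative on smoking — the
#: healthy-volunteer pattern of large volunteer biobanks — plus pairwise
#: interaction terms (e.g. sex-by-education, employment-by-health,
#: household-size-by-income), which are what distorts pairwise
#: *correlations* in the selected sample rather than only shifting means.
#: Interaction mass is concentrated on pairs involving a continuous or
#: low-cardinality variable so that the distortion is identifiable from a
#: survey-sized reference sample, and coefficient magnitudes sit at the
#: top of the correlation-bias range that volunteer-biobank weighting
#: studies document (pairwise distortions up to ~0.2, with the normalized
#: weights leaving an effective sample of roughly a quarter to a third of
#: the nominal one).
HEALTHY_VOLUNTEER_SELECTION: dict = {
    "education": 0.40,
    "overall_health": 0.30,
    "income": 0.25,
    "smoking": -0.25,
    "age": 0.20,
    ("employment", "overall_health"): 0.35,
    ("age", "overall_health"): 0.30,
    ("sex", "education"): 0.30,
    ("age", "bmi"): -0.30,
    ("smoking", "overall_health"): -0.30,
    ("sex", "age"): 0.30,
    ("sex", "bmi"): -0.25,
    ("age", "smoking"): -0.25,
    ("education", "age"): 0.25,
}


@dataclass
class Scenario:
    """A full simulation recipe: population, traits, auxiliaries, selection."""

    population: PopulationConfig
    trait_h2: Mapping[str, float]
    trait_n_causal: Mapping[str, int]
    loadings: Mapping[str, Mapping[str, float]]
    participation: ParticipationModel
    n_reference: int = 2_000
    reference_design_scheme: Optional[Mapping] = None
    seed: int = 0


def healthy_volunteer_scenario(
    seed: int = 0,
    n_population: int = 50_000,
    n_snps: int = 5_000,
    n_reference: int = 2_000,
    target_fraction: float = 0.10,
) -> Scenario:
    """Default collider scenario mirroring healthy-volunteer selection.

    Participation selects ~10% of the target population (a desk-scale
    fraction giving ~5,000 volunteers from the 50,000 default population)
    on education, health, income (positively) and smoking (negatively),
    with interaction terms that additionally distort pairwise correlations
    among the selected — the collider signature of volunteer cohorts.
    """
    return Scenario(
        population=PopulationConfig(
            n_population=n_population,
            n_snps=n_snps,
            maf_range=(0.05, 0.5),
            ld_block_size=5,
            ld_rho=0.35,
            seed=seed,
        ),
        trait_h2={"health": 0.3, "ses": 0.3},
        trait_n_causal={"health": 500, "ses": 500},
        loadings=HEALTHY_VOLUNTEER_LOADINGS,
        participation=ParticipationModel(
            logit_coefficients=HEALTHY_VOLUNTEER_SELECTION,
            target_fraction=target_fraction,
        ),
        n_reference=n_reference,
        seed=seed,
    )


def generate_scenario(scenario: Scenario) -> dict:
    """Materialize a scenario: genotypes, traits, cohort, reference sample.

    Returns a dict with keys ``genotypes`` (GenotypeSet over the full
    population), ``traits`` (DataFrame of latent trait values),
    ``causal_effects`` (dict trait -> effect vector), ``population``
    (CohortTable with participation labels and true_P), ``selected`` and
    ``reference`` (CohortTable subsets), and ``selected_index`` /
    ``reference_index`` (row indices into the population genotypes).
    """
    seq = np.random.SeedSequence(scenario.seed)
    seeds = seq.generate_state(4 + len(scenario.trait_h2))

    pop_cfg = scenario.population
    pop_cfg.seed = int(seeds[0]) % (2**31)
    g = simulate_genotypes(pop_cfg)

    rng = np.random.default_rng(int(seeds[1]) % (2**31))
    traits = {}
    effects = {}
    for k, name in enumerate(sorted(scenario.trait_h2)):
        m_causal = min(scenario.trait_n_causal[name], g.n_snps)
        beta = np.zeros(g.n_snps)
        causal_idx = rng.choice(g.n_snps, size=m_causal, replace=False)
        beta[causal_idx] = rng.standard_normal(m_causal) / np.sqrt(m_causal)
        model = TraitModel(causal_effects=beta, h2_target=scenario.trait_h2[name])
        traits[name] = simulate_phenotype(g, model, seed=int(seeds[4 + k]) % (2**31))
        effects[name] = beta
    traits_df = pd.DataFrame(traits)

    aux = simulate_auxiliary(
        traits_df, scenario.loadings, seed=int(seeds[2]) % (2**31)
    )
    population = apply_participation(
        aux, scenario.participation, seed=int(seeds[3]) % (2**31)
    )

    selected_index = np.flatnonzero(population["participation"].to_numpy() == 1)
    reference = draw_reference_sample(
        population,
        scenario.n_reference,
        design_scheme=scenario.reference_design_scheme,
        seed=(int(seeds[3]) + 1) % (2**31),
    )
    reference_index = reference.index.to_numpy()

    return {
        "genotypes": g,
        "traits": traits_df,
        "causal_effects": effects,
        "population": population,
        "selected": population.iloc[selected_index].copy(),
        "reference": reference,
        "selected_index": selected_index,
        "reference_index": reference_index,
    }
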