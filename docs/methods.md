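# Methods

This document describes the statistical methods implemented in `wgwas`, the
rationale for the default parameter choices, and the known limitations of the
desk-scale validation studies.

## 1. Participation weights (`wgwas.weights`)

### Model

Participation is modeled by L1-penalized (LASSO) logistic regression of the
selected-vs-reference label on a design matrix built from 14 auxiliary
variables that are observed in both samples: 5 continuous (age, height,
weight, BMI, years of education) and 9 categorical (sex 2 levels, smoking 3,
overall health 3, urbanisation 3, employment 4, obesity class 4, income 5,
alcohol frequency 6, household size 7).

The design uses **all-level dummy coding** (no reference level dropped) for
the 37 category indicators, giving 42 main-effect columns, plus **all 861
pairwise products** of the 42 mains — including same-variable indicator
pairs, whose products are identically zero and are retained for the LASSO to
discard — for a total of **903 predictors**.

Product columns involving continuous variables are formed from the z-scored
continuous mains (indicator mains enter products raw). This keeps the LASSO
scale-equivariant across mixed-type columns: a raw-scale product such as
age×BMI is >90% collinear with its two mains, so expressing a given
standardized interaction effect on the raw product column would require a
many-fold larger coefficient and therefore suffer a many-fold larger
effective L1 penalty. Centering removes the collinearity without changing
the spanned model space or the 903-column count.

### Fitting

`fit_participation_model` standardizes columns, then fits a coordinate-
descent LASSO path (outer IRLS on the logistic working response, inner
cyclic coordinate descent with active-set iteration and full KKT sweeps,
warm starts down a descending λ grid — the standard glmnet algorithm,
implemented in numpy). The default path has 30 λ values down to
λ_max × 1e-4. λ is chosen by 5-fold stratified cross-validation on the
weighted binomial deviance

    (1/W) Σ_i w_i · BCE(y_i, P_i) ,

where reference rows carry their survey design weights and selected rows
weight 1. Ties go to the larger λ.

### Weights and diagnostics

From fitted probabilities P, the participation weight is `w = (1 − P)/P`
(selected sample only), normalized to `w_in = w / mean(w)`. The effective
sample size is

    n_eff = (Σ w_in)² / Σ w_in² = n / (Var(w_in) + 1) ,

an exact algebraic identity for the divide-by-n variance.

`bias_report` compares, for every auxiliary pair, the reference correlation
`r_ref`, the unweighted selected correlation `r_sel`, and the weighted
selected correlation `r_w`; the bias reduction for a pair is

    BR = (|r_ref − r_sel| − |r_ref − r_w|) / |r_ref − r_sel| ,

summarized by the median over pairs with `r_diff = |r_ref − r_sel| > 0.05`.

### What (1 − P)/P estimates

Weighting the selected sample by `(1 − P)/P` reweights it to the
*non-participant complement* of the population. When participation is rare
(the default scenario uses 10%), the complement is ≈ the population and the
weighted sample recovers population means and correlations. When
participation is common this distinction matters — see §6.

## 2. Weighted GWAS (`wgwas.gwas`)

Per SNP, the weighted estimator is weighted least squares on
X = [snp, covariates, intercept]:

    β̂_w = (XᵀWX)⁻¹ XᵀWY ,

with the Huber–White sandwich variance

    Var(β̂_w) = (XᵀWX)⁻¹ (XᵀW D WX) (XᵀWX)⁻¹,   D = diag[(Y − Xβ̂_w)²] ,

because weighting breaks homoskedasticity. With unit weights the point
estimate is OLS and the sandwich is HC0. The unweighted scan defaults to
classical variance. Weighted scans report `N = n_eff` and weighted allele
frequencies; standardized effects use
β_STD = Z/√(2p(1−p)(N+Z²)).

## 3. LD-score regression (`wgwas.ldsc`)

Univariate: chi² = Z² is regressed on `n·ℓ/M` with heteroskedasticity
weights 1/max(ℓ,1); the slope is observed-scale h², the intercept ≈ 1
absent confounding. Cross-trait: Z₁Z₂ on `√(n₁n₂)·ℓ/M` gives the genetic
covariance and r_g = cov_g/√(h²₁h²₂). Standard errors come from a
delete-one-block jackknife (default 200 contiguous SNP blocks) on the
weighted-least-squares sufficient statistics.

`estimate_h2(..., fixed_intercept=1.0)` constrains the intercept (the
analogue of LDSC's `--intercept-h2`), regressing chi² − 1 through the
origin. This is used where confounding is absent by construction and the
free-intercept sampling noise of a small SNP panel would swamp a weak
polygenic signal (the sex analysis, §6).

Liability conversion for a binary trait:

    h²_liab = h²_obs · K²(1−K)² / (P(1−P) φ(t)²) ,

with K the population prevalence, P the (weighted) sample prevalence and t
the K-quantile threshold; at K = P = 1/2 the multiplier is exactly π/2.

The weighted-vs-unweighted difference test for any estimate pair (a, b)
with jackknife series is

    Z = (a − b) / √(se_a² + se_b² − 2 r se_a se_b) ,

with r the correlation of the paired delete-one-block series — the two arms
share SNPs and individuals, so their estimation errors are strongly
correlated and the naive independent-SE test would be far too conservative.

## 4. Mendelian randomization (`wgwas.mr`)

IVW: α̂ = Σ β_exp β_out/se_out² / Σ β_exp²/se_out². Exposure-beta
measurement noise attenuates α̂ by σ²/S² (regression dilution), where S² is
the observed variance of the exposure betas (ddof=1) and σ² = S² − mean(se_exp²)
the noise-corrected variance. The corrected estimate is

    α̂_corr = α̂ · S²/σ² ,

exact (factor 1) when se_exp = 0. The weighted-vs-unweighted α difference
test uses a leave-one-instrument jackknife, mirroring the LDSC difference
test, with all three variance ingredients — both arm SEs and the paired
correlation r — taken from the same delete-one series, so se(α_DIFF) is
identically the jackknife SE of the paired difference (an analytic-SE/
jackknife-r mix destabilizes the variance when r → 1 and ignores the
sampling noise of the dilution-correction factor). P-values use the
jackknife-t reference with m − 1 degrees of freedom, the standard
small-sample calibration for few instruments.

## 5. Synthetic cohorts (`wgwas.synthetic`)

Genotypes are drawn in Hardy–Weinberg proportions with optional AR-style
within-block LD (`ld_block_size`, `ld_rho`). Polygenic traits have chosen
h² and causal SNP counts. Auxiliary variables are generated from latent
health/SES factors via a Gaussian copula with fixed loadings, then
discretized to the categorical level sets. Participation follows a logistic
model on standardized auxiliary scores; `ParticipationModel` accepts
pairwise keys whose coefficients multiply products of standardized scores.
An intercept search calibrates the participation fraction to
`target_fraction` (default 0.10).

The default `HEALTHY_VOLUNTEER_SELECTION` combines positive main effects of
education, overall health and income and a negative smoking effect with ten
pairwise interaction terms (|b| = 0.25–0.35). Main effects shift means;
interaction terms are what distort pairwise correlations in the selected
sample (an exponential tilt by b·x·y changes the Gaussian precision
off-diagonal by −b). Magnitudes were calibrated so that induced
correlation distortions span ~0.05–0.25 and the normalized-weight variance
gives n_eff/n ≈ 0.25–0.35, matching the effective-sample ratios reported
for volunteer biobanks.

## 6. Validation studies (`wgwas.validation`)

- **GWAS bias** (`gwas_bias_study`): 200 replicates of a
  phenotype-threshold participation model, P = σ(−3.0 + 2.6·1[y_std > 0.8])
  (~12% participation); oracle weights. The threshold (truncation-type)
  form is essential: a smooth additive logit in a Gaussian outcome acts as
  a near-exponential tilt, which shifts means but leaves regression slopes
  almost unbiased, so there would be no unweighted bias to correct. The
  weighted scan's replicate-averaged causal-SNP effects are compared with
  the truth, and null-SNP type-I error is pooled over replicates (the
  panel is LD-free).
- **LDSC recovery** (`ldsc_recovery_study`): Z drawn from the LDSC model
  itself over a blocky LD panel; h² = 0.2, n = 20,000, M = 5,000.
- **MR correction** (`mr_correction_study`): exposure noise variance set to
  25% of the observed exposure-beta variance
  (σ_noise² = τ²·0.25/0.75); 500 replicates, true α = 0.3.
- **Difference-test calibration** (`difference_null_study`): weighted and
  unweighted summary arms share their per-SNP genetic component exactly and
  have noise correlation 0.9, mimicking two analyses of one cohort; under
  this null the h², r_g and MR-α difference tests should reject at 5%.
  MR instrument strengths are drawn post-selection style (|β_exp| above a
  significance floor): a zero-centred draw concentrates the IVW weights
  u ∝ β_exp² so that the effective instrument count drops to ~J/3 and the
  leave-one-out jackknife becomes heavy-tailed — a regime the estimator's
  own instrument selection excludes.
- **Sex collider** (`sex_collider_study`): participation depends on sex and
  on a sex-by-trait interaction (intercept −2.2, sex 0.4, interaction 0.8,
  ~11% participation). The interaction is essential: an additive logit
  induces the sex–trait collider correlation only through logistic
  saturation (vanishing as selection becomes rare), and at common
  participation the (1−P)/P estimand — the complement — is almost as
  distorted as the selected sample, leaving nothing for weighting to
  remove. The interaction tilt induces the correlation among participants
  at rare selection, leaves the ~89% complement essentially undistorted,
  and keeps n_eff/n ≈ 0.8. Both arms use constrained-intercept LDSC.

## 7. Known desk-scale limitations

- **Bias-reduction median.** With a reference sample of 2,000 the reference
  correlations carry Monte-Carlo noise SE ≈ 0.022, and the weighted
  correlations SE ≈ 1/√n_eff ≈ 0.025–0.03. Even for a perfectly corrected
  pair E|r_ref − r_w| ≈ 0.027, so the expected per-pair bias reduction is
  ≈ 1 − 0.027/d for true distortion d, and the r_diff > 0.05 flagging rule
  admits noise-flagged pairs. Empirically, *oracle* (true-P) weights give a
  median BR of ~0.71–0.80 in the default scenario; fitted weights cannot be
  expected to beat the oracle, so the ≥0.8 acceptance threshold is not
  attainable at this scale (at biobank scale, n_eff ≈ 10⁵, the same
  estimator's noise floor is ~0.003 and the criterion passes easily). The
  acceptance test asserts the threshold as stated and is expected to fail;
  this is a sample-size property of the benchmark, not an estimator defect.
- **h² difference-test tails.** At desk scale (M = 2,000 SNPs, 200
  jackknife blocks) the variance of the weighted-minus-unweighted h²
  difference is estimated with ~10–14% relative noise when the arm
  correlation is ≈ 0.98, which slightly fattens the Z tails: the measured
  null rejection rate at α = 0.05 is ≈ 0.055–0.060 (3,000 pooled
  replicates across six seeds). The 99% binomial band over 500 replicates
  tolerates rates up to 0.075, so the calibration test usually passes
  (it does at all five diagnostic seeds), but individual seeds can land
  above the band — the pinned-seed acceptance run drew 0.080. At
  biobank SNP counts the same construction is far better resolved.
- **LDSC precision.** Free-intercept LDSC on panels of 10³–10⁴ SNPs has
  slope/intercept SEs orders of magnitude above biobank-scale analyses;
  studies are designed around that (constrained intercepts, model-drawn Z,
  strong simulated signals).
- **LASSO shrinkage.** At the cross-validated λ the retained interaction
  coefficients are shrunk 20–40%, leaving part of each correlation
  distortion uncorrected. This matches LASSO theory (CV minimizes predictive
  deviance, not coefficient bias) and contributes to the gap between fitted
  and oracle weights.
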