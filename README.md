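# wgwas — participation-bias correction for biobank genetics

Volunteer cohorts are not random samples of their target populations:
participation depends on health, education, income and other analysis
variables, which makes the analyzed sample a *collider-conditioned* subset
and biases genetic associations, heritability, genetic correlations and
Mendelian-randomization estimates. `wgwas` implements the full
inverse-probability-weighting correction workflow:

1. **`wgwas.synthetic`** — simulate a target population (genotypes with
   optional LD, polygenic traits, 14 harmonized auxiliary variables), a
   logistic participation mechanism (with optional pairwise interaction
   effects), and a representative reference sample.
2. **`wgwas.weights`** — build the 903-predictor design matrix (all-level
   dummies + all pairwise products), fit the LASSO participation model by
   cross-validated coordinate descent, construct normalized weights
   w = (1−P)/P, and quantify correlation-bias reduction.
3. **`wgwas.gwas`** — weighted least-squares association scans with
   Huber–White sandwich standard errors; QC, clumping, PCs, scan comparison.
4. **`wgwas.ldsc`** — LD-score regression heritability and genetic
   correlation with block-jackknife SEs, liability conversion, and
   weighted-vs-unweighted difference tests.
5. **`wgwas.mr`** — inverse-variance-weighted MR with a regression-dilution
   correction for noisy exposure betas, and weighted-vs-unweighted
   comparison.
6. **`wgwas.pipeline` / `wgwas.cli`** — an end-to-end configurable run.

See `docs/methods.md` for formulas, parameter rationale and desk-scale
limitations.

## Worked example

```python
import numpy as np
from wgwas import gwas, ldsc
from wgwas import synthetic as syn
from wgwas import weights as wmod

# 1. Simulate: 50,000-person population, ~5,000 volunteers, 2,000 reference
scenario = syn.healthy_volunteer_scenario(seed=1, n_snps=500)
data = syn.generate_scenario(scenario)
selected, reference = data["selected"], data["reference"]

# 2. Fit the participation model and build weights
stacked = syn.stack_cohorts(selected, reference)
design = wmod.build_design(stacked)            # 903 predictors
fit = wmod.fit_participation_model(
    design,
    stacked["participation"].to_numpy(),
    sample_weight=stacked["design_weight"].to_numpy(),
    seed=1,
)
pw = wmod.compute_weights(fit.P)               # selected-sample weights
print(f"retained predictors: {fit.n_retained_predictors}")
print(f"n = {len(pw.w)}, n_eff = {pw.n_effective:.0f}")

# 3. How much correlation bias do the weights remove?
report = wmod.bias_report(selected, reference, pw.w_in,
                          variables=syn.AUX_VARIABLES)
print(wmod.summarize_bias_reduction(report))

# 4. Weighted vs unweighted GWAS of the selection-linked trait
g_sel = data["genotypes"].subset(individuals=data["selected_index"])
y = data["traits"]["health"].to_numpy()[data["selected_index"]]
ss = gwas.run_scan(g_sel, y)                     # classical OLS
ss_w = gwas.run_scan(g_sel, y, weights=pw.w_in)  # WLS + sandwich SE

# 5. Heritability in both arms, and the difference test
ld = ldsc.compute_ld_scores(g_sel, window_kb=100.0)
fit_u = ldsc.estimate_h2(ss, ld, n_blocks=50)
fit_w = ldsc.estimate_h2(ss_w, ld, n_blocks=50)
r = ldsc.jackknife_correlation(fit_u.blocks, fit_w.blocks)
diff = ldsc.difference_test(fit_w.h2, fit_u.h2, fit_w.se, fit_u.se, r)
print(f"h2 unweighted {fit_u.h2:.3f}, weighted {fit_w.h2:.3f}, "
      f"difference P = {diff.p:.3f}")
```

Output (exact values from this seed):

```
retained predictors: 108
n = 4924, n_eff = 2674
{'median': 0.6712504709687961, 'mean': 0.5766413443767546, 'min': -0.1759618290494459, 'max': 0.9633674416396986, 'n_pairs': 24}
h2 unweighted 1.132, weighted 1.289, difference P = 0.691
```

(On a 500-SNP toy panel the free-intercept LDSC slope is extremely noisy —
point estimates above 1 are routine; the example's point is the weight
diagnostics and the paired difference test, which correctly finds no
weighted-vs-unweighted difference here.)

Or run the whole pipeline from the command line:

```bash
wgwas run-all --seed 1 --out runs/demo     # simulate → weights → scans → LDSC → MR
wgwas report --run-dir runs/demo           # print the run summary
```

## Validation

`wgwas.validation` contains replicated simulation studies (GWAS bias
correction, LDSC recovery, MR dilution correction, difference-test
calibration, the sex collider analysis). They back the acceptance tests in
`tests/test_acceptance.py` and the summary script:

```bash
python scripts/acceptance.py --seed 1 --out acceptance.json
```

Two acceptance properties fail honestly at desk scale and are asserted as
stated rather than weakened (see `docs/methods.md` §7 and the decisions
ledger for the quantitative analyses):

- the ≥0.8 median bias-reduction threshold is not attainable with a
  2,000-person reference sample — even oracle true-probability weights
  reach only ~0.7–0.8 because of the reference correlation noise floor;
- the h² difference test carries a mild desk-scale inflation (true null
  rejection ≈ 0.055–0.060 at α = 0.05 with 200 jackknife blocks); it
  passes the 99% binomial band at all five diagnostic seeds, but the
  pinned acceptance seed drew 0.080, just above the 0.075 bound.

## Layout

```
src/wgwas/        library (synthetic, weights, gwas, ldsc, mr, io, pipeline, cli, validation)
tests/            pytest suite; tests/test_acceptance.py holds the acceptance criteria
scripts/          acceptance.py summary script
docs/methods.md   methods, parameter rationale, limitations
```
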