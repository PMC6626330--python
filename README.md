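# highutil

Identify *impactable* high health-care utilizers from the residuals of
expenditure risk-adjustment models on administrative claims data.

## The problem

The top decile of health-care utilizers accounts for the majority of
spending, and payers (Medicaid programs, managed-care organizations)
want to know which of those costs are *impactable* — amenable to
prevention — rather than simply large. Ranking members by raw cost or
visit counts conflates expensive-but-appropriate care (cancer, trauma)
with unexplained over-utilization. The alternative implemented here:

1. **Risk adjustment.** Normalize each member's annual spending to a
   per-member per-month (PMPM) amount, log10-transform it, and regress
   it on exogenous factors only — clinical condition categories,
   age, sex, race, disabled status, county, insurance plan:

   *y* = **β·x** + *ε*,  with *y* = log10 PMPM.

   Fit by OLS, and alternatively by a gradient-boosted tree ensemble
   (regularized squared-error objective, 1000 trees, 60/40 hold-out,
   5-fold CV over tree depth and minimum leaf size) to absorb
   condition-condition interactions.
2. **Tail detection.** If the model explained all systematic variation,
   standardized residuals would be normal. The observed residual
   distribution has a long right tail; members beyond the point where
   the Q-Q curve *consistently* exceeds the theoretical normal quantiles
   (by more than a tolerance δ, default 0.1 SD) are flagged as high
   utilizers — typically 1–7% of the cohort. A fixed top-5% cutoff is
   available for model comparisons.
3. **Validation of impactability.** The flagged population is
   characterized against everyone else (demographics, Charlson-style
   comorbidity burden, spending by setting); its year-to-year
   persistence is quantified by Pearson correlation of residual rank
   percentiles; spending is decomposed to individual diagnosis codes
   across the residual spectrum; and setting-stratified residuals
   (inpatient, emergency department) are tested against potentially
   preventable event (PPR/PPV) counts and expenditures.

Because real Medicaid claims are protected health information, the
package ships a fully specified synthetic claims generator
(`highutil.synthetic_claims`) that plants a persistent over-utilizing
subpopulation plus an AR(1) member frailty, with a hidden-truth sidecar
so every pipeline stage is testable against ground truth.

## Worked example

```python
import numpy as np
import highutil as hu

data = hu.simulate(hu.GeneratorConfig(n_members=20_000, seed=3))
cohort = hu.build_cohort(data.members, data.claims, data.mapping, 2012)
design = hu.build_design_matrix(cohort)
fit = hu.fit_linear(design)
print(f"cohort n={len(cohort)}, linear R^2={fit.r_squared:.3f}")

flags = hu.flag_high_utilizers(fit.residuals, mode="threshold")
truth = data.truth[data.truth.year == 2012].set_index("member_id")
flagged = set(flags.loc[flags.high_utilizer, "member_id"])
planted = set(truth.index[truth.planted]) & set(cohort.member_id)
print(f"flagged {len(flagged)} members "
      f"({flags.high_utilizer.mean():.1%} of cohort), "
      f"sensitivity vs truth {len(flagged & planted)/len(planted):.2f}")
```

prints

```
cohort n=18082, linear R^2=0.538
flagged 984 members (5.4% of cohort), sensitivity vs truth 0.79
```

18,082 of the 20,000 simulated members pass the inclusion rules (ages
18–60, not pregnant, nonzero spending) in 2012. The covariates explain
about 54% of the variance of log10 PMPM; the consistent-deviation scan
of the residual Q-Q curve flags 5.4% of the cohort, and those flags
recover 79% of the members the generator truly planted with excess
utilization — members whose spending is high *for reasons the measured
risk factors cannot explain*.

The same objects feed the rest of the pipeline: `correlation_matrix`
(year-to-year persistence of residual ranks), `group_by_residual` +
`breakdown_table` (per-diagnosis-code decomposition),
`fit_stratified` + `compare_ppe` (preventable-event association).
`highutil run-all --config cfg.yaml` runs every stage from one YAML
config into a run directory with a reproducibility manifest.

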