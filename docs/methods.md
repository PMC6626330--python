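# Methods

## The analysis model

The unit of analysis is the member-year. For each calendar year the
cohort is restricted to adults aged 18–60, not pregnant, with nonzero
total paid claims. The dependent variable is log10 of per-member
per-month expenditure, PMPM = total annual paid amount / months
enrolled; the log transform tames the heavy right skew of raw costs,
and zero-cost members are excluded by the inclusion rule before the
transform so no epsilon offset is needed.

Risk adjustment regresses log10 PMPM on exogenous covariates only:
one-hot condition-category indicators (derived from each year's claims
through a two-column diagnosis-code → category mapping, emulating
CCS-style grouping; unmapped codes are routed to an `UNCLASSIFIED`
catch-all rather than dropped), age, and one-hot sex, race, disabled
status, county and plan. Each categorical drops its first (sorted)
level as the reference and an explicit intercept is kept; condition
categories are multi-label indicators and are all retained. Only
zero-variance and exactly collinear columns are removed (pivoted-QR
rank detection, dropped columns logged) — correlated but distinct
clinical covariates stay in, since the coefficients are never
interpreted individually, only the residuals are used.

Two fitters produce residuals for every cohort row:

- **OLS** (statsmodels), with R², the overall F-test, and the
  Breusch–Pagan heteroscedasticity test reported as diagnostics.
- **Gradient-boosted trees** (xgboost, squared-error objective with
  leaf-count and leaf-weight regularization). 40% of rows are held
  out; 5-fold cross-validation on the training split selects
  `max_depth` ∈ {3, 5, 7} and `min_child_weight` ∈ {10, 50, 200} by
  minimum MSE; the selected model is refit on the training split and
  scored on train, test and all rows. 1000 trees with learning rate
  0.03: the slow rate keeps the train/test R² gap small, which is the
  adequacy rule used to accept the ensemble (similar train and test R²
  ⇒ no overfitting). A large gap would invalidate residuals computed
  on training rows.

## Tail detection

Standardized residuals are sorted against theoretical normal quantiles
at plotting positions (i − 0.5)/n. The high-utilizer threshold is the
smallest standardized residual t such that **every** order statistic
above t exceeds its theoretical quantile by more than δ (default 0.1 SD
units, configurable) — deviation that is *consistent* from t rightward,
not a single excursion. Two numerical refinements:

- Extreme order statistics whose asymptotic quantile standard error
  √(p(1−p)/n)/φ(z_p) exceeds δ/4 are excluded from the consistency
  scan: their sampling noise is of the same order as the deviation
  being tested, so a handful of extreme points would otherwise veto an
  obviously deviating tail. They are still flagged once above t.
- The implied flagged fraction is clipped into [min_frac, max_frac]
  (defaults 1% and 7%, the range the flagged share is expected to
  occupy); if no consistent deviation exists at all (e.g. perfectly
  normal residuals, or δ → ∞) the max_frac quantile is returned with a
  warning. Note the fallback deliberately breaks monotonicity of the
  flagged fraction in δ: within the detectable regime a larger δ never
  flags more members, but past the detectable regime the fallback pins
  the fraction at max_frac.

Top-k mode flags the ⌊fraction·N⌋ largest residuals (floor, so printed
cohort sizes reproduce printed top-5% counts exactly); ties break by
(residual desc, member id asc) so both modes are deterministic and the
threshold and top modes flag identical sets at the implied fraction.

## Temporal persistence, breakdown, stratified models

Persistence: each year's residuals are converted to average-rank
percentiles in (0, 1] (ties share their mean rank) and year pairs are
correlated (Pearson) over members present in both years; members
missing from a year are dropped pairwise. **Signed** residuals are
ranked by default even though one could rank absolute deviations: the
follow-up statistic (mean next-year percentile of the flagged group)
is only meaningful when over- and under-utilization occupy opposite
tails; absolute-value ranking is available via `use_absolute=True`.

Breakdown: within a 3-digit diagnosis-code prefix family, each claim's
cost is attributed to its principal code; the disease cohort (members
with ≥ 1 claim in the family in the index year) is sorted by residual
descending and chunked into fixed-size groups (default 5000, last group
smaller); per (group, code) the table reports the number of patients
touching the code and the group-mean per-code PMPM averaged over *all*
group members, so per-code means sum exactly to the group's category
total. Groups formed on index-year residuals can be applied to a later
year's costs.

Stratified models rebuild the dependent variable from one setting's
claims only (inpatient or emergency), restrict the cohort to members
with nonzero spend in that setting, keep the covariates unchanged, and
flag the tail with the same δ. Preventable-event association compares
flagged vs other members on PPR/PPV counts and expenditures (two-sided
Mann–Whitney U with tie correction), index year and next year
(conditioning on presence in the next year's table), and reports
Pearson correlations between stratified residuals and log10 PMPM PPE
expenditures over members with positive PPE spend (the log is undefined
at zero; zero-spend members still enter the count/mean comparisons).

## The synthetic claims generator

The generator emulates the statistical structure the analysis assumes,
with a hidden-truth sidecar for evaluation. For member i in year t,

log10 PMPM_it = β·x_it + u_it + v_it + w_it

- **u** — planted latent excess: a fixed fraction of members
  (`excess_fraction`, default 5%) is planted; for them u follows a
  stationary AR(1) with mean `excess_shift` (default 0.90 = 3
  σ_noise), SD `excess_sd` (default 0.05) and year-to-year correlation
  `persistence_rho` (default 0.5); for everyone else u ≡ 0. The small
  within-planted SD makes the planted trait essentially a persistent
  mean shift — the "long right tail" the method targets.
- **v** — member frailty: an AR(1) with the same ρ shared by *all*
  members, carrying `noise_persistent_share` (default 0.4) of the
  noise variance. This represents stable unmeasured health and
  social factors; without it, year-to-year rank correlation across the
  full cohort would come only from the planted/non-planted split and
  would not decay with the year gap, contrary to how real residual
  correlations behave.
- **w** — transient iid noise with the remaining variance, so the
  single-year noise SD is exactly `sigma_noise` (default 0.30 on the
  log10 scale, chosen so the covariates explain roughly half the
  response variance, as in large claims data).

Covariate effects (β, default values in `DEFAULT_BETA`) cover 13
synthetic condition categories, age, sex, disabled status, county and
plan. Claims are generated per (member-year, category): at least one
claim each plus a Poisson count, each claim assigned a principal code,
a setting (from member-level Dirichlet setting shares, concentration
25 around inpatient/ED/professional/pharmacy/other = .25/.08/.32/.25/.10)
and a log-normal weight; amounts are scaled so claim lines sum
*exactly* (up to one float subtraction) to the member's model total.
Two variation mechanisms are planted for the breakdown analysis:

- *within-code variance*: hypertension (codes 4011/4019, stable 20/80
  mix) — per-code costs scale with the member's total, so the same
  code costs far more at the high-residual end;
- *mixture shift*: chronic kidney disease (5851–5856) — the end-stage
  code's assignment probability follows a logistic link in (u + v)
  with slope 2.0, so the high-residual end holds more end-stage
  patients.

Preventable events: PPR and PPV counts are Poisson with log-link rate
base·exp(c·(u+v)) (c = `ppe_coupling`, default 1.0; bases 0.15 and 1.0
events/year), and per-event costs are log-normal with median scaled by
10^(c·`ppe_cost_share`·(u+v)) (default share 0.5) — over-utilizers'
preventable events are both more frequent and costlier, which is what
produces a sizable residual–log-expenditure correlation among members
with any events. Setting `ppe_coupling = 0` decouples counts and costs
alike. Zero count forces zero expenditure.

All draws come from substreams spawned in documented order (members,
claims, PPE) from one seed, so identical configs reproduce identical
tables and downstream stages can be regenerated independently.

### What the generator does not emulate

Realistic ICD-9 ontology coverage, actuarially calibrated cost levels,
geographic structure, correlated setting-specific shocks (setting
shares are independent of the latent excess), enrollment churn beyond
uniform month counts, and count-based PPE logic (readmission windows).
Tests passing on this generator show the *pipeline* does what it
claims under the stated statistical assumptions — not that those
assumptions hold in any particular claims warehouse.

## Problem sizes and numerical choices

Default generator size is 20,000 members × 4 years; recovery,
temporal, breakdown and preventable-event checks run at 50,000 members
(planted-tail recovery at top-5% flagging then achieves sensitivity
and precision ≈ 0.77 against the sidecar, with Monte-Carlo SE ≈ 0.008).
Conservation identities are asserted at 1e-12 relative tolerance
(floating-point summation), OLS oracle agreement at 1e-10, and
orthogonality X'ε at 1e-8 on standardized columns. Currency is kept as
unrounded floats throughout the generator. CSV artifacts written by
the pipeline store residuals with `%.17g` and are re-read with
round-trip float parsing, so a stage re-run from cached artifacts is
byte-identical.

## Known limitations

- The consistency threshold δ is the one genuinely free parameter of
  tail detection; the default 0.1 was fixed a priori and the flagged
  fraction is clipped to [1%, 7%] regardless.
- The linear and tree models share one covariate encoding; interactions
  are only probed through the tree ensemble, not added to the OLS.
- The stratified emergency-department model inherits substantial
  setting-share noise at small claim counts; its flagged fraction sits
  near the lower clip bound (1–3%).
- `UNCLASSIFIED` diagnosis handling keeps rows but can dilute category
  indicators if the supplied mapping is incomplete.
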