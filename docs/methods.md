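# Methods

## Scope and data model

The package analyses a two-arm randomized trial (web-based self-help
intervention vs waiting-list control) with waves at 0, 3 and 6 months.
Symptom severity is the IDS-SR total score (0–84; the instrument's 30 items
include two alternative pairs — appetite and weight increase/decrease — so 28
items are scored, which is why `ids_total` applies a max-of-pair rule to
reach the 0–84 range). Resource use per wave follows a cost-questionnaire
recall convention: the baseline questionnaire covers the preceding month,
follow-up questionnaires the elapsed 3-month period. This wave-covers-
elapsed-period convention is an assumption; instruments in this family do
not always state their recall window, and every window length is carried in
`WAVE_WINDOW_MONTHS` so the convention is changeable in one place.

The comparative horizon is 3 months: the control arm receives the
intervention afterwards, so 6-month analyses are emitted only under a
`descriptive` flag and never as headline output.

## Eligibility

Included: baseline IDS-SR in [14, 38] (inclusive; indicated prevention in
subclinical and mild depression), age ≥ 18, and suicidality item 18 below
the exclusion cutoff. The cutoff is not standardized; the default excludes
item-18 scores ≥ 2 (a conventional screen) and is configurable. Records
without a baseline score are rejected as unscreenable.

## Outcomes

* **Responder**: IDS-SR decrease ≥ 50% from baseline, inclusive at exactly
  half. Rates are intent-to-treat: the denominator is everyone randomized.
* **Individual effect size**: d_i = (IDS_i[TX] − IDS_i[T0]) / SD(IDS[T0]),
  with the pooled baseline SD over both arms as the single normalizer
  (per-arm SDs are configurable but a common scale keeps individual effect
  sizes comparable across arms). Negative d means improvement.
* **Utility mapping**: Δu_i = −f · d_i, where f is the utility difference
  associated with one effect-size unit in depression. f has **no default**:
  published estimates vary and the mapping is linear in f, so it must be an
  explicit analysis choice. Examples in this repository use f = 0.117, a
  plausible literature magnitude for depressive disorders. Changes are
  clamped to keep utilities on [0, 1] against a baseline anchor.
* **QALYs**: area under the linearly interpolated utility-change curve
  (default), or a rectangle rule in which each wave's utility change applies
  to the whole preceding interval. The two conventions differ by a factor of
  two for a single follow-up (0.125·u vs 0.25·u per quarter-year); both are
  implemented because the field uses both, and the linear-interpolation AUC
  is the default as the less abrupt assumption.

## Costing

Four categories: intervention, health care, patient and family, productivity.

* Unit prices are data, not code: a packaged CSV fixture of
  Dutch-guideline-style prices (GP visit €33, psychologist €94, informal
  care at a €14/h domestic-help proxy wage, per-day medication prices by
  indication, …), all overridable, with year-indexing factors to the 2016
  reference year.
* **Intervention**: annual platform cost divided by yearly accounts
  (€19,500 / 5,000 = €3.90 per participant by default; only the €3.90 ratio
  matters). The opportunity-cost variant adds participant time
  (3.5 h × €14/h = €49, giving €52.90 in total). The cost applies to every
  randomized intervention participant — dropouts kept their accounts — and
  to the control arm only at the 6-month horizon (post-crossover).
* **Productivity**: friction-cost approach. The 85-calendar-day friction
  period converts to workdays as ⌊85 · workdays_per_week / 7⌋ = 60 at the
  default 5-day week (the conversion is a package choice; guidance states
  the period in calendar days only); absence days beyond the cap cost
  nothing. Presenteeism is affected-days × (1 − efficiency) × daily wage,
  with a single average daily wage (default €230) rather than age/sex
  strata. The cap applies per costed wave.
* **Perspectives**: societal (all categories), health care (intervention +
  health-care costs), employer (intervention + productivity, paid employees
  only). Discounting is not applied at this horizon; a rate parameter exists
  but defaults to 0.

## Missing data

Dropout is treated as missing at random given arm, baseline GAD-7 and age —
the covariates that drive the generator's dropout model — and is
predominantly monotone (3-month dropouts are missing at 6 months).

* **PMM** (main): for each target, OLS on observed cases, predicted values
  for all, and each missing value replaced by the observed value of one of
  k = 5 nearest donors by predicted mean (ties broken by participant order),
  drawn independently per imputation (m = 5). Imputing only observed values
  respects the right skew and the zero mass of cost data. Imputation is
  wave-sequential: 3-month targets from baseline predictors (age, sex, arm,
  baseline IDS-SR, JSEQ, PSS, GAD-7, plus baseline cost subtotals for cost
  targets), 6-month targets additionally from the same variable at 3 months.
  Costs are imputed at category-subtotal level, then summed per perspective;
  imputing only the grand total would lock in the societal perspective.
* **Screened regression** (sensitivity): univariate logistic screen for
  association with 3-month dropout and univariate linear screen for
  association with the observed outcome (α = 0.05 each); the union plus the
  arm indicator feeds a deterministic linear imputation (m = 1, no noise).
* **LOCF** (sensitivity): last observed value carried forward; cost
  subtotals are rescaled by the recall-window ratio (×3 from the 1-month
  baseline window to a 3-month wave) so window lengths stay comparable.

Differential attrition is tested with a Pearson chi-square on the 2×2
arm-by-dropout table, df = 1, without continuity correction (the correction
is conservative and the uncorrected statistic is the one comparable across
reports at this sample size).

## Estimation and uncertainty

Two-step feasible GLS for the SUR system: per-equation OLS, residual
covariance Σ̂ = E'E/n (a ridge floor of 1e−10·(trace/2 + 1) keeps Σ̂
invertible when a bootstrap resample degenerates), then joint GLS. With
identical regressor sets GLS reduces to OLS exactly, which the tests use as
an oracle against statsmodels. Default covariate sets: baseline productivity
costs in the cost equation (the known baseline imbalance) and baseline
IDS-SR in the effect equation; the no-baseline-adjustment scenario drops
both.

Bootstrap: B = 5000 resamples with replacement, stratified by arm (arm sizes
preserved, so degenerate single-arm resamples cannot occur), SUR refit per
resample via a vectorized batched path that mirrors the scalar algebra
exactly (tested to 1e−7). The bootstrap runs within each of the m imputed
datasets from independent seed streams and the m·B replicates are pooled
into one cloud — bootstrap-within-imputation is the common practice in
trial-based CEA when the imputation and resampling orderings are both
defensible. Point estimates are pooled across imputations Rubin-style (mean
coefficients; total variance = mean within + (1 + 1/m) between).

Plane and curves: quadrant shares use strict inequalities (ΔC = 0 is not
cost-saving, ΔE = 0 is not more effective), so shares sum to exactly 100.
The CEAC is the fraction of replicates with positive net monetary benefit
λ·ΔE − ΔC at each λ on a €0–80,000/QALY grid (€1,000 steps); €20,000/QALY is
the conventional ceiling for milder conditions. The ICER/ICUR reports
dominance instead of a ratio in the SE/NW quadrants and flags ΔE = 0 as
undefined-ratio.

Sample size: the smallest per-arm n whose exact two-sided two-sample t-test
power (noncentral t, noncentrality d·√(n/2), df = 2n − 2) reaches the
target; at d = 0.33, α = 0.05, power 0.80 this gives 146 per arm (n = 145
reaches 0.7997).

## Synthetic generator

The generator emulates the study conditions the pipeline targets: arms of
165/164; baseline IDS-SR as a rounded truncated normal (mean 25, SD 6) on
[14, 38]; ~70% paid employment; baseline covariates (age 43 ± 13, GAD-7
10 ± 4, JSEQ, PSS) matched to typical means. The 3-month change is
mean_change_control (2.0 points) plus d·SD for the intervention arm with
residual SD 7; d defaults to 0.41, calibrated so complete-case responder
rates land near 14% vs 7–8% (the trial's powered design effect of 0.33 is a
different quantity — a mean-difference assumption — and underproduces the
responder split under this change model). Dropout at 3 months follows a
logistic model with intercept logit(0.146), arm log-odds 1.411 (back-solved
from 41.2% vs 14.6%), and slopes 0.06 per GAD-7 point and −0.015 per year of
age; additional 6-month dropout (0.30/0.41) yields ~59%/~50% cumulative
loss. Costs are zero-inflated gammas per item scaled by the recall window;
baseline productivity day-counts are scaled per arm to hit mean baseline
productivity costs of ≈€729 vs ≈€582, and follow-up productivity is
arm-invariant by default (factor 0.85 of the control baseline rate), with
`followup_productivity_treatment_factor < 1` available to encode a
cost-saving treatment truth for end-to-end recovery studies.

What the generator does **not** emulate: item-level IDS-SR responses,
within-participant correlation of resource use over waves, seasonal or
calendar effects, non-monotone intermittent missingness, and any
informative (missing-not-at-random) dropout. Passing tests therefore show
the pipeline recovers known truths under MAR dropout and skewed costs, not
that it is robust to MNAR mechanisms real trials may contain.

## Simulation sizes and numerical choices

The test suite runs Monte-Carlo checks at sizes chosen to keep sampling
error well below the asserted tolerances: 500 generator replications for
dropout calibration (±0.03 band), 200 for the null-effect and
productivity-ordering invariants, 100 for the PMM bias oracle (<0.5 score
points), 20,000 simulated trials for the power cross-check (±0.01), and 50
full-pipeline replications at B = 200, m = 2 for end-to-end recovery, with
one full-scale B = 5000, m = 5 run (a few seconds on one CPU) exercised
separately. Determinism throughout comes from `numpy` `SeedSequence`
spawning: one user seed fans out to per-imputation and per-bootstrap
streams, so any scenario is bit-reproducible from its seed and config hash.

## Known limitations

* The utility conversion factor is external; QALY magnitudes scale linearly
  with it and carry its uncertainty, which the bootstrap does not see.
* The linear probability model for the responder effect can in principle
  predict outside [0, 1]; it is kept because the arm coefficient is then a
  responder-rate difference, which is the quantity of interest. A logit
  variant is deliberately out of scope.
* Regression imputation is deterministic (no posterior draws), so its m = 1
  results understate imputation uncertainty — it exists as a sensitivity
  mirror, not as a recommended method.
* Cost imputation at subtotal level assumes the category split of a
  participant's missing wave resembles that of observed donors.
* The employer perspective drops unpaid participants rather than zeroing
  them, matching the subgroup logic of a paid-work analysis.
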