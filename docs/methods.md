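# Methods

`trialcea` implements a trial-based economic evaluation of a chronic-care
intervention against usual care over an 18-month horizon, from the societal
perspective, together with a calibrated synthetic-trial generator used for
testing and method studies. This note records the model, the defaults and
their rationale, the numerical choices, and the known limitations.

## Effects

Health-related quality of life is measured with the EQ-5D-5L (five dimensions,
five levels; utilities on [−0.446, 1]) at months 0, 6, 12 and 18; capability
well-being with the ICECAP-A (five attributes, four levels; utilities on
[0, 1]) on the same schedule. Tariff tables map level profiles to utilities.
The bundled tariffs are *synthetic toys* — additive per-dimension decrements
anchored at 1.0 for the best profile and at the instrument's floor for the
worst — because national value sets are licensed artefacts; real analyses
supply their own tariff CSV.

QALYs and WALYs are the area under the utility curve in year units. Between
measurements the utility is interpolated linearly (trapezoid rule), the
standard area-under-curve convention for trial-based analyses; a
duration-weighted rectangle rule would be the main alternative, but the
trapezoid is what "utility × time in state" resolves to once utilities change
between visits. Accrual in the intervals starting at or after month 12 (the
second follow-up year) is discounted once at 1.5% per year. The cost and
effect questionnaires sit on different schedules (3- vs 6-monthly); we read
"discounted at T15 and T18" as "year-two accrual carries one annual discount
factor", the simplest reading consistent with both schedules.

## Costs

Resource use is recorded 3-monthly (months 0–18) in 19 categories covering
primary care, out-of-hours care, paramedical and mental healthcare, hospital
care, home care, informal care, out-of-pocket prevention spending and
productivity losses. Volumes are valued at Dutch standard 2024 unit prices
(GP consultation €44, home nursing €95/h, hospitalisation €624/day, …);
prices from other years are indexed with consumer-price-index factors.
Hospitalisation is valued per day, the Dutch costing-manual convention.

Productivity losses use the friction cost method: paid-work absence is valued
at sex-specific hourly wages (€50 men, €41 women, 8 h per working day) for at
most 143 working days (20 weeks) per sick-leave spell. The friction cap is
carried across consecutive positive periods — a spell that spans periods is
still one spell — and an intervening zero or missing period closes the spell.
Unpaid work and informal care are valued at the €19/h replacement rate. The
productivity questionnaire has a 4-week recall on a 3-month schedule, so each
observation is extrapolated ×3 to cover its period before valuation.

The seven questionnaires cover 21 months; the baseline questionnaire recalls
the pre-trial period. The 18-month cost total therefore sums the six
follow-up periods (T3–T18), with the T15 and T18 periods discounted at 4%
per year, while the baseline period serves as the baseline-cost covariate of
the adjusted regressions. The generic aggregation operation can also sum all
seven periods when a caller wants the full recorded horizon.

The intervention arm carries a fixed digital-platform subscription of €27
per year. The default books the flat €27 (mirroring the published cost
table); a prorated 1.5× (€40.50 for 18 months) convention is available via
`prorate_fee`. Medication costs are out of scope (the underlying trial found
no between-arm difference and excluded them).

Perspectives: the societal total is exactly healthcare (incl. home care) +
patient/family + productivity + intervention components; the healthcare
perspective keeps only healthcare and intervention components. The home-care
exclusion scenario zeroes the three home-care categories everywhere,
including the baseline covariate.

## Missing data

Three tiers, applied in order:

1. **Item level** (contact reported, volume missing): deterministic fill with
   the arm × timepoint mean of observed positive volumes; fallback to the
   participant's own mean over other timepoints; escalation to
   questionnaire-level missingness when no donor exists. Every fill is logged
   with its tier.
2. **Home care**: with ~95–99% of participants reporting none, a chained
   regression model is hopeless; each participant's missing entries get the
   mode of their own observed series. Ties break to the *smallest* modal
   value (conservative toward the dominant zero mass). A fully missing series
   falls back to the arm mode. This tier runs before MICE and home care is
   excluded from the chained model.
3. **Questionnaire level**: utilities and period-level cost components are
   imputed with chained equations and predictive mean matching (PMM), split
   by arm, m = 15, 20 cycles, 5 donors. The visit order is ascending
   missingness; chains initialise from random draws of the observed
   marginals; regression coefficients are perturbed with a draw from their
   estimated sampling distribution (type-1 PMM) and a small trace-scaled
   ridge keeps the normal equations solvable when predictors approach the
   group sample size. Each variable's predictors are the demographics,
   education and condition flags plus the same variable at other timepoints —
   keeping the model well-conditioned in a 58-participant arm — rather than
   every outcome column at once. PMM guarantees every imputed value is an
   observed donor value, preserving the skewness of costs.

Deaths are dropped before imputation (modified intention-to-treat: early
deaths have no data and are unrelated to the intervention).

Pooling uses Rubin's rules, `T = W + (1 + 1/m)B`, with Barnard–Rubin
small-sample degrees of freedom when a complete-data df is supplied (the
pipeline passes n − p) and normal-theory intervals in the degenerate B = 0
case.

## Incremental analysis

Adjusted mean differences come from OLS of the outcome on the arm indicator,
baseline utility, baseline cost, age, sex and the four condition flags
(COPD, asthma, type-2 diabetes, heart failure — the "clinical conditions"
coding is a package choice). The ICER divides the unrounded pooled ΔC by the
unrounded pooled ΔE; dividing *rounded* table entries gives a visibly
different ratio (1213/0.019 ≈ 63 842), which is why the worked-arithmetic
check brackets rather than pins this quantity. |ΔE| < 1e−9 flags the ICER
undefined instead of raising.

Uncertainty: non-parametric bootstrap, resampling participants with
replacement stratified by arm (arm sizes fixed), refitting both regressions
per replicate; ceil(B/m) replicates within each imputed dataset are
concatenated and truncated to B = 5000, so the pair cloud carries both
sampling and imputation spread. Singular resamples are redrawn and counted.
Quadrant ties land as: ΔC = 0 is "not more costly", ΔE = 0 "not more
effective". CEAC(λ) is the share of pairs with λΔE − ΔC > 0 on a €0–100 000
grid in €500 steps, with the €20 000 Dutch reference threshold reported
separately. Table-style confidence intervals use Rubin pooling; the
percentile information lives in the pair cloud itself.

The per-protocol scenario drops non-adherent intervention participants (the
control arm is never filtered by adherence) and re-runs imputation on the
filtered population, which respects split-by-arm imputation.

## Synthetic-trial generator

The generator reproduces the structure the analysis assumes, with defaults at
the published calibration: arms 173/58; age ≈ 63 (SD 9–10); 68% male;
condition prevalences per arm; baseline EQ-5D-5L means 0.844/0.875 and
ICECAP-A 0.844/0.899 (intervention/control); incremental QALY 0.019, WALY
0.022, incremental societal cost €1213; home-care zero shares 95%/99%;
non-adherence 26.6%; 15% questionnaire-level missingness (the m = 15
convention of matching the missing fraction), 2% item-level gaps, 2% deaths.

*Utilities.* Baseline draws are latent normal, clipped to the instrument
range; follow-up adds AR(1) noise (SD 0.13, ρ = 0.5 per 6 months) and an
additive intervention shift. Because clipping attenuates additive effects,
the latent means are solved (censored-normal closed form + Brent root
finding) so the *observed* baseline means equal the configured values, and
the shift is solved so the discounted, baseline-adjusted incremental accrual
equals the configured truth.

*Costs.* Each category is two-part: Bernoulli period-level use × log-normal
volume, times a participant-level log-normal frailty (mean 1, σ = 0.4) that
induces within-person correlation. Default use probabilities and conditional
means are calibrated so control-arm expected valued totals reproduce the
published control cost rows; per-category dispersions are not published, so
the σ values are plausibility choices. Home care is participant-persistent:
a user flag per arm (5%/1%) with user-level per-period euros (skewed,
log-normal). The configured incremental cost is realised as fee + home-care
gap + a solved multiplicative scaling of intervention-arm healthcare volumes
(the published pattern: the cost increase is healthcare-driven).

*Estimand exactness.* Arm effects apply to follow-up observations only and
baseline *cost* distributions are arm-exchangeable (baseline home care is
drawn from the control process in both arms), so the baseline-adjusted
regression targets the configured truth; with arm-equal baseline utility
distributions (the parameter-recovery configurations) the match is exact.
With the default baseline-utility imbalance the adjusted estimand deviates
from the configured value only through the clipping nonlinearity — small, but
the published baseline home-care imbalance is deliberately *not* emulated,
since it would make the adjusted-estimand calibration intractable.

*Missingness* is questionnaire-level MAR: the missingness log-odds shift with
age and observed baseline EQ-5D utility only. Deaths occur uniformly over
follow-up and blank all post-death waves. Adherence is drawn independently of
outcomes (configurable in principle; the underlying trial argued excluded
patients were not sicker).

What the generator does **not** emulate: GP-practice clustering (the original
analysis ignored it too), baseline cost imbalance between arms, item response
content, correlation between the two instruments' errors, non-adherence that
correlates with outcomes, and any secular time trend. Passing tests therefore
validate the estimation machinery under the stated data-generating process,
not robustness to those real-data features.

## CEAC behaviour under a true null

One calibration check asks that, with true ΔC = ΔE = 0, CEAC(€20 000) land
near 0.5 in ≥90% of replications. That cannot hold for any correct
implementation: the CEAC at a threshold equals one minus the one-sided
p-value of the estimated incremental net benefit, and under the null a
p-value is asymptotically Uniform(0, 1) across replications — so CEAC(λ) is
uniform too, and only ≈30% of null runs can fall in (0.35, 0.65). The test is
implemented exactly as stated and fails honestly; the distributional fact,
not the code, is the explanation. (The *point estimates* under the null do
concentrate at zero, and that recovery is separately verified.)

## Problem sizes and numerical choices

Unit and property tests run at n ≤ a few hundred; the calibration suites use
200 trials at n = (400, 400) for CI coverage and 50 replications at
n = (2000, 2000) for null behaviour, with B = 300 bootstrap replicates where
only a probability near 0.5 is needed (Monte-Carlo SE ≈ 0.03). The full
published-scale run (n = 231, m = 15, B = 5000) executes in the acceptance
script. OLS uses exact normal-equation solves; the MICE ridge is 1e−6 of the
mean Gram diagonal; bootstrap resampling is arm-stratified with fixed arm
sizes; all randomness flows from explicit seeds (imputation and bootstrap
streams are derived from the scenario seed, and per-arm imputation streams
are keyed by a stable digest of the arm label so one arm's data never
perturbs the other's draws).

## Known limitations

- Toy tariffs are not national value sets; absolute utility levels are
  illustrative.
- MICE on period-level component costs (not per-category volumes): category
  detail inside an imputed questionnaire is not reconstructed.
- Type-1 PMM with a modest parameter draw can understate between-imputation
  variance slightly relative to a fully Bayesian sampler.
- The friction cap across spells assumes a missing period closes a spell;
  with heavy absence and much missingness this is a lower-bound convention.
- Normal-theory OLS intervals on skewed cost totals rely on n in the
  hundreds; at very small n the bootstrap percentile view is preferable.
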