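# Methods

## Model

Fracture and death compete. The quantity scored is the cumulative
incidence function (CIF) of fracture, modelled through the
subdistribution hazard (Fine–Gray): the instantaneous fracture rate
among subjects who have not yet fractured, including those who already
died. With dummy-coded covariates x (13 per sex: 3 age, 3 BMI, 7 flags;
age 50–59 and BMI 18.5–22.9 kg/m² are reference levels),

    I(t | x) = 1 − exp(−exp(β′(x − M)) · Λ₀(t)),

where M are cohort covariate means and Λ₀ the baseline cumulative
subdistribution hazard at M. The shipped calculator is the *anchor
form*: the reference profile's 7-year risk a (2.14% men, 7.49% women)
gives H_ref = −ln(1 − a), and

    risk(x) = 1 − exp(−H_ref · Π sHRₖ^{xₖ}).

Both forms equal 1 − exp(−exp(β′x)·c) with c fixed by the reference
profile, so the reparameterisation is exact (the test suite verifies
agreement to 1e-12 against a fitted model). The anchor form is used
because the source publication prints neither Λ₀(7) nor the means M, but
its risk table pins the anchors directly.

## Estimation

- **IPCW risk sets.** The censoring distribution Ĝ is a Kaplan–Meier
  estimate treating censoring (code 0) as the event, fitted on the whole
  cohort (not covariate-stratified). A subject dying at Tᵢ stays in the
  risk set after Tᵢ with weight Ĝ(t−)/Ĝ(Tᵢ−); the weight becomes 0 where
  Ĝ(Tᵢ−) = 0. Left limits are used throughout.
- **Optimisation.** Newton–Raphson on the weighted partial likelihood,
  Breslow tie handling, step-halving when a step would decrease the
  likelihood (with slack 1e-9·(1+|ℓ|), since near the optimum the
  log-likelihood of a 50,000-subject cohort moves only at floating-point
  level), convergence at gradient sup-norm < 1e-8, at most 50
  iterations. Diverging |β| > 15 is flagged as suspected monotone
  likelihood (separation). Constant or collinear columns raise an error
  naming the offending covariates.
- **Complexity.** Risk-set sums decompose into suffix sums over subjects
  ordered by time plus prefix sums over prior deaths, so each Newton
  iteration is O(n·p²) after one O(n log n) sort; a 50,000-subject,
  13-covariate fit takes about a second and ~6 iterations.
- **Variance.** Model-based inverse observed information. The Fine–Gray
  sandwich variance (which accounts for estimating Ĝ) is not
  implemented; on simulated data it differs by a few percent of CI width
  and does not move point estimates. Point estimates agree with R's
  `cmprsk::crr` to ~1e-6 on shared data (tested).
- **Baseline and prediction.** Weighted Breslow estimator at the
  centered covariates; predictions are right-continuous step functions
  with I(0|x) = 0. Prediction at t = 0 returns 0; negative t raises.
- **Proportionality screen.** Weighted Schoenfeld residuals (observed
  minus weighted risk-set mean at each fracture time); the per-covariate
  least-squares slope of residual on event time with its p-value is
  reported. Under proportional subdistribution hazards the slope is
  non-significant in ≥ 95% of simulated replicates.

## Synthetic cohort generator

The generator emulates a national health-screening cohort aged 50–90 so
the pipeline is testable without the source registry, which is not
publicly deposited.

- **Covariates** are drawn from the published *marginal* frequencies
  (independent marginals; the joint distribution was never published —
  a documented limitation: real risk factors are correlated, e.g.
  smoking with alcohol, so synthetic discrimination and covariance
  structure do not transfer to real data).
- **Outcomes** follow the classic indirect Fine–Gray construction:
  F₁(t|x) = 1 − [1 − p·(1 − e^{−t})]^{exp(β′x)}, which has exactly
  proportional subdistribution hazards, making parameter recovery a
  valid test of the fitter. A subject fractures with probability
  F₁(∞|x); fracture times come from one uniform draw by CIF inversion;
  everyone else gets an exponential death time; censoring is
  min(administrative cut-off at 7 years, exponential drop-out).
- **Defaults.** β = ln(published sHRs); p chosen so the reference
  stratum's 7-year CIF equals the published anchors,
  p = a/(1 − e⁻⁷) (0.02142 men, 0.07497 women). Death rates are the
  package's own choices (the publication reports none): 0.008/yr (men)
  and 0.005/yr (women) at 50–59 with age-band multipliers 1, 2, 4, 8 —
  roughly national-life-table magnitudes for a screened (healthier)
  population; drop-out 0.01/yr, low because registry linkage loses few
  subjects. The unit-rate exponential mixing concentrates fracture
  times in the first ~3 years; this is a property of the classic
  construction, not of real fracture incidence, and matters only for
  quantities that depend on event-time spacing (e.g. person-years).

## Validation machinery

- **Observed risk**: Aalen–Johansen CIF (not 1 − KM), so deaths are
  handled consistently with the model. Implemented directly (the
  recursion is deterministic and vectorised); cross-checked against
  lifelines' estimator in the tests.
- **Calibration**: subjects ranked by predicted risk (stable order for
  ties, warning when predictions are constant), split into tenths;
  per tenth the mean predicted risk, observed CIF at the horizon, and
  observed/predicted ratio.
- **Discrimination**: unweighted Wolbers-style competing-risks
  concordance — cases are fractures by t; comparable partners are
  subjects event-free past the case's time plus subjects whose first
  event was death (any time); predictor ties count 1/2. Without
  competing deaths it reduces exactly to Harrell's C (tested against
  lifelines).
- **Incidence**: events per 1,000 person-years with log-normal CIs
  (rate·exp(±1.96/√d)); exact Poisson (chi-square) intervals behind
  `method="exact"`; zero-event strata report rate 0 with lower bound 0.

## Known inconsistencies in the published surface

Two discrepancies are internal to the source tables and therefore not
reproducible by any faithful implementation:

1. **Women's smoking row.** Recomputing the risk-by-age table from the
   printed sHRs and anchors reproduces 62 of 64 cells within ±0.15 pp
   (2-decimal rounding propagation). The women's current-smoking cells
   at ages 70–79/80–89 deviate by 0.20/0.21 pp; back-solving that row
   gives an unrounded smoking sHR ≈ 1.140, which is inconsistent with
   the printed 1.15 beyond rounding. The package keeps the printed 1.15.
2. **Anchors vs crude rates.** The published reference-profile risks
   exceed what the published crude age-specific rates imply (women 50–59:
   anchor 7.49% vs ≈ 4.6% from 6.50/1,000 PY over ~7.1 PY mean
   follow-up). The generator is calibrated to the anchors (the
   calculator's own scale), so its implied women's total incidence is
   ≈ 19–21/1,000 PY, above the registry's 12.09 — same order, not the
   same number. Calibration of the *calculator* is unaffected: data
   generated from the anchored process is scored by the anchored
   calculator, and decile ratios are ≈ 1.

## Problem sizes used by the test suite

Chosen as the smallest sizes at which the statistical assertions have
comfortable power: marginal-frequency checks at n = 200,000 draws;
closed-form CIF and parameter-recovery checks at n = 50,000 (50
replicates per sex); Wald coverage over 200 single-covariate replicates
at n = 20,000; self-calibration at n = 100,000. Note that the
median-over-50-replicates bias statistic has a sampling SD of ≈ 0.036–
0.039 for the rarest covariates (0.5–1.2% prevalence, SE ≈ 0.20–0.22
per fit), so that statistic — unlike the estimator — cannot be expected
to sit below 0.02 uniformly; the corresponding acceptance assertion
records this.

## Other limitations

Banded age only (no continuous age); smoking binarised to current vs
not; no BMD, falls history or diet (not in the source model); no
time-varying covariates, recurrent events, left truncation, stratified
baselines or interaction terms; a single competing event (death);
independent censoring assumed.
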