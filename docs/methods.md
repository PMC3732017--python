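# Methods

`surroval` implements the standard two-level framework for validating a
time-to-event surrogate endpoint (a composite such as disease-free or
progression-free survival, or locoregional control) against overall
survival (OS) in a meta-analysis of randomised trials with individual
patient data. This note records the models, the defaults and why they were
chosen, the numerical decisions, and what the synthetic data do and do not
demonstrate.

## Endpoint definitions

From each patient's event history (times of locoregional event, distant
event, death, and last follow-up, all in years from randomisation) three
endpoints are derived:

- **OS** — time to death from any cause; censored at last follow-up.
- **DFS/PFS** — time to the first of locoregional event, distant event, or
  death; censored at last follow-up when no event is documented. DFS
  (operable setting) and PFS (locally advanced setting) are the same
  derivation under two names.
- **Locoregional control** — time to the first locoregional event;
  censored at the earliest of distant progression, death, and last
  follow-up. Death is censoring here, not an event — this differs from a
  competing-risks treatment, and is deliberate.

Conventions where the field is not unanimous: a locoregional event tied
with a competing event at the same time counts as an event (events beat
censoring at equal times); under fixed-horizon censoring, events exactly at
the horizon are retained and only times strictly beyond it are censored.
Inputs are year-valued floats (the package does not parse calendar dates),
so ties are exact float equality; the generator and horizon censoring are
the only sources of ties, and both produce exact ones.

## Individual-level model

The within-patient association between surrogate time S and survival time T
is summarised by the rank correlation of their joint distribution,
estimated under right censoring with a **two-stage semiparametric copula
model**. The joint survival function is modelled as

    P(S > s, T > t) = C_theta( S1(s), S2(t) ),

with C an archimedean copula (Clayton `(u^-θ + v^-θ - 1)^(-1/θ)` or Gumbel
`exp(-[(-ln u)^θ + (-ln v)^θ]^(1/θ))`). Stage 1 estimates the margins S1,
S2 by Kaplan-Meier and plugs them in as pseudo-observations (clipped to
`[1/2n, 1 - 1/2n]`); stage 2 maximises the censored pseudo-likelihood whose
patient contributions are the copula density (both events observed), a
partial derivative of C (one event), or C itself (both censored).

θ maps to Kendall's τ in closed form (Clayton `τ = θ/(θ+2)`, Gumbel
`τ = 1 − 1/θ`) and to Spearman's ρ by quadrature of `12∬C(u,v)dudv − 3`.
The reported surrogacy measure is ρ². Because the estimator uses ranks
only, it is invariant to strictly monotone transforms of either time axis.

Choices:

- **Family is configuration, not estimation.** Clayton (lower-tail
  dependence: early joint events cluster) is the default; Gumbel
  (upper-tail) is the bracketing alternative; `independence` is the null
  model. The two-stage semiparametric route was preferred over joint
  parametric maximisation for robustness to margin misspecification.
- **Confidence interval** for ρ² by patient-level nonparametric bootstrap,
  200 replicates, percentile method. At meta-analysis sample sizes
  (thousands of patients) any interval is extremely narrow; the bootstrap
  is assumption-light and its replicate count is configurable.
- A composite surrogate **shares its death component with OS**, so the
  observed ρ² of the derived endpoint pair exceeds what the latent copula
  τ alone would give; ρ² grows with the fraction of patients whose first
  event is death (verified as a monotonicity property in the tests).

## Per-trial treatment effects

Treatment effects are log hazard ratios from a Cox proportional-hazards
model with the single binary covariate *arm*, fitted per trial and per
endpoint by Newton-Raphson on the partial likelihood with **Efron's tie
correction**; standard errors come from the inverse observed information.
The implementation is specialised to one binary covariate, reducing each
likelihood evaluation to per-event-time risk-set counts — this is what
makes the recovery simulations (thousands of per-trial fits) cheap. It is
cross-checked in the tests against both a derivative-free maximiser of the
explicitly coded partial likelihood and lifelines' `CoxPHFitter`.

Trials in which all events fall in one arm have a monotone partial
likelihood and no finite estimate; they are **excluded from the trial-level
regression with a logged warning** rather than patched with a continuity
correction.

## Trial-level model

With per-trial effects (xᵢ, yᵢ) = (log HR on surrogate, log HR on OS) and
trial sizes wᵢ, the trial-level model is weighted least squares of y on x
with intercept, weights normalised to mean 1. R² is the weighted
coefficient of determination; its CI is a trial-level bootstrap (2000
resamples, percentile; degenerate resamples with constant x are redrawn).
Estimation error in the per-trial log HRs is ignored by design — the plain
size-weighted regression is the transparent, assumption-light default; a
measurement-error-adjusted meta-analytic model is a known, deliberate
omission (see Limitations). Weights are patient counts by default;
`summarize_trials` also emits event counts so `weight_col="n_events_true"`
switches the convention. An origin-forced fit is available via
`include_intercept=False`.

The **prediction interval** for a new trial at surrogate effect x₀ is the
classical WLS interval `ŷ(x₀) ± t_{K−2} · sqrt(σ̂²(1/w₀ + x₀'(X'WX)⁻¹x₀))`.
The new trial's weight w₀ defaults to the weighted-mean trial size (so the
"1 + leverage" form holds); any size can be supplied.

The **surrogate threshold effect (STE)** is the minimum treatment effect on
the surrogate that predicts a non-zero OS effect: the root of the upper
95% prediction limit as a function of the surrogate log HR, searched over
HR_S ∈ [0.2, 1.5] by Brent's method. When the slope is non-positive or the
upper limit does not change sign in the bracket the STE is reported as
undefined with a reason — an upper limit positive throughout means no
realistic surrogate benefit would be convincing; negative throughout means
the threshold lies beyond 1.5. With zero residual variance, intercept 0 and
slope 1 the STE is exactly 1, the degenerate-collapse limit.

## Validation

- **Leave-one-trial-out.** Each trial is removed, the regression refitted,
  and the held-out trial's observed OS effect compared with the 95%
  prediction interval at its surrogate effect. The held-out trial's
  prediction weight is its own size by default (the trial is known when it
  is being predicted); the mean-size convention is available. If a refit's
  surrogate effects are constant (exchangeable trials) an intercept-only
  weighted model supplies the prediction. The summary is the containment
  count "m of K trials inside". Coverage on correctly specified simulations
  is checked against the band [0.90, 0.99] over 200 replicates of 20
  trials — prediction intervals at small K cannot pin 95% exactly.
- **Fixed-horizon sensitivity.** All patients are censored at an early
  surrogate horizon (3-year DFS or 2-year PFS) and a 5-year OS horizon, and
  the trial-level analysis recomputed; a horizon sweep supports the
  "how early is early enough" question. Horizons at or beyond the longest
  follow-up reproduce the unrestricted analysis bit-identically.

## Classification scale

Squared correlations are labelled on the conventional scale: strictly above
0.9 excellent, above 0.75 very good, above 0.5 good, above 0.25 moderate,
otherwise poor. Boundaries fall downward (0.75 is "good", 0.25 is "poor").
Full precision is always serialised; rounding to two decimals is display
only (intervals on squared correlations near 1 collapse when rounded).

## Synthetic data: what it emulates, and what it does not

Real surrogate-validation IPD are rarely shareable, so the generator plants
known truth at both levels:

- per trial i, true effects (aᵢ, bᵢ) on surrogate and OS are bivariate
  normal with configurable means, SDs and correlation r —
  **r² is the target trial-level R²** in the error-free limit;
- per patient, a uniform pair from a Clayton/Gumbel copula at a configured
  Kendall τ is inverted through arm-specific **exponential margins**
  (closed-form inversion, constant HR over time — matching the
  proportional-hazards estimation downstream), with independent exponential
  censoring plus an administrative horizon.

Two generators differ in what the surrogate is. `simulate_meta_analysis`
stores the raw copula draw as the surrogate event — the clean construction
for verifying the individual-level estimator (its surrogate margin is not
conditioned on preceding death, so a recorded progression may follow
death; such rows are statistically intended, not clinically meaningful).
`simulate_event_history` builds a structured history: a first progression
(locoregional with probability `prob_locoregional`, else distant) and a
death time whose post-progression residual hazard is multiplied by
`1 + excess_hazard_ratio`, so composite-endpoint derivations and the
locoregional-control censoring rule have real work to do.

Defaults (`SimulationConfig()`) emulate a locally-advanced-type
meta-analysis: 15 trials × 170 patients; baseline hazards 1.0/y (surrogate)
and 0.6/y (OS), i.e. medians ≈ 8 and ≈ 14 months; administrative horizon
8 y and random censoring 0.02/y, giving ~95% event fractions; mean effects
log 0.82 and log 0.86; between-trial SDs 0.15 with correlation 0.95; latent
copula τ 0.45, which after composite-endpoint coupling yields observed
PFS-OS ρ² around 0.8–0.9. Seeding uses one master seed with per-trial
substreams spawned from it, so enlarging `n_trials` leaves earlier trials
byte-identical.

Not emulated (and therefore not demonstrated by passing tests): staggered
recruitment calendars, interval-censored assessment schedules,
cause-specific death, non-proportional hazards, informative censoring, and
within-trial covariate heterogeneity. Passing recovery tests show the
estimators find planted truth under the model's own assumptions; they do
not certify behaviour on data violating them.

## Numerical choices

- Copula terms are computed in logs with log-sum-exp stabilisation, so the
  likelihood stays finite up to θ ≈ 400 (τ ≈ 0.995); the association
  parameter is optimised as log θ (Clayton) or log(θ−1) (Gumbel) by bounded
  scalar minimisation, tolerance 1e-8, with hits of the bounds flagged
  `at_boundary` (comonotone input is the canonical case).
- Spearman's ρ from θ uses 64-node tensor Gauss-Legendre quadrature,
  agreeing with adaptive integration to < 1e-6.
- Kaplan-Meier margins are clipped to `[1/2n, 1 − 1/2n]` before entering
  the copula likelihood.
- Cox Newton iterations use step-halving; convergence at |score| < 1e-10.
- WLS prediction uses the exact `(X'WX)⁻¹` from the fit; the STE root is
  found by `brentq` at xtol 1e-12 within the HR bracket [0.2, 1.5].
- Problem sizes in the simulation-based tests (e.g. 200 replicates of 30
  trials × 2000 patients for R² recovery; n = 5000 for copula recovery;
  10⁶ Monte-Carlo draws for the Spearman oracle) were chosen so Monte-Carlo
  error is comfortably below each asserted tolerance while the whole suite
  stays quick to run.

## Limitations

- The measurement-error-adjusted (meta-analytic bivariate) trial-level
  model is not implemented; at typical per-trial sizes the plain weighted
  regression attenuates R² slightly toward zero.
- Only Clayton, Gumbel and independence copulas are available, with a
  single time-constant association parameter.
- The proportion-of-treatment-effect-explained measure is out of scope, as
  are stratified/adjusted Cox models and competing-risks cumulative
  incidence for locoregional control.
- The O−E/V (log-rank) estimator of the hazard ratio is a possible
  alternative to the Cox partial likelihood; it is not implemented.
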