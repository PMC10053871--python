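# Methods

## Estimand and design

The package emulates a two-arm pragmatic trial on observational admission
records. Time zero is hospital admission (day 1); the strategies are "start
the drug within the grace period of *g* days" versus "do not start it within
*g* days"; follow-up ends at in-hospital death, discharge alive, or
administratively at τ days (defaults *g* = 2, τ = 60). The estimand is the
observational analogue of an intention-to-treat effect: initiation within
the grace period, regardless of later adherence, with patients who start
treatment after day *g* counting as untreated throughout. Death and
discharge are treated as competing absorbing states — discharge is taken as
a proxy for recovery, which presumes low post-discharge mortality and few
readmissions.

Identification rests on (i) conditional exchangeability of the
treatment-initiation process given the baseline covariates entering the
censoring models, (ii) positivity (every covariate pattern has a
non-negligible probability of following either strategy), and (iii) correct
specification of the censoring models. Time-varying confounding within the
grace period is not addressed; the short grace period is the design's
defence.

## Day conventions and tie-breaks

Days are positive integers from admission; an event or treatment on the
admission calendar day is day 1, so "within two days" means treatment day
∈ {1, 2}. Within a day, treatment initiation is resolved before the outcome
draw — a recorded administration implies the patient was alive and in
hospital — so a same-day treatment-and-event tie censors the untreated-arm
clone and attributes the event to the treated arm only. Events on day
*e* ≤ *g* before any treatment are kept by both clones. Ties between causes
on the same day are handled from the same at-risk set (end day ≥ *t*); finer
within-day ordering is unidentifiable at daily resolution.

## Artificial censoring and weighting

Per arm, a Cox proportional-hazards model (Breslow ties, Breslow baseline)
is fitted to time-to-artificial-censoring over the grace period: follow-up
min(end day, *g*), "event" = artificial censoring, everything else censored
for that process. The linear predictor uses the baseline covariates in
untransformed form.

Two weight constructions are provided.

**Ladder (default).** The discrete per-day censoring hazards
α_s(x) = dΛ₀(s)·exp((x−x̄)β) are converted into day-level retention
probabilities and each person-day row is weighted by the inverse probability
that the clone still contributes that day. The lag is arm-specific and
mirrors the censoring mechanism: untreated-arm censoring acts at the *start*
of the treatment day (a censored clone contributes *t* − 1 at-risk days, and
the day-*s* weight is 1/Π_{u≤s}(1−α_u)), while treated-arm censoring acts at
the *end* of the grace period (censored clones contribute *g* at-risk days
and the ladder is lagged one day). Past the grace period the weight is
constant at 1/P(uncensored through *g*). Under this convention the weighted
person-day population reconstructs the baseline cohort day by day, and the
occurrence/exposure estimator is calibrated: this is what the parameter-
recovery and bias-correction acceptance tests exercise.

**Fixed (option `weight_mode="fixed"`).** One weight per clone, evaluated at
day *g*: clones followed past the grace period carry 1/P(uncensored through
*g*), everything ending within it carries 1, and censored clones contribute
their full end day of person-time. This mirrors the simplest published
description of the design, but at daily resolution it attenuates all four
hazards toward zero — the censored clone's final day is immortal person-time
(the within-day tie-break means no event could be observed on it), and a
single end-of-grace weight misprices within-grace events relative to
past-grace survivors. It is retained for comparison, not for inference.

P(uncensored through *g*) itself can be represented in the exponential form
exp(−Λ₀(g)·e^{xβ}) — the conventional Cox survival output — or in the
discrete product-limit form Π(1−α_s(x)); with per-day censoring hazards of
0.3–0.5, as a short grace period produces, the two differ materially, and
the ladder always uses the product-limit form.

**Positivity guard.** The exponential link can extrapolate fitted discrete
hazards above 1 for covariate extremes. Per-day hazards are therefore capped
at 0.90 (retention ≥ 10% per day, so one day contributes at most a factor 10
to any weight), with binding caps logged. A patient whose modelled chance of
staying uncensored falls below that has no effective representation under
the arm's strategy, and the inverse weight would be pure extrapolation.
Additional quantile truncation is available but off by default; probabilities
are floored at 1e−10 before inversion.

## Outcome model

Four weighted pooled logistic regressions (per arm × cause, the competing
cause coded as an event-free day) on the person-day table estimate the
constant cause-specific daily hazards. With an intercept-only linear
predictor the fitted hazard equals Σ(w·events)/Σ(w·person-days) exactly, so
the clone-level fast path used inside the bootstrap is the same estimator.
Optional admission-month adjustment enters as a categorical covariate; the
marginal hazard is the fitted per-month hazard standardised over the cloned
cohort's month distribution. The odds-ratio/hazard-ratio gap of the logistic
parameterisation is bounded by (1−p₀)/(1−p₁), under 20% for daily hazards
below 0.15.

Risk-scale measures use the continuous closed forms
CIF(t) = (λ_c/λ)(1−e^{−λt}) evaluated on the integer day grid 0..τ. The
generator is discrete (daily Bernoulli), whose exact CIF replaces e^{−λt}
with (1−λ)^t; at λ ≈ 0.125/day the two differ by up to ~0.02 in incidence,
which is why the nonparametric-agreement check runs on the continuous-time
exponential generator instead. Ratios with zero denominators are reported as
NaN, never raised. Curves are plotted to day 30; estimates are always
reported at τ.

## Nonparametric comparators

Weighted Nelson–Aalen cumulative hazards and weighted Aalen–Johansen
cumulative incidences are computed from clone-level data with each clone
carrying its final-day weight; cause-specific hazards sum to the all-cause
hazard, and death + discharge incidence + survival = 1 wherever no external
censoring mass remains. The naive comparator is 1 − Kaplan–Meier for death
with discharges censored, on the original uncloned cohort, grouped by
treatment within the grace period (default), ever-treatment (which adds
immortal time bias to the demonstration), or ungrouped. Sample-path-wise,
the naive curve dominates the Aalen–Johansen death incidence as soon as
discharges occur — the competing-risks bias the package exists to avoid.

## Inference

Percentile bootstrap, resampling *patients* (never clones) with replacement;
each replicate re-clones, re-censors, re-fits both censoring models,
re-weights and re-estimates, so the weighting step's variability enters the
intervals. Replicate draws come from a single seeded generator; failing
replicates are dropped and counted, and more than 10% failures aborts.
B = 500 by default. No BCa correction and no analytic variances are
provided.

## Synthetic data generator

`simulate_cohort` emulates the hospital world the estimator is built for:
baseline covariates (age, sex, SpO₂, respiratory rate, creatinine, admission
month) drawn from clipped normal/lognormal/categorical marginals; a
discrete-time initiation process with day-specific intercepts (calibrated so
that roughly 55% of patients start within the two-day grace period, ~94% of
those on day 1, and a 1%/day late-initiation rate thereafter); and competing
constant cause-specific hazards (defaults λ_death = 0.01/day,
λ_discharge = 0.115/day — an 8% baseline mortality risk and 8-day mean stay —
with treated multipliers HR₂ = 0.8, HR₃ = 1.0). The confounded scenario lets
hypoxia and age drive both initiation and death (treatment log-odds −0.12
per SpO₂ point and +0.03 per year; death log-hazard −0.15 per SpO₂ point and
+0.04 per year): hypoxia is the treatment indication and the dominant
prognostic factor in this setting. Within a day, treatment resolves before
the exit draw, matching the emulation's tie-break; per-patient daily exit
probabilities are proportionally capped at 0.99.

`true_quantities` returns the counterfactual estimand values: the configured
rates when covariates do not act on the hazards, otherwise marginal
occurrence/exposure rates over τ days averaged over a large covariate sample
using per-patient geometric closed forms (no day loop). A separate
continuous-time generator (`simulate_exponential_exits`) draws competing
exponential exit times for validating the continuous CIF forms.

What the generator does **not** emulate: time-varying covariates or hazards,
readmissions, post-discharge mortality, transfers, measurement error, or
misspecified functional forms beyond the logistic-vs-proportional-hazards
mismatch of the censoring model. A green recovery test therefore shows the
estimator is calibrated when its assumptions hold approximately — not that
it is robust to violations the generator never produces.

## Numerical choices

* Cox fit: Newton–Raphson on the Breslow partial likelihood with internal
  covariate standardisation, step-halving, relative-tolerance convergence
  (gradient scaled by event count); arms with no artificial censorings yield
  a degenerate model with all probabilities 1 and a warning.
* Per-day censoring-hazard cap 0.90; probability floor 1e−10; per-patient
  total daily exit probability cap 0.99 in the generator.
* Pooled logistic fits via IRLS; a zero-event cause returns hazard 0 (the
  boundary MLE) directly; |coefficient| > 30 in an adjusted fit is treated
  as separation and raised with advice to drop the adjustment.
* All estimators are invariant to rescaling all weights by a constant;
  the bootstrap uses the numpy fast path, which is pinned to the frame-based
  pipeline by an exact equivalence test.

## Limitations

Constant hazards are a deliberate simplification; neither piecewise nor
spline hazards, nor Fine–Gray subdistribution models, are implemented.
Per-protocol effects, g-estimation, stabilised weights, sequential-trials
emulation, time-varying confounding and left truncation are out of scope.
The treated-arm pseudo-population is slightly under-reconstructed when many
events fall inside the grace period (their mass sits in the day-*g*
censoring risk set); at daily resolution this is a structural approximation
of the design, visible in the mass-conservation test's looser treated-arm
band.
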