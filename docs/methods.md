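# Methods

## Model and assumptions

`hnsurv` models overall survival with a parametric proportional-hazards (PH)
time-to-event model. The baseline hazard h0(t) belongs to one of four
families, parameterised on the rate convention (λ in 1/years, dimensionless
shape γ):

| family      | h0(t)                          | H0(t)                 |
|-------------|--------------------------------|-----------------------|
| exponential | λ                              | λt                    |
| Weibull     | λγ(λt)^(γ−1)                   | (λt)^γ                |
| Gompertz    | λ·e^(γt)                       | (λ/γ)(e^(γt) − 1)     |
| log-logistic| λγ(λt)^(γ−1) / (1 + (λt)^γ)    | log(1 + (λt)^γ)       |

Covariates enter multiplicatively on the hazard, h(t|x) = h0(t)·exp(β'x), so
S(t|x) = exp(−H0(t)·exp(β'x)) and every exp(βⱼ) is a hazard ratio. Two
substantive assumptions follow:

* **Proportional hazards, not accelerated failure time.** For the
  log-logistic family the common regression convention is AFT / proportional
  odds; the PH link is used here because the shipped coefficient set is
  published as hazard ratios that track semiparametric Cox hazard ratios on
  the same data. Under PH the log-logistic loses its proportional-odds
  interpretation but keeps its non-monotone baseline hazard, which is what
  the family selection rewarded.
* **Rate convention for λ.** The baseline median of the log-logistic is
  1/λ = 2.92 years at λ = 0.342, consistent with the cohort-level median OS
  of ~3.5 years; a scale convention (median = λ) would put the baseline
  median below five months and contradict every published hazard ratio. All
  internal quantities use this convention consistently.

The reference patient (all indicators zero, age 58) is a 58-year-old with
non-radiotherapy-associated, localised disease of "others" histology, R2 or
no resection, no radiotherapy, no chemotherapy. Age enters as (age − 58)
years, so the age hazard ratio is "per year away from the cohort median".
Events at exactly the 7-year administrative cap count as events; strictly
longer follow-up is censored at 7.0 years.

## Estimation

The right-censored log-likelihood Σ δ·[log h0(t) + β'x] − H0(t)·e^(β'x) is
maximised with L-BFGS-B on the unconstrained scale (log λ, log γ, β) with
analytic gradients, from six deterministic starts (λ0 ∈ {1, 0.5}/median(t),
γ0 ∈ {0.7, 1, 1.5}), inside a generous box (|log λ| ≤ 20, |log γ| ≤ 10,
|β| ≤ 30) that keeps the search out of overflow territory and gives boundary
solutions a defined stop — e.g. Gompertz fitted to data with a
non-increasing hazard collapses to γ → 0, its exponential limit, and is then
out-ranked by the exponential on the parameter-count tie-break. A damped
Newton polish (finite-difference Hessian of the analytic gradient) drives
the scaled projected gradient below 1e−9 (contract: 1e−5); standard errors
come from the inverse observed Hessian on the natural (λ, γ, β) scale, and
relative standard errors are SE/|estimate|. The OFV is −2·log-likelihood
without constant terms. Family selection fits all four baselines without
covariates and ranks by OFV, ties broken by fewer parameters.

The Cox layer maximises the Efron-tie-corrected partial likelihood by
Newton–Raphson with step-halving to a gradient max-norm below 1e−8 (risk-set
suffix sums are accumulated in extended precision, which keeps the gradient
noise floor around 1e−11; Breslow ties are available and coincide with Efron
on tie-free data). Monotone likelihood is flagged when a coefficient passes
|β| > 20. The proportional-hazards test is the Grambsch–Therneau score test
on scaled Schoenfeld residuals: with u = Σ (g(tₖ) − ḡ)·sₖ over events,
C = Var(β̂) and d events, the global statistic is d·u'Cu / Σ(g−ḡ)²
(chi-square, p df) and per-covariate d·([Cu]ⱼ)² / (Cⱼⱼ·Σ(g−ḡ)²); the two
coincide for one covariate. The default time transform is the
left-continuous 1 − KM(t−) ("km"), with "rank" and "identity" available.
Univariable screening tests each variable as a block (joint Wald over its
indicator columns, α = 0.05) to avoid reference-level artefacts; the
multivariable model is built by bidirectional AIC stepwise over the screened
variables with histology, resection margin, radiotherapy dose and
chemotherapy forced (they are the clinical interventions of interest
regardless of significance). Stepwise direction "both" is an assumption —
the workflow being reproduced does not state it.

Kaplan–Meier estimation uses the standard product-limit estimator with
Greenwood variance; pointwise CIs are on the log(−log S) scale, the median
CI inverts that band (the lower band reaches 0.5 first), and "unreached" is
reported explicitly rather than as a number. Ties of events and censorings
at one instant count the censored subjects as still at risk.

## Synthetic-data generator

The generator emulates the study conditions of the source registry cohort:

* **Categorical covariates** are drawn independently from the published
  marginal frequencies (exact count fractions out of 275: e.g. metastatic
  41/275, R0 98/275, high-dose RT 48/275, chemotherapy 90/275,
  RT-associated 31/275).
* **Age** comes from a monotone piecewise-linear quantile function through
  (q01, q25, q50, q75, q99) = (18, 38.5, 58, 71.5, 95) years, truncated to
  [18, 95]. Only the median and IQR are published; the tail anchors are a
  choice, set to plausible clinical extremes.
* **Event times** are drawn by inverse-CDF sampling from the generating
  model (the built-in published model by default): t = S⁻¹(u|x),
  u ~ Uniform(0,1).
* **Censoring** is an independent exponential dropout with rate
  log(2)/3.42 ≈ 0.203/year — chosen so the dropout median equals the
  reported 3.42-year median follow-up — plus the 7-year administrative cap.
  The reverse-KM median follow-up of default cohorts averages ≈ 3.4 years.
* **Missingness** can be injected MCAR per variable to exercise the
  ≥50%-missingness filter.

**Known realism gap.** Only marginal covariate frequencies are published, so
covariates are sampled independently; in real registry data adverse factors
cluster (metastatic disease, aggressive histology and no resection
co-occur). Because exp(−H0(t)·θ) is convex in the hazard multiplier θ,
removing that θ-variance *lowers* expected cohort survival: under
independent marginals the expected KM 5-year OS is ≈ 25%, noticeably below
the ≈ 43% observed in the source cohort, and the cohort-level mixture median
is ≈ 2.0 years versus ≈ 3.5 observed. Tests and calibration checks that
condition on covariates (parameter recovery, VPC coverage, family selection,
per-profile predictions) are unaffected by this gap; cohort-level marginal
summaries from synthetic data are approximate by construction, and passing
them says nothing about the joint covariate structure of real data. An
optional `margin_given_extent` override exists for sensitivity analyses and
is off by default.

## Visual predictive check

Each VPC replicate keeps every subject's covariates and censoring pattern
and redraws only the event time from the fitted model; the censoring time of
a subject whose death was observed is unknown and is taken as the 7-year
cap (the conservative standard). Kaplan–Meier curves are evaluated on a
fixed 101-point grid over [0, 7] years per stratum, and summarised by
pointwise 2.5/50/97.5 percentile bands. The default stratification is
one-factor-at-a-time: every level of the six modelled categorical factors
plus an age dichotomy at 58 years (19 strata); it is fully overridable.
Coverage — the fraction of grid points where the observed KM curve lies
inside the band — is ≥ 0.9 on average when the generating model is checked
against its own data and collapses under baseline misspecification (e.g.
exponential fitted to Gompertz data).

## Prognosis calculator

Predictions are closed-form: median OS solves S(t|x) = 0.5 exactly (for the
published model, t = (2^(1/θ) − 1)^(1/γ)/λ), and t-year survival is a direct
evaluation of S. A Monte-Carlo route (inverse-CDF simulation of event
times) is available for cross-checks and mirrors how simulation-based tools
derive the same quantities; it agrees with the closed form in expectation
and the closed form is preferred for determinism. Horizons beyond 15 years
are refused rather than extrapolated, as they lie outside the follow-up
support of the underlying cohort. Scenario comparison reports exact deltas
of medians and horizon survivals and is antisymmetric by construction.
Directional treatment conclusions under the published model (R1 resection
beats no resection everywhere; absolute benefits shrink with age; adding
chemotherapy to high-dose radiotherapy adds benefit; radiotherapy-associated
disease is adverse at fixed treatment) follow from coefficient signs as
closed-form inequalities and are asserted in the test-suite. Published
scenario *magnitudes* from the original browser tool could not be
reconciled exactly under the documented rate-PH parameterisation and are not
asserted — only directions are.

## Problem sizes and numerical choices

Simulation-based checks use sizes chosen to make their statistical criteria
sharp at interactive runtimes: parameter recovery refits 20 cohorts of
5000; family selection 50 cohorts of 500; PH-test size 500 cohorts of 300;
cohort-level calibration 200 cohorts of 275; VPC checks 200 replicates of a
275-subject cohort. Quantile/survival inverse identities hold to 1e−10,
quadrature-vs-closed-form cumulative hazards to 1e−8, Efron-vs-Breslow on
tie-free data to 1e−10, and the product-limit estimator is checked against
an exact rational-arithmetic oracle on small cohorts. All stochastic tests
run under fixed seeds; cohort generation is reproducible from a single
integer seed through one `numpy` Generator.

## Limitations

* The package models overall survival only; progression-free survival is
  supported solely through the generic Cox screening layer.
* No frailty, cure-fraction, time-varying-covariate or AFT models; no
  multiple imputation (missingness handling is the drop filter only).
* The built-in published model is a constant set transcribed from the
  source analysis; its data-dependent diagnostics (e.g. its original OFV)
  cannot be recomputed without the undeposited registry data.
* Synthetic cohorts are calibrated to marginal covariate frequencies and a
  summary follow-up statistic; joint covariate structure and the true
  censoring process are unpublished (see the realism gap above).
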