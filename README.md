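# hnsurv

Parametric proportional-hazards survival modelling and prognosis simulation
for head and neck sarcoma (HNS) cohorts.

HNS are rare, heterogeneous cancers with poor outcomes and no realistic path
to large randomised trials, so prognosis and treatment-benefit estimates must
come from modelling retrospective registry cohorts. `hnsurv` implements that
full workflow for a registry-style cohort of ~275 patients, and ships the
published fitted model as a closed-form prognostic calculator for overall
survival (OS) under any combination of patient, disease and treatment
covariates.

## The model

Each patient contributes a right-censored follow-up pair (t, δ) and a
covariate vector

x = [age−58, RT-associated, R0, R1, locally-advanced, metastatic,
angiosarcoma, rhabdomyosarcoma, UPS, RT-high, RT-low, chemo],

where all entries except the centred age are 0/1 indicators against the
reference patient (58 years old, not radiotherapy-associated, R2-or-no
resection, localised disease, "others" histology, no radiotherapy, no
chemotherapy). Covariates act proportionally on a parametric baseline hazard:

    h(t | x) = h0(t) · exp(β'x),      S(t | x) = exp(−H0(t) · exp(β'x)),

with h0 drawn from one of four families (exponential, Weibull, Gompertz,
log-logistic) on the rate convention (λ per year, shape γ). Candidate
baselines are fitted by right-censored maximum likelihood,

    ℓ = Σᵢ δᵢ·[log h0(tᵢ) + β'xᵢ] − H0(tᵢ)·exp(β'xᵢ),

and compared by objective function value (OFV = −2ℓ, lower is better). The
selected published model is log-logistic with λ = 0.342 / year and γ = 1.61,
so the reference-patient median OS is 1/λ = 2.92 years, and each exp(βⱼ) is a
hazard ratio (e.g. metastatic disease: exp(2.50) = 12.18).

Around the core model the package provides:

* **cohort** — validated patient records, covariate encoding, the 7-year
  administrative censoring rule, ≥50%-missingness variable filter, CSV I/O;
* **cox** — univariable Cox screening (block Wald tests), forced-variable
  bidirectional AIC stepwise model building, and the Grambsch–Therneau
  scaled-Schoenfeld proportional-hazards test (per covariate and global),
  with the Efron-tie partial likelihood implemented exactly;
* **km** — Kaplan–Meier estimation with Greenwood variance, log−log CIs,
  median OS with band-inversion CI, and reverse-KM median follow-up;
* **simulate** — synthetic registry-like cohorts: published marginal
  covariate frequencies, anchored age quantile function (median 58,
  IQR 38.5–71.5), inverse-CDF event times from any fitted model, exponential
  dropout calibrated to a 3.42-year median follow-up, 7-year cap;
* **vpc** — stratified visual predictive checks (simulated KM percentile
  bands vs the observed curve, with per-stratum coverage);
* **calculator** — the closed-form prognosis engine with the published
  model built in.

## Worked example

Predicted OS for a 30-year-old with localised angiosarcoma after an R1
resection, no radiotherapy or chemotherapy:

```
$ hnsurv predict --age 30 --histology angiosarcoma --extent localised --margin R1
{
  "hazard_multiplier": 1.0242903178906215,
  "median_os_years": 2.864387860830805,
  "survival": {
    "1y": 0.8457173643150829,
    "2y": 0.6414874412749956,
    "5y": 0.2879276378260985
  }
}
```

The hazard multiplier exp(β'x) = 1.024 combines the protective age term
(28 years younger than the reference, HR 1.02 per year) with the adverse
angiosarcoma histology (HR 2.13) and the protective R1 margin (HR 0.75); the
model then gives a median OS of 2.86 years and a 5-year OS of 28.8%. The
same patient without any resection:

```
$ hnsurv scenario \
    --profile-a '{"age": 30, "histology": "angiosarcoma", "margin": "R1"}' \
    --profile-b '{"age": 30, "histology": "angiosarcoma", "margin": "R2_or_none"}'
{
  "delta_median_os_years": 0.5999903017514039,
  "median_a": 2.864387860830805,
  "median_b": 2.264397559079401
}
```

i.e. the R1 resection is predicted to add 0.60 years of median OS for this
patient — and less for the same contrast at higher ages, since the positive
age coefficient compresses absolute benefits.

The same API is available from Python:

```python
from hnsurv import PatientProfile, builtin_published_model, predict_profile

model = builtin_published_model()
pred = predict_profile(model, PatientProfile(age=30, histology="angiosarcoma",
                                             margin="R1"))
print(pred.median_os, pred.survival_at[5.0])
```

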