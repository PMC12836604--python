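"""Prognosis engine: survival prediction for arbitrary covariate profiles.

Ships the published log-logistic proportional-hazards model as a built-in
constant set (baseline λ = 0.342 per year, γ = 1.61, twelve covariate
log-hazard coefficients) and predicts, in closed form, the full survival
curve, median overall survival and t-year survival for any combination of
patient, disease and treatment covariates; scenario comparison quantifies the
expected benefit of one treatment plan over another.

All predictions are exact closed-form evaluations of S(t|x) = exp(−H0(t)·θ);
a Monte-Carlo route (inverse-CDF simulation) is available for cross-checks
and mirrors how the original browser tool derived its curves.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import (
    COVARIATE_NAMES,
    EXTENT_LEVELS,
    HISTOLOGY_LEVELS,
    MARGIN_LEVELS,
    RT_DOSE_LEVELS,
    encode_covariates,
)
from .fitting import FittedTTEModel
from .hazards import HazardParams, survival, survival_quantile

__all__ = [
    "PatientProfile",
    "PredictionResult",
    "ScenarioComparison",
    "builtin_published_model",
    "predict_profile",
    "compare_scenarios",
    "enumerate_all_profiles",
    "load_model",
    "save_model",
]

#: published model constants: baseline (λ, γ) with per-coefficient
#: (estimate, relative standard error); exp(estimate) reproduces every
#: printed hazard ratio of the fitted parametric model
_PUBLISHED = {
    "family": "loglogistic",
    "lambda": (0.342, 0.329),
    "gamma": (1.61, 0.067),
    "beta": {
        "age": (0.016, 0.160),
        "rt_associated": (0.786, 0.561),
        "R0": (-0.680, 0.138),
        "R1": (-0.286, 0.840),
        "locally_advanced": (0.211, 1.56),
        "metastatic": (2.50, 0.410),
        "angiosarcoma": (0.758, 0.608),
        "rhabdomyosarcoma": (0.590, 0.865),
        "ups": (1.484, 0.517),
        "rt_high": (-0.390, 0.464),
        "rt_low": (-0.075, 2.93),
        "chemo": (-0.223, 0.771),
    },
}

#: horizon beyond which predictions are refused (beyond follow-up support)
MAX_HORIZON = 15.0


def builtin_published_model() -> FittedTTEModel:
    """The published fitted model as a FittedTTEModel constant."""
    beta = np.array([_PUBLISHED["beta"][n][0] for n in COVARIATE_NAMES])
    est = {"lambda": _PUBLISHED["lambda"][0], "gamma": _PUBLISHED["gamma"][0],
           **{n: v[0] for n, v in _PUBLISHED["beta"].items()}}
    rse = {"lambda": _PUBLISHED["lambda"][1], "gamma": _PUBLISHED["gamma"][1],
           **{n: v[1] for n, v in _PUBLISHED["beta"].items()}}
    se = {k: rse[k] * abs(est[k]) for k in rse}
    return FittedTTEModel(
        params=HazardParams("loglogistic", est["lambda"], est["gamma"]),
        beta=beta,
        beta_names=COVARIATE_NAMES,
        se=se,
        rse=rse,
        n=275,
        n_events=0,
    )


@dataclass(frozen=True)
class PatientProfile:
    """A covariate profile for prediction (no follow-up needed)."""

    age: float = 58.0
    rt_associated: bool = False
    histology: str = "others"
    extent: str = "localised"
    margin: str = "R2_or_none"
    rt_dose: str = "none"
    chemo: bool = False

    def encode(self) -> np.ndarray:
        return encode_covariates(self)


REFERENCE_PROFILE = PatientProfile()


@dataclass
class PredictionResult:
    profile: PatientProfile
    theta: float
    median_os: float
    survival_at: Dict[float, float]
    curve_times: np.ndarray
    curve_survival: np.ndarray


@dataclass
class ScenarioComparison:
    profile_a: PatientProfile
    profile_b: PatientProfile
    prediction_a: PredictionResult
    prediction_b: PredictionResult
    delta_median_os: float
    delta_survival_at: Dict[float, float]
    note: Optional[str] = None


def predict_profile(
    model: FittedTTEModel,
    profile: PatientProfile,
    horizons: Sequence[float] = (1.0, 2.0, 5.0),
    curve_max: float = MAX_HORIZON,
    n_grid: int = 301,
) -> PredictionResult:
    """Closed-form survival prediction for one profile.

    Median OS solves S(t|x) = 0.5 exactly; the curve spans [0, ``curve_max``]
    years. Horizons beyond 15 years are refused (outside the observable
    follow-up support of the underlying cohort).
    """
    for h in horizons:
        if h > MAX_HORIZON:
            raise ValueError(
                f"horizon {h} y exceeds the {MAX_HORIZON:g}-year support of the model"
            )
    theta = float(model.theta(profile.encode())[0])
    med = float(survival_quantile(model.params, 0.5, theta))
    grid = np.linspace(0.0, min(curve_max, MAX_HORIZON), n_grid)
    curve = np.asarray(survival(model.params, grid, theta), dtype=float)
    at = {float(h): float(survival(model.params, h, theta)) for h in horizons}
    return PredictionResult(
        profile=profile,
        theta=theta,
        median_os=med,
        survival_at=at,
        curve_times=grid,
        curve_survival=curve,
    )


def predict_median_mc(
    model: FittedTTEModel,
    profile: PatientProfile,
    n_sim: int = 1000,
    seed: int = 0,
) -> float:
    """Monte-Carlo median OS (inverse-CDF simulation), the stochastic
    counterpart of the closed-form median; identical in expectation."""
    rng = np.random.default_rng(seed)
    theta = float(model.theta(profile.encode())[0])
    t = survival_quantile(model.params, rng.uniform(size=n_sim), theta)
    return float(np.median(t))


def compare_scenarios(
    model: FittedTTEModel,
    profile_a: PatientProfile,
    profile_b: PatientProfile,
    horizons: Sequence[float] = (1.0, 2.0, 5.0),
) -> ScenarioComparison:
    """Closed-form deltas (a − b) of median OS and horizon survival.

    Antisymmetric under swapping the profiles; identical profiles return
    zero deltas with an explanatory note.
    """
    pa = predict_profile(model, profile_a, horizons)
    pb = predict_profile(model, profile_b, horizons)
    note = None
    if profile_a == profile_b:
        note = "profiles are identical; all deltas are zero"
    return ScenarioComparison(
        profile_a=profile_a,
        profile_b=profile_b,
        prediction_a=pa,
        prediction_b=pb,
        delta_median_os=pa.median_os - pb.median_os,
        delta_survival_at={
            h: pa.survival_at[h] - pb.survival_at[h] for h in pa.survival_at
        },
        note=note,
    )


def enumerate_all_profiles(
    model: FittedTTEModel,
    age_grid: Sequence[float],
    horizons: Sequence[float] = (1.0, 2.0, 5.0),
) -> pd.DataFrame:
    """Predictions for every categorical covariate combination at each age:
    margins (3) × extent (3) × histology (4) × RT dose (3) × RT-associated
    (2) × chemotherapy (2) = 432 rows per age value."""
    age_grid = list(age_grid)
    if not age_grid:
        raise ValueError("age_grid must be nonempty")
    rows = []
    for age in age_grid:
        for margin, extent, hist, dose, rta, chemo in itertools.product(
            MARGIN_LEVELS, EXTENT_LEVELS, HISTOLOGY_LEVELS, RT_DOSE_LEVELS,
            (False, True), (False, True),
        ):
            prof = PatientProfile(
                age=age, rt_associated=rta, histology=hist, extent=extent,
                margin=margin, rt_dose=dose, chemo=chemo,
            )
            theta = float(model.theta(prof.encode())[0])
            row = {
                "age": age, "margin": margin, "extent": extent,
                "histology": hist, "rt_dose": dose, "rt_associated": rta,
                "chemo": chemo, "theta": theta,
                "median_os": float(survival_quantile(model.params, 0.5, theta)),
            }
            for h in horizons:
                row[f"survival_{h:g}y"] = float(survival(model.params, h, theta))
            rows.append(row)
    return pd.DataFrame(rows)


def save_model(model: FittedTTEModel, path) -> None:
    """Serialise a fitted model to the JSON model schema."""
    Path(path).write_text(json.dumps(model.to_dict(), indent=2))


def load_model(path) -> FittedTTEModel:
    """Load a model JSON file; schema violations name the offending key."""
    try:
        d = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"{path}: not valid JSON ({exc})") from exc
    try:
        return FittedTTEModel.from_dict(d)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc
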