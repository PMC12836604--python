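"""Patient-level data model for right-censored survival cohorts.

One row per patient: demographics, disease factors (histology, extent,
radiotherapy-associated status), treatment factors (resection margin,
radiotherapy dose, chemotherapy) and the observed follow-up pair
(time in years since diagnosis, event indicator; event = death).

The covariate encoding matches the published proportional-hazards
parameterisation: age enters centred at the cohort median of 58 years, every
other modelled field enters as 0/1 indicators against its reference level
(R2-or-no-resection, localised, "others" histology, no radiotherapy, no
chemotherapy, not radiotherapy-associated), so that the reference patient maps
to the all-zero covariate vector and the baseline hazard refers to a
58-year-old with every factor at reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

# ---------------------------------------------------------------------------
# categorical vocabularies (order fixes the indicator layout)

HISTOLOGY_LEVELS = ("others", "angiosarcoma", "rhabdomyosarcoma", "ups")
EXTENT_LEVELS = ("localised", "locally_advanced", "metastatic")
MARGIN_LEVELS = ("R2_or_none", "R0", "R1")
RT_DOSE_LEVELS = ("none", "low", "high")
SEX_LEVELS = ("male", "female")
RACE_LEVELS = ("chinese", "indian", "malay", "others")

#: age is centred at the cohort median before entering the linear predictor
AGE_CENTER = 58.0

#: administrative right-censoring horizon, years
ADMIN_CAP = 7.0

#: coefficient order of the published model; encode_covariates follows it
COVARIATE_NAMES = (
    "age",
    "rt_associated",
    "R0",
    "R1",
    "locally_advanced",
    "metastatic",
    "angiosarcoma",
    "rhabdomyosarcoma",
    "ups",
    "rt_high",
    "rt_low",
    "chemo",
)

CSV_COLUMNS = (
    "patient_id",
    "age_years",
    "sex",
    "race",
    "rt_associated",
    "histology",
    "extent",
    "margin",
    "rt_dose",
    "chemo",
    "time_years",
    "event",
)

_CATEGORICAL_DOMAINS = {
    "histology": HISTOLOGY_LEVELS,
    "extent": EXTENT_LEVELS,
    "margin": MARGIN_LEVELS,
    "rt_dose": RT_DOSE_LEVELS,
    "sex": SEX_LEVELS,
    "race": RACE_LEVELS,
}


class CohortValidationError(ValueError):
    """A record or file violates the cohort schema."""


def _check_level(name: str, value: str, levels: Sequence[str]) -> str:
    if value not in levels:
        raise CohortValidationError(
            f"unknown {name} value {value!r}; expected one of {list(levels)}"
        )
    return value


@dataclass
class SurvivalRecord:
    """One patient's covariates plus the (time, event) follow-up pair.

    Sex and race are carried for descriptives but are not part of the
    modelled covariate vector.
    """

    patient_id: str
    age: float
    rt_associated: bool
    histology: str
    extent: str
    margin: str
    rt_dose: str
    chemo: bool
    time: float
    event: bool
    sex: str = "male"
    race: str = "others"

    def __post_init__(self) -> None:
        if not self.age > 0:
            raise CohortValidationError(f"age must be positive, got {self.age}")
        if not self.time > 0:
            raise CohortValidationError(f"time must be positive, got {self.time}")
        for name, levels in _CATEGORICAL_DOMAINS.items():
            _check_level(name, getattr(self, name), levels)
        self.rt_associated = bool(self.rt_associated)
        self.chemo = bool(self.chemo)
        self.event = bool(self.event)


def encode_covariates(record) -> np.ndarray:
    """Map a record (or any object with the covariate fields) to the ordered
    12-vector [age−58, rt_assoc, R0, R1, locally_advanced, metastatic,
    angiosarcoma, rhabdomyosarcoma, ups, rt_high, rt_low, chemo].

    The reference profile (58-year-old, not RT-associated, R2-or-none margin,
    localised, "others" histology, no RT, no chemo) maps to the zero vector.
    """
    hist = _check_level("histology", record.histology, HISTOLOGY_LEVELS)
    ext = _check_level("extent", record.extent, EXTENT_LEVELS)
    marg = _check_level("margin", record.margin, MARGIN_LEVELS)
    dose = _check_level("rt_dose", record.rt_dose, RT_DOSE_LEVELS)
    return np.array(
        [
            float(record.age) - AGE_CENTER,
            float(bool(record.rt_associated)),
            float(marg == "R0"),
            float(marg == "R1"),
            float(ext == "locally_advanced"),
            float(ext == "metastatic"),
            float(hist == "angiosarcoma"),
            float(hist == "rhabdomyosarcoma"),
            float(hist == "ups"),
            float(dose == "high"),
            float(dose == "low"),
            float(bool(record.chemo)),
        ]
    )


def design_matrix(records: Iterable) -> np.ndarray:
    """Stack encode_covariates over records into an (n, 12) matrix."""
    return np.array([encode_covariates(r) for r in records], dtype=float)


def apply_censoring_rule(
    time: float, event: bool, cap: float = ADMIN_CAP
) -> tuple[float, bool]:
    """Administrative right censoring: follow-up beyond ``cap`` years is cut
    at the cap and the subject is censored there. An event at exactly the cap
    is retained as an event (the cap truncates event-free follow-up).
    """
    if not time > 0:
        raise CohortValidationError(f"time must be positive, got {time}")
    if time > cap:
        return cap, False
    return float(time), bool(event)


def censor_cohort(records: Sequence[SurvivalRecord], cap: float = ADMIN_CAP) -> list[SurvivalRecord]:
    """Apply the administrative censoring rule to every record."""
    out = []
    for r in records:
        t, e = apply_censoring_rule(r.time, r.event, cap)
        out.append(replace(r, time=t, event=e))
    return out


def missingness_filter(
    table: pd.DataFrame, threshold: float = 0.5
) -> tuple[list[str], pd.Series]:
    """Drop variables with a missing-data fraction ≥ ``threshold``.

    Returns (retained column names, per-column missing fractions). A column
    missing in exactly the threshold fraction of rows is dropped (>= rule).
    """
    if table.empty:
        raise CohortValidationError("missingness_filter requires a nonempty table")
    frac = table.isna().mean()
    kept = [c for c in table.columns if frac[c] < threshold]
    return kept, frac


# ---------------------------------------------------------------------------
# CSV I/O

_BOOL_TOKENS = {"0": False, "1": True, "true": True, "false": False,
                "yes": True, "no": False}


def _parse_bool(name: str, value, row: int):
    token = str(value).strip().lower()
    if token not in _BOOL_TOKENS:
        raise CohortValidationError(
            f"row {row}: cannot parse {name}={value!r} as a 0/1 flag"
        )
    return _BOOL_TOKENS[token]


def read_cohort(path) -> list[SurvivalRecord]:
    """Read a cohort CSV (schema: ``patient_id,age_years,sex,race,
    rt_associated,histology,extent,margin,rt_dose,chemo,time_years,event``)
    into validated records. Malformed rows are reported with their row number;
    an empty file yields an empty cohort with a warning.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError:
        warnings.warn(f"{path}: empty cohort file", stacklevel=2)
        return []
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise CohortValidationError(f"{path}: missing mandatory columns {missing}")
    records = []
    for i, row in df.iterrows():
        rownum = int(i) + 2  # 1-based with header line
        try:
            records.append(
                SurvivalRecord(
                    patient_id=str(row["patient_id"]),
                    age=float(row["age_years"]),
                    sex=str(row["sex"]),
                    race=str(row["race"]),
                    rt_associated=_parse_bool("rt_associated", row["rt_associated"], rownum),
                    histology=str(row["histology"]),
                    extent=str(row["extent"]),
                    margin=str(row["margin"]),
                    rt_dose=str(row["rt_dose"]),
                    chemo=_parse_bool("chemo", row["chemo"], rownum),
                    time=float(row["time_years"]),
                    event=_parse_bool("event", row["event"], rownum),
                )
            )
        except CohortValidationError as exc:
            raise CohortValidationError(f"{path}: row {rownum}: {exc}") from exc
        except (TypeError, ValueError) as exc:
            raise CohortValidationError(f"{path}: row {rownum}: {exc}") from exc
    return records


def write_cohort(records: Sequence[SurvivalRecord], path) -> None:
    """Write records to the cohort CSV schema (lossless round trip; reals at
    10 significant digits)."""
    to_frame(records).to_csv(path, index=False, float_format="%.10g")


def to_frame(records: Sequence[SurvivalRecord]) -> pd.DataFrame:
    """Records as a DataFrame in the canonical CSV column order."""
    rows = [
        {
            "patient_id": r.patient_id,
            "age_years": r.age,
            "sex": r.sex,
            "race": r.race,
            "rt_associated": int(r.rt_associated),
            "histology": r.histology,
            "extent": r.extent,
            "margin": r.margin,
            "rt_dose": r.rt_dose,
            "chemo": int(r.chemo),
            "time_years": r.time,
            "event": int(r.event),
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=list(CSV_COLUMNS))


def times_events(records: Sequence[SurvivalRecord]) -> tuple[np.ndarray, np.ndarray]:
    """(times, events) arrays for estimator entry points."""
    t = np.array([r.time for r in records], dtype=float)
    e = np.array([r.event for r in records], dtype=bool)
    return t, e
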