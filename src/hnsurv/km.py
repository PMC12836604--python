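"""Kaplan–Meier product-limit estimation with Greenwood variance.

Provides the nonparametric survival layer used for cohort descriptives, as
the observation side of visual predictive checks, and for reverse-KM median
follow-up. Ties of events and censorings at the same instant follow the
standard convention: events happen first, so same-time censored subjects are
still at risk for that event time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from scipy.stats import norm

Z95 = float(norm.ppf(0.975))


@dataclass
class KMEstimate:
    """Step-function survival estimate.

    ``times`` are the distinct event times; ``survival[j]`` is S(times[j]);
    ``greenwood_var[j]`` is Greenwood's variance of S at that step;
    ``n_risk``/``n_event`` count subjects at risk and events per step.
    """

    times: np.ndarray
    survival: np.ndarray
    greenwood_var: np.ndarray
    n_risk: np.ndarray
    n_event: np.ndarray
    n: int
    max_followup: float

    def survival_at(self, t) -> np.ndarray:
        """Step-function evaluation S(t) (right-continuous)."""
        t = np.asarray(t, dtype=float)
        if self.times.size == 0:
            return np.ones_like(t) if t.shape else 1.0
        idx = np.searchsorted(self.times, t, side="right") - 1
        s = np.where(idx < 0, 1.0, self.survival[np.clip(idx, 0, None)])
        return s if s.shape else float(s)


def km_fit(times, events) -> KMEstimate:
    """Product-limit estimate Π_{t_j ≤ t} (1 − d_j / n_j) over event times."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.size == 0:
        raise ValueError("km_fit requires a nonempty sample")
    if np.any(t <= 0):
        raise ValueError("all times must be positive")
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    uniq = np.unique(t)
    # counts per distinct time
    d = np.zeros(uniq.size)
    c = np.zeros(uniq.size)
    idx = np.searchsorted(uniq, t)
    np.add.at(d, idx, e.astype(float))
    np.add.at(c, idx, (~e).astype(float))
    n_at_risk = t.size - np.concatenate([[0.0], np.cumsum(d + c)[:-1]])
    has_event = d > 0
    et, dj, nj = uniq[has_event], d[has_event], n_at_risk[has_event]
    frac = dj / nj
    surv = np.cumprod(1.0 - frac)
    with np.errstate(divide="ignore", invalid="ignore"):
        gw_terms = np.where(nj > dj, dj / (nj * (nj - dj)), np.inf)
        gw = surv**2 * np.cumsum(gw_terms)
    gw = np.where(np.isfinite(gw), gw, 0.0)  # variance at S=0 taken as 0
    return KMEstimate(
        times=et,
        survival=surv,
        greenwood_var=gw,
        n_risk=nj,
        n_event=dj,
        n=int(t.size),
        max_followup=float(t.max()),
    )


def _loglog_ci(s: np.ndarray, var: np.ndarray, z: float = Z95):
    """95% pointwise CI on the log(−log S) scale (stays inside (0,1))."""
    lo = np.zeros_like(s)
    hi = np.ones_like(s)
    interior = (s > 0.0) & (s < 1.0)
    ss = s[interior]
    se_cll = np.sqrt(var[interior]) / (ss * np.abs(np.log(ss)))
    cll = np.log(-np.log(ss))
    lo[interior] = np.exp(-np.exp(cll + z * se_cll))
    hi[interior] = np.exp(-np.exp(cll - z * se_cll))
    lo[s == 1.0] = 1.0
    hi[s == 0.0] = 0.0
    return lo, hi


def km_survival_at(est: KMEstimate, t: float):
    """S(t) with a log−log Greenwood 95% CI.

    Beyond the last observed follow-up, the last step value is returned with
    an extrapolation warning.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    if t > est.max_followup:
        warnings.warn(
            f"t={t} exceeds the last observed follow-up "
            f"({est.max_followup:.3g}); returning the last step value",
            stacklevel=2,
        )
    idx = int(np.searchsorted(est.times, t, side="right")) - 1
    if idx < 0:
        return 1.0, (1.0, 1.0)
    s = float(est.survival[idx])
    v = float(est.greenwood_var[idx])
    lo, hi = _loglog_ci(np.array([s]), np.array([v]))
    return s, (float(lo[0]), float(hi[0]))


def km_median_ci(est: KMEstimate):
    """Median survival (first time S(t) ≤ 0.5) with a 95% CI obtained by
    inverting the log−log confidence band (Brookmeyer–Crowley style).

    Returns (median, (lo, hi)); any of the three is None when unreached.
    """
    lo_band, hi_band = _loglog_ci(est.survival, est.greenwood_var)
    median = _first_crossing(est.times, est.survival)
    # plausible medians are the times where 0.5 lies inside the band: the
    # lower band reaches 0.5 first (CI lower limit), the upper band last
    ci_lo = _first_crossing(est.times, lo_band)
    ci_hi = _first_crossing(est.times, hi_band)
    return median, (ci_lo, ci_hi)


def _first_crossing(times, values, level: float = 0.5):
    below = values <= level
    if not below.any():
        return None
    return float(times[int(np.argmax(below))])


def median_followup_reverse_km(times, events) -> Optional[float]:
    """Median follow-up by the reverse Kaplan–Meier method: censorings become
    the events of interest and deaths censor."""
    est = km_fit(times, ~np.asarray(events, dtype=bool))
    return _first_crossing(est.times, est.survival)


def km_curve_on_grid(times, events, grid) -> np.ndarray:
    """KM survival evaluated on a time grid; fast path for simulation loops."""
    return np.asarray(km_fit(times, events).survival_at(grid), dtype=float)
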