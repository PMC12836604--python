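"""Cox partial likelihood, screening workflow and Schoenfeld diagnostics."""

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter

from hnsurv import (
    CoxError,
    GeneratorConfig,
    cohort_records,
    cox_fit,
    cox_partial_loglik,
    generate_cohort,
    schoenfeld_global_test,
    stepwise_build,
    univariable_screen,
)


def two_arm(n, hr, rng, base=0.3, censor=0.15):
    x = rng.binomial(1, 0.5, n).astype(float)
    t = rng.exponential(1.0 / (base * hr**x))
    c = np.minimum(rng.exponential(1.0 / censor, n), 7.0)
    return np.minimum(t, c), (t <= c).astype(float), x[:, None]


class TestCoxFit:
    def test_recovers_true_log_hazard_ratio(self, rng):
        t, e, X = two_arm(1000, 2.0, rng)
        fit = cox_fit((t, e, X, ["arm"]))
        assert abs(fit.beta[0] - np.log(2.0)) < 3 * fit.se[0]

    def test_null_covariate_near_zero(self, rng):
        t, e, X = two_arm(1000, 1.0, rng)
        fit = cox_fit((t, e, X, ["coin"]))
        assert abs(fit.beta[0]) < 3 * fit.se[0]

    def test_gradient_at_optimum_below_contract(self, rng):
        t, e, X = two_arm(500, 1.8, rng)
        fit = cox_fit((t, e, X, ["arm"]))
        _, g, _ = cox_partial_loglik(fit.beta, t, e, X)
        assert np.max(np.abs(g)) < 1e-8

    def test_efron_equals_breslow_without_ties(self, rng):
        t, e, X = two_arm(300, 2.0, rng)
        ev = t[e > 0]
        assert np.unique(ev).size == ev.size  # continuous event times: no ties
        for beta in ([0.0], [0.5], [-0.7]):
            ll_e, _, _ = cox_partial_loglik(np.array(beta), t, e, X, ties="efron")
            ll_b, _, _ = cox_partial_loglik(np.array(beta), t, e, X, ties="breslow")
            assert ll_e == pytest.approx(ll_b, abs=1e-10)

    def test_matches_lifelines_with_ties(self, rng):
        t, e, X = two_arm(400, 1.7, rng)
        t = np.round(t, 1) + 0.05  # force heavy ties
        x2 = rng.normal(size=400)
        X = np.column_stack([X[:, 0], x2])
        fit = cox_fit((t, e, X, ["arm", "marker"]))
        df = pd.DataFrame({"T": t, "E": e, "arm": X[:, 0], "marker": x2})
        ref = CoxPHFitter().fit(df, "T", "E")
        assert np.allclose(fit.beta, ref.params_.values, atol=1e-6)
        assert np.allclose(fit.se, ref.standard_errors_.values, atol=1e-6)
        assert fit.loglik_partial == pytest.approx(ref.log_likelihood_, abs=1e-6)

    def test_invariant_to_time_rescaling(self, rng):
        t, e, X = two_arm(400, 2.0, rng)
        fit_y = cox_fit((t, e, X, ["arm"]))
        fit_m = cox_fit((t * 12.0, e, X, ["arm"]))
        assert fit_y.hr[0] == pytest.approx(fit_m.hr[0], rel=1e-8)
        assert fit_y.p_values[0] == pytest.approx(fit_m.p_values[0], rel=1e-6)

    def test_monotone_likelihood_raises(self):
        # perfectly separated covariate: all events in one arm before any other
        t = np.r_[np.linspace(0.1, 1, 10), np.linspace(2, 3, 10)]
        e = np.ones(20)
        X = np.r_[np.ones(10), np.zeros(10)][:, None]
        with pytest.raises(CoxError):
            cox_fit((t, e, X, ["sep"]))

    def test_needs_two_distinct_event_times(self):
        t = np.array([1.0, 1.0, 2.0])
        e = np.array([1.0, 1.0, 0.0])
        with pytest.raises(CoxError, match="distinct event times"):
            cox_fit((t, e, np.ones((3, 1)) * [[1], [0], [1]], ["x"]))

    def test_aic_identity(self, small_cohort):
        fit = cox_fit(small_cohort, ["age", "extent"])
        assert fit.aic == pytest.approx(-2 * fit.loglik_partial + 2 * len(fit.beta))


class TestScreen:
    def test_strong_covariate_kept(self, rng):
        t, e, X = two_arm(500, 3.0, rng)
        df, _ = generate_cohort(GeneratorConfig(n=500, seed=14))
        df["time_years"], df["event"] = t, e.astype(int)
        df["rt_associated"] = X[:, 0].astype(int)
        screen = univariable_screen(cohort_records(df), ["rt_associated"])
        assert bool(screen.loc[0, "kept"])

    def test_empty_candidates_empty_result(self, small_cohort):
        screen = univariable_screen(small_cohort, [])
        assert len(screen) == 0

    def test_noise_covariate_type_i_error_calibrated(self):
        """Pure-noise binary covariate kept in roughly alpha of replicates."""
        reps, kept = 200, 0
        for r in range(reps):
            rng = np.random.default_rng(5000 + r)
            n = 150
            t = rng.exponential(2.0, n)
            c = np.minimum(rng.exponential(5.0, n), 7.0)
            obs, e = np.minimum(t, c), (t <= c).astype(float)
            x = rng.binomial(1, 0.5, n).astype(float)[:, None]
            fit = cox_fit((obs, e, x, ["noise"]))
            kept += fit.p_values[0] < 0.05
        assert 0.02 <= kept / reps <= 0.09

    def test_categorical_block_is_jointly_tested(self, small_cohort):
        screen = univariable_screen(small_cohort, ["histology"])
        assert int(screen.loc[0, "df"]) == 3  # three non-reference levels


class TestStepwise:
    def test_forced_only_input_keeps_forced_block(self, small_cohort):
        fit = stepwise_build(small_cohort, [])
        assert set(fit.variables) == {"histology", "margin", "rt_dose", "chemo"}

    def test_informative_variable_retained_over_noise(self):
        keeps = 0
        reps = 20
        for r in range(reps):
            df, _ = generate_cohort(GeneratorConfig(n=400, seed=7000 + r))
            recs = cohort_records(df)  # age & extent are truly prognostic here
            fit = stepwise_build(recs, ["extent", "sex"])  # sex is pure noise
            keeps += "extent" in fit.variables
        assert keeps >= 0.9 * reps

    def test_stepwise_aic_no_worse_than_full_model(self, small_cohort):
        screened = ["age", "extent", "rt_associated", "sex"]
        step = stepwise_build(small_cohort, screened)
        full = cox_fit(
            small_cohort,
            list(dict.fromkeys(["histology", "margin", "rt_dose", "chemo"] + screened)),
        )
        assert step.aic <= full.aic + 1e-9


class TestSchoenfeld:
    def test_single_covariate_global_equals_covariate_p(self, rng):
        t, e, X = two_arm(400, 2.0, rng)
        fit = cox_fit((t, e, X, ["arm"]))
        res = schoenfeld_global_test(fit)
        assert res["global_p"] == pytest.approx(res["p"][0], rel=1e-10)

    def test_detects_time_decaying_effect(self):
        """Hazard effect β(t) = 1 − 0.2t violates proportionality; the test
        should reject in well over half the replicates at n=1000."""
        lam = 0.3
        rej = 0
        reps = 30
        for r in range(reps):
            rng = np.random.default_rng(300 + r)
            n = 1000
            x = rng.binomial(1, 0.5, n).astype(float)
            u = rng.uniform(size=n)
            # x=0: exponential(lam); x=1: H(t)=lam*e/0.2*(1-e^{-0.2t})
            t0 = -np.log(u) / lam
            z = -np.log(u) * 0.2 / (lam * np.e)
            with np.errstate(invalid="ignore", divide="ignore"):
                t1 = np.where(z < 1, -np.log1p(-np.minimum(z, 1 - 1e-12)) / 0.2, np.inf)
            t = np.where(x > 0, t1, t0)
            c = np.minimum(rng.exponential(6.0, n), 7.0)
            obs, e = np.minimum(t, c), (t <= c).astype(float)
            fit = cox_fit((obs, e, x[:, None], ["arm"]))
            rej += schoenfeld_global_test(fit)["global_p"] < 0.05
        assert rej / reps > 0.5

    def test_transform_options(self, rng):
        t, e, X = two_arm(300, 1.5, rng)
        fit = cox_fit((t, e, X, ["arm"]))
        for tr in ("km", "rank", "identity"):
            res = schoenfeld_global_test(fit, time_transform=tr)
            assert 0.0 <= res["global_p"] <= 1.0
        with pytest.raises(ValueError):
            schoenfeld_global_test(fit, time_transform="log-log")
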