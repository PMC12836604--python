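"""Prognosis calculator: published constants, closed-form predictions,
scenario comparisons and model serialisation."""

import numpy as np
import pytest

from hnsurv import (
    PatientProfile,
    REFERENCE_PROFILE,
    builtin_published_model,
    compare_scenarios,
    enumerate_all_profiles,
    load_model,
    predict_profile,
    save_model,
    survival,
)
from hnsurv.calculator import predict_median_mc

#: printed hazard ratios of the published fitted model, by coefficient
PRINTED_HRS = {
    "age": 1.02,
    "rt_associated": 2.19,
    "R0": 0.51,
    "R1": 0.75,
    "locally_advanced": 1.23,
    "metastatic": 12.18,
    "angiosarcoma": 2.13,
    "rhabdomyosarcoma": 1.80,
    "ups": 4.41,
    "rt_high": 0.68,
    "rt_low": 0.93,
    "chemo": 0.80,
}


class TestPublishedConstants:
    def test_all_twelve_hazard_ratios_reproduced(self, published_model):
        hrs = published_model.hazard_ratios()
        for name, printed in PRINTED_HRS.items():
            assert round(hrs[name], 2) == pytest.approx(printed), name

    def test_metastatic_coefficient_exponentiates_to_printed_hr(self, published_model):
        assert round(float(np.exp(2.50)), 2) == 12.18
        assert published_model.beta[list(published_model.beta_names).index("metastatic")] == 2.50

    def test_baseline_parameters(self, published_model):
        assert published_model.params.family == "loglogistic"
        assert published_model.params.lam == 0.342
        assert published_model.params.gamma == 1.61


class TestPredictProfile:
    def test_reference_profile_median(self, published_model):
        pred = predict_profile(published_model, REFERENCE_PROFILE)
        assert pred.theta == pytest.approx(1.0)
        assert pred.median_os == pytest.approx(2.924, abs=1e-3)

    def test_metastatic_profile_median_closed_form(self, published_model):
        pred = predict_profile(
            published_model, PatientProfile(extent="metastatic")
        )
        # (2^(1/theta) − 1)^(1/gamma) / lambda with theta = exp(2.50)
        th = float(np.exp(2.50))
        expected = (2 ** (1 / th) - 1) ** (1 / 1.61) / 0.342
        assert pred.theta == pytest.approx(th)
        assert pred.median_os == pytest.approx(expected, rel=1e-12)
        assert pred.median_os == pytest.approx(0.5017, abs=2e-4)

    def test_survival_at_median_is_half(self, published_model, rng):
        for _ in range(50):
            prof = PatientProfile(
                age=float(rng.uniform(20, 90)),
                rt_associated=bool(rng.integers(2)),
                histology=str(rng.choice(["others", "angiosarcoma", "rhabdomyosarcoma", "ups"])),
                extent=str(rng.choice(["localised", "locally_advanced", "metastatic"])),
                margin=str(rng.choice(["R2_or_none", "R0", "R1"])),
                rt_dose=str(rng.choice(["none", "low", "high"])),
                chemo=bool(rng.integers(2)),
            )
            pred = predict_profile(published_model, prof)
            s = float(survival(published_model.params, pred.median_os, pred.theta))
            assert s == pytest.approx(0.5, abs=1e-10)

    def test_horizon_beyond_support_refused(self, published_model):
        with pytest.raises(ValueError, match="support"):
            predict_profile(published_model, REFERENCE_PROFILE, horizons=[20.0])

    def test_monte_carlo_median_agrees_with_closed_form(self, published_model):
        mc = predict_median_mc(published_model, REFERENCE_PROFILE, n_sim=20000, seed=1)
        assert mc == pytest.approx(2.924, rel=0.05)


class TestScenarios:
    def test_identical_profiles_zero_delta_with_note(self, published_model):
        cmp_ = compare_scenarios(published_model, REFERENCE_PROFILE, REFERENCE_PROFILE)
        assert cmp_.delta_median_os == 0.0
        assert all(v == 0.0 for v in cmp_.delta_survival_at.values())
        assert cmp_.note is not None

    def test_antisymmetric_under_profile_swap(self, published_model):
        a = PatientProfile(margin="R1", histology="angiosarcoma", age=30.0)
        b = PatientProfile(margin="R2_or_none", histology="angiosarcoma", age=30.0)
        ab = compare_scenarios(published_model, a, b)
        ba = compare_scenarios(published_model, b, a)
        assert ab.delta_median_os == pytest.approx(-ba.delta_median_os, rel=1e-12)
        for h in ab.delta_survival_at:
            assert ab.delta_survival_at[h] == pytest.approx(
                -ba.delta_survival_at[h], rel=1e-12
            )

    def test_median_monotone_decreasing_in_linear_predictor(self, published_model, rng):
        """Over many random profile pairs, the higher-risk profile always has
        the shorter predicted median."""
        profiles = []
        for _ in range(200):
            profiles.append(
                PatientProfile(
                    age=float(rng.uniform(20, 90)),
                    rt_associated=bool(rng.integers(2)),
                    histology=str(rng.choice(["others", "angiosarcoma", "rhabdomyosarcoma", "ups"])),
                    extent=str(rng.choice(["localised", "locally_advanced", "metastatic"])),
                    margin=str(rng.choice(["R2_or_none", "R0", "R1"])),
                    rt_dose=str(rng.choice(["none", "low", "high"])),
                    chemo=bool(rng.integers(2)),
                )
            )
        preds = [predict_profile(published_model, p) for p in profiles]
        for i in range(0, 200, 2):
            a, b = preds[i], preds[i + 1]
            if a.theta == b.theta:
                continue
            hi, lo = (a, b) if a.theta > b.theta else (b, a)
            assert hi.median_os < lo.median_os


class TestEnumeration:
    def test_single_age_gives_432_rows(self, published_model):
        table = enumerate_all_profiles(published_model, [58.0])
        assert len(table) == 432

    def test_minimum_risk_profile_is_best_treatment_combination(self, published_model):
        table = enumerate_all_profiles(published_model, [58.0])
        best = table.loc[table["theta"].idxmin()]
        assert best["margin"] == "R0"
        assert best["extent"] == "localised"
        assert best["histology"] == "others"
        assert best["rt_dose"] == "high"
        assert bool(best["chemo"]) is True
        assert bool(best["rt_associated"]) is False

    def test_all_rows_satisfy_median_definition(self, published_model):
        table = enumerate_all_profiles(published_model, [40.0]).sample(40, random_state=0)
        for _, row in table.iterrows():
            s = float(survival(published_model.params, row["median_os"], row["theta"]))
            assert s == pytest.approx(0.5, abs=1e-10)

    def test_empty_age_grid_rejected(self, published_model):
        with pytest.raises(ValueError):
            enumerate_all_profiles(published_model, [])


class TestSerialisation:
    def test_round_trip_identical_predictions(self, published_model, tmp_path):
        path = tmp_path / "model.json"
        save_model(published_model, path)
        back = load_model(path)
        for prof in (REFERENCE_PROFILE, PatientProfile(extent="metastatic", age=75.0)):
            p1 = predict_profile(published_model, prof)
            p2 = predict_profile(back, prof)
            assert p1.median_os == pytest.approx(p2.median_os, abs=1e-12)
            assert np.allclose(p1.curve_survival, p2.curve_survival, atol=1e-12)

    def test_missing_coefficient_named_in_error(self, published_model, tmp_path):
        d = published_model.to_dict()
        del d["beta"]["metastatic"]
        path = tmp_path / "broken.json"
        import json

        path.write_text(json.dumps(d))
        with pytest.raises(ValueError, match="metastatic"):
            load_model(path)

    def test_invalid_json_reported(self, tmp_path):
        path = tmp_path / "garbage.json"
        path.write_text("{not json")
        with pytest.raises(ValueError, match="JSON"):
            load_model(path)


class TestTreatmentDirections:
    def test_r1_margin_benefit_shrinks_with_age(self, published_model):
        """The R1-vs-no-resection median-OS gain is positive and larger for a
        30-year-old than an 80-year-old with localised angiosarcoma."""
        def delta_at(age):
            a = PatientProfile(age=age, histology="angiosarcoma", margin="R1")
            b = PatientProfile(age=age, histology="angiosarcoma", margin="R2_or_none")
            return compare_scenarios(published_model, a, b).delta_median_os

        deltas = [delta_at(a) for a in np.arange(30.0, 81.0, 10.0)]
        assert all(d > 0 for d in deltas)
        assert all(x > y for x, y in zip(deltas, deltas[1:]))  # monotone in age
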