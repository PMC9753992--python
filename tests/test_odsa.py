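"""Growth curves, 4PL fitting, reductions, threshold classification, inflection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from obp.odsa import (
    CATEGORIES,
    THRESHOLDS,
    DoseResponseModel,
    FitFailure,
    InflectionReport,
    ReductionProfile,
    classify_response,
    detect_inflection,
    estimate_growth,
    fit_ic50,
    reduction_profiles,
    threshold_matrix,
    viability_reduction,
)
from obp.synthetic import PlateParams, four_param_logistic, generate_plate


class TestGrowth:
    def test_exact_doubling_gives_one_day_doubling_time(self):
        days = np.arange(6)
        res = estimate_growth(days, 100.0 * 2.0**days)
        assert res.doubling_time_days == pytest.approx(1.0)

    def test_flat_series_has_zero_rate_and_infinite_doubling(self):
        res = estimate_growth([0, 2, 4, 6], [500.0] * 4)
        assert res.rate_per_day == pytest.approx(0.0)
        assert res.doubling_time_days == np.inf

    def test_noisy_exponential_rate_recovered_within_10pct(self):
        rng = np.random.default_rng(1)
        days = np.arange(0, 11)
        true_rate = 0.35
        signal = 1000 * np.exp(true_rate * days) * np.exp(rng.normal(0, 0.05, len(days)))
        res = estimate_growth(days, signal)
        assert res.rate_per_day == pytest.approx(true_rate, rel=0.10)

    def test_nonpositive_signal_rejected(self):
        with pytest.raises(ValueError):
            estimate_growth([0, 1, 2], [10.0, 0.0, 5.0])


class TestDoseResponse:
    @pytest.mark.parametrize("ic50", [7.6, 1.4])
    def test_noiseless_recovery_to_three_significant_figures(self, ic50):
        doses = np.array([0.0] + list(np.geomspace(ic50 / 30, ic50 * 30, 7)))
        viab = four_param_logistic(doses, ic50, 1.0, 0.0, 1.0)
        est, hill, bottom, top = fit_ic50(doses, viab)
        assert est == pytest.approx(ic50, rel=5e-4)
        assert top == pytest.approx(1.0, abs=0.01)

    def test_gem_grid_with_extremes_recovers_within_5pct(self):
        doses = np.array([0.0, 0.02, 0.16, 0.8, 4.0, 20.0])
        viab = four_param_logistic(doses, 1.4, 1.0, 0.0, 1.0)
        est, *_ = fit_ic50(doses, viab)
        assert est == pytest.approx(1.4, rel=0.05)

    def test_flat_viabilities_fail_explicitly(self):
        with pytest.raises(FitFailure, match="transition"):
            fit_ic50([0.0, 0.1, 1.0, 10.0, 100.0], [1.0] * 5)

    def test_too_few_dose_levels_fail(self):
        with pytest.raises(FitFailure):
            DoseResponseModel([0, 1, 2], [1.0, 0.5, 0.1])

    def test_from_plate_normalizes_to_vehicle_mean(self):
        plate = generate_plate(PlateParams(cv_noise=0.0))
        model = DoseResponseModel.from_plate(plate, "PATXO066", "GEM")
        res = model.fit()
        assert res.ic50 == pytest.approx(1.4, rel=0.05)
        assert "ic50" in res.summary()

    def test_noisy_triplicates_recover_within_20pct_in_aggregate(self):
        est = []
        for seed in range(20):
            p = PlateParams(
                dose_grids={"GEM": tuple(np.geomspace(0.05, 40.0, 7))},
                cv_noise=0.10,
                seed=seed,
            )
            res = DoseResponseModel.from_plate(generate_plate(p), "PATXO066", "GEM").fit()
            est.append(res.ic50)
        geo = np.exp(np.mean(np.log(est)))
        assert abs(geo - 1.4) / 1.4 < 0.20


class TestReductions:
    def test_arithmetic(self):
        assert viability_reduction([650.0], [1000.0]) == pytest.approx(35.0)
        assert viability_reduction([1000.0] * 3, [1000.0] * 3) == 0.0

    def test_zero_vehicle_mean_undefined(self):
        with pytest.raises(ValueError):
            viability_reduction([1.0], [0.0])

    def test_profiles_match_brute_force_mean_ratio(self):
        plate = generate_plate(
            PlateParams(cv_noise=0.2, seed=7, true_ic50={("PATXO066", "GEM"): 0.9})
        )
        (profile,) = reduction_profiles(plate)
        vehicle = plate[plate["is_vehicle"]]["signal"].mean()
        for dose, got in zip(profile.doses, profile.reductions_pct):
            treated = plate[(plate["dose"] == dose) & ~plate["is_vehicle"]]["signal"].mean()
            assert got == pytest.approx(100 * (1 - treated / vehicle))


class TestClassification:
    @pytest.mark.parametrize(
        "reductions,category,effective",
        [
            ((35, 40, 50), "responder", True),
            ((10, 35, 40), "intermediate", True),
            ((5, 10, 15), "nonresponder", False),
            ((-20, -5, 10), "nonresponder", False),
        ],
    )
    def test_rule_at_30(self, reductions, category, effective):
        call = classify_response(
            ReductionProfile("m", "GEM/PAC", tuple(float(r) for r in reductions)), 30.0
        )
        assert call.category == category
        assert call.effective is effective

    def test_nonstandard_threshold_warns(self):
        profile = ReductionProfile("m", "FFX", (10.0, 20.0, 30.0))
        with pytest.warns(UserWarning, match="nonstandard"):
            classify_response(profile, 25.0)

    @given(
        r=st.tuples(
            st.floats(-50, 100), st.floats(-50, 100), st.floats(-50, 100)
        )
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_category_monotone_in_threshold(self, r):
        rank = {c: i for i, c in enumerate(CATEGORIES)}
        profile = ReductionProfile("m", "FFX", r)
        cats = [classify_response(profile, float(t)).category for t in THRESHOLDS]
        assert all(rank[a] <= rank[b] for a, b in zip(cats, cats[1:]))
        effs = [classify_response(profile, float(t)).effective for t in THRESHOLDS]
        # effective at a higher bar implies effective at every lower bar
        assert all(not (hi and not lo) for lo, hi in zip(effs, effs[1:]))


class TestThresholdMatrix:
    def test_always_responding_model(self):
        m = threshold_matrix([ReductionProfile("m", "FFX", (60.0, 70.0, 80.0))])
        assert (m.categories.loc[("m", "FFX")] == "responder").all()

    def test_25pct_model_flips_between_20_and_30(self):
        m = threshold_matrix([ReductionProfile("m", "FFX", (25.0, 25.0, 25.0))])
        row = m.categories.loc[("m", "FFX")]
        assert row[10] == row[20] == "responder"
        assert row[30] == row[40] == "nonresponder"

    def test_matrix_equals_percell_reclassification_on_random_cohort(self):
        rng = np.random.default_rng(42)
        profiles = [
            ReductionProfile(f"m{i}", "GEM/PAC", tuple(rng.uniform(-20, 90, 3)))
            for i in range(100)
        ]
        m = threshold_matrix(profiles)
        for p in profiles:
            for t in THRESHOLDS:
                assert m.categories.loc[(p.model_id, "GEM/PAC"), t] == classify_response(
                    p, float(t)
                ).category
        # binary collapse: intermediate becomes responder
        assert not (m.binary == "intermediate").any().any()

    def test_counts_sum_to_cohort_size(self):
        rng = np.random.default_rng(1)
        profiles = [
            ReductionProfile(f"m{i}", "FFX", tuple(rng.uniform(0, 60, 3)))
            for i in range(23)
        ]
        m = threshold_matrix(profiles)
        assert (m.counts.sum(axis=0) == 23).all()


class TestInflection:
    def test_identical_counts_return_default_without_inflection(self):
        m = threshold_matrix([ReductionProfile("m", "FFX", (95.0, 96.0, 97.0))])
        rep = detect_inflection(m)
        assert isinstance(rep, InflectionReport)
        assert not rep.has_inflection
        assert rep.selected_threshold_pct == 30

    def test_mass_shift_between_20_and_30_selects_30(self):
        profiles = [
            ReductionProfile(f"m{i}", "FFX", (25.0, 26.0, 27.0)) for i in range(8)
        ]
        rep = detect_inflection(threshold_matrix(profiles))
        assert rep.has_inflection
        assert rep.selected_threshold_pct == 30

    def test_mass_shift_between_10_and_20_selects_20(self):
        profiles = [
            ReductionProfile(f"m{i}", "FFX", (15.0, 16.0, 17.0)) for i in range(5)
        ]
        rep = detect_inflection(threshold_matrix(profiles))
        assert rep.selected_threshold_pct == 20
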