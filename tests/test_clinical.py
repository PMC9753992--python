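"""Exact small-sample tests, response encoding, concordance, prognosis."""

from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from obp.clinical import (
    encode_clinical_response,
    fisher_exact_2x2,
    logrank,
    match_rates,
    mcnemar_exact,
    ratio_prognosis,
)
from obp.datasets import (
    effective_calls,
    load_odsa_reductions,
    load_prognosis_cohort,
    load_table1,
    reduction_profiles_from_frame,
)
from obp.synthetic import CohortParams, generate_cohort


class TestEncodeClinicalResponse:
    def test_decreasing_ca199_is_responder(self):
        status, reason = encode_clinical_response(
            {"regimen": "GA", "ca199_pre": 500.0, "ca199_post": 100.0,
             "received_neoadjuvant": True}
        )
        assert (status, reason) == ("responder", None)

    def test_normal_baseline_excluded(self):
        status, reason = encode_clinical_response(
            {"ca199_pre": 12.0, "ca199_post": 9.0, "received_neoadjuvant": True}
        )
        assert (status, reason) == ("excluded", "normal_baseline")

    def test_no_neoadjuvant_excluded(self):
        status, reason = encode_clinical_response(
            {"ca199_pre": 500.0, "ca199_post": None, "received_neoadjuvant": False}
        )
        assert (status, reason) == ("excluded", "no_neoadjuvant_therapy")

    def test_missing_values_excluded_not_error(self):
        status, reason = encode_clinical_response(
            {"ca199_pre": np.nan, "ca199_post": 10.0, "received_neoadjuvant": True}
        )
        assert (status, reason) == ("excluded", "missing_ca199")

    def test_rising_ca199_is_nonresponder(self):
        status, _ = encode_clinical_response(
            {"ca199_pre": 150.0, "ca199_post": 230.0, "received_neoadjuvant": True}
        )
        assert status == "nonresponder"

    def test_exclusion_does_not_alter_other_records(self):
        cohort = load_table1()
        full = [encode_clinical_response(r)[0] for _, r in cohort.iterrows()]
        kept = cohort[[encode_clinical_response(r)[0] != "excluded" for _, r in cohort.iterrows()]]
        again = [encode_clinical_response(r)[0] for _, r in kept.iterrows()]
        assert again == [s for s in full if s != "excluded"]


class TestMcNemarExact:
    @pytest.mark.parametrize("b,c,expected", [(0, 0, 1.0), (1, 1, 1.0), (5, 0, 0.0625)])
    def test_closed_form_examples(self, b, c, expected):
        assert mcnemar_exact(b, c) == pytest.approx(expected)

    def test_symmetric_and_equals_enumeration_up_to_12(self):
        """Doubled-tail exact McNemar equals brute-force binomial enumeration."""
        for n in range(0, 13):
            for b in range(0, n + 1):
                c = n - b
                # brute force: sum the point masses of each tail directly
                pmf = [comb(n, k) / 2.0**n if n else 1.0 for k in range(n + 1)]
                lower = sum(pmf[: b + 1])
                upper = sum(pmf[b:])
                expected = min(1.0, 2.0 * min(lower, upper)) if n else 1.0
                assert mcnemar_exact(b, c) == pytest.approx(expected, abs=1e-12)
                assert mcnemar_exact(b, c) == pytest.approx(mcnemar_exact(c, b))

    def test_mid_p_variant_is_smaller(self):
        assert mcnemar_exact(2, 7, mid_p=True) < mcnemar_exact(2, 7)

    @pytest.mark.parametrize("b,c", [(1, 4), (3, 3), (0, 7), (5, 9)])
    def test_agrees_with_statsmodels_exact_mcnemar(self, b, c):
        sm = pytest.importorskip("statsmodels.stats.contingency_tables")
        res = sm.mcnemar([[10, b], [c, 10]], exact=True)
        assert mcnemar_exact(b, c) == pytest.approx(float(res.pvalue), abs=1e-12)


def _fisher_enumeration(table: np.ndarray) -> float:
    """Independent oracle: full hypergeometric enumeration over fixed margins."""
    a, b = int(table[0, 0]), int(table[0, 1])
    c, d = int(table[1, 0]), int(table[1, 1])
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if n == 0:
        return 1.0
    lo, hi = max(0, c1 - r2), min(r1, c1)
    probs = {
        x: stats.hypergeom.pmf(x, n, r1, c1) for x in range(lo, hi + 1)
    }
    p_obs = probs[a]
    return float(sum(p for p in probs.values() if p <= p_obs * (1 + 1e-9)))


class TestFisherExact:
    @pytest.mark.parametrize(
        "table,expected",
        [
            ([[5, 0], [0, 3]], 1.0 / 56.0),
            ([[0, 0], [0, 3]], 1.0),
            ([[2, 0], [0, 2]], 1.0 / 3.0),
        ],
    )
    def test_reference_tables(self, table, expected):
        assert fisher_exact_2x2(table) == pytest.approx(expected, rel=1e-6)

    def test_equals_full_enumeration_for_all_tables_up_to_n20(self):
        for n in range(0, 21):
            for a in range(n + 1):
                for b in range(n - a + 1):
                    for c in range(n - a - b + 1):
                        d = n - a - b - c
                        t = np.array([[a, b], [c, d]])
                        assert fisher_exact_2x2(t) == pytest.approx(
                            _fisher_enumeration(t), abs=1e-9
                        ), t.tolist()

    def test_rejects_negative_entries(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[1, -1], [0, 2]])


class TestLogrank:
    def test_identical_groups_statistic_zero_p_one(self):
        t = [5.0, 8.0, 12.0, 20.0] * 2
        e = [True, True, False, True] * 2
        g = ["a"] * 4 + ["b"] * 4
        stat, p = logrank(t, e, g)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_no_events_gives_p_one(self):
        stat, p = logrank([1.0, 2.0, 3.0, 4.0], [False] * 4, ["a", "a", "b", "b"])
        assert (stat, p) == (0.0, 1.0)

    def test_hand_computed_six_patient_example(self):
        # group a: events at 1, 2; group b: event at 4, censored 3, 5, 6.
        # O-E and variance accumulated by hand over event times 1, 2, 4:
        #   t=1: n=6, na=2, d=1 -> e_a = 1/3,  v = (2*4*1*5)/(36*5) = 2/9
        #   t=2: n=5, na=1, d=1 -> e_a = 1/5,  v = (1*4*1*4)/(25*4) = 4/25
        #   t=4: n=3, na=0, d=1 -> e_a = 0,    v = 0
        # O_a = 2, E_a = 8/15, V = 2/9 + 4/25 = 86/225
        times = [1.0, 2.0, 4.0, 3.0, 5.0, 6.0]
        events = [True, True, True, False, False, False]
        groups = ["a", "a", "b", "b", "b", "b"]
        expected = (2 - 8 / 15) ** 2 / (86 / 225)
        stat, p = logrank(times, events, groups)
        assert stat == pytest.approx(expected, rel=1e-9)
        assert p == pytest.approx(stats.chi2.sf(expected, 1), rel=1e-9)

    def test_asymptotic_p_agrees_with_permutation_at_n100(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(10.0, 100)
        e = rng.random(100) < 0.8
        g = np.array(["a"] * 50 + ["b"] * 50)
        stat, p = logrank(t, e, g)
        perm_hits = 0
        n_perm = 1000
        for _ in range(n_perm):
            gp = rng.permutation(g)
            s, _ = logrank(t, e, gp)
            perm_hits += s >= stat
        assert abs(perm_hits / n_perm - p) < 0.05

    def test_rejects_under_hazard_ratio_4_in_at_least_90_of_100_seeds(self):
        hits = 0
        for seed in range(100):
            df = generate_cohort(
                CohortParams(
                    n_patients=400,
                    high_ratio_fraction=0.5,
                    median_survival_months={"high": 40.0, "low": 10.0},
                    seed=seed,
                )
            )
            _, p = logrank(
                df["survival_months"], df["event"], df["ratio_group"]
            )
            hits += p < 0.05
        assert hits >= 90


class TestMatchRates:
    def test_table1_fixture_reproduces_match_rates(self):
        profiles = reduction_profiles_from_frame(load_odsa_reductions())
        result = match_rates(load_table1(), effective_calls(profiles, 30.0))
        assert result.per_regimen["GA"] == (3, 4)
        assert result.per_regimen["FFX"] == (7, 8)
        assert result.match_pct("GA") == 75.0
        assert result.match_pct("FFX") == 87.5
        assert result.overall_effective == (16, 21)
        assert result.overall_effective_pct == 76.1
        assert len(result.exclusions["normal_baseline"]) == 5
        assert len(result.exclusions["no_neoadjuvant_therapy"]) == 5

    def test_all_effective_all_responders_gives_100pct(self):
        cohort = pd.DataFrame(
            {
                "pdo_id": ["p1", "p2"],
                "regimen": ["GA", "FFX"],
                "ca199_pre": [400.0, 300.0],
                "ca199_post": [100.0, 50.0],
                "received_neoadjuvant": [True, True],
            }
        )
        calls = {("p1", "GEM/PAC"): True, ("p2", "FFX"): True}
        res = match_rates(cohort, calls)
        assert res.match_pct("GA") == 100.0
        assert res.match_pct("FFX") == 100.0
        assert res.overall_effective_pct == 100.0
        assert res.mcnemar_p == 1.0

    def test_eligible_record_without_call_is_input_error(self):
        cohort = pd.DataFrame(
            {
                "pdo_id": ["p1"],
                "regimen": ["GA"],
                "ca199_pre": [400.0],
                "ca199_post": [100.0],
                "received_neoadjuvant": [True],
            }
        )
        with pytest.raises(KeyError):
            match_rates(cohort, {})


class TestRatioPrognosis:
    def test_landmark_table_reproduces_reference_fisher_p(self):
        res = ratio_prognosis(load_prognosis_cohort(), landmark_months=32.0)
        np.testing.assert_array_equal(res.table, [[5, 0], [0, 3]])
        assert res.fisher_p == pytest.approx(1.0 / 56.0, rel=1e-6)
        assert round(res.fisher_p, 4) == 0.0179

    def test_identical_survival_in_both_groups_gives_logrank_p_one(self):
        df = pd.DataFrame(
            {
                "sma_ck19_ratio": [2.0, 2.0, 0.5, 0.5],
                "survival_months": [10.0, 20.0, 10.0, 20.0],
                "event": [True, True, True, True],
            }
        )
        res = ratio_prognosis(df, landmark_months=32.0)
        assert res.logrank_p == pytest.approx(1.0)

    def test_ratio_exactly_one_goes_high_with_warning(self):
        df = pd.DataFrame(
            {
                "sma_ck19_ratio": [1.0, 0.5, 2.0],
                "survival_months": [40.0, 10.0, 50.0],
                "event": [False, True, False],
            }
        )
        with pytest.warns(UserWarning, match="1.0"):
            res = ratio_prognosis(df)
        assert res.group_sizes == {"high": 2, "low": 1}

    def test_censored_before_landmark_excluded_from_table(self):
        df = pd.DataFrame(
            {
                "sma_ck19_ratio": [2.0, 2.0, 0.5, 0.5],
                "survival_months": [40.0, 20.0, 40.0, 10.0],
                "event": [False, False, True, True],
            }
        )
        res = ratio_prognosis(df)
        assert res.n_censored_before_landmark == 1
        assert res.table.sum() == 3
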