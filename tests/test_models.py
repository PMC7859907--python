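"""Trajectory model fitting, inversion, pseudo-r² and the factor screen."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sharkheal.errors import (
    FitFailureError,
    InsufficientDataError,
    UnreachableThresholdError,
)
from sharkheal.models import (
    ExponentialHealingModel,
    HealingFactorScreen,
    QuadraticPlateauModel,
    apply_exclusions,
    day_to_threshold,
    gaussian_loglik,
    nagelkerke_r2,
)
from sharkheal.models import _plateau_curve


def _table(rows):
    return pd.DataFrame(rows)


class TestExclusions:
    def test_curve_fit_drops_late_sightings(self):
        t = _table([{"day_offset": d, "percent_healed": 10.0, "rate": 1.0}
                    for d in (10, 140, 200)])
        out = apply_exclusions(t, "curve_fit")
        assert sorted(out["day_offset"]) == [10, 140]

    def test_rate_fit_drops_negative_rates(self):
        t = _table([{"day_offset": d, "percent_healed": 10.0, "rate": r}
                    for d, r in [(5, 5.0), (10, -2.0), (20, 1.0)]])
        out = apply_exclusions(t, "rate_fit")
        assert sorted(out["rate"]) == [1.0, 5.0]

    def test_mixed_model_drops_fully_healed_and_day0(self):
        t = _table([
            {"day_offset": 0, "percent_healed": 0.0, "rate": np.nan},
            {"day_offset": 10, "percent_healed": 60.0, "rate": 6.0},
            {"day_offset": 30, "percent_healed": 100.0, "rate": 2.0},
        ])
        out = apply_exclusions(t, "mixed_model")
        assert out["day_offset"].tolist() == [10]

    def test_empty_after_filtering_raises(self):
        t = _table([{"day_offset": 200, "percent_healed": 99.0, "rate": 1.0}])
        with pytest.raises(InsufficientDataError):
            apply_exclusions(t, "curve_fit")


class TestDayToThreshold:
    def test_half_life_identity(self):
        assert day_to_threshold(100.0, math.log(2.0), 50.0) == pytest.approx(1.0)

    def test_unreachable_threshold(self):
        with pytest.raises(UnreachableThresholdError):
            day_to_threshold(90.0, 0.1, 90.0)
        with pytest.raises(UnreachableThresholdError):
            day_to_threshold(85.0, 0.1, 90.0)

    @given(
        a=st.floats(90.5, 120.0),
        b=st.floats(0.01, 0.5),
        tau=st.floats(1.0, 90.0),
    )
    @settings(deadline=None, max_examples=200)
    def test_inversion_identity(self, a, b, tau):
        x = day_to_threshold(a, b, tau)
        assert a * (1.0 - math.exp(-b * x)) == pytest.approx(tau, abs=1e-9)

    @given(a=st.floats(95.0, 120.0), b=st.floats(0.01, 0.5))
    @settings(deadline=None, max_examples=100)
    def test_monotone_in_threshold_and_rate(self, a, b):
        assert day_to_threshold(a, b, 50.0) < day_to_threshold(a, b, 90.0)
        assert day_to_threshold(a, 2.0 * b, 90.0) < day_to_threshold(a, b, 90.0)


class TestExponentialFit:
    def test_zero_noise_recovery(self):
        days = np.arange(1.0, 61.0)
        y = 95.0 * (1.0 - np.exp(-0.1 * days))
        res = ExponentialHealingModel(days, y).fit()
        assert res.a == pytest.approx(95.0, abs=1e-6)
        assert res.b == pytest.approx(0.1, abs=1e-6)
        assert res.rsquared == pytest.approx(1.0)

    def test_underdetermined_raises(self):
        with pytest.raises(FitFailureError):
            ExponentialHealingModel([0.0, 5.0], [0.0, 40.0])

    def test_matches_coarse_grid_search(self, rng):
        days = np.array([2.0, 5.0, 10.0, 20.0, 40.0, 80.0])
        y = 93.0 * (1.0 - np.exp(-0.09 * days)) + rng.normal(0, 5.0, len(days))
        res = ExponentialHealingModel(days, y).fit()
        grid_a = np.linspace(50, 150, 201)
        grid_b = np.linspace(0.005, 0.5, 200)
        best = min(
            ((np.sum((y - a * (1 - np.exp(-b * days))) ** 2), a, b)
             for a in grid_a for b in grid_b),
        )
        assert res.rss <= best[0] + 1e-9
        # continuous optimum can sit up to ~a grid step from the lattice best
        assert res.a == pytest.approx(best[1], abs=0.75)
        assert res.b == pytest.approx(best[2], abs=0.005)

    def test_confidence_interval_coverage(self):
        """~95% Wald intervals cover the truth in most noisy replicates."""
        a_true, b_true, sigma = 93.0, 0.1, 8.0
        days = np.arange(1.0, 61.0, 2.0)
        mean = a_true * (1.0 - np.exp(-b_true * days))
        hits = 0
        n_rep = 200
        rng = np.random.default_rng(99)
        for _ in range(n_rep):
            res = ExponentialHealingModel(days, mean + rng.normal(0, sigma, len(days))).fit()
            se = res.bse
            ok_a = abs(res.a - a_true) <= 1.96 * se[0]
            ok_b = abs(res.b - b_true) <= 1.96 * se[1]
            hits += ok_a and ok_b
        assert hits / n_rep >= 0.90


class TestPlateauFit:
    def test_zero_noise_recovery(self):
        days = np.arange(1.0, 61.0, 2.0)
        y = _plateau_curve(days, 9.306, -0.513, 33.1)
        res = QuadraticPlateauModel(days, y).fit()
        assert res.a == pytest.approx(9.306, abs=1e-4)
        assert res.b == pytest.approx(-0.513, abs=1e-4)
        assert res.x_cl == pytest.approx(33.1, abs=1e-4)
        assert res.plateau_value == pytest.approx(9.306 - 0.513 * 33.1 / 2.0, abs=1e-6)

    def test_zero_slope_and_continuity_at_critical_day(self):
        a, b, x_cl = 9.306, -0.513, 33.1
        eps = 1e-6
        below = _plateau_curve(np.array([x_cl - eps]), a, b, x_cl)[0]
        above = _plateau_curve(np.array([x_cl + eps]), a, b, x_cl)[0]
        assert above == pytest.approx(below, abs=1e-9)
        slope = (below - _plateau_curve(np.array([x_cl - 2 * eps]), a, b, x_cl)[0]) / eps
        assert abs(slope) < 1e-6

    def test_underdetermined_raises(self):
        with pytest.raises(FitFailureError):
            QuadraticPlateauModel([1.0, 2.0, 3.0], [5.0, 4.0, 3.0])

    def test_reports_se_and_t_for_critical_day(self, rng):
        days = np.arange(1.0, 81.0, 2.0)
        y = _plateau_curve(days, 10.0, -0.4, 30.0) + rng.normal(0, 0.5, len(days))
        res = QuadraticPlateauModel(days, y).fit()
        assert res.x_cl_se > 0
        assert res.x_cl_t == pytest.approx(res.x_cl / res.x_cl_se)
        assert 20.0 < res.x_cl < 40.0


class TestNagelkerke:
    def test_equal_likelihoods_give_zero(self):
        ll = gaussian_loglik(50.0, 10)
        assert nagelkerke_r2(ll, ll, 10) == 0.0

    def test_hand_computed_value(self):
        # n=8, rss_model=2, rss_null=20: direct evaluation of the formula
        n, rss_m, rss_0 = 8, 2.0, 20.0
        ll_m, ll_0 = gaussian_loglik(rss_m, n), gaussian_loglik(rss_0, n)
        expected = (1 - math.exp(2 * (ll_0 - ll_m) / n)) / (1 - math.exp(2 * ll_0 / n))
        got = nagelkerke_r2(ll_m, ll_0, n)
        assert got == pytest.approx(expected)
        assert 0.0 < got <= 1.0

    def test_model_worse_than_null_rejected(self):
        with pytest.raises(ValueError):
            nagelkerke_r2(gaussian_loglik(30.0, 10), gaussian_loglik(20.0, 10), 10)


class TestFactorScreen:
    def test_screen_detects_type_effect_in_one_cohort(self):
        from sharkheal.simulate import CohortConfig, generate_cohort

        cohort = generate_cohort(CohortConfig(seed=5))
        res = HealingFactorScreen.from_rates_frame(cohort.rates_frame()).fit()
        assert "type" in res.retained
        terms = {r.term for r in res.results}
        assert terms == {"type", "location", "severity"}
        assert all(r.p >= 0.0 and r.df >= 1 for r in res.results)

    def test_single_shark_uses_fallback_structure(self):
        from sharkheal.simulate import CohortConfig, generate_cohort

        cohort = generate_cohort(CohortConfig(n_injuries=8, n_sharks=1, seed=2))
        res = HealingFactorScreen.from_rates_frame(cohort.rates_frame()).fit()
        assert "fallback" in res.random_structure

    def test_requires_day0_rows_excluded(self):
        t = _table([
            {"day_offset": 0, "percent_healed": 0.0, "rate": np.nan,
             "injury_id": "i", "shark_id": "s"},
        ])
        with pytest.raises(ValueError):
            HealingFactorScreen(t)
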