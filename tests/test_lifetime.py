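"""Lifetime engine: discounting closed forms, trace propagation, projection
invariants and the microsimulation oracle."""
import warnings

import numpy as np
import pytest

import scadcost as sc
from scadcost.exceptions import ConfigurationError
from scadcost.lifetime import discount_factor
from scadcost.params import CYCLE_YEARS, EventCostBands, PanelCostParams, TransitionHazard, TransitionParams


def _params(stable=None, post_cvd=0.0, post_noncvd=0.0):
    stable = stable or {}
    def th(rate):
        return TransitionHazard(np.log(rate) if rate > 0 else -np.inf)
    full = {e: th(stable.get(e, 0.0))
            for e in ("ami", "istroke", "hstroke", "cvd_death", "noncvd_death")}
    return TransitionParams.with_shared_post(full, th(post_cvd), th(post_noncvd))


def _cost_params(baseline=341.0, trend=10.0, with_events=True):
    def cp(cat, scale=1.0):
        events = {}
        if with_events:
            events = {
                "ami": EventCostBands(*(scale * v for v in (5028, 1400, 750, 499, 521))),
                "istroke": EventCostBands(*(scale * v for v in (5800, 1700, 900, 502, 430))),
                "hstroke": EventCostBands(*(scale * v for v in (7200, 1900, 900, 477, 450))),
            }
        else:
            events = {e: EventCostBands(0, 0, 0, 0, 0) for e in ("ami", "istroke", "hstroke")}
        return PanelCostParams(
            category=cat, baseline_cost=baseline * scale, period_trend=trend * scale,
            event_increments=events,
            death_increments={"cvd_death": 2008.0 * scale, "noncvd_death": 2240.0 * scale})
    return {"total": cp("total"), "cvd": cp("cvd", 0.7), "chd": cp("chd", 0.55)}


class TestDiscounting:
    def test_zero_rate_is_plain_sum(self):
        costs = [100.0, 200.0, 50.0]
        assert sc.discount_stream(costs, 0.0) == pytest.approx(350.0)

    def test_one_year_present_value(self):
        # a cost of 1035 exactly one year out at 3.5% discounts to 1000
        k = 365.25 / 90.0 + 0.5  # (k - 0.5) cycles = one year
        assert 1035.0 * discount_factor(k, 0.035, "mid") == pytest.approx(1000.0)

    def test_constant_stream_matches_annuity_closed_form(self):
        c, rate, K = 250.0, 0.035, 80
        got = sc.discount_stream(np.full(K, c), rate)
        v = 1.0 / (1.0 + rate)
        q = v ** CYCLE_YEARS
        expected = c * v ** (0.5 * CYCLE_YEARS) * (1 - q ** K) / (1 - q)
        assert got == pytest.approx(expected, abs=1e-9)

    def test_end_of_cycle_convention_discounts_more(self):
        costs = np.full(40, 100.0)
        assert sc.discount_stream(costs, 0.035, "end") < sc.discount_stream(costs, 0.035, "mid")

    def test_negative_rate_rejected(self):
        with pytest.raises(ConfigurationError):
            sc.discount_stream([1.0], -0.01)


class TestTrace:
    def test_zero_hazards_costs_follow_trend_exactly(self):
        trace = sc.run_trace(_params(), _cost_params(with_events=False), {}, 30)
        expected = 341.0 + 10.0 * np.arange(30)
        assert np.allclose(trace.expected_costs["total"], expected)
        assert np.allclose(trace.survival, 1.0)

    def test_occupancy_rows_sum_to_one(self):
        p = _params({"ami": 0.01, "istroke": 0.002, "hstroke": 0.001,
                     "cvd_death": 0.005, "noncvd_death": 0.01},
                    post_cvd=0.03, post_noncvd=0.02)
        trace = sc.run_trace(p, _cost_params(), {}, 100)
        assert np.allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-10)
        # absorbing states non-decreasing
        death_cols = [i for i, s in enumerate(trace.states) if s.startswith("death")]
        dead = trace.occupancy[:, death_cols].sum(axis=1)
        assert (np.diff(dead) >= -1e-12).all()

    def test_horizon_below_five_years_rejected(self):
        with pytest.raises(ConfigurationError):
            sc.run_trace(_params(), _cost_params(), {}, 10)


class TestProjection:
    def test_flat_cost_zero_hazard_five_year_total(self):
        cps = _cost_params(baseline=100.0, trend=0.0, with_events=False)
        pj = sc.project(_params(), cps, {}, horizon_cycles=20, annual_rate=0.0)
        assert pj.cell("five_year", "total", False) == pytest.approx(2000.0)
        assert pj.cell("five_year", "total", True) == pytest.approx(2000.0)

    def test_immediate_death_lifetime_is_first_cycle_cost_plus_increment(self):
        p = _params({"cvd_death": 50.0})  # dies in cycle 1 almost surely
        cps = _cost_params(with_events=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pj = sc.project(p, cps, {}, horizon_cycles=40, annual_rate=0.0)
        assert pj.cell("lifetime", "total", False) == pytest.approx(341.0 + 2008.0, rel=1e-6)
        assert pj.life_expectancy == pytest.approx(0.0, abs=1e-6)

    def test_discounted_never_exceeds_undiscounted(self):
        p = _params({"ami": 0.008, "cvd_death": 0.004, "noncvd_death": 0.012},
                    post_cvd=0.04, post_noncvd=0.02)
        pj = sc.project(p, _cost_params(), {}, horizon_cycles=400)
        for horizon in ("five_year", "lifetime"):
            for cat in ("total", "cvd", "chd"):
                assert pj.cell(horizon, cat, True) <= pj.cell(horizon, cat, False)
        # category and horizon orderings
        for disc in (False, True):
            assert pj.cell("five_year", "chd", disc) <= pj.cell("five_year", "cvd", disc) \
                <= pj.cell("five_year", "total", disc)
            assert pj.cell("five_year", "total", disc) <= pj.cell("lifetime", "total", disc)

    def test_lifetime_nondecreasing_in_horizon(self):
        p = _params({"noncvd_death": 0.02})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pj1 = sc.project(p, _cost_params(), {}, horizon_cycles=100)
            pj2 = sc.project(p, _cost_params(), {}, horizon_cycles=200)
        assert pj2.cell("lifetime", "total", False) >= pj1.cell("lifetime", "total", False)

    def test_missing_category_rejected(self):
        cps = _cost_params()
        del cps["chd"]
        with pytest.raises(ConfigurationError):
            sc.project(_params(), cps, {}, horizon_cycles=20)

    def test_cost_curve_crossing_between_risk_profiles(self):
        # high-hazard profile accrues more early cost; low-hazard profile
        # overtakes on lifetime totals through longer survival
        high = _params({"ami": 0.02, "cvd_death": 0.01, "noncvd_death": 0.02},
                       post_cvd=0.06, post_noncvd=0.04)
        low = _params({"ami": 0.002, "cvd_death": 0.001, "noncvd_death": 0.004},
                      post_cvd=0.02, post_noncvd=0.01)
        cps = _cost_params()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pj_high = sc.project(high, cps, {}, horizon_cycles=600)
            pj_low = sc.project(low, cps, {}, horizon_cycles=600)
        assert pj_high.cell("five_year", "total", False) > pj_low.cell("five_year", "total", False)
        assert pj_low.cell("lifetime", "total", False) > pj_high.cell("lifetime", "total", False)


class TestMicrosimulation:
    P = _params({"ami": 0.01, "istroke": 0.003, "hstroke": 0.001,
                 "cvd_death": 0.006, "noncvd_death": 0.015},
                post_cvd=0.04, post_noncvd=0.025)

    def test_zero_hazards_zero_variance(self):
        ms = sc.microsimulate(_params(), _cost_params(with_events=False), {},
                              n=2000, seed=0, horizon_cycles=20)
        assert ms.standard_errors["lifetime"]["total"]["undiscounted"] == 0.0
        assert np.allclose(ms.survival, 1.0)

    def test_agrees_with_trace(self):
        cps = _cost_params()
        pj = sc.project(self.P, cps, {}, horizon_cycles=150)
        ms = sc.microsimulate(self.P, cps, {}, n=60000, seed=3, horizon_cycles=150)
        for horizon in ("five_year", "lifetime"):
            for cat in ("total", "cvd", "chd"):
                for disc, key in ((False, "undiscounted"), (True, "discounted")):
                    se = ms.standard_errors[horizon][cat][key]
                    assert abs(pj.cell(horizon, cat, disc)
                               - ms.cell(horizon, cat, disc)) < 3 * se + 1e-9
        assert abs(pj.life_expectancy - ms.life_expectancy) \
            < 3 * ms.standard_errors["life_expectancy"]

    def test_determinism_given_seed(self):
        cps = _cost_params()
        a = sc.microsimulate(self.P, cps, {}, n=3000, seed=9, horizon_cycles=60)
        b = sc.microsimulate(self.P, cps, {}, n=3000, seed=9, horizon_cycles=60)
        assert a.cell("lifetime", "total", False) == b.cell("lifetime", "total", False)

    def test_standard_errors_shrink_with_root_n(self):
        cps = _cost_params()
        a = sc.microsimulate(self.P, cps, {}, n=5000, seed=1, horizon_cycles=60)
        b = sc.microsimulate(self.P, cps, {}, n=20000, seed=2, horizon_cycles=60)
        ratio = (a.standard_errors["lifetime"]["total"]["undiscounted"]
                 / b.standard_errors["lifetime"]["total"]["undiscounted"])
        assert ratio == pytest.approx(2.0, rel=0.25)

    def test_small_n_rejected(self):
        with pytest.raises(ConfigurationError):
            sc.microsimulate(self.P, _cost_params(), {}, n=10, seed=0)
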