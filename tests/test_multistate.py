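"""Multistate transition model: matrix kinematics, closed forms, recovery."""
import warnings

import numpy as np
import pandas as pd
import pytest

import scadcost as sc
from scadcost.markov import state_space, transition_matrix_full
from scadcost.params import CYCLE_YEARS, TransitionHazard, TransitionParams

from conftest import zero_hazard_params


def _params(stable=None, post_cvd=0.0, post_noncvd=0.0):
    stable = stable or {}
    def th(rate):
        return TransitionHazard(np.log(rate) if rate > 0 else -np.inf)
    full = {e: th(stable.get(e, 0.0))
            for e in ("ami", "istroke", "hstroke", "cvd_death", "noncvd_death")}
    return TransitionParams.with_shared_post(full, th(post_cvd), th(post_noncvd))


class TestTransitionMatrix:
    def test_zero_hazards_identity_rows(self):
        p = _params()
        row = sc.transition_matrix(p, {}, "stable")
        assert row["stable"] == 1.0
        assert row.drop("stable").sum() == 0.0

    def test_single_risk_closed_form(self):
        h = 0.05
        p = _params({"cvd_death": h})
        row = sc.transition_matrix(p, {}, "stable")
        assert row["death_cvd"] == pytest.approx(1 - np.exp(-h))
        assert row["stable"] == pytest.approx(np.exp(-h))

    def test_rows_sum_to_one_for_all_states(self):
        p = _params({"ami": 0.01, "istroke": 0.005, "hstroke": 0.001,
                     "cvd_death": 0.004, "noncvd_death": 0.01},
                    post_cvd=0.03, post_noncvd=0.02)
        P = transition_matrix_full(p, {"age_c": 5.0})
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)
        assert (P >= 0).all()

    def test_death_rows_absorbing(self):
        p = _params({"ami": 0.01})
        for d in ("death_cvd", "death_noncvd"):
            row = sc.transition_matrix(p, {}, d)
            assert row[d] == 1.0 and row.sum() == 1.0

    def test_tunnel_progression(self):
        p = _params({"ami": 0.01}, post_cvd=0.02, post_noncvd=0.01)
        row = sc.transition_matrix(p, {}, "ami_b2")
        stay = np.exp(-(0.02 + 0.01))
        assert row["ami_b3"] == pytest.approx(stay)
        row4 = sc.transition_matrix(p, {}, "ami_b4")
        assert row4["ami_long"] == pytest.approx(stay)
        rowl = sc.transition_matrix(p, {}, "ami_long")
        assert rowl["ami_long"] == pytest.approx(stay)


class TestFiveYearRisk:
    def test_zero_hazards(self):
        assert sc.five_year_risk(_params(), {}) == 0.0

    def test_only_cvd_death_closed_form(self):
        h = 0.01
        assert sc.five_year_risk(_params({"cvd_death": h}), {}) \
            == pytest.approx(1 - np.exp(-20 * h))

    def test_competing_noncvd_death_reduces_risk(self):
        base = sc.five_year_risk(_params({"ami": 0.01}), {})
        with_comp = sc.five_year_risk(_params({"ami": 0.01, "noncvd_death": 0.05}), {})
        assert with_comp < base

    def test_matches_microsimulation(self):
        p = _params({"ami": 0.008, "istroke": 0.003, "hstroke": 0.001,
                     "cvd_death": 0.004, "noncvd_death": 0.012},
                    post_cvd=0.03, post_noncvd=0.02)
        analytic = sc.five_year_risk(p, {})
        # microsimulation oracle over the same transition kinematics
        rng = np.random.default_rng(0)
        n = 200000
        P = transition_matrix_full(p, {})
        Pcum = np.cumsum(P, axis=1)
        space = state_space()
        stable = space.index("stable")
        first_cvd = 0
        state = np.full(n, stable)
        event_states = {space.index(s) for s in
                        ("ami_b1", "istroke_b1", "hstroke_b1", "death_cvd")}
        done = np.zeros(n, dtype=bool)
        for _ in range(20):
            active = (state == stable) & ~done
            idx = np.where(active)[0]
            u = rng.random(len(idx))
            nxt = (u[:, None] >= Pcum[state[idx]]).sum(axis=1)
            hit = np.isin(nxt, list(event_states))
            first_cvd += hit.sum()
            done[idx[nxt != stable]] = True
            state[idx] = np.where(nxt == stable, stable, -1)
        mc = first_cvd / n
        se = np.sqrt(analytic * (1 - analytic) / n)
        assert abs(analytic - mc) < 3 * se


class TestLifeExpectancy:
    def test_constant_hazard_matches_geometric_sum(self):
        q = 0.05
        h = -np.log(1 - q)
        p = _params({"noncvd_death": h})
        le = sc.life_expectancy(p, {}, horizon_cycles=600)
        expected = (1 - q) / q * CYCLE_YEARS  # geometric-sum oracle
        assert le == pytest.approx(expected, rel=1e-6)

    def test_immediate_absorption_gives_zero(self):
        p = _params({"cvd_death": 50.0})  # per-cycle death probability ~ 1
        le = sc.life_expectancy(p, {}, horizon_cycles=30)
        assert le == pytest.approx(0.0, abs=1e-6)

    def test_higher_hazards_lower_life_expectancy(self):
        base = {"ami": 0.005, "cvd_death": 0.004, "noncvd_death": 0.01}
        p1 = _params(base, post_cvd=0.03, post_noncvd=0.02)
        p2 = _params({k: 1.5 * v for k, v in base.items()},
                     post_cvd=0.045, post_noncvd=0.03)
        le1 = sc.life_expectancy(p1, {}, horizon_cycles=800)
        le2 = sc.life_expectancy(p2, {}, horizon_cycles=800)
        assert le2 < le1

    def test_truncation_warning_when_horizon_too_short(self):
        p = _params({"noncvd_death": 0.001})
        with pytest.warns(UserWarning, match="truncated"):
            sc.life_expectancy(p, {}, horizon_cycles=25)


class TestSurvivalCurve:
    def test_monotone_non_increasing_in_unit_interval(self):
        from scadcost.multistate import survival_curve

        p = _params({"ami": 0.01, "cvd_death": 0.005, "noncvd_death": 0.01},
                    post_cvd=0.04, post_noncvd=0.02)
        s = survival_curve(p, {}, 200)
        assert ((s >= -1e-12) & (s <= 1 + 1e-12)).all()
        assert (np.diff(s) <= 1e-12).all()


class TestFit:
    def test_doubling_cohort_identical_estimates(self):
        cfg = sc.default_config(n_patients=800, seed=51, horizon_cycles=20)
        t = sc.simulate(cfg)
        b, e = t["baseline"], t["events"]
        r1 = sc.MultistateModel(b, e).fit()
        b2 = pd.concat([b, b.assign(patient_id=b["patient_id"] + 10000)],
                       ignore_index=True)
        e2 = pd.concat([e, e.assign(patient_id=e["patient_id"] + 10000)],
                       ignore_index=True)
        r2 = sc.MultistateModel(b2, e2).fit()
        # identical up to optimizer convergence tolerance (the mean-loglikelihood
        # objective is analytically invariant under duplication)
        for k in r1.transition_params.transitions:
            assert r1.transition_params.transitions[k].log_baseline == pytest.approx(
                r2.transition_params.transitions[k].log_baseline, abs=1e-3)

    def test_absent_transition_floored_with_warning(self):
        hz = zero_hazard_params()
        hz["stable:cvd_death"] = {"rate": 0.01, "log_hr": {}}
        cfg = sc.default_config(n_patients=2000, seed=52, horizon_cycles=10,
                                censoring_rate=0.0, hazard_params=hz)
        t = sc.simulate(cfg)
        with pytest.warns(UserWarning, match="stable->ami"):
            res = sc.MultistateModel(t["baseline"], t["events"]).fit()
        assert res.transition_params.transitions["stable:ami"].log_baseline \
            <= np.log(1e-8) + 1e-9
        # the observed transition is recovered
        est = res.transition_params.transitions["stable:cvd_death"].log_baseline
        se = res.bse["stable:cvd_death"]["log_baseline"]
        assert abs(est - np.log(0.01)) < 3 * se

    def test_no_events_at_all_raises(self):
        cfg = sc.default_config(n_patients=50, seed=53, censoring_rate=0.0,
                                hazard_params=zero_hazard_params())
        t = sc.simulate(cfg)
        with pytest.raises(Exception, match="larger"):
            sc.MultistateModel(t["baseline"], t["events"]).fit()

    def test_covariate_effect_recovery(self):
        # a strong age effect on AMI hazard is recovered within 3 SEs
        hz = zero_hazard_params()
        hz["stable:ami"] = {"rate": 0.01, "log_hr": {"age_c": 0.08}}
        hz["stable:noncvd_death"] = {"rate": 0.01, "log_hr": {}}
        hz["post:cvd_death"] = {"rate": 0.03, "log_hr": {}}
        hz["post:noncvd_death"] = {"rate": 0.02, "log_hr": {}}
        cfg = sc.default_config(n_patients=8000, seed=54, horizon_cycles=24,
                                hazard_params=hz)
        t = sc.simulate(cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sc.MultistateModel(t["baseline"], t["events"]).fit()
        tr = res.transition_params.transitions["stable:ami"]
        se = res.bse["stable:ami"]
        assert abs(tr.log_baseline - np.log(0.01)) < 3 * se["log_baseline"]
        assert abs(tr.effects["age_c"] - 0.08) < 3 * se["age_c"]
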