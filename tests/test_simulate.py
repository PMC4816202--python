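"""Synthetic cohort generator: distributional targets, event process closed
forms, cost means, determinism."""
import numpy as np
import pandas as pd
import pytest

import scadcost as sc
from scadcost.exceptions import ConfigurationError
from scadcost.simulate import implied_category_params

from conftest import plain_cost_params, zero_hazard_params


class TestBaseline:
    def test_covariate_mix_matches_configuration(self):
        cfg = sc.default_config(n_patients=100000, seed=1)
        b = sc.generate_baseline(cfg)
        assert len(b) == 100000
        assert abs((b["sex"] == "female").mean() - 0.44) < 0.005
        assert abs((b["diagnosis"] == "stable_angina").mean() - 0.474) < 0.005
        men = b[b["sex"] == "male"]
        women = b[b["sex"] == "female"]
        assert abs(men["age_at_entry"].mean() - 67) < 0.5
        assert abs(women["age_at_entry"].mean() - 72) < 0.5

    def test_degenerate_single_male_no_missing(self):
        cfg = sc.default_config(
            n_patients=1, seed=5, female_fraction=0.0,
            missingness_rates={k: 0.0 for k in ("heart_rate", "creatinine", "haemoglobin")})
        b = sc.generate_baseline(cfg)
        assert len(b) == 1
        assert b.loc[0, "sex"] == "male"
        assert not b[["heart_rate", "creatinine", "haemoglobin"]].isna().any().any()

    def test_missingness_rate_matches_binomial_oracle(self):
        n = 50000
        cfg = sc.default_config(
            n_patients=n, seed=9,
            missingness_rates={"heart_rate": 0.3, "creatinine": 0.0, "haemoglobin": 0.0})
        b = sc.generate_baseline(cfg)
        observed = b["heart_rate"].isna().mean()
        # independent binomial oracle with the same rate
        oracle = np.random.default_rng(123).binomial(1, 0.3, n).mean()
        assert abs(observed - 0.3) < 0.01
        assert abs(observed - oracle) < 0.015

    def test_invalid_config_names_field(self):
        with pytest.raises(ConfigurationError, match="female_fraction"):
            sc.default_config(female_fraction=1.5)
        with pytest.raises(ConfigurationError, match="diagnosis_mix"):
            sc.default_config(diagnosis_mix={d: 0.2 for d in
                                             ("stable_angina", "unstable_angina", "stemi",
                                              "nstemi", "other_chd")} | {"stable_angina": 0.3})
        with pytest.raises(ConfigurationError, match="gamma_shape"):
            sc.default_config(gamma_shape=0.0)


class TestEvents:
    def test_zero_hazards_produce_no_events(self):
        cfg = sc.default_config(n_patients=200, seed=2, censoring_rate=0.0,
                                hazard_params=zero_hazard_params())
        b = sc.generate_baseline(cfg)
        e = sc.simulate_events(b, cfg)
        assert len(e) == 0

    def test_single_hazard_survival_matches_geometric_closed_form(self):
        # only CVD death at h = 0.02/cycle: S(20) = exp(-0.02)^20
        hz = zero_hazard_params()
        hz["stable:cvd_death"] = {"rate": 0.02, "log_hr": {}}
        n = 50000
        cfg = sc.default_config(n_patients=n, seed=11, censoring_rate=0.0,
                                horizon_cycles=20, hazard_params=hz)
        b = sc.generate_baseline(cfg)
        e = sc.simulate_events(b, cfg)
        surv = 1 - len(e) / n
        expected = np.exp(-0.02) ** 20
        mc_se = np.sqrt(expected * (1 - expected) / n)
        assert abs(surv - expected) < 3 * mc_se

    def test_post_event_death_strictly_after_event(self, small_cohort):
        e = small_cohort["events"]
        nonfatal = e[e["event_type"].isin(("ami", "istroke", "hstroke"))]
        deaths = e[e["event_type"].isin(("cvd_death", "noncvd_death"))]
        merged = nonfatal.merge(deaths, on="patient_id", suffixes=("_event", "_death"))
        assert (merged["cycle_death"] > merged["cycle_event"]).all()

    def test_at_most_one_first_event_and_only_death_after(self, small_cohort):
        e = small_cohort["events"]
        real = e[e["event_type"] != "censoring"]
        for _, grp in real.groupby("patient_id"):
            assert len(grp) <= 2
            if len(grp) == 2:
                ordered = grp.sort_values("cycle")
                assert ordered.iloc[0]["event_type"] in ("ami", "istroke", "hstroke")
                assert ordered.iloc[1]["event_type"] in ("cvd_death", "noncvd_death")

    def test_event_type_fractions_match_hazard_ratios(self):
        # empirical cause mix converges to h_c / H among first events
        hz = zero_hazard_params()
        hz["stable:ami"] = {"rate": 0.01, "log_hr": {}}
        hz["stable:cvd_death"] = {"rate": 0.03, "log_hr": {}}
        n = 50000
        cfg = sc.default_config(n_patients=n, seed=13, censoring_rate=0.0,
                                horizon_cycles=10, hazard_params=hz)
        b = sc.generate_baseline(cfg)
        e = sc.simulate_events(b, cfg)
        frac_ami = (e["event_type"] == "ami").mean()
        expected = 0.01 / 0.04
        se = np.sqrt(expected * (1 - expected) / len(e))
        assert abs(frac_ami - expected) < 3 * se


class TestCosts:
    def test_vanishing_noise_recovers_baseline_mean(self):
        cp = plain_cost_params(period_trend=0.0)
        cfg = sc.default_config(n_patients=50, seed=3, gamma_shape=1e6,
                                censoring_rate=0.0, horizon_cycles=8,
                                hazard_params=zero_hazard_params(), cost_params=cp)
        t = sc.simulate(cfg)
        total, _, _ = sc.compose_cost_categories(t["period_costs"])
        assert np.allclose(total, 341.0, rtol=0.01)

    def test_cycle1_mean_matches_configured_baseline(self):
        cfg = sc.default_config(n_patients=20000, seed=4, censoring_rate=0.0,
                                horizon_cycles=4, hazard_params=zero_hazard_params(),
                                cost_params=plain_cost_params())
        t = sc.simulate(cfg)
        p = t["period_costs"]
        total, _, _ = sc.compose_cost_categories(p[p["cycle"] == 1])
        se = total.std(ddof=1) / np.sqrt(len(total))
        assert abs(total.mean() - 341.0) < 3 * se
        # trend: cycle-4 mean is 341 + 30
        t4, _, _ = sc.compose_cost_categories(p[p["cycle"] == 4])
        se4 = t4.std(ddof=1) / np.sqrt(len(t4))
        assert abs(t4.mean() - 371.0) < 3 * se4

    def test_censoring_truncates_panel(self, small_cohort):
        b, p = small_cohort["baseline"], small_cohort["period_costs"]
        last = p.groupby("patient_id")["cycle"].max()
        fu = b.set_index("patient_id")["followup_cycles"]
        assert (last <= fu.loc[last.index]).all()
        assert (last == fu.loc[last.index]).all()

    def test_category_nesting_row_wise(self, small_cohort):
        p = small_cohort["period_costs"]
        assert (p["inpatient_chd"] <= p["inpatient_cvd"] + 1e-9).all()
        assert (p["inpatient_cvd"] <= p["inpatient_total"] + 1e-9).all()
        assert (p["drugs_cvd"] <= p["drugs_total"] + 1e-9).all()
        total, cvd, chd = sc.compose_cost_categories(p)
        assert (chd <= cvd + 1e-9).all() and (cvd <= total + 1e-9).all()

    def test_per_band_cost_means_match_implied_params(self):
        # pooled per-cycle means converge to the additive means per event band
        cfg = sc.default_config(n_patients=20000, seed=17, horizon_cycles=20)
        t = sc.simulate(cfg)
        p, e, b = t["period_costs"], t["events"], t["baseline"]
        ami = e[e["event_type"] == "ami"][["patient_id", "cycle"]].rename(
            columns={"cycle": "event_cycle"})
        merged = p.merge(ami, on="patient_id")
        band1 = merged[merged["cycle"] == merged["event_cycle"]]
        total, _, _ = sc.compose_cost_categories(band1)
        # expected mean: 341 + 10*(cycle-1) + covariate effects + 5028
        X = sc.params.design_matrix(
            b.set_index("patient_id").loc[band1["patient_id"]],
            list(cfg.cost_params.covariate_effects))
        eff = sum(v * X[k].to_numpy() for k, v in cfg.cost_params.covariate_effects.items())
        expected = 341 + 10 * (band1["cycle"].to_numpy() - 1) + eff + 5028
        resid = total.to_numpy() - expected
        se = resid.std(ddof=1) / np.sqrt(len(resid))
        assert abs(resid.mean()) < 3 * se

    def test_implied_category_params_are_nested(self):
        cfg = sc.default_config()
        tot = implied_category_params(cfg, "total")
        cvd = implied_category_params(cfg, "cvd")
        chd = implied_category_params(cfg, "chd")
        assert chd.baseline_cost <= cvd.baseline_cost <= tot.baseline_cost
        for e in ("ami", "istroke", "hstroke"):
            for b_ in range(5):
                vals = [p.event_increments[e].as_tuple()[b_] for p in (chd, cvd, tot)]
                assert vals[0] <= vals[1] <= vals[2]


class TestDeterminism:
    def test_identical_config_and_seed_reproduce_tables(self):
        cfg = sc.default_config(n_patients=300, seed=21)
        t1 = sc.simulate(cfg)
        t2 = sc.simulate(cfg)
        for k in t1:
            pd.testing.assert_frame_equal(t1[k], t2[k])

    def test_different_seeds_differ(self):
        t1 = sc.simulate(sc.default_config(n_patients=300, seed=1))
        t2 = sc.simulate(sc.default_config(n_patients=300, seed=2))
        assert not t1["baseline"]["age_at_entry"].equals(t2["baseline"]["age_at_entry"])
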