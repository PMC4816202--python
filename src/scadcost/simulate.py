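"""Synthetic SCAD cohort generator.

Produces the three analysis tables — patient baseline, dated clinical events,
and the 90-day period-cost panel — with the statistical structure the
downstream estimators assume:

* baseline covariates drawn from the configured mix (sex, age by sex, the
  five-way SCAD diagnosis split, comorbidity flags, Gaussian biomarkers with
  configurable missingness, MCAR by default);
* a discrete-cycle competing-risks event process: in every 90-day cycle a
  stable patient faces cause-specific exponential hazards for non-fatal AMI,
  ischaemic stroke, haemorrhagic stroke, CVD death and non-CVD death,
  converted to per-cycle probabilities p_c = h_c/H · (1 − exp(−H)); after a
  non-fatal first event only the two death transitions remain; independent
  per-cycle Bernoulli censoring;
* gamma-distributed period costs whose means follow the additive panel
  structure (baseline + trend·(cycle−1) + covariate effects + event-band
  increment + death-period increment), split across nested cost components so
  the CHD ⊆ CVD ⊆ total category composition holds row by row.

Everything is deterministic given the config seed.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .config import COST_COMPONENTS, SimulationConfig
from .exceptions import ParameterError
from .params import (
    COMORBIDITY_FLAGS,
    CYCLE_DAYS,
    DEATH_TYPES,
    DIAGNOSIS_LEVELS,
    EVENT_TYPES,
    FIRST_EVENT_TYPES,
    PanelCostParams,
    EventCostBands,
    design_matrix,
)

#: components contributing to each reported cost category
CATEGORY_COMPONENTS = {
    "chd": ("inpatient_chd", "primary_care", "diagnostics", "drugs_cvd"),
    "cvd": ("inpatient_chd", "inpatient_cvd_extra", "primary_care", "diagnostics", "drugs_cvd"),
    "total": COST_COMPONENTS,
}


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


# ---------------------------------------------------------------------------
# Baseline


def generate_baseline(config: SimulationConfig) -> pd.DataFrame:
    """Generate the patient baseline table.

    Exit columns are provisional (study end); :func:`apply_exit` finalizes them
    once events have been simulated.
    """
    config.validate()
    n = config.n_patients
    rng = _rng(config, 1)

    sex = np.where(rng.random(n) < config.female_fraction, "female", "male")
    age_mean = np.where(sex == "female", config.age_mean_female, config.age_mean_male)
    age = np.clip(rng.normal(age_mean, config.age_sd), *config.age_bounds)
    diagnosis = rng.choice(
        DIAGNOSIS_LEVELS, size=n,
        p=[config.diagnosis_mix[d] for d in DIAGNOSIS_LEVELS])

    entry = (np.datetime64(config.study_start)
             + rng.integers(0, config.entry_spread_days + 1, size=n).astype("timedelta64[D]"))

    out = pd.DataFrame({
        "patient_id": np.arange(1, n + 1),
        "entry_date": entry,
        "sex": sex,
        "age_at_entry": np.round(age, 1),
        "diagnosis": diagnosis,
    })
    for flag in COMORBIDITY_FLAGS:
        p = config.comorbidity_prevalences.get(flag, 0.0)
        out[flag] = (rng.random(n) < p).astype(int)

    for b in config.biomarker_means:
        vals = rng.normal(config.biomarker_means[b], config.biomarker_sds.get(b, 0.0), n)
        rate = config.missingness_rates.get(b, 0.0)
        if config.missingness_mechanism == "age":
            # logistic tilt in age around the overall rate
            logit = np.log(rate / (1 - rate)) if 0 < rate < 1 else -np.inf
            p_miss = 1.0 / (1.0 + np.exp(-(logit + 0.03 * (age - age.mean()))))
        else:
            p_miss = np.full(n, rate)
        miss = rng.random(n) < p_miss
        vals = np.round(vals, 2)
        out[b] = np.where(miss, np.nan, vals)

    # provisional exit at study horizon; overwritten by apply_exit
    out["followup_cycles"] = config.horizon_cycles
    out["exit_date"] = out["entry_date"] + np.timedelta64(int(CYCLE_DAYS), "D") * config.horizon_cycles
    out["exit_reason"] = "study_end"
    return out


# ---------------------------------------------------------------------------
# Events


def simulate_events(baseline: pd.DataFrame, config: SimulationConfig) -> pd.DataFrame:
    """Simulate first events, post-event deaths and censoring.

    Returns an event table with columns ``patient_id, event_type, cycle, date``;
    ``event_type`` is one of the three non-fatal events, the two death causes,
    or ``censoring`` (non-death loss to follow-up before the study horizon).
    Patients reaching the horizon without a terminal record are administratively
    censored at the horizon and carry no ``censoring`` row (their baseline
    ``exit_reason`` is ``study_end``).
    """
    config.validate()
    params = config.transition_params()
    n = len(baseline)
    rng = _rng(config, 2)

    X = design_matrix(baseline, _hazard_covariates(params))
    stable_h = _hazard_matrix(X, params, [f"stable:{e}" for e in FIRST_EVENT_TYPES])
    post_h = {
        e: _hazard_matrix(X, params, [f"post_{e}:{d}" for d in DEATH_TYPES])
        for e in EVENT_TYPES
    }

    stable_p, stable_stay = _cycle_probabilities(stable_h)
    post_p = {e: _cycle_probabilities(post_h[e]) for e in EVENT_TYPES}

    STABLE, POST, GONE = 0, 1, 2
    state = np.full(n, STABLE, dtype=np.int8)
    post_type = np.full(n, -1, dtype=np.int8)  # index into EVENT_TYPES
    post_entry = np.full(n, -1, dtype=int)     # cycle the non-fatal event occurred

    records: list[tuple[int, str, int]] = []  # (row index, event_type, cycle)
    followup = np.full(n, config.horizon_cycles, dtype=int)
    exit_reason = np.full(n, "study_end", dtype=object)

    for cycle in range(1, config.horizon_cycles + 1):
        active = state != GONE
        if not active.any():
            break
        u = rng.random(n)

        # stable patients: competing first events
        mask = active & (state == STABLE)
        if mask.any():
            cum = np.cumsum(stable_p[mask], axis=1)
            idx = np.where(mask)[0]
            drawn = u[idx, None] < cum
            has_event = drawn.any(axis=1)
            cause = np.argmax(drawn, axis=1)
            for i, c in zip(idx[has_event], cause[has_event]):
                etype = FIRST_EVENT_TYPES[c]
                records.append((i, etype, cycle))
                if etype in DEATH_TYPES:
                    state[i] = GONE
                    followup[i] = cycle
                    exit_reason[i] = "death_cvd" if etype == "cvd_death" else "death_noncvd"
                else:
                    state[i] = POST
                    post_type[i] = EVENT_TYPES.index(etype)
                    post_entry[i] = cycle

        # post-event patients (excluding those whose event happened this cycle)
        for ei, e in enumerate(EVENT_TYPES):
            mask = active & (state == POST) & (post_type == ei) & (post_entry < cycle)
            if mask.any():
                p, _ = post_p[e]
                cum = np.cumsum(p[mask], axis=1)
                idx = np.where(mask)[0]
                drawn = u[idx, None] < cum
                has_death = drawn.any(axis=1)
                cause = np.argmax(drawn, axis=1)
                for i, c in zip(idx[has_death], cause[has_death]):
                    dtype_ = DEATH_TYPES[c]
                    records.append((i, dtype_, cycle))
                    state[i] = GONE
                    followup[i] = cycle
                    exit_reason[i] = "death_cvd" if dtype_ == "cvd_death" else "death_noncvd"

        # independent censoring of everyone still under follow-up
        if config.censoring_rate > 0 and cycle < config.horizon_cycles:
            alive = state != GONE
            cens = alive & (rng.random(n) < config.censoring_rate)
            for i in np.where(cens)[0]:
                records.append((i, "censoring", cycle))
                state[i] = GONE
                followup[i] = cycle
                exit_reason[i] = "transfer_out"

    pid = baseline["patient_id"].to_numpy()
    entry = baseline["entry_date"].to_numpy()
    rows = [
        {
            "patient_id": pid[i],
            "event_type": etype,
            "cycle": cyc,
            "date": entry[i] + np.timedelta64(int(cyc * CYCLE_DAYS), "D"),
        }
        for i, etype, cyc in records
    ]
    events = pd.DataFrame(rows, columns=["patient_id", "event_type", "cycle", "date"])
    events = events.sort_values(["patient_id", "cycle"], kind="stable").reset_index(drop=True)
    return events


def apply_exit(baseline: pd.DataFrame, events: pd.DataFrame,
               horizon_cycles: int | None = None) -> pd.DataFrame:
    """Finalize baseline exit columns from an event table.

    Patients with a death record exit at the death cycle; a ``censoring``
    record marks transfer out; everyone else is administratively censored at
    the horizon (``study_end``).
    """
    out = baseline.copy()
    if horizon_cycles is None:
        horizon_cycles = int(out["followup_cycles"].max())
    terminal = events[events["event_type"].isin([*DEATH_TYPES, "censoring"])]
    terminal = terminal.drop_duplicates("patient_id", keep="last").set_index("patient_id")
    cyc = out["patient_id"].map(terminal["cycle"])
    kind = out["patient_id"].map(terminal["event_type"])
    out["followup_cycles"] = cyc.fillna(horizon_cycles).astype(int)
    out["exit_reason"] = kind.map({
        "cvd_death": "death_cvd", "noncvd_death": "death_noncvd",
        "censoring": "transfer_out"}).fillna("study_end")
    out["exit_date"] = out["entry_date"] + (
        out["followup_cycles"].to_numpy() * int(CYCLE_DAYS)).astype("timedelta64[D]")
    return out


def _hazard_covariates(params) -> list[str]:
    names: set[str] = set()
    for t in params.transitions.values():
        names |= set(t.effects)
    return sorted(names)


def _hazard_matrix(X: pd.DataFrame, params, keys: list[str]) -> np.ndarray:
    """n × len(keys) matrix of cause-specific hazards per cycle."""
    n = len(X)
    H = np.zeros((n, len(keys)))
    for j, key in enumerate(keys):
        t = params.transitions[key]
        lin = np.full(n, t.log_baseline)
        for c, b in t.effects.items():
            lin = lin + b * X[c].to_numpy()
        H[:, j] = np.exp(lin)
    return H


def _cycle_probabilities(h: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Competing-risks per-cycle probabilities and stay probability, row-wise."""
    H = h.sum(axis=1)
    stay = np.exp(-H)
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(H > 0, -np.expm1(-H) / np.where(H > 0, H, 1.0), 0.0)
    return h * scale[:, None], stay


# ---------------------------------------------------------------------------
# Costs


def implied_category_params(config: SimulationConfig, category: str) -> PanelCostParams:
    """Ground-truth panel parameters for a cost category implied by the
    component-share structure (total is scaled by the category's share of the
    core cost and of each increment)."""
    comps = CATEGORY_COMPONENTS[category]
    core_w = sum(config.core_cost_shares.get(c, 0.0) for c in comps)
    tot = config.cost_params
    events = {}
    for e, bands in tot.event_increments.items():
        w = sum(config.event_cost_shares[e].get(c, 0.0) for c in comps)
        events[e] = EventCostBands(*(w * b for b in bands.as_tuple()))
    deaths = {
        d: sum(config.event_cost_shares[d].get(c, 0.0) for c in comps) * v
        for d, v in tot.death_increments.items()
    }
    return PanelCostParams(
        category=category,
        baseline_cost=core_w * tot.baseline_cost,
        period_trend=core_w * tot.period_trend,
        covariate_effects={k: core_w * v for k, v in tot.covariate_effects.items()},
        event_increments=events,
        death_increments=deaths,
    )


def simulate_costs(
    baseline: pd.DataFrame, events: pd.DataFrame, config: SimulationConfig
) -> pd.DataFrame:
    """Simulate the 90-day period-cost panel.

    One row per patient per observed cycle (1..followup). Component costs are
    independent gamma draws with shape ``config.gamma_shape`` and means given
    by the additive panel structure split across components; utilization
    counters (hospitalization flags, stays, length of stay, consultations,
    revascularization and drug-class flags) are drawn alongside.
    """
    config.validate()
    rng = _rng(config, 3)
    tot = config.cost_params

    followup = baseline["followup_cycles"].to_numpy(dtype=int)
    n = len(baseline)
    pid = baseline["patient_id"].to_numpy()

    # long patient-cycle frame
    reps = followup
    row_pid = np.repeat(pid, reps)
    row_idx = np.repeat(np.arange(n), reps)
    cycle = np.concatenate([np.arange(1, k + 1) for k in reps]) if n else np.array([], dtype=int)

    # core mean: baseline + trend + covariate effects
    X = design_matrix(baseline, list(tot.covariate_effects))
    cov_eff = np.zeros(n)
    for c, b in tot.covariate_effects.items():
        cov_eff += b * X[c].to_numpy()
    core = tot.baseline_cost + tot.period_trend * (cycle - 1) + cov_eff[row_idx]
    if (core <= 0).any():
        bad = row_pid[core <= 0][:5]
        raise ParameterError(
            "additive cost structure implies non-positive core period cost for "
            f"patients {bad.tolist()} (configure baseline/trend/effects to keep means positive)")

    # event state per patient-cycle
    ev = events[events["event_type"].isin(EVENT_TYPES)]
    event_cycle = np.full(n, -1, dtype=int)
    event_kind = np.full(n, -1, dtype=int)
    pos = {p: i for i, p in enumerate(pid)}
    for p, etype, cyc in zip(ev["patient_id"], ev["event_type"], ev["cycle"]):
        event_cycle[pos[p]] = cyc
        event_kind[pos[p]] = EVENT_TYPES.index(etype)

    since = np.where(event_cycle[row_idx] > 0, cycle - event_cycle[row_idx] + 1, 0)
    kind = event_kind[row_idx]

    # death cycle
    death_kind = np.full(n, -1, dtype=int)
    dv = events[events["event_type"].isin(DEATH_TYPES)]
    for p, etype in zip(dv["patient_id"], dv["event_type"]):
        death_kind[pos[p]] = DEATH_TYPES.index(etype)
    is_death_cycle = (cycle == followup[row_idx]) & (death_kind[row_idx] >= 0)

    # component means
    m = len(cycle)
    comp_means = {
        c: core * config.core_cost_shares.get(c, 0.0) for c in COST_COMPONENTS
    }
    for ei, e in enumerate(EVENT_TYPES):
        bands = tot.event_increments.get(e)
        if bands is None:
            continue
        in_band = (kind == ei) & (since >= 1)
        if not in_band.any():
            continue
        inc = np.zeros(m)
        s = since[in_band]
        inc_vals = np.where(
            s <= 4,
            np.take(np.array(bands.as_tuple()[:4]), np.clip(s - 1, 0, 3)),
            bands.long_run,
        )
        inc[in_band] = inc_vals
        for c, w in config.event_cost_shares[e].items():
            comp_means[c] = comp_means[c] + w * inc
    for di, d in enumerate(DEATH_TYPES):
        mask = is_death_cycle & (death_kind[row_idx] == di)
        if not mask.any():
            continue
        inc = np.zeros(m)
        inc[mask] = tot.death_increments.get(d, 0.0)
        for c, w in config.event_cost_shares[d].items():
            comp_means[c] = comp_means[c] + w * inc

    # gamma draws
    k = config.gamma_shape
    comps = {}
    for c in COST_COMPONENTS:
        mean = comp_means[c]
        vals = np.zeros(m)
        posm = mean > 0
        vals[posm] = rng.gamma(k, mean[posm] / k)
        comps[c] = np.round(vals, 2)

    inpatient_chd = comps["inpatient_chd"]
    inpatient_cvd = inpatient_chd + comps["inpatient_cvd_extra"]
    inpatient_total = inpatient_cvd + comps["inpatient_noncvd"]
    drugs_cvd = comps["drugs_cvd"]
    drugs_total = drugs_cvd + comps["drugs_noncvd"]

    panel = pd.DataFrame({
        "patient_id": row_pid,
        "cycle": cycle,
        "inpatient_total": inpatient_total,
        "inpatient_cvd": inpatient_cvd,
        "inpatient_chd": inpatient_chd,
        "primary_care": comps["primary_care"],
        "diagnostics": comps["diagnostics"],
        "drugs_total": drugs_total,
        "drugs_cvd": drugs_cvd,
    })

    # ------------------------------------------------------------------ utilization
    util = config.utilization
    scale = util["hospitalization_cost_scale"]
    mean_ip_chd = comp_means["inpatient_chd"]
    mean_ip_cvd = mean_ip_chd + comp_means["inpatient_cvd_extra"]
    mean_ip_tot = mean_ip_cvd + comp_means["inpatient_noncvd"]
    u = rng.random(m)
    hosp_chd = u < 1 - np.exp(-mean_ip_chd / scale)
    hosp_cvd = u < 1 - np.exp(-mean_ip_cvd / scale)
    hosp_tot = u < 1 - np.exp(-mean_ip_tot / scale)

    def stays_and_los(flag):
        stays = np.where(flag, 1 + rng.poisson(util["extra_stay_rate"], m), 0)
        los = np.where(flag, stays * (1 + rng.poisson(util["los_rate"], m)), 0)
        return stays, los

    stays_chd, los_chd = stays_and_los(hosp_chd)
    extra_cvd = hosp_cvd & ~hosp_chd
    stays_cvd = stays_chd + np.where(extra_cvd, 1 + rng.poisson(util["extra_stay_rate"], m), 0)
    los_cvd = los_chd + np.where(extra_cvd, 1 + rng.poisson(util["los_rate"], m), 0)
    extra_tot = hosp_tot & ~hosp_cvd
    stays_tot = stays_cvd + np.where(extra_tot, 1 + rng.poisson(util["extra_stay_rate"], m), 0)
    los_tot = los_cvd + np.where(extra_tot, 1 + rng.poisson(util["los_rate"], m), 0)

    band1_ami = (kind == EVENT_TYPES.index("ami")) & (since == 1)
    any_band1 = since == 1
    panel["hospitalized"] = hosp_tot.astype(int)
    panel["hospitalized_cvd"] = hosp_cvd.astype(int)
    panel["hospitalized_chd"] = hosp_chd.astype(int)
    panel["stays"] = stays_tot
    panel["stays_cvd"] = stays_cvd
    panel["stays_chd"] = stays_chd
    panel["los_days"] = los_tot
    panel["los_days_cvd"] = los_cvd
    panel["los_days_chd"] = los_chd
    panel["consultations"] = rng.poisson(
        util["consultation_rate"] + util["consultation_event_extra"] * any_band1, m)
    panel["pci"] = (rng.random(m) < util["pci_rate"] + util["pci_event_extra"] * band1_ami).astype(int)
    panel["cabg"] = (rng.random(m) < util["cabg_rate"] + util["cabg_event_extra"] * band1_ami).astype(int)

    drug_cols = ["on_drugs", "on_cvd_drugs", "anticoagulant", "acei_arb",
                 "antiplatelet", "beta_blocker", "ccb"]
    per_patient = {c: (rng.random(n) < util[c]).astype(int) for c in drug_cols}
    # taking any CVD drug implies taking some drug
    per_patient["on_drugs"] = np.maximum(per_patient["on_drugs"], per_patient["on_cvd_drugs"])
    for c in drug_cols:
        panel[c] = per_patient[c][row_idx]
    return panel


# ---------------------------------------------------------------------------
# Orchestration


def simulate(config: SimulationConfig) -> dict[str, pd.DataFrame]:
    """Run the full generator: baseline, events, panel (exit columns finalized)."""
    baseline = generate_baseline(config)
    events = simulate_events(baseline, config)
    baseline = apply_exit(baseline, events)
    panel = simulate_costs(baseline, events, config)
    return {"baseline": baseline, "events": events, "period_costs": panel}


def write_tables(tables: dict[str, pd.DataFrame], out_dir) -> None:
    """Write baseline.csv, events.csv, period_costs.csv (UTF-8, headered)."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    for name in ("baseline", "events", "period_costs"):
        tables[name].to_csv(os.path.join(out_dir, f"{name}.csv"), index=False)


def read_tables(in_dir) -> dict[str, pd.DataFrame]:
    import os

    out = {}
    for name in ("baseline", "events", "period_costs"):
        path = os.path.join(in_dir, f"{name}.csv")
        df = pd.read_csv(path)
        for col in ("entry_date", "exit_date", "date"):
            if col in df.columns:
                df[col] = pd.to_datetime(df[col])
        out[name] = df
    return out
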