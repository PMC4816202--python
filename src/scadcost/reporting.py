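"""Risk-decile stratified reporting and pipeline orchestration.

Patients are ranked by modelled 5-year probability of a cardiovascular event
(AMI, either stroke, or CVD death), split into ten near-equal groups, and
each decile is represented by its average covariate pattern (continuous
covariates by their mean, binary covariates by their prevalence entered as a
fractional covariate value). Each representative profile is projected with
the Markov cost engine to produce a Table-3-style report and per-cycle cost
and survival curves.
"""
from __future__ import annotations

import hashlib
import json
import os
import tempfile

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .costing import cost_share
from .lifetime import DEFAULT_HORIZON, DEFAULT_RATE, CostProjection, project, run_trace
from .multistate import five_year_risk
from .params import (
    CATEGORIES,
    FIRST_EVENT_TYPES,
    CYCLE_YEARS,
    TransitionParams,
    design_matrix,
)


def patient_risks(baseline: pd.DataFrame, params: TransitionParams,
                  cycles: int = 20) -> pd.Series:
    """Vectorized per-patient 5-year CVD event risk."""
    covs = sorted({c for t in params.transitions.values() for c in t.effects})
    X = design_matrix(baseline, covs)
    n = len(baseline)
    h = np.zeros((n, len(FIRST_EVENT_TYPES)))
    for j, e in enumerate(FIRST_EVENT_TYPES):
        t = params.transitions[f"stable:{e}"]
        lin = np.full(n, t.log_baseline)
        for c, b in t.effects.items():
            lin = lin + b * X[c].to_numpy()
        h[:, j] = np.exp(lin)
    H = h.sum(axis=1)
    cvd = h[:, :4].sum(axis=1)  # ami, istroke, hstroke, cvd_death
    with np.errstate(invalid="ignore", divide="ignore"):
        p_cvd = np.where(H > 0, cvd / np.where(H > 0, H, 1.0) * (-np.expm1(-H)), 0.0)
        s = np.exp(-H)
        risk = np.where(H > 0, p_cvd * (1 - s ** cycles) / (1 - s), 0.0)
    return pd.Series(risk, index=baseline.index, name="five_year_risk")


def assign_deciles(baseline: pd.DataFrame, params: TransitionParams) -> pd.Series:
    """Decile labels 1..10 by ranked 5-year risk; ties broken by patient id."""
    if len(baseline) < 10:
        raise ConfigurationError(
            f"decile assignment needs at least 10 patients, got {len(baseline)}")
    risk = patient_risks(baseline, params)
    order = baseline.assign(_risk=risk.to_numpy()).sort_values(
        ["_risk", "patient_id"], kind="stable").index
    labels = pd.Series(0, index=baseline.index, dtype=int, name="decile")
    for d, chunk in enumerate(np.array_split(np.asarray(order), 10), start=1):
        labels.loc[chunk] = d
    return labels


def representative_profile(members: pd.DataFrame,
                           covariates: list[str]) -> dict[str, float]:
    """Average covariate pattern of a decile: means for continuous covariates,
    prevalences (fractional values) for binary ones."""
    if len(members) == 0:
        raise ConfigurationError("cannot build a profile from an empty decile")
    X = design_matrix(members, covariates)
    return {c: float(X[c].mean()) for c in covariates}


def build_decile_profiles(
    baseline: pd.DataFrame,
    params: TransitionParams,
    covariates: list[str] | None = None,
) -> pd.DataFrame:
    """Decile table: representative profiles plus mean age and risk."""
    if covariates is None:
        covariates = sorted({c for t in params.transitions.values() for c in t.effects})
    deciles = assign_deciles(baseline, params)
    rows = []
    for d in range(1, 11):
        members = baseline[deciles == d]
        prof = representative_profile(members, covariates)
        rows.append({
            "decile": d,
            "n": len(members),
            "average_age": float(members["age_at_entry"].mean()),
            "five_year_risk": five_year_risk(params, prof),
            **{f"profile_{k}": v for k, v in prof.items()},
        })
    return pd.DataFrame(rows)


def profile_from_decile_row(row: pd.Series) -> dict[str, float]:
    return {k[len("profile_"):]: float(v) for k, v in row.items()
            if str(k).startswith("profile_")}


def project_deciles(
    profiles: pd.DataFrame,
    params: TransitionParams,
    cost_params,
    horizon_cycles: int = DEFAULT_HORIZON,
    annual_rate: float = DEFAULT_RATE,
    discount_timing: str = "mid",
) -> dict[int, CostProjection]:
    out = {}
    for _, row in profiles.iterrows():
        prof = profile_from_decile_row(row)
        out[int(row["decile"])] = project(
            params, cost_params, prof, horizon_cycles=horizon_cycles,
            annual_rate=annual_rate, discount_timing=discount_timing)
    return out


def build_table3(profiles: pd.DataFrame,
                 projections: dict[int, CostProjection]) -> pd.DataFrame:
    """Table-3-style report: one column block per decile.

    Rows: 5-year risk (%), average age, life expectancy (years), 5-year and
    lifetime total/CVD/CHD costs (discounted and undiscounted, £ rounded to
    the nearest integer) plus derived CHD/total and CVD/total shares (1
    decimal). £ risks are rounded to 2 decimals as printed.
    """
    missing = [int(d) for d in profiles["decile"] if int(d) not in projections]
    if missing:
        raise ConfigurationError(f"missing projections for deciles {missing}")
    rows = []
    for _, prow in profiles.sort_values("decile").iterrows():
        d = int(prow["decile"])
        pj = projections[d]
        row = {
            "decile": d,
            "five_year_risk_pct": round(100 * pj.five_year_risk, 2),
            "average_age": round(float(prow["average_age"]), 0),
            "life_expectancy_years": round(pj.life_expectancy, 2),
        }
        for horizon in ("five_year", "lifetime"):
            for cat in CATEGORIES:
                for disc, tag in ((False, ""), (True, "_discounted")):
                    row[f"{horizon}_{cat}{tag}"] = round(pj.cell(horizon, cat, disc))
            tot = pj.cell(horizon, "total", False)
            row[f"{horizon}_chd_share_pct"] = cost_share(pj.cell(horizon, "chd", False), tot)
            row[f"{horizon}_cvd_share_pct"] = cost_share(pj.cell(horizon, "cvd", False), tot)
        rows.append(row)
    return pd.DataFrame(rows)


def build_cost_curves(profiles: pd.DataFrame, params: TransitionParams,
                      cost_params, horizon_cycles: int = 100) -> pd.DataFrame:
    """Per-cycle cumulative expected costs and survival per decile (the data
    behind cost-over-time figures)."""
    frames = []
    for _, row in profiles.sort_values("decile").iterrows():
        prof = profile_from_decile_row(row)
        trace = run_trace(params, cost_params, prof, horizon_cycles)
        df = pd.DataFrame({
            "decile": int(row["decile"]),
            "cycle": np.arange(1, horizon_cycles + 1),
            "years": np.arange(1, horizon_cycles + 1) * CYCLE_YEARS,
            "survival": trace.survival,
        })
        for cat in CATEGORIES:
            df[f"cumulative_{cat}"] = np.cumsum(trace.expected_costs[cat])
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Atomic exports


def _atomic_write(df_or_text, path):
    d = os.path.dirname(os.path.abspath(path))
    os.makedirs(d, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=d, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            if isinstance(df_or_text, pd.DataFrame):
                df_or_text.to_csv(fh, index=False, lineterminator="\n")
            else:
                fh.write(df_or_text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def export_outputs(results: dict, out_dir) -> list[str]:
    """Write the report files atomically (temp file + rename).

    ``results`` may contain: table1, table2, forest_plot, table3, cost_curves
    (DataFrames) and run_metadata (dict). Returns the paths written.
    """
    written = []
    for name in ("table1", "table2", "forest_plot", "table3", "cost_curves"):
        if name in results:
            path = os.path.join(out_dir, f"{name}.csv")
            _atomic_write(results[name], path)
            written.append(path)
    if "run_metadata" in results:
        path = os.path.join(out_dir, "run_metadata.json")
        _atomic_write(json.dumps(results["run_metadata"], indent=2, sort_keys=True) + "\n", path)
        written.append(path)
    return written


def config_hash(config) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Full pipeline


def run_all(config, out_dir=None, seed: int | None = None,
            horizon_cycles: int = DEFAULT_HORIZON,
            annual_rate: float = DEFAULT_RATE,
            discount_timing: str = "mid",
            m_imputations: int = 5) -> dict:
    """Simulate, build windows, summarize, fit all three models, project
    deciles and (optionally) export every report table."""
    from . import cohort, costing
    from .multistate import MultistateModel
    from .panel import fit_panel_triplet
    from .regression import GammaCostModel
    from .simulate import simulate as run_simulation, write_tables

    if seed is not None:
        config = type(config).from_dict({**config.to_dict(), "seed": seed})
    tables = run_simulation(config)
    baseline, events, panel = tables["baseline"], tables["events"], tables["period_costs"]
    windows = cohort.build_analysis_windows(baseline, events)

    table1 = costing.summarize_utilization(panel, windows, "first_scad_year")
    table1_post = costing.summarize_utilization(panel, windows, "first_post_event_year")
    cost_first = costing.summarize_costs(panel, windows, "first_scad_year")
    cost_post = costing.summarize_costs(panel, windows, "first_post_event_year")

    glm = GammaCostModel.from_tables(baseline, panel, windows).fit(
        m=m_imputations, seed=config.seed)
    forest = glm.natural_effects()

    cost_params = fit_panel_triplet(panel, events, baseline)
    ms = MultistateModel(baseline, events).fit()

    profiles = build_decile_profiles(baseline, ms.transition_params)
    projections = project_deciles(profiles, ms.transition_params, cost_params,
                                  horizon_cycles=horizon_cycles,
                                  annual_rate=annual_rate,
                                  discount_timing=discount_timing)
    table3 = build_table3(profiles, projections)
    curves = build_cost_curves(profiles, ms.transition_params, cost_params)

    table2 = pd.concat([
        cost_first.stats.assign(window="first_scad_year").reset_index(names="component"),
        cost_post.stats.assign(window="first_post_event_year").reset_index(names="component"),
    ], ignore_index=True) if not (cost_first.empty and cost_post.empty) else pd.DataFrame()

    results = {
        "tables": tables,
        "windows": windows,
        "table1": pd.concat([
            table1.assign(window="first_scad_year"),
            table1_post.assign(window="first_post_event_year"),
        ], ignore_index=True),
        "table2": table2,
        "cost_summaries": {"first_scad_year": cost_first, "first_post_event_year": cost_post},
        "glm_results": glm,
        "forest_plot": forest,
        "panel_params": cost_params,
        "multistate_results": ms,
        "decile_profiles": profiles,
        "projections": projections,
        "table3": table3,
        "cost_curves": curves,
        "run_metadata": {
            "seed": config.seed,
            "n_patients": config.n_patients,
            "config_hash": config_hash(config),
            "horizon_cycles": horizon_cycles,
            "annual_rate": annual_rate,
            "discount_timing": discount_timing,
            "m_imputations": m_imputations,
        },
    }
    if out_dir is not None:
        write_tables(tables, out_dir)
        cohort.write_windows(windows, os.path.join(out_dir, "windows.csv"))
        export_outputs(results, out_dir)
        for cat, cp in cost_params.items():
            cp.to_json(os.path.join(out_dir, f"panel_params_{cat}.json"))
        ms.transition_params.to_json(os.path.join(out_dir, "transitions.json"))
    return results
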