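"""Utilization and cost summaries over analysis windows.

Implements the nested cost-category composition — CHD hospitalizations are a
subset of CVD hospitalizations; both categories additionally include all
primary care, diagnostics and CVD drug costs — and Table-style summaries of
per-patient annual costs and utilization over complete windows.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DataIntegrityError

COST_COLUMNS = (
    "inpatient_total", "inpatient_cvd", "inpatient_chd",
    "primary_care", "diagnostics", "drugs_total", "drugs_cvd",
)


def compose_cost_categories(row):
    """Total/CVD/CHD cost composition for a period-cost row (or frame).

    total = inpatient_total + primary_care + diagnostics + drugs_total;
    cvd   = inpatient_cvd  + primary_care + diagnostics + drugs_cvd;
    chd   = inpatient_chd  + primary_care + diagnostics + drugs_cvd.
    """
    for c in COST_COLUMNS:
        v = row[c]
        neg = (v < 0).any() if hasattr(v, "any") else v < 0
        if neg:
            raise DataIntegrityError(f"negative cost component {c!r}")
    common = row["primary_care"] + row["diagnostics"]
    total = row["inpatient_total"] + common + row["drugs_total"]
    cvd = row["inpatient_cvd"] + common + row["drugs_cvd"]
    chd = row["inpatient_chd"] + common + row["drugs_cvd"]
    return total, cvd, chd


def cost_share(part_mean: float, total_mean: float, decimals: int = 1) -> float:
    """Share of total cost, as a percentage of means, rounded for reporting."""
    if total_mean == 0:
        return 0.0
    return round(100.0 * part_mean / total_mean, decimals)


@dataclass
class CostSummary:
    """Per-window-kind cost summary: per-component and per-category statistics."""

    window_kind: str
    n: int
    stats: pd.DataFrame = field(default_factory=pd.DataFrame)  # mean/sd/median/iqr per column
    shares: dict[str, float] = field(default_factory=dict)

    @property
    def empty(self) -> bool:
        return self.n == 0

    def mean(self, column: str) -> float:
        return float(self.stats.loc[column, "mean"])


def _window_totals(panel: pd.DataFrame, windows: pd.DataFrame, window_kind: str) -> pd.DataFrame:
    """Per-patient sums of each cost column over complete windows of a kind."""
    w = windows[(windows["window_kind"] == window_kind) & windows["complete"]]
    if w.empty:
        return pd.DataFrame(columns=["patient_id", *COST_COLUMNS, "total_cost", "cvd_cost", "chd_cost"])
    merged = panel.merge(w[["patient_id", "start_cycle", "end_cycle"]], on="patient_id")
    merged = merged[(merged["cycle"] >= merged["start_cycle"]) & (merged["cycle"] <= merged["end_cycle"])]
    sums = merged.groupby("patient_id", sort=True)[list(COST_COLUMNS)].sum()
    # patients whose window ends in death may have fewer than four rows; missing
    # cycles accrue zero (death stops accrual), so plain sums are correct, but a
    # patient with no rows at all (death in the entry cycle before any panel row)
    # would drop out; reindex over window patients to keep them at zero.
    sums = sums.reindex(w["patient_id"].to_numpy(), fill_value=0.0)
    total, cvd, chd = compose_cost_categories(sums)
    sums["total_cost"], sums["cvd_cost"], sums["chd_cost"] = total, cvd, chd
    return sums.reset_index()


def summarize_costs(panel: pd.DataFrame, windows: pd.DataFrame, window_kind: str) -> CostSummary:
    """Table-2-style summary of annual costs over complete windows.

    Means and SDs (n−1 denominator), medians and IQRs per component and per
    composed category; shares are ratios of means (×100).
    """
    totals = _window_totals(panel, windows, window_kind)
    if totals.empty:
        return CostSummary(window_kind=window_kind, n=0)
    cols = [*COST_COLUMNS, "total_cost", "cvd_cost", "chd_cost"]
    stats = pd.DataFrame({
        "mean": totals[cols].mean(),
        "sd": totals[cols].std(ddof=1),
        "median": totals[cols].median(),
        "q1": totals[cols].quantile(0.25),
        "q3": totals[cols].quantile(0.75),
    })
    tm = stats.loc["total_cost", "mean"]
    shares = {
        "chd": cost_share(stats.loc["chd_cost", "mean"], tm),
        "cvd": cost_share(stats.loc["cvd_cost", "mean"], tm),
        "hospitalization": cost_share(stats.loc["inpatient_total", "mean"], tm),
        "primary_care": cost_share(stats.loc["primary_care", "mean"], tm),
        "diagnostics": cost_share(stats.loc["diagnostics", "mean"], tm),
        "drugs": cost_share(stats.loc["drugs_total", "mean"], tm),
    }
    return CostSummary(window_kind=window_kind, n=len(totals), stats=stats, shares=shares)


UTILIZATION_FLAGS = ("hospitalized", "hospitalized_cvd", "hospitalized_chd")
DRUG_FLAGS = ("on_drugs", "on_cvd_drugs", "anticoagulant", "acei_arb",
              "antiplatelet", "beta_blocker", "ccb")


def summarize_utilization(panel: pd.DataFrame, windows: pd.DataFrame, window_kind: str) -> pd.DataFrame:
    """Table-1-style utilization summary over complete windows.

    Percentages of patients with ≥1 hospitalization (any/CVD/CHD), conditional
    mean stays and length of stay among the hospitalized, mean primary-care
    consultations, revascularization percentages and drug-class percentages.
    Returns a two-column frame (statistic, value).
    """
    w = windows[(windows["window_kind"] == window_kind) & windows["complete"]]
    rows: list[tuple[str, float]] = []
    if w.empty:
        return pd.DataFrame(rows, columns=["statistic", "value"])
    merged = panel.merge(w[["patient_id", "start_cycle", "end_cycle"]], on="patient_id")
    merged = merged[(merged["cycle"] >= merged["start_cycle"]) & (merged["cycle"] <= merged["end_cycle"])]
    agg = {
        **{c: "max" for c in (*UTILIZATION_FLAGS, *DRUG_FLAGS, "pci", "cabg")},
        **{c: "sum" for c in ("stays", "stays_cvd", "stays_chd",
                              "los_days", "los_days_cvd", "los_days_chd",
                              "consultations")},
    }
    per_patient = merged.groupby("patient_id", sort=True).agg(agg)
    per_patient = per_patient.reindex(w["patient_id"].to_numpy(), fill_value=0)
    n = len(per_patient)
    rows.append(("n", float(n)))
    for flag, label in [("hospitalized", "hospitalized_pct"),
                        ("hospitalized_cvd", "hospitalized_cvd_pct"),
                        ("hospitalized_chd", "hospitalized_chd_pct")]:
        rows.append((label, 100.0 * per_patient[flag].mean()))
    for flag, stays, los, tag in [
        ("hospitalized", "stays", "los_days", ""),
        ("hospitalized_cvd", "stays_cvd", "los_days_cvd", "_cvd"),
        ("hospitalized_chd", "stays_chd", "los_days_chd", "_chd"),
    ]:
        sub = per_patient[per_patient[flag] > 0]
        rows.append((f"mean_stays{tag}_if_hospitalized",
                     float(sub[stays].mean()) if len(sub) else 0.0))
        rows.append((f"mean_los{tag}_if_hospitalized",
                     float((sub[los] / sub[stays].clip(lower=1)).mean()) if len(sub) else 0.0))
    rows.append(("mean_consultations", float(per_patient["consultations"].mean())))
    rows.append(("any_revascularization_pct",
                 100.0 * float(((per_patient["pci"] + per_patient["cabg"]) > 0).mean())))
    rows.append(("pci_pct", 100.0 * float(per_patient["pci"].mean())))
    rows.append(("cabg_pct", 100.0 * float(per_patient["cabg"].mean())))
    for flag in DRUG_FLAGS:
        rows.append((f"{flag}_pct", 100.0 * float(per_patient[flag].mean())))
    return pd.DataFrame(rows, columns=["statistic", "value"])


def first_year_totals(panel: pd.DataFrame, windows: pd.DataFrame) -> pd.DataFrame:
    """Per-patient first-year total costs over complete first-year windows
    (the response of the first-year cost regression)."""
    totals = _window_totals(panel, windows, "first_scad_year")
    return totals[["patient_id", "total_cost", "cvd_cost", "chd_cost"]]
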