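"""90-day panel cost model.

Estimates the additive period-cost structure — baseline level, linear
per-period trend, time-invariant covariate effects, event increments in four
90-day bands after each non-fatal event followed by a constant long-run
increment, and death-period increments — by pooled least squares on the £
scale with patient-clustered standard errors. The additive-on-£ estimator is
a deliberate modelling choice: the published structure (a £ baseline plus a £
per-period trend plus £ event increments) is additive on the natural scale.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .exceptions import ConfigurationError, DataIntegrityError, SingularDesignError
from .params import (
    DEATH_TYPES,
    EVENT_TYPES,
    PANEL_COVARIATES,
    EventCostBands,
    PanelCostParams,
    design_matrix,
    linear_effect,
)

BAND_LABELS = ("b1", "b2", "b3", "b4", "long")


def _band_column(event: str, band: str) -> str:
    return f"{event}_{band}"


def build_design_panel(
    panel: pd.DataFrame,
    events: pd.DataFrame,
    baseline: pd.DataFrame,
    covariates: list[str] = PANEL_COVARIATES,
) -> pd.DataFrame:
    """One row per patient-cycle with trend, covariates and event indicators.

    Band indicators are mutually exclusive per event: ``<event>_b1`` marks the
    cycle of the event itself, ``_b2``..``_b4`` the three following cycles,
    ``_long`` every cycle from the fifth onwards. Death indicators mark the
    cycle of death. Only the first non-fatal event carries increments.
    """
    if panel.duplicated(["patient_id", "cycle"]).any():
        dups = panel[panel.duplicated(["patient_id", "cycle"])]["patient_id"].unique()
        raise DataIntegrityError(f"duplicate patient-cycle rows for patients {dups[:10].tolist()}")

    design = panel[["patient_id", "cycle"]].copy()
    design["elapsed"] = design["cycle"] - 1

    X = design_matrix(baseline, list(covariates))
    X = X.assign(patient_id=baseline["patient_id"].to_numpy())
    design = design.merge(X, on="patient_id", how="left")
    if design[list(covariates)].isna().any().any():
        missing = design.loc[design[list(covariates)].isna().any(axis=1), "patient_id"].unique()
        raise DataIntegrityError(f"panel rows for patients missing from baseline: {missing[:10].tolist()}")

    # first non-fatal event per patient
    ev = events[events["event_type"].isin(EVENT_TYPES)]
    first = (ev.sort_values(["patient_id", "cycle"], kind="stable")
               .groupby("patient_id", sort=False).first())
    emap = design["patient_id"].map(first["event_type"]) if len(first) else pd.Series(
        np.nan, index=design.index)
    ecyc = design["patient_id"].map(first["cycle"]) if len(first) else pd.Series(
        np.nan, index=design.index)
    since = np.where(ecyc.notna(), design["cycle"] - ecyc + 1, 0)

    for e in EVENT_TYPES:
        is_e = (emap == e).to_numpy()
        for b, label in enumerate(BAND_LABELS[:4], start=1):
            design[_band_column(e, label)] = (is_e & (since == b)).astype(float)
        design[_band_column(e, "long")] = (is_e & (since >= 5)).astype(float)

    dv = events[events["event_type"].isin(DEATH_TYPES)]
    dmap = design["patient_id"].map(dv.set_index("patient_id")["event_type"]) if len(dv) else \
        pd.Series(np.nan, index=design.index)
    dcyc = design["patient_id"].map(dv.set_index("patient_id")["cycle"]) if len(dv) else \
        pd.Series(np.nan, index=design.index)
    for d in DEATH_TYPES:
        design[d] = ((dmap == d) & (dcyc == design["cycle"])).astype(float)
    return design


def design_columns(covariates=PANEL_COVARIATES) -> list[str]:
    cols = ["elapsed", *covariates]
    for e in EVENT_TYPES:
        cols += [_band_column(e, b) for b in BAND_LABELS]
    cols += list(DEATH_TYPES)
    return cols


class PanelCostModel:
    """Pooled least-squares panel model for one cost category.

    Parameters
    ----------
    design : output of :func:`build_design_panel`.
    response : per-cycle cost series aligned with ``design`` (£).
    category : reported category name ('total', 'cvd' or 'chd').
    """

    def __init__(self, design: pd.DataFrame, response: pd.Series | np.ndarray,
                 category: str = "total", covariates: list[str] = PANEL_COVARIATES):
        self.design = design.reset_index(drop=True)
        self.response = np.asarray(response, dtype=float)
        if len(self.response) != len(self.design):
            raise ConfigurationError("response length does not match design")
        self.category = category
        self.covariates = list(covariates)

    @classmethod
    def from_tables(cls, panel, events, baseline, category="total",
                    covariates=PANEL_COVARIATES):
        from .costing import compose_cost_categories

        design = build_design_panel(panel, events, baseline, covariates)
        total, cvd, chd = compose_cost_categories(panel)
        response = {"total": total, "cvd": cvd, "chd": chd}[category]
        return cls(design, response, category=category, covariates=covariates)

    def fit(self, cov_type: str = "cluster") -> "PanelCostResults":
        cols = design_columns(self.covariates)
        X = self.design[cols]
        # drop indicator columns with no support (e.g. no haemorrhagic strokes
        # in a small cohort); their parameters are reported as 0 with a warning
        zero_cols = [c for c in cols if not np.any(X[c].to_numpy())
                     and c not in ("elapsed", *self.covariates)]
        if zero_cols:
            warnings.warn(
                f"panel design has no observations for {zero_cols}; "
                "their increments are fixed at 0", stacklevel=2)
            X = X.drop(columns=zero_cols)
        arr = X.to_numpy()
        if np.linalg.matrix_rank(arr) < arr.shape[1]:
            from .regression import _aliased_columns

            raise SingularDesignError(
                f"collinear panel design; aliased columns: {_aliased_columns(X)}")
        Xc = sm.add_constant(X, has_constant="add")
        model = sm.OLS(self.response, Xc)
        if cov_type == "cluster":
            res = model.fit(cov_type="cluster",
                            cov_kwds={"groups": self.design["patient_id"]})
        else:
            res = model.fit()
        return PanelCostResults(self, res, zero_cols)


class PanelCostResults:
    """Fitted panel cost structure with cluster-robust uncertainty."""

    def __init__(self, model: PanelCostModel, res, zero_cols):
        self.model = model
        self._res = res
        self.dropped = list(zero_cols)

    @property
    def params(self) -> pd.Series:
        p = self._res.params.copy()
        for c in self.dropped:
            p[c] = 0.0
        return p

    @property
    def bse(self) -> pd.Series:
        b = self._res.bse.copy()
        for c in self.dropped:
            b[c] = np.nan
        return b

    @property
    def cost_params(self) -> PanelCostParams:
        p = self.params
        events = {}
        for e in EVENT_TYPES:
            events[e] = EventCostBands(*(float(p[_band_column(e, b)]) for b in BAND_LABELS))
        return PanelCostParams(
            category=self.model.category,
            baseline_cost=float(p["const"]),
            period_trend=float(p["elapsed"]),
            covariate_effects={c: float(p[c]) for c in self.model.covariates},
            event_increments=events,
            death_increments={d: float(p[d]) for d in DEATH_TYPES},
        )

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({"coef": self.params, "se": self.bse})

    def __repr__(self):
        return (f"<PanelCostResults[{self.model.category}]: "
                f"{len(self.model.design)} patient-cycles, "
                f"{self.model.design['patient_id'].nunique()} patients>")


def fit_panel(panel, events, baseline, category="total",
              covariates=PANEL_COVARIATES) -> PanelCostParams:
    """Convenience wrapper: fit one category and return its PanelCostParams."""
    return PanelCostModel.from_tables(
        panel, events, baseline, category=category, covariates=covariates
    ).fit().cost_params


def fit_panel_triplet(panel, events, baseline,
                      covariates=PANEL_COVARIATES) -> dict[str, PanelCostParams]:
    """Fit total, CVD and CHD categories on the same design."""
    from .costing import compose_cost_categories

    design = build_design_panel(panel, events, baseline, covariates)
    total, cvd, chd = compose_cost_categories(panel)
    out = {}
    for cat, y in [("total", total), ("cvd", cvd), ("chd", chd)]:
        out[cat] = PanelCostModel(design, y, category=cat,
                                  covariates=covariates).fit().cost_params
    return out


def predict_period_cost(
    params: PanelCostParams,
    profile,
    cycle: int,
    event: str | None = None,
    cycles_since_event: int | None = None,
    death: str | None = None,
) -> float:
    """Mean period cost for a covariate profile, cycle and event state.

    ``event``/``cycles_since_event`` select the band increment of a prior
    non-fatal event (1 = the event cycle); ``death`` adds the death-period
    increment. Negative predictions are floored at 0 with a warning.
    """
    cost = (params.baseline_cost
            + params.period_trend * (cycle - 1)
            + linear_effect(params.covariate_effects, profile))
    if event is not None:
        if event not in params.event_increments:
            raise ConfigurationError(f"unknown event type {event!r}")
        if cycles_since_event is None:
            raise ConfigurationError("cycles_since_event required with event")
        cost += params.event_increments[event].band(cycles_since_event)
    if death is not None:
        if death not in params.death_increments:
            raise ConfigurationError(f"unknown death type {death!r}")
        cost += params.death_increments[death]
    if cost < 0:
        warnings.warn(f"negative predicted period cost ({cost:.2f}) floored at 0",
                      stacklevel=2)
        return 0.0
    return float(cost)
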