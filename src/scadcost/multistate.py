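"""Multistate transition model on the 90-day cycle grid.

States: Stable SCAD; post-AMI, post-ischaemic-stroke and post-haemorrhagic-
stroke (each realized downstream as four one-cycle tunnel states plus a
long-run state, to carry the time-since-event cost bands); and two absorbing
death states (CVD, non-CVD).

Estimation is discrete-cycle cause-specific maximum likelihood: within each
cycle a patient in state s faces cause-specific exponential rates
h_c = exp(β0_c + x'β_c); the per-cycle probability of transition c is
p_c = h_c/H · (1 − exp(−H)) with H = Σ h_c, and exp(−H) of staying. Because
covariates are time-invariant and the hazards time-homogeneous, the
likelihood collapses to per-patient sufficient statistics (cycles at risk,
observed transition), which keeps the fit fast at large n. Standard errors
come from the inverse observed information (finite differences of the
analytic score).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize

from .exceptions import ConfigurationError, ConvergenceError, DataIntegrityError
from .params import (
    CYCLE_YEARS,
    DEATH_TYPES,
    EVENT_TYPES,
    FIRST_EVENT_TYPES,
    HAZARD_COVARIATES,
    TransitionHazard,
    TransitionParams,
    design_matrix,
)

#: floor for log baseline hazards of transitions with an empty risk set
LOG_HAZARD_FLOOR = np.log(1e-8)


# ---------------------------------------------------------------------------
# Core likelihood for one state with competing causes


class _CompetingRiskMLE:
    """MLE for one state's competing cause-specific hazards.

    Data: per patient, exposure (cycles at risk in the state) and the observed
    transition cause (or none). Parameters per cause: intercept + covariate
    coefficients, laid out cause-major.
    """

    def __init__(self, X: np.ndarray, exposure: np.ndarray, cause: np.ndarray,
                 n_causes: int, cov_names: list[str]):
        self.X = np.column_stack([np.ones(len(X)), X])  # n x (1+k)
        self.exposure = exposure.astype(float)
        self.cause = cause  # -1 = censored in state
        self.n_causes = n_causes
        self.cov_names = cov_names
        self.k = self.X.shape[1]
        # objective is the mean loglikelihood per patient, so the fit is exactly
        # invariant under duplicating the cohort
        self.norm = float(len(X)) or 1.0
        # causes with zero observed events: intercept pinned at floor, betas fixed 0
        self.event_counts = np.array([(cause == c).sum() for c in range(n_causes)])

    # parameter vector: for each cause, (intercept, betas...) — full layout;
    # optimization works on the free subset
    def _free_mask(self) -> np.ndarray:
        mask = np.ones(self.n_causes * self.k, dtype=bool)
        for c in range(self.n_causes):
            if self.event_counts[c] == 0:
                mask[c * self.k + 1:(c + 1) * self.k] = False  # betas fixed at 0
        return mask

    def _hazards(self, theta: np.ndarray) -> np.ndarray:
        """n × n_causes matrix of per-cycle rates."""
        B = theta.reshape(self.n_causes, self.k)
        return np.exp(np.clip(self.X @ B.T, -700, 50))

    def neg_loglike(self, theta: np.ndarray) -> float:
        h = self._hazards(theta)
        H = h.sum(axis=1)
        ev = self.cause >= 0
        # survival cycles: exposure - 1 for event patients (the event cycle is
        # accounted by the event term), exposure for censored-in-state patients
        surv_cycles = self.exposure - ev
        ll = -(surv_cycles * H).sum()
        if ev.any():
            He = H[ev]
            hc = h[ev, self.cause[ev]]
            with np.errstate(divide="ignore"):
                ll += (np.log(hc) - np.log(He) + np.log(-np.expm1(-He))).sum()
        return -ll / self.norm

    def score(self, theta: np.ndarray) -> np.ndarray:
        h = self._hazards(theta)
        H = h.sum(axis=1)
        ev = self.cause >= 0
        surv_cycles = self.exposure - ev
        # d ll / d eta_c = h_c * [ -surv_cycles + ev*(-1/H + e^{-H}/(1-e^{-H})) ] + 1{cause=c}
        common = -surv_cycles.astype(float)
        He = np.where(ev, H, 1.0)
        frac = np.where(ev, -1.0 / He + np.exp(-He) / (-np.expm1(-He)), 0.0)
        common = common + frac
        g = np.empty(self.n_causes * self.k)
        for c in range(self.n_causes):
            w = h[:, c] * common
            w = w + (self.cause == c)
            g[c * self.k:(c + 1) * self.k] = w @ self.X
        return -g / self.norm  # negative mean-loglik gradient

    def fit(self) -> tuple[np.ndarray, np.ndarray]:
        """Returns (theta, standard errors), both in the full layout."""
        theta0 = np.zeros(self.n_causes * self.k)
        total_exposure = self.exposure.sum()
        for c in range(self.n_causes):
            rate = max(self.event_counts[c], 0.5) / max(total_exposure, 1.0)
            theta0[c * self.k] = np.log(rate)
        mask = self._free_mask()
        fixed = theta0.copy()
        for c in range(self.n_causes):
            if self.event_counts[c] == 0:
                fixed[c * self.k] = LOG_HAZARD_FLOOR

        def unpack(free):
            th = fixed.copy()
            th[mask] = free
            return th

        bounds = []
        for i in np.where(mask)[0]:
            if i % self.k == 0:
                bounds.append((LOG_HAZARD_FLOOR, 10.0))
            else:
                bounds.append((-20.0, 20.0))

        res = scipy.optimize.minimize(
            lambda f: self.neg_loglike(unpack(f)),
            theta0[mask],
            jac=lambda f: self.score(unpack(f))[mask],
            method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-9},
        )
        if not res.success and "ABNORMAL" in str(res.message).upper():
            raise ConvergenceError(f"competing-risk MLE failed: {res.message} "
                                   f"after {res.nit} iterations")
        theta = unpack(res.x)
        se = np.full_like(theta, np.nan)
        se[mask] = self._free_se(theta, mask)
        return theta, se

    def _free_se(self, theta, mask):
        free = theta[mask]
        eps = 1e-5 * np.maximum(1.0, np.abs(free))
        p = len(free)
        Hess = np.zeros((p, p))

        def grad_at(f):
            th = theta.copy()
            th[mask] = f
            return self.score(th)[mask]

        for j in range(p):
            step = np.zeros(p)
            step[j] = eps[j]
            Hess[:, j] = (grad_at(free + step) - grad_at(free - step)) / (2 * eps[j])
        Hess = (Hess + Hess.T) / 2 * self.norm  # observed information (un-normalized)
        try:
            cov = np.linalg.inv(Hess)
            d = np.diag(cov).copy()
            d[d < 0] = np.nan
            return np.sqrt(d)
        except np.linalg.LinAlgError:
            return np.full(p, np.nan)


# ---------------------------------------------------------------------------
# Sufficient statistics from the event table


def _state_histories(baseline: pd.DataFrame, events: pd.DataFrame):
    """Per-patient (stable exposure, stable cause), and per post-event type
    (exposure, cause) arrays aligned with the baseline row order."""
    n = len(baseline)
    followup = baseline["followup_cycles"].to_numpy(dtype=int)
    pos = {p: i for i, p in enumerate(baseline["patient_id"].to_numpy())}

    unknown = sorted(set(events["patient_id"]) - set(pos))
    if unknown:
        raise DataIntegrityError(f"events reference unknown patient ids: {unknown[:10]}")

    first_cycle = np.zeros(n, dtype=int)
    stable_cause = np.full(n, -1, dtype=int)     # index into FIRST_EVENT_TYPES
    post_cause = np.full(n, -1, dtype=int)       # index into DEATH_TYPES
    post_death_cycle = np.zeros(n, dtype=int)

    real = events[events["event_type"] != "censoring"]
    by_patient = real.sort_values(["patient_id", "cycle"], kind="stable").groupby(
        "patient_id", sort=False)
    for pid, grp in by_patient:
        i = pos[pid]
        e0 = grp.iloc[0]
        first_cycle[i] = int(e0["cycle"])
        stable_cause[i] = FIRST_EVENT_TYPES.index(e0["event_type"])
        if len(grp) > 1:
            e1 = grp.iloc[1]
            if e1["event_type"] not in DEATH_TYPES:
                raise DataIntegrityError(
                    f"patient {pid} has a second non-death event {e1['event_type']!r}")
            post_cause[i] = DEATH_TYPES.index(e1["event_type"])
            post_death_cycle[i] = int(e1["cycle"])

    stable_exposure = np.where(stable_cause >= 0, first_cycle, followup)
    post_exposure = np.where(
        stable_cause >= 0,
        np.where(post_cause >= 0, post_death_cycle, followup) - first_cycle,
        0,
    )
    return stable_exposure, stable_cause, post_exposure, post_cause, first_cycle


# ---------------------------------------------------------------------------
# Model / Results


class MultistateModel:
    """Discrete-cycle cause-specific hazard model for the six-state structure.

    ``share_post_event_hazards=True`` (default) pools post-event person-cycles
    across the three non-fatal event types when estimating post-event
    mortality, mirroring the simulation's shared post-event process; set False
    to estimate the six post-event transitions separately (needs many strokes).
    """

    def __init__(self, baseline: pd.DataFrame, events: pd.DataFrame,
                 covariates: list[str] = HAZARD_COVARIATES,
                 share_post_event_hazards: bool = True):
        self.baseline = baseline.reset_index(drop=True)
        self.events = events
        self.covariates = list(covariates)
        self.share_post = share_post_event_hazards

    def fit(self) -> "MultistateResults":
        X = design_matrix(self.baseline, self.covariates).to_numpy(dtype=float)
        (stable_exp, stable_cause, post_exp, post_cause, _) = _state_histories(
            self.baseline, self.events)
        if (stable_cause >= 0).sum() == 0:
            raise ConvergenceError(
                "no events observed at all; use a larger (synthetic) cohort")

        stable = _CompetingRiskMLE(X, stable_exp, stable_cause,
                                   len(FIRST_EVENT_TYPES), self.covariates)
        for c, e in enumerate(FIRST_EVENT_TYPES):
            if stable.event_counts[c] == 0:
                warnings.warn(f"no observed stable->{e} transitions; hazard floored "
                              "and covariate effects dropped", stacklevel=2)
        th_s, se_s = stable.fit()

        transitions: dict[str, TransitionHazard] = {}
        bse: dict[str, dict[str, float]] = {}
        k = stable.k
        for c, e in enumerate(FIRST_EVENT_TYPES):
            seg = th_s[c * k:(c + 1) * k]
            seg_se = se_s[c * k:(c + 1) * k]
            transitions[f"stable:{e}"] = TransitionHazard(
                log_baseline=float(seg[0]),
                effects={nm: float(v) for nm, v in zip(self.covariates, seg[1:])})
            bse[f"stable:{e}"] = {"log_baseline": float(seg_se[0]),
                                  **{nm: float(v) for nm, v in zip(self.covariates, seg_se[1:])}}

        in_post = post_exp > 0
        if self.share_post:
            groups = [("post", in_post, post_exp, post_cause)]
        else:
            groups = []
            for ei, e in enumerate(EVENT_TYPES):
                mask = in_post & (stable_cause == ei)
                groups.append((f"post_{e}", mask, post_exp, post_cause))

        post_fits = {}
        for name, mask, exp_, cause_ in groups:
            if mask.sum() == 0:
                warnings.warn(f"no person-cycles in state {name}; post-event "
                              "hazards floored", stacklevel=2)
                th_p = np.full(2 * stable.k, LOG_HAZARD_FLOOR)
                th_p[1:stable.k] = 0.0
                th_p[stable.k + 1:] = 0.0
                se_p = np.full(2 * stable.k, np.nan)
            else:
                mle = _CompetingRiskMLE(X[mask], exp_[mask], cause_[mask],
                                        len(DEATH_TYPES), self.covariates)
                th_p, se_p = mle.fit()
            post_fits[name] = (th_p, se_p)

        for e in EVENT_TYPES:
            name = "post" if self.share_post else f"post_{e}"
            th_p, se_p = post_fits[name]
            for c, d in enumerate(DEATH_TYPES):
                seg = th_p[c * k:(c + 1) * k]
                seg_se = se_p[c * k:(c + 1) * k]
                transitions[f"post_{e}:{d}"] = TransitionHazard(
                    log_baseline=float(seg[0]),
                    effects={nm: float(v) for nm, v in zip(self.covariates, seg[1:])})
                bse[f"post_{e}:{d}"] = {
                    "log_baseline": float(seg_se[0]),
                    **{nm: float(v) for nm, v in zip(self.covariates, seg_se[1:])}}

        return MultistateResults(self, TransitionParams(transitions), bse)


class MultistateResults:
    """Fitted transition structure with standard errors and derived summaries."""

    def __init__(self, model: MultistateModel, params: TransitionParams, bse: dict):
        self.model = model
        self.transition_params = params
        self.bse = bse

    @property
    def params(self) -> TransitionParams:
        return self.transition_params

    def summary(self) -> pd.DataFrame:
        rows = []
        for key, t in self.transition_params.transitions.items():
            se = self.bse.get(key, {})
            rows.append({"transition": key, "parameter": "log_baseline",
                         "estimate": t.log_baseline, "se": se.get("log_baseline", np.nan)})
            for nm, v in t.effects.items():
                rows.append({"transition": key, "parameter": nm,
                             "estimate": v, "se": se.get(nm, np.nan)})
        return pd.DataFrame(rows)

    def five_year_risk(self, profile) -> float:
        return five_year_risk(self.transition_params, profile)

    def life_expectancy(self, profile, horizon_cycles: int = 400) -> float:
        return life_expectancy(self.transition_params, profile, horizon_cycles)


def fit_transitions(baseline, events, covariates=HAZARD_COVARIATES,
                    share_post_event_hazards=True) -> TransitionParams:
    """Convenience wrapper returning the fitted TransitionParams."""
    return MultistateModel(baseline, events, covariates,
                           share_post_event_hazards).fit().transition_params


# ---------------------------------------------------------------------------
# Derived quantities


def transition_matrix(params: TransitionParams, profile, state: str,
                      cycle: int = 1) -> pd.Series:
    """Probability row over successor states (time-homogeneous in cycle)."""
    from .markov import state_space, transition_row

    space = state_space()
    if state not in space:
        raise ConfigurationError(f"unknown state {state!r}")
    return pd.Series(transition_row(params, profile, state), index=space)


def five_year_risk(params: TransitionParams, profile, cycles: int = 20) -> float:
    """Probability that the first CVD event (AMI, either stroke, or CVD death)
    occurs within ``cycles`` cycles, with non-CVD death as a competing risk.

    With time-invariant covariates the stable-state transition probabilities
    are constant, so the absorption sum has the closed form
    p_cvd · (1 − s^T)/(1 − s), s = exp(−H)."""
    h = params.stable_hazards(profile)
    H = sum(h.values())
    if H <= 0:
        return 0.0
    p_cvd = (h["ami"] + h["istroke"] + h["hstroke"] + h["cvd_death"]) / H * (-np.expm1(-H))
    s = np.exp(-H)
    return float(p_cvd * (1 - s ** cycles) / (1 - s))


def survival_curve(params: TransitionParams, profile, horizon_cycles: int) -> np.ndarray:
    """P(alive at end of cycle k), k = 1..horizon, from the cohort trace."""
    from .markov import run_occupancy

    occ, alive_idx = run_occupancy(params, profile, horizon_cycles)
    return occ[:, alive_idx].sum(axis=1)


def life_expectancy(params: TransitionParams, profile,
                    horizon_cycles: int = 400) -> float:
    """Σ_k survival(k) · (90/365.25) years, end-of-cycle convention."""
    surv = survival_curve(params, profile, horizon_cycles)
    if surv[-1] > 1e-4:
        warnings.warn(
            f"survival at horizon is {surv[-1]:.2e} (> 1e-4); life expectancy "
            "is truncated — increase horizon_cycles", stacklevel=2)
    return float(surv.sum() * CYCLE_YEARS)
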