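"""Simulation configuration for the synthetic SCAD cohort generator.

The defaults encode the study conditions the generator emulates: the covariate
mix of the source cohort (44% female, mean ages 67/72, the five-way SCAD
diagnosis split), a competing-risks event process on 90-day cycles whose
hazards rise steeply with age (roughly ten-fold across the 5-year-risk decile
range), and an additive 90-day cost process anchored at the published worked
example (baseline £341 per cycle, trend £10 per cycle, AMI event-cycle
increment £5028 with £521 per cycle long-run, death-period increments
£2008/£2240 for CVD/non-CVD death). Comorbidity prevalences, biomarker
distributions, missingness rates and the band-2..4 stroke/AMI increments are
not printed in the available source and are set to values realistic for a UK
SCAD population; see docs/methods.md.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import yaml

from .exceptions import ConfigurationError
from .params import (
    DIAGNOSIS_LEVELS,
    EVENT_TYPES,
    DEATH_TYPES,
    FIRST_EVENT_TYPES,
    EventCostBands,
    PanelCostParams,
    TransitionHazard,
    TransitionParams,
)

#: cost components of a 90-day period row, in nesting order
COST_COMPONENTS = (
    "inpatient_chd",
    "inpatient_cvd_extra",   # CVD inpatient beyond CHD
    "inpatient_noncvd",      # inpatient beyond CVD
    "primary_care",
    "diagnostics",
    "drugs_cvd",
    "drugs_noncvd",
)


def _default_core_shares() -> dict[str, float]:
    # split of the background (non-event) period cost across components;
    # proportions chosen so a no-event year reproduces the rough component mix
    # of first-year costs (inpatient ~24%, primary care ~34%, ...)
    return {
        "inpatient_chd": 0.100,
        "inpatient_cvd_extra": 0.060,
        "inpatient_noncvd": 0.083,
        "primary_care": 0.342,
        "diagnostics": 0.103,
        "drugs_cvd": 0.077,
        "drugs_noncvd": 0.235,
    }


def _default_event_shares() -> dict[str, dict[str, float]]:
    # split of each event/death increment across components: AMI costs are
    # dominated by CHD hospitalization, strokes by non-CHD CVD hospitalization,
    # non-CVD death by non-CVD hospitalization
    return {
        "ami": {"inpatient_chd": 0.81, "inpatient_cvd_extra": 0.13, "inpatient_noncvd": 0.04,
                "primary_care": 0.01, "diagnostics": 0.005, "drugs_cvd": 0.005},
        "istroke": {"inpatient_chd": 0.02, "inpatient_cvd_extra": 0.90, "inpatient_noncvd": 0.05,
                    "primary_care": 0.02, "diagnostics": 0.005, "drugs_cvd": 0.005},
        "hstroke": {"inpatient_chd": 0.02, "inpatient_cvd_extra": 0.90, "inpatient_noncvd": 0.05,
                    "primary_care": 0.02, "diagnostics": 0.005, "drugs_cvd": 0.005},
        "cvd_death": {"inpatient_chd": 0.45, "inpatient_cvd_extra": 0.40,
                      "inpatient_noncvd": 0.13, "primary_care": 0.02},
        "noncvd_death": {"inpatient_chd": 0.02, "inpatient_cvd_extra": 0.03,
                         "inpatient_noncvd": 0.90, "primary_care": 0.05},
    }


def default_cost_params() -> PanelCostParams:
    """Ground-truth total-cost panel parameters (the published worked example
    supplies the baseline, trend, AMI band-1/long-run and death increments; the
    remaining bands are chosen so first-year event totals match the published
    first-year incremental event costs: £7677 AMI, £8902 ischaemic stroke,
    £10 477 haemorrhagic stroke)."""
    return PanelCostParams(
        category="total",
        baseline_cost=341.0,
        period_trend=10.0,
        covariate_effects={
            "female": -60.0,
            "age_c": 4.0,
            "heart_failure": 160.0,
            "renal_disease": 300.0,
            "diabetes": 60.0,
            "copd": 90.0,
            "cancer": 250.0,
            "smoking": 30.0,
        },
        event_increments={
            "ami": EventCostBands(5028.0, 1400.0, 750.0, 499.0, 521.0),
            "istroke": EventCostBands(5800.0, 1700.0, 900.0, 502.0, 430.0),
            "hstroke": EventCostBands(7200.0, 1900.0, 900.0, 477.0, 450.0),
        },
        death_increments={"cvd_death": 2008.0, "noncvd_death": 2240.0},
    )


def default_hazards() -> dict[str, dict]:
    """Per-cycle cause-specific baseline rates (reference: male, age 69, no
    comorbidities) and log hazard ratios. Calibrated so the 20-cycle CVD event
    risk spans roughly 3.5%–44% between ages 52 and 84 (the span of the
    published risk deciles) and, because covariates stay time-invariant during
    extrapolation, so non-CVD mortality uses a flatter age slope whose implied
    life expectancies bracket the published ~27- to ~5.5-year decile range."""
    age = 0.085
    return {
        "stable:ami": {"rate": 0.0035, "log_hr": {"age_c": age, "female": -0.15,
                                                  "heart_failure": 0.25, "smoking": 0.35}},
        "stable:istroke": {"rate": 0.0018, "log_hr": {"age_c": age, "smoking": 0.25}},
        "stable:hstroke": {"rate": 0.0004, "log_hr": {"age_c": age, "smoking": 0.20}},
        "stable:cvd_death": {"rate": 0.0018, "log_hr": {"age_c": age, "female": -0.10,
                                                        "heart_failure": 0.55, "smoking": 0.15}},
        "stable:noncvd_death": {"rate": 0.016, "log_hr": {"age_c": 0.050, "female": -0.05,
                                                          "smoking": 0.30}},
        "post:cvd_death": {"rate": 0.025, "log_hr": {"age_c": 0.05, "heart_failure": 0.30}},
        "post:noncvd_death": {"rate": 0.012, "log_hr": {"age_c": 0.07, "smoking": 0.25}},
    }


def _default_utilization() -> dict[str, float]:
    return {
        # hospitalization probability per cycle: 1 - exp(-mean inpatient cost / scale)
        "hospitalization_cost_scale": 600.0,
        "consultation_rate": 2.7,          # per cycle
        "consultation_event_extra": 1.5,   # extra in event band-1 cycles
        "extra_stay_rate": 0.35,           # Poisson extra stays beyond the first
        "los_rate": 3.0,                   # Poisson days beyond 1 per stay
        "pci_rate": 0.003,                 # per cycle
        "pci_event_extra": 0.10,           # extra in AMI band-1 cycles
        "cabg_rate": 0.003,
        "cabg_event_extra": 0.04,
        # persistent per-patient drug-class probabilities
        "on_drugs": 0.913,
        "on_cvd_drugs": 0.882,
        "anticoagulant": 0.087,
        "acei_arb": 0.477,
        "antiplatelet": 0.656,
        "beta_blocker": 0.460,
        "ccb": 0.315,
    }


@dataclass
class SimulationConfig:
    """Full parameterization of the synthetic three-table generator."""

    n_patients: int = 10000
    seed: int = 0
    female_fraction: float = 0.44
    age_mean_male: float = 67.0
    age_mean_female: float = 72.0
    age_sd: float = 9.0
    age_bounds: tuple[float, float] = (35.0, 95.0)
    diagnosis_mix: dict[str, float] = field(default_factory=lambda: {
        "stable_angina": 0.474, "unstable_angina": 0.135,
        "stemi": 0.067, "nstemi": 0.097, "other_chd": 0.227,
    })
    comorbidity_prevalences: dict[str, float] = field(default_factory=lambda: {
        "heart_failure": 0.08, "renal_disease": 0.05, "diabetes": 0.16,
        "copd": 0.11, "cancer": 0.08, "smoking": 0.19,
    })
    biomarker_means: dict[str, float] = field(default_factory=lambda: {
        "heart_rate": 72.0, "creatinine": 95.0, "haemoglobin": 13.8,
    })
    biomarker_sds: dict[str, float] = field(default_factory=lambda: {
        "heart_rate": 12.0, "creatinine": 28.0, "haemoglobin": 1.6,
    })
    missingness_rates: dict[str, float] = field(default_factory=lambda: {
        "heart_rate": 0.18, "creatinine": 0.22, "haemoglobin": 0.25,
    })
    #: 'mcar' (default) or 'age' (missingness probability rises with age,
    #: a simple covariate-dependent mechanism)
    missingness_mechanism: str = "mcar"
    hazard_params: dict[str, dict] = field(default_factory=default_hazards)
    cost_params: PanelCostParams = field(default_factory=default_cost_params)
    core_cost_shares: dict[str, float] = field(default_factory=_default_core_shares)
    event_cost_shares: dict[str, dict[str, float]] = field(default_factory=_default_event_shares)
    gamma_shape: float = 0.5
    censoring_rate: float = 0.01
    horizon_cycles: int = 40
    utilization: dict[str, float] = field(default_factory=_default_utilization)
    study_start: str = "2001-01-01"
    entry_spread_days: int = 2920  # entries spread over ~8 years

    # -- validation ---------------------------------------------------------
    def validate(self) -> "SimulationConfig":
        def check_prob(name, p):
            if not (0.0 <= p <= 1.0):
                raise ConfigurationError(f"{name} must be a probability in [0, 1], got {p}")

        if self.n_patients < 1:
            raise ConfigurationError(f"n_patients must be >= 1, got {self.n_patients}")
        check_prob("female_fraction", self.female_fraction)
        check_prob("censoring_rate", self.censoring_rate)
        if self.gamma_shape <= 0:
            raise ConfigurationError(f"gamma_shape must be > 0, got {self.gamma_shape}")
        if self.horizon_cycles < 1:
            raise ConfigurationError(f"horizon_cycles must be >= 1, got {self.horizon_cycles}")
        if set(self.diagnosis_mix) != set(DIAGNOSIS_LEVELS):
            raise ConfigurationError(
                f"diagnosis_mix must have keys {DIAGNOSIS_LEVELS}, got {sorted(self.diagnosis_mix)}")
        for k, p in self.diagnosis_mix.items():
            check_prob(f"diagnosis_mix[{k}]", p)
        if abs(sum(self.diagnosis_mix.values()) - 1.0) > 1e-9:
            raise ConfigurationError(
                f"diagnosis_mix must sum to 1 within 1e-9, sums to {sum(self.diagnosis_mix.values())}")
        for k, p in self.comorbidity_prevalences.items():
            check_prob(f"comorbidity_prevalences[{k}]", p)
        for k, p in self.missingness_rates.items():
            check_prob(f"missingness_rates[{k}]", p)
            if k not in self.biomarker_means:
                raise ConfigurationError(f"missingness_rates names unknown biomarker {k!r}")
        for k, sd in self.biomarker_sds.items():
            if sd < 0:
                raise ConfigurationError(f"biomarker_sds[{k}] must be >= 0, got {sd}")
        if self.missingness_mechanism not in ("mcar", "age"):
            raise ConfigurationError(
                f"missingness_mechanism must be 'mcar' or 'age', got {self.missingness_mechanism!r}")
        required = {f"stable:{e}" for e in FIRST_EVENT_TYPES}
        post_full = {f"post_{e}:{d}" for e in EVENT_TYPES for d in DEATH_TYPES}
        post_shared = {f"post:{d}" for d in DEATH_TYPES}
        keys = set(self.hazard_params)
        if not (required <= keys and (post_shared <= keys or post_full <= keys)):
            raise ConfigurationError(
                "hazard_params must cover the five stable transitions and post-event "
                f"death transitions; got {sorted(keys)}")
        for k, spec in self.hazard_params.items():
            if spec.get("rate", -1.0) < 0:
                raise ConfigurationError(f"hazard_params[{k}].rate must be >= 0")
        for name, shares in [("core_cost_shares", self.core_cost_shares),
                             *((f"event_cost_shares[{k}]", v) for k, v in self.event_cost_shares.items())]:
            for comp, s in shares.items():
                if comp not in COST_COMPONENTS:
                    raise ConfigurationError(f"{name} names unknown component {comp!r}")
                if s < 0:
                    raise ConfigurationError(f"{name}[{comp}] must be >= 0, got {s}")
            if abs(sum(shares.values()) - 1.0) > 1e-9:
                raise ConfigurationError(f"{name} must sum to 1, sums to {sum(shares.values())}")
        return self

    # -- transition parameters ---------------------------------------------
    def transition_params(self) -> TransitionParams:
        """Ground-truth TransitionParams implied by ``hazard_params``."""
        def haz(key):
            spec = self.hazard_params[key]
            if spec["rate"] <= 0:
                return TransitionHazard(log_baseline=-np.inf, effects=dict(spec.get("log_hr", {})))
            return TransitionHazard(log_baseline=float(np.log(spec["rate"])),
                                    effects=dict(spec.get("log_hr", {})))

        trans = {f"stable:{e}": haz(f"stable:{e}") for e in FIRST_EVENT_TYPES}
        for e in EVENT_TYPES:
            for d in DEATH_TYPES:
                key = f"post_{e}:{d}" if f"post_{e}:{d}" in self.hazard_params else f"post:{d}"
                trans[f"post_{e}:{d}"] = haz(key)
        return TransitionParams(trans)

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["cost_params"] = self.cost_params.to_dict()
        d["age_bounds"] = list(self.age_bounds)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        if "cost_params" in d and not isinstance(d["cost_params"], PanelCostParams):
            d["cost_params"] = PanelCostParams.from_dict(d["cost_params"])
        if "age_bounds" in d:
            d["age_bounds"] = tuple(d["age_bounds"])
        return cls(**d).validate()

    @classmethod
    def from_file(cls, path) -> "SimulationConfig":
        """Load a config from YAML or JSON."""
        with open(path) as fh:
            text = fh.read()
        data = yaml.safe_load(text)
        return cls.from_dict(data)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            if str(path).endswith(".json"):
                json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            else:
                yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def default_config(n_patients: int = 10000, seed: int = 0, **overrides) -> SimulationConfig:
    """The default study-condition configuration."""
    return SimulationConfig(n_patients=n_patients, seed=seed, **overrides).validate()
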