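"""Shared parameter containers and covariate design helpers.

The package works on a 90-day ("cycle") grid throughout: the cost panel, the
event process and the Markov extrapolation all use the same discretization, and
a model "year" is four cycles (360 days).
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, ParameterError

# ---------------------------------------------------------------------------
# Vocabulary

DIAGNOSIS_LEVELS = ("stable_angina", "unstable_angina", "stemi", "nstemi", "other_chd")
COMORBIDITY_FLAGS = ("heart_failure", "renal_disease", "diabetes", "copd", "cancer", "smoking")
BIOMARKERS = ("heart_rate", "creatinine", "haemoglobin")

#: non-fatal first-event types
EVENT_TYPES = ("ami", "istroke", "hstroke")
#: absorbing death causes
DEATH_TYPES = ("cvd_death", "noncvd_death")
#: competing first events out of the stable state
FIRST_EVENT_TYPES = EVENT_TYPES + DEATH_TYPES

CATEGORIES = ("total", "cvd", "chd")

#: days per cycle and per (average calendar) year
CYCLE_DAYS = 90.0
YEAR_DAYS = 365.25
CYCLE_YEARS = CYCLE_DAYS / YEAR_DAYS
#: cycles per model year (the 360-day analysis year)
CYCLES_PER_YEAR = 4

AGE_REFERENCE = 69.0  # centering age for design matrices (the paper's worked example age)

#: default covariates entering the cause-specific hazard models
HAZARD_COVARIATES = ("age_c", "female", "heart_failure", "smoking")
#: default covariates entering the panel cost model
PANEL_COVARIATES = ("female", "age_c") + COMORBIDITY_FLAGS


def glm_covariates(biomarkers: Iterable[str] = BIOMARKERS) -> tuple[str, ...]:
    """Default covariate list for the first-year cost regression.

    Diagnosis dummies use stable angina as the reference level; biomarkers are
    entered centred at their cohort mean.
    """
    diag = tuple(f"diag_{d}" for d in DIAGNOSIS_LEVELS if d != "stable_angina")
    bio = tuple(f"{b}_c" for b in biomarkers)
    return ("female", "age_c") + diag + COMORBIDITY_FLAGS + bio


# ---------------------------------------------------------------------------
# Design matrix construction


def design_matrix(baseline: pd.DataFrame, covariates: Iterable[str]) -> pd.DataFrame:
    """Build a numeric design matrix (no intercept column) from a baseline table.

    Recognised covariate names:

    * ``female`` — indicator from the ``sex`` column;
    * ``age_c`` — ``age_at_entry`` centred at :data:`AGE_REFERENCE`;
    * ``diag_<level>`` — diagnosis dummies;
    * comorbidity flags — cast to float;
    * ``<biomarker>_c`` — biomarker centred at its observed cohort mean
      (missing values propagate as NaN);
    * any other name — taken verbatim from the table.
    """
    cols = {}
    for name in covariates:
        if name == "female":
            cols[name] = (baseline["sex"] == "female").astype(float)
        elif name == "age_c":
            cols[name] = baseline["age_at_entry"].astype(float) - AGE_REFERENCE
        elif name.startswith("diag_"):
            level = name[len("diag_"):]
            if level not in DIAGNOSIS_LEVELS:
                raise ConfigurationError(f"unknown diagnosis level in covariate {name!r}")
            cols[name] = (baseline["diagnosis"] == level).astype(float)
        elif name.endswith("_c") and name[:-2] in baseline.columns:
            raw = baseline[name[:-2]].astype(float)
            cols[name] = raw - raw.mean()
        elif name in baseline.columns:
            cols[name] = baseline[name].astype(float)
        else:
            raise ConfigurationError(f"covariate {name!r} not derivable from baseline table")
    out = pd.DataFrame(cols, index=baseline.index)
    return out


def profile_from_row(row: Mapping[str, float], covariates: Iterable[str]) -> dict[str, float]:
    """Extract a covariate profile dict from a design-matrix row."""
    return {c: float(row[c]) for c in covariates}


def linear_effect(effects: Mapping[str, float], profile: Mapping[str, float]) -> float:
    """Sum of covariate effects for a profile; missing profile entries count as 0."""
    return float(sum(v * float(profile.get(k, 0.0)) for k, v in effects.items()))


# ---------------------------------------------------------------------------
# Panel cost parameters


@dataclass
class EventCostBands:
    """Additive cost increments in the four 90-day bands after a non-fatal event.

    ``band_1`` is the cycle of the event itself; ``long_run`` applies from the
    fifth cycle (beyond 360 days) onwards, indefinitely.
    """

    band_1: float
    band_2: float
    band_3: float
    band_4: float
    long_run: float

    def band(self, cycles_since_event: int) -> float:
        """Increment for a given time since the event (1 = the event cycle)."""
        if cycles_since_event < 1:
            raise ValueError("cycles_since_event starts at 1 (the event cycle)")
        if cycles_since_event <= 4:
            return (self.band_1, self.band_2, self.band_3, self.band_4)[cycles_since_event - 1]
        return self.long_run

    @property
    def first_year_total(self) -> float:
        """Incremental cost of the event over the first model year (four bands)."""
        return self.band_1 + self.band_2 + self.band_3 + self.band_4

    def as_tuple(self) -> tuple[float, float, float, float, float]:
        return (self.band_1, self.band_2, self.band_3, self.band_4, self.long_run)


@dataclass
class PanelCostParams:
    """Additive 90-day period cost structure for one cost category.

    mean cost per cycle = ``baseline_cost`` + ``period_trend``·(cycle − 1)
    + covariate effects + event-band increment + death-period increment.
    """

    category: str
    baseline_cost: float
    period_trend: float
    covariate_effects: dict[str, float] = field(default_factory=dict)
    event_increments: dict[str, EventCostBands] = field(default_factory=dict)
    death_increments: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ConfigurationError(f"category must be one of {CATEGORIES}, got {self.category!r}")
        for e, bands in self.event_increments.items():
            if e not in EVENT_TYPES:
                raise ConfigurationError(f"unknown event type {e!r} in event_increments")
            if not all(np.isfinite(bands.as_tuple())):
                raise ConfigurationError(f"non-finite cost band for event {e!r}")
        for d in self.death_increments:
            if d not in DEATH_TYPES:
                raise ConfigurationError(f"unknown death type {d!r} in death_increments")

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "PanelCostParams":
        d = dict(d)
        d["event_increments"] = {
            k: EventCostBands(**v) for k, v in d.get("event_increments", {}).items()
        }
        return cls(**d)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "PanelCostParams":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# Transition parameters


@dataclass
class TransitionHazard:
    """One cause-specific transition: log baseline hazard per cycle plus log hazard ratios."""

    log_baseline: float
    effects: dict[str, float] = field(default_factory=dict)

    def hazard(self, profile: Mapping[str, float]) -> float:
        """Cause-specific hazard (events per cycle) for a covariate profile."""
        return float(np.exp(self.log_baseline + linear_effect(self.effects, profile)))


def transition_keys() -> list[str]:
    """All transitions of the six-state structure, as ``from:to`` strings."""
    keys = [f"stable:{e}" for e in FIRST_EVENT_TYPES]
    for e in EVENT_TYPES:
        for d in DEATH_TYPES:
            keys.append(f"post_{e}:{d}")
    return keys


@dataclass
class TransitionParams:
    """Covariate-conditional cause-specific hazards on the 90-day cycle grid.

    Keys are ``"stable:<event>"`` for the five competing first events and
    ``"post_<event>:<death>"`` for post-event mortality. Hazards are
    exponential rates per cycle; per-cycle transition probabilities follow the
    competing-risks conversion p_c = h_c/H · (1 − exp(−H)).
    """

    transitions: dict[str, TransitionHazard]

    def __post_init__(self):
        missing = set(transition_keys()) - set(self.transitions)
        if missing:
            raise ConfigurationError(f"missing transition parameters: {sorted(missing)}")

    @classmethod
    def with_shared_post(
        cls,
        stable: Mapping[str, TransitionHazard],
        post_cvd_death: TransitionHazard,
        post_noncvd_death: TransitionHazard,
    ) -> "TransitionParams":
        """Build full parameters with post-event mortality shared across event types."""
        trans = {f"stable:{e}": stable[e] for e in FIRST_EVENT_TYPES}
        for e in EVENT_TYPES:
            trans[f"post_{e}:cvd_death"] = post_cvd_death
            trans[f"post_{e}:noncvd_death"] = post_noncvd_death
        return cls(trans)

    def stable_hazards(self, profile: Mapping[str, float]) -> dict[str, float]:
        return {e: self.transitions[f"stable:{e}"].hazard(profile) for e in FIRST_EVENT_TYPES}

    def post_event_hazards(self, event: str, profile: Mapping[str, float]) -> dict[str, float]:
        return {d: self.transitions[f"post_{event}:{d}"].hazard(profile) for d in DEATH_TYPES}

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {k: asdict(v) for k, v in self.transitions.items()}

    @classmethod
    def from_dict(cls, d: Mapping) -> "TransitionParams":
        return cls({k: TransitionHazard(**v) for k, v in d.items()})

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "TransitionParams":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def competing_risk_probabilities(hazards: Mapping[str, float]) -> dict[str, float]:
    """Per-cycle transition probabilities from cause-specific exponential rates.

    p_c = h_c / H · (1 − exp(−H)) with H = Σ h_c; the stay probability is
    exp(−H). All hazards must be ≥ 0.
    """
    h = np.array([hazards[k] for k in hazards], dtype=float)
    if (h < 0).any():
        raise ParameterError(f"negative hazard in {dict(hazards)!r}")
    H = h.sum()
    if H <= 0:
        return {k: 0.0 for k in hazards}
    scale = -np.expm1(-H) / H  # (1 - exp(-H)) / H
    return {k: float(hk * scale) for k, hk in zip(hazards, h)}
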