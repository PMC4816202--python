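"""State space and transition kinematics for the Markov cost engine.

The six clinical states are realized as 18 model states: Stable; for each
non-fatal event type four one-cycle tunnel states (time-since-event bands
1–4) plus a long-run state; and the two absorbing death states. Tunnel band b
transitions only to band b+1 (band 4 to long-run) or to a death state, which
is exactly what lets a memoryless Markov structure carry the
time-since-event cost bands of the panel model.
"""
from __future__ import annotations

from functools import lru_cache

import numpy as np

from .exceptions import ConfigurationError
from .params import EVENT_TYPES, TransitionParams, competing_risk_probabilities


@lru_cache(maxsize=1)
def state_space() -> tuple[str, ...]:
    states = ["stable"]
    for e in EVENT_TYPES:
        states += [f"{e}_b{b}" for b in (1, 2, 3, 4)] + [f"{e}_long"]
    states += ["death_cvd", "death_noncvd"]
    return tuple(states)


def state_index(state: str) -> int:
    try:
        return state_space().index(state)
    except ValueError:
        raise ConfigurationError(f"unknown state {state!r}") from None


def alive_states() -> tuple[str, ...]:
    return tuple(s for s in state_space() if not s.startswith("death"))


def _death_index(d: str) -> int:
    return state_index("death_cvd" if d == "cvd_death" else "death_noncvd")


def transition_row(params: TransitionParams, profile, state: str) -> np.ndarray:
    """One row of the transition matrix (time-homogeneous per profile)."""
    space = state_space()
    row = np.zeros(len(space))
    i = {s: j for j, s in enumerate(space)}
    if state.startswith("death"):
        row[i[state]] = 1.0
        return row
    if state == "stable":
        h = params.stable_hazards(profile)
        p = competing_risk_probabilities(h)
        row[i["ami_b1"]] = p["ami"]
        row[i["istroke_b1"]] = p["istroke"]
        row[i["hstroke_b1"]] = p["hstroke"]
        row[_death_index("cvd_death")] = p["cvd_death"]
        row[_death_index("noncvd_death")] = p["noncvd_death"]
        row[i["stable"]] = 1.0 - sum(p.values())
        return row
    # post-event states
    for e in EVENT_TYPES:
        if state.startswith(e):
            h = params.post_event_hazards(e, profile)
            p = competing_risk_probabilities(h)
            row[_death_index("cvd_death")] = p["cvd_death"]
            row[_death_index("noncvd_death")] = p["noncvd_death"]
            stay = 1.0 - sum(p.values())
            if state == f"{e}_long":
                nxt = f"{e}_long"
            else:
                b = int(state[-1])
                nxt = f"{e}_b{b + 1}" if b < 4 else f"{e}_long"
            row[i[nxt]] = stay
            return row
    raise ConfigurationError(f"unknown state {state!r}")


def transition_matrix_full(params: TransitionParams, profile) -> np.ndarray:
    """Full 18×18 transition matrix for a profile."""
    space = state_space()
    P = np.vstack([transition_row(params, profile, s) for s in space])
    rs = P.sum(axis=1)
    if not np.allclose(rs, 1.0, atol=1e-12):
        raise ConfigurationError(f"transition rows do not sum to 1: {rs}")
    return P


def run_occupancy(params: TransitionParams, profile,
                  horizon_cycles: int) -> tuple[np.ndarray, np.ndarray]:
    """Occupancy matrix (cycles × states), post-transition convention.

    Row k (0-based) is the distribution after the transitions of cycle k+1;
    entering ``<e>_b1`` in row k means the event happened during cycle k+1.
    Also returns the indices of alive states.
    """
    P = transition_matrix_full(params, profile)
    space = state_space()
    occ = np.zeros((horizon_cycles, len(space)))
    v = np.zeros(len(space))
    v[state_index("stable")] = 1.0
    for k in range(horizon_cycles):
        v = v @ P
        occ[k] = v
    alive_idx = np.array([j for j, s in enumerate(space) if not s.startswith("death")])
    return occ, alive_idx
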