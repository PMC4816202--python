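"""Cohort entry rules and analysis-window derivation.

Two windows are analysed per patient: the first year in the cohort (cycles
1–4) and, for patients whose first event is non-fatal, the first year after
that event (four cycles starting at the event cycle). A window is *complete*
if it is fully observed or ends in death; windows cut short by any non-death
censoring are flagged incomplete and excluded from cost summaries, mirroring
the convention that right-censoring for reasons other than mortality is
dropped while decedents are retained.
"""
from __future__ import annotations

import datetime as dt

import pandas as pd

from .exceptions import DataIntegrityError
from .params import CYCLES_PER_YEAR, DIAGNOSIS_LEVELS, EVENT_TYPES

#: entry is deferred by six months (a fixed 182 days) after an acute coronary
#: syndrome, to separate stable-phase costs from the acute/high-risk period
ACS_DIAGNOSES = ("unstable_angina", "stemi", "nstemi")
ACS_ENTRY_OFFSET_DAYS = 182


def derive_entry_date(diagnosis_date, diagnosis: str):
    """Cohort entry date from a diagnosis date and SCAD diagnosis category.

    Stable angina and unspecified CHD enter at diagnosis; ACS diagnoses
    (unstable angina, STEMI, NSTEMI) enter 182 days later.
    """
    if diagnosis not in DIAGNOSIS_LEVELS:
        raise DataIntegrityError(f"unknown diagnosis {diagnosis!r}")
    if diagnosis in ACS_DIAGNOSES:
        if isinstance(diagnosis_date, (dt.date, dt.datetime)):
            return diagnosis_date + dt.timedelta(days=ACS_ENTRY_OFFSET_DAYS)
        return pd.Timestamp(diagnosis_date) + pd.Timedelta(days=ACS_ENTRY_OFFSET_DAYS)
    return diagnosis_date


def build_analysis_windows(baseline: pd.DataFrame, events: pd.DataFrame) -> pd.DataFrame:
    """Derive first-year and first-post-event-year analysis windows.

    Returns one ``first_scad_year`` row per patient and one
    ``first_post_event_year`` row per patient whose first event is non-fatal,
    with columns ``patient_id, window_kind, start_cycle, end_cycle, complete,
    index_event_type``.
    """
    known = set(baseline["patient_id"])
    unknown = sorted(set(events["patient_id"]) - known)
    if unknown:
        raise DataIntegrityError(f"events reference unknown patient ids: {unknown[:10]}")

    followup = baseline.set_index("patient_id")["followup_cycles"]
    died = baseline.set_index("patient_id")["exit_reason"].isin(["death_cvd", "death_noncvd"])

    # first event per patient (smallest cycle among non-censoring events)
    real = events[events["event_type"] != "censoring"]
    first = (real.sort_values(["patient_id", "cycle"], kind="stable")
                 .groupby("patient_id", sort=False).first())

    rows = []
    for pid in baseline["patient_id"]:
        fu = int(followup.loc[pid])
        dead = bool(died.loc[pid])
        rows.append(_window(pid, "first_scad_year", 1, fu, dead, None))
        if pid in first.index:
            etype = first.loc[pid, "event_type"]
            if etype in EVENT_TYPES:
                start = int(first.loc[pid, "cycle"])
                rows.append(_window(pid, "first_post_event_year", start, fu, dead, etype))
    windows = pd.DataFrame(rows, columns=[
        "patient_id", "window_kind", "start_cycle", "end_cycle", "complete",
        "index_event_type"])
    return windows


def _window(pid, kind, start, followup, died, index_event):
    end = start + CYCLES_PER_YEAR - 1
    # complete if fully observed, or follow-up ended inside the window by death
    complete = followup >= end or (died and followup >= start)
    return {
        "patient_id": pid,
        "window_kind": kind,
        "start_cycle": start,
        "end_cycle": end,
        "complete": bool(complete),
        "index_event_type": index_event,
    }


def write_windows(windows: pd.DataFrame, path) -> None:
    windows.to_csv(path, index=False)
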