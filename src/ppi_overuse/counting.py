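"""Andersen-Gill counting-process data construction.

Each patient contributes half-open risk intervals ``(start, stop]`` on the
days-since-index scale, partitioning ``[0, censor_time]``.  Interval
boundaries are placed at every exceeding-fill date (event rows), every
time-varying covariate change, and the censoring time.  Covariates are
constant within an interval; when a covariate changes on the same day an
event occurs, the pre-change value is in force (changes apply from the
next interval).

Censoring is the earliest of: a new indication for long-term PPI use
(including post-index chronic/unspecified PUD codes), the administrative
follow-up cap, the regional deprescribing cutoff for patients in the
flagged network, the end of data, and — in the secondary analysis — the
first gastroprotection-guideline qualification.  Ties are resolved by a
fixed cause priority with administrative causes last.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import GASTRO_CLASSES, active_windows
from .cohort import DEFAULT_CHRONIC_CLASSES, DEFAULT_INDICATION_CLASSES
from .config import CensorPlan, StudyCalendar

logger = logging.getLogger(__name__)

#: tie-break priority of censoring causes (administrative causes last)
CAUSE_PRIORITY = (
    "new_indication",
    "guideline_qualification",
    "visn17",
    "end_of_data",
    "max_followup",
)

#: time-varying covariates entering the default model
DEFAULT_TV_CLASSES = ("nsaid", "aspirin", "anticoagulant")

FRAILTY_DUMMIES = ("prefrail", "mildly_frail", "moderately_frail", "severely_frail")


# ---------------------------------------------------------------------------
# censoring
# ---------------------------------------------------------------------------


def censor_time(
    index_day: int,
    visn: int,
    event_days_by_cause: Mapping[str, int | None],
    plan: CensorPlan,
    calendar: StudyCalendar | None = None,
) -> tuple[int, str]:
    """Follow-up end (days since index) and its cause for one patient.

    ``event_days_by_cause`` may carry absolute days for
    ``"new_indication"`` (first disqualifying diagnosis) and
    ``"guideline_qualification"`` (first qualification day, used only when
    the plan censors on qualification).
    """
    cal = calendar or StudyCalendar()
    candidates: dict[str, float] = {"max_followup": float(plan.max_followup)}
    end_of_data = cal.end_of_data_day - index_day
    candidates["end_of_data"] = float(end_of_data)
    if visn == plan.visn17_network:
        candidates["visn17"] = float(cal.to_day(plan.visn17_cutoff) - index_day)
    if plan.indication_censoring:
        d = event_days_by_cause.get("new_indication")
        if d is not None:
            candidates["new_indication"] = float(d - index_day)
    if plan.guideline_censoring:
        d = event_days_by_cause.get("guideline_qualification")
        if d is not None:
            candidates["guideline_qualification"] = float(d - index_day)

    t = min(candidates.values())
    for cause in CAUSE_PRIORITY:
        if cause in candidates and candidates[cause] == t:
            return int(t), cause
    raise AssertionError("unreachable: some cause must attain the minimum")


# ---------------------------------------------------------------------------
# interval construction (single patient)
# ---------------------------------------------------------------------------


def build_intervals(
    event_days: Sequence[int],
    change_points: Sequence[float],
    censor_day: int,
    baseline: Mapping[str, float],
    tv_windows: Mapping[str, Sequence[tuple[float, float]]] | None = None,
) -> list[dict]:
    """Risk intervals for one patient.

    Parameters
    ----------
    event_days:
        Exceeding-fill days since index; duplicates collapse to one event,
        fills after the censor time are excluded (logged), an event exactly
        at the censor time is kept.
    change_points:
        Days at which any time-varying covariate changes value.
    tv_windows:
        Per-class merged half-open active windows ``[a, b)`` on the
        days-since-index scale; the class indicator for an interval
        ``(u, v]`` is the window membership of the open segment ``(u, v)``.
    """
    if censor_day <= 0:
        return []
    events = sorted({int(d) for d in event_days})
    late = [d for d in events if d > censor_day]
    if late:
        logger.debug("dropping %d event(s) after censor time", len(late))
    zero = [d for d in events if d <= 0]
    if zero:
        logger.debug("dropping %d event(s) at/before time zero", len(zero))
    events = [d for d in events if 0 < d <= censor_day]

    cuts = {float(censor_day)}
    cuts.update(float(d) for d in events)
    cuts.update(float(c) for c in change_points if 0.0 < c < censor_day)
    bounds = sorted(cuts)

    tv_windows = tv_windows or {}
    event_set = set(events)
    rows = []
    start = 0.0
    for stop in bounds:
        mid = (start + stop) / 2.0
        row = {"start": start, "stop": stop, "event": int(stop in event_set)}
        row.update(baseline)
        for cls, wins in tv_windows.items():
            row[cls] = float(any(a <= mid < b for a, b in wins))
        rows.append(row)
        start = stop
    return rows


# ---------------------------------------------------------------------------
# covariate design
# ---------------------------------------------------------------------------


def prepare_baseline_covariates(
    patients: pd.DataFrame,
    cohort: pd.DataFrame,
    factors: Sequence[str],
    frailty_column: str = "frailty",
) -> pd.DataFrame:
    """Design matrix of baseline covariates, indexed by patient id.

    ``factors`` may name patient-table columns directly, plus the special
    entries ``"inpatient"`` (taken from the cohort's index diagnosis),
    ``"gi_bleed_at_index"``, ``"frailty"`` (expands to four dummies against
    the nonfrail reference) and ``"index_year"``.
    """
    elig = cohort[cohort["eligible"].astype(bool)]
    merged = elig.merge(patients, on="patient_id", how="left", suffixes=("", "_pt"))
    out = pd.DataFrame(index=merged["patient_id"].to_numpy())
    for f in factors:
        if f == "inpatient":
            out[f] = merged["inpatient_index"].astype(float).to_numpy()
        elif f == "gi_bleed_at_index":
            out[f] = merged["gi_bleed_at_index"].astype(float).to_numpy()
        elif f == "frailty":
            for lev in FRAILTY_DUMMIES:
                out[lev] = (merged[frailty_column] == lev).astype(float).to_numpy()
        elif f in merged.columns:
            out[f] = merged[f].astype(float).to_numpy()
        else:
            raise KeyError(f"unknown baseline factor {f!r}")
    return out


# ---------------------------------------------------------------------------
# cohort-level assembly
# ---------------------------------------------------------------------------


def build_counting_data(
    cohort: pd.DataFrame,
    classified_fills: pd.DataFrame,
    fills: pd.DataFrame,
    diagnoses: pd.DataFrame,
    patients: pd.DataFrame,
    plan: CensorPlan,
    calendar: StudyCalendar | None = None,
    baseline_factors: Sequence[str] = ("inpatient",),
    tv_classes: Sequence[str] = DEFAULT_TV_CLASSES,
    grace_days: int = 30,
    indication_classes: Sequence[str] = DEFAULT_INDICATION_CLASSES,
    chronic_classes: Sequence[str] = DEFAULT_CHRONIC_CLASSES,
    guideline_days: Mapping[int, int] | None = None,
) -> pd.DataFrame:
    """Build the full counting-process table for the eligible cohort.

    Returns one row per risk interval with columns ``patient_id, start,
    stop, event, censor_cause`` plus one column per covariate.  Patients
    whose censor time is non-positive contribute no rows.
    """
    cal = calendar or StudyCalendar()
    elig = cohort[cohort["eligible"].astype(bool)]
    baseline = prepare_baseline_covariates(patients, cohort, baseline_factors)

    visn_by_pid = (
        patients.set_index("patient_id")["visn"]
        if "visn" in patients.columns
        else pd.Series(dtype=int)
    )

    censor_conds = tuple(indication_classes) + tuple(chronic_classes)
    post = diagnoses[diagnoses["condition"].isin(censor_conds)]
    idx_by_pid = elig.set_index("patient_id")["index_day"]
    post = post.merge(idx_by_pid.rename("index_day"), on="patient_id")
    post = post[post["day"] > post["index_day"]]
    first_indication = post.groupby("patient_id")["day"].min()

    events_by_pid: dict[int, np.ndarray] = {}
    if len(classified_fills):
        exceed = classified_fills[classified_fills["status"] == "exceeds"]
        events_by_pid = {
            int(pid): grp["day"].to_numpy() for pid, grp in exceed.groupby("patient_id")
        }

    wins_by_pid_cls: dict[tuple[int, str], list[tuple[float, float]]] = {}
    med = fills[fills["drug_class"].isin(tv_classes)] if len(fills) else fills
    if len(med):
        for (pid, cls), grp in med.groupby(["patient_id", "drug_class"]):
            wins_by_pid_cls[(int(pid), str(cls))] = active_windows(
                grp["day"].to_numpy(), grp["days_supply"].to_numpy(), grace_days
            )

    base_rows = baseline.to_dict("index")
    first_ind_d = first_indication.to_dict()
    visn_d = visn_by_pid.to_dict() if len(visn_by_pid) else {}

    all_rows: list[dict] = []
    for pid, index_day in idx_by_pid.items():
        pid = int(pid)
        index_day = int(index_day)
        by_cause: dict[str, int | None] = {"new_indication": first_ind_d.get(pid)}
        if guideline_days is not None:
            by_cause["guideline_qualification"] = guideline_days.get(pid)
        visn = int(visn_d.get(pid, -1))
        t_cens, cause = censor_time(index_day, visn, by_cause, plan, cal)
        if t_cens <= 0:
            continue

        tvw = {}
        changes: list[float] = []
        for cls in tv_classes:
            wins = wins_by_pid_cls.get((pid, cls), [])
            rel = [(a - index_day, b - index_day) for a, b in wins]
            tvw[cls] = rel
            for a, b in rel:
                changes.extend((a, b))
        ev = events_by_pid.get(pid, ())
        ev_rel = [int(d - index_day) for d in ev]
        rows = build_intervals(ev_rel, changes, t_cens, base_rows[pid], tvw)
        for r in rows:
            r["patient_id"] = pid
            r["censor_cause"] = cause
        all_rows.extend(rows)

    if not all_rows:
        cols = ["patient_id", "start", "stop", "event", "censor_cause"]
        return pd.DataFrame(columns=cols)
    out = pd.DataFrame(all_rows)
    front = ["patient_id", "start", "stop", "event"]
    cols = front + [c for c in out.columns if c not in front + ["censor_cause"]] + ["censor_cause"]
    return out[cols]
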