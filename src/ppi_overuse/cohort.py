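"""New-user cohort eligibility and attrition.

The analytic cohort consists of patients with a *first* acute PUD
diagnosis (the index date) who look like true treatment initiators:
an upper endoscopy in conjunction with the index diagnosis, no prior
chronic/unspecified PUD, no other indication for acute or chronic PPI use
at any time before index, no PPI fill during the washout window
[index - 365, index - 14] (both ends inclusive), and a qualifying PPI fill
within 14 days on/after index.

Exclusions are evaluated in that fixed order and each patient receives the
first failing reason; eligibility is a pure function of one patient's own
records, so the build is idempotent and order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

#: exclusion reasons, in evaluation order
EXCLUSION_ORDER = (
    "no_endoscopy",
    "prior_chronic_pud",
    "prior_ppi_indication",
    "washout_ppi_fill",
    "no_initial_ppi_fill",
)

DEFAULT_CHRONIC_CLASSES = ("chronic_pud", "unspecified_pud")
DEFAULT_INDICATION_CLASSES = ("ppi_indication", "gerd", "barretts", "esophagitis")


@dataclass(frozen=True)
class CohortRecord:
    patient_id: int
    index_day: int
    inpatient_index: bool
    gi_bleed_at_index: bool
    eligible: bool
    exclusion_reason: str | None


# ---------------------------------------------------------------------------
# per-patient operations
# ---------------------------------------------------------------------------


def find_index(events: pd.DataFrame) -> CohortRecord | None:
    """Draft cohort record from one patient's diagnosis events.

    The index date is the earliest acute-PUD event; its inpatient flag is
    copied onto the draft.  Patients with no acute PUD are not emitted.
    """
    acute = events[events["condition"] == "acute_pud"]
    if acute.empty:
        return None
    index_day = int(acute["day"].min())
    at_index = acute[acute["day"] == index_day]
    return CohortRecord(
        patient_id=int(events["patient_id"].iloc[0]),
        index_day=index_day,
        inpatient_index=bool(at_index["inpatient"].max()),
        gi_bleed_at_index=False,
        eligible=True,
        exclusion_reason=None,
    )


def apply_exclusions(
    draft: CohortRecord,
    events: pd.DataFrame,
    fills: pd.DataFrame,
    endoscopy_window: int = 30,
    washout: tuple[int, int] = (365, 14),
    initiation_window: int = 14,
    chronic_classes: Sequence[str] = DEFAULT_CHRONIC_CLASSES,
    indication_classes: Sequence[str] = DEFAULT_INDICATION_CLASSES,
    gi_bleed_window: int = 7,
) -> CohortRecord:
    """Apply the eligibility rules to a draft record, one patient at a time.

    Returns the record with ``eligible`` set and the *first* failing
    exclusion reason, if any.  The washout interval
    ``[index - washout[0], index - washout[1]]`` is closed on both ends;
    the initiation window ``[index, index + initiation_window]`` is
    inclusive.
    """
    idx = draft.index_day
    cond = events["condition"]
    day = events["day"]

    reason: str | None = None
    endo = events[(cond == "endoscopy") & (day >= idx - endoscopy_window) & (day <= idx + endoscopy_window)]
    if endo.empty:
        reason = "no_endoscopy"
    elif ((cond.isin(chronic_classes)) & (day < idx)).any():
        reason = "prior_chronic_pud"
    elif ((cond.isin(indication_classes)) & (day < idx)).any():
        reason = "prior_ppi_indication"
    else:
        ppi = fills[fills["drug_class"] == "ppi"] if len(fills) else fills
        fday = ppi["day"] if len(ppi) else pd.Series(dtype=np.int64)
        if ((fday >= idx - washout[0]) & (fday <= idx - washout[1])).any():
            reason = "washout_ppi_fill"
        elif not ((fday >= idx) & (fday <= idx + initiation_window)).any():
            reason = "no_initial_ppi_fill"

    gi_bleed = (
        (cond == "gi_bleed") & (day >= idx - gi_bleed_window) & (day <= idx + gi_bleed_window)
    ).any()
    return CohortRecord(
        patient_id=draft.patient_id,
        index_day=idx,
        inpatient_index=draft.inpatient_index,
        gi_bleed_at_index=bool(gi_bleed),
        eligible=reason is None,
        exclusion_reason=reason,
    )


# ---------------------------------------------------------------------------
# cohort-level (vectorised) build
# ---------------------------------------------------------------------------


def build_cohort(
    diagnoses: pd.DataFrame,
    fills: pd.DataFrame,
    endoscopy_window: int = 30,
    washout: tuple[int, int] = (365, 14),
    initiation_window: int = 14,
    chronic_classes: Sequence[str] = DEFAULT_CHRONIC_CLASSES,
    indication_classes: Sequence[str] = DEFAULT_INDICATION_CLASSES,
    gi_bleed_window: int = 7,
    min_index_day: int | None = None,
) -> pd.DataFrame:
    """Build the cohort table for all patients at once.

    Equivalent to :func:`find_index` + :func:`apply_exclusions` per
    patient, evaluated with vectorised joins.  ``min_index_day`` supports
    the calendar-restriction sensitivity analysis (index on/after a date);
    patients failing it get reason ``index_before_restriction`` evaluated
    before all other rules.

    Returns columns ``patient_id, index_day, inpatient_index,
    gi_bleed_at_index, eligible, exclusion_reason``.
    """
    acute = diagnoses[diagnoses["condition"] == "acute_pud"]
    if acute.empty:
        return pd.DataFrame(
            columns=[
                "patient_id",
                "index_day",
                "inpatient_index",
                "gi_bleed_at_index",
                "eligible",
                "exclusion_reason",
            ]
        )
    idx = acute.groupby("patient_id")["day"].min().rename("index_day")
    at_index = acute.merge(idx, on="patient_id")
    at_index = at_index[at_index["day"] == at_index["index_day"]]
    inpat = at_index.groupby("patient_id")["inpatient"].max().astype(bool)

    base = idx.reset_index()
    base["inpatient_index"] = base["patient_id"].map(inpat).fillna(False).astype(bool)

    def _merge_flag(sub: pd.DataFrame, name: str, lo_off, hi_off, day_col="day") -> pd.Series:
        """True per patient iff any row day in [index+lo_off, index+hi_off]."""
        if sub.empty:
            return pd.Series(False, index=base["patient_id"])
        m = sub.merge(idx, on="patient_id")
        hit = m[(m[day_col] >= m["index_day"] + lo_off) & (m[day_col] <= m["index_day"] + hi_off)]
        flag = pd.Series(False, index=base["patient_id"])
        flag.loc[flag.index.isin(hit["patient_id"])] = True
        return flag

    pids = base["patient_id"]
    endo = _merge_flag(
        diagnoses[diagnoses["condition"] == "endoscopy"], "endo", -endoscopy_window, endoscopy_window
    )
    chronic = _merge_flag(
        diagnoses[diagnoses["condition"].isin(chronic_classes)], "chronic", -(10**9), -1
    )
    indic = _merge_flag(
        diagnoses[diagnoses["condition"].isin(indication_classes)], "indic", -(10**9), -1
    )
    ppi = fills[fills["drug_class"] == "ppi"] if len(fills) else fills
    washed = _merge_flag(ppi, "wash", -washout[0], -washout[1])
    initiated = _merge_flag(ppi, "init", 0, initiation_window)
    gi_bleed = _merge_flag(
        diagnoses[diagnoses["condition"] == "gi_bleed"], "gib", -gi_bleed_window, gi_bleed_window
    )

    conds = []
    choices = []
    if min_index_day is not None:
        conds.append((base["index_day"] < min_index_day).to_numpy())
        choices.append("index_before_restriction")
    conds += [
        ~endo.loc[pids].to_numpy(),
        chronic.loc[pids].to_numpy(),
        indic.loc[pids].to_numpy(),
        washed.loc[pids].to_numpy(),
        ~initiated.loc[pids].to_numpy(),
    ]
    choices += list(EXCLUSION_ORDER)
    reason = np.select(conds, choices, default="")

    out = base.copy()
    out["gi_bleed_at_index"] = out["patient_id"].map(gi_bleed).astype(bool)
    out["eligible"] = reason == ""
    out["exclusion_reason"] = np.where(reason == "", None, reason)
    return out.sort_values("patient_id", kind="stable").reset_index(drop=True)


def attrition_table(cohort: pd.DataFrame, min_index_day: int | None = None) -> pd.DataFrame:
    """Ordered attrition counts: emitted patients, each exclusion step, eligible.

    Counts satisfy ``emitted == eligible + sum(excluded-by-reason)`` and are
    invariant to input ordering.
    """
    steps = ["patients_with_acute_pud"]
    counts = [len(cohort)]
    order = (("index_before_restriction",) if min_index_day is not None else ()) + EXCLUSION_ORDER
    for reason in order:
        steps.append(f"excluded_{reason}")
        counts.append(int((cohort["exclusion_reason"] == reason).sum()) if len(cohort) else 0)
    steps.append("eligible")
    counts.append(int(cohort["eligible"].sum()) if len(cohort) else 0)
    return pd.DataFrame({"step": steps, "count": counts})
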