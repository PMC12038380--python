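"""Prescription-duration classification and the gastroprotection rule engine.

A filled PPI prescription *exceeds the approved duration* when its supply
runs past 60 days after the index acute-PUD diagnosis (8-week approved
course, rounded up to 60 days because US prescriptions are typically
written in 30-day increments).  Two classes of exception reclassify a fill
as approved:

* the *H. pylori* exception — a fill whose supply ends within 60 days of
  the patient's first *H. pylori* diagnosis covers eradication therapy;
* (secondary analysis) the patient meets any active *gastroprotection
  guideline*, a calendar-gated combination of co-medication exposure, age
  and bleeding history under which long-term PPI use is indicated.

Each fill is classified on its own dates: leftover backstock from earlier
fills is deliberately ignored, since prescribers do not net out remaining
supply when renewing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

APPROVED_THRESHOLD_DAYS = 60
HP_MARGIN_DAYS = 60
DEFAULT_GRACE_DAYS = 30


class DataError(ValueError):
    """Raised on structurally invalid input rows."""


# ---------------------------------------------------------------------------
# single-fill classification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClassifiedFill:
    patient_id: int
    fill_date: int
    days_supply: int
    supply_end: int
    status: str  # "approved" | "exceeds"
    reason: str  # "within_60d" | "hp_exception" | "gastroprotection" | "post_endoscopy" | "exceeds"
    prescriber_type: str = ""


def classify_fill(
    fill: dict | pd.Series,
    index_date: int,
    first_hp_date: int | None = None,
    threshold_days: int = APPROVED_THRESHOLD_DAYS,
    hp_margin_days: int = HP_MARGIN_DAYS,
) -> ClassifiedFill:
    """Classify one PPI fill against the approved-duration threshold.

    A fill exceeds the approved duration iff ``supply_end > index + 60``
    (strict: a supply ending exactly on day 60 is approved) and the supply
    does not end within 60 days of the first *H. pylori* diagnosis
    (inclusive: ``supply_end == hp + 60`` is approved).
    """
    fill_date = int(fill["day"] if "day" in fill else fill["fill_date"])
    days_supply = int(fill["days_supply"])
    if days_supply <= 0:
        raise DataError(f"non-positive days_supply {days_supply} on day {fill_date}")
    if fill_date < index_date:
        raise DataError(f"fill on day {fill_date} precedes index day {index_date}")
    supply_end = fill_date + days_supply
    if supply_end <= index_date + threshold_days:
        status, reason = "approved", "within_60d"
    elif first_hp_date is not None and supply_end <= first_hp_date + hp_margin_days:
        status, reason = "approved", "hp_exception"
    else:
        status, reason = "exceeds", "exceeds"
    presc = fill["prescriber_type"] if "prescriber_type" in fill else ""
    return ClassifiedFill(
        patient_id=int(fill["patient_id"]) if "patient_id" in fill else -1,
        fill_date=fill_date,
        days_supply=days_supply,
        supply_end=supply_end,
        status=status,
        reason=reason,
        prescriber_type=str(presc),
    )


# ---------------------------------------------------------------------------
# medication exposure windows
# ---------------------------------------------------------------------------


def merge_windows(windows: Iterable[tuple[float, float]]) -> list[tuple[float, float]]:
    """Union of half-open ``[a, b)`` windows, merged and sorted."""
    ws = sorted(windows)
    if not ws:
        return []
    merged = [list(ws[0])]
    for a, b in ws[1:]:
        if a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return [(a, b) for a, b in merged]


def active_windows(
    fill_days: Sequence[int],
    supplies: Sequence[int],
    grace_days: int = DEFAULT_GRACE_DAYS,
) -> list[tuple[float, float]]:
    """Merged half-open windows ``[fill, fill + supply + grace)`` of active use."""
    return merge_windows(
        (float(d), float(d + s + grace_days)) for d, s in zip(fill_days, supplies)
    )


def medication_active(
    fill_days: Sequence[int],
    supplies: Sequence[int],
    date: float,
    grace_days: int = DEFAULT_GRACE_DAYS,
) -> bool:
    """True iff ``date`` falls inside any ``[fill, fill + supply + grace)`` window."""
    return any(a <= date < b for a, b in active_windows(fill_days, supplies, grace_days))


# ---------------------------------------------------------------------------
# gastroprotection guideline rules
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PatientState:
    """Point-in-time state evaluated by guideline predicates."""

    age: float
    active_classes: frozenset[str]
    pud_history: bool = True  # post-index this is true by cohort construction
    gi_bleed_history: bool = False

    def on(self, cls: str) -> bool:
        return cls in self.active_classes

    def n_antithrombotic_or_nsaid(self) -> int:
        return sum(
            self.on(c) for c in ("aspirin", "nsaid", "anticoagulant", "antiplatelet")
        )


@dataclass(frozen=True)
class GuidelineRule:
    """One gastroprotection criterion with its calendar activation gate.

    ``introduced_year`` is the guideline's publication year; the rule is
    assessed only from January 1 of the following year onward.
    """

    rule_id: str
    introduced_year: int
    predicate: Callable[[PatientState], bool] = field(compare=False)

    @property
    def activation_year(self) -> int:
        return self.introduced_year + 1


def default_guideline_rules(
    activation_overrides: dict[str, int] | None = None,
) -> list[GuidelineRule]:
    """The six gastroprotection criteria with their introduction years.

    ``activation_overrides`` maps rule_id to a replacement introduction
    year (the rule still activates the following January 1).
    """
    rules = [
        GuidelineRule(
            "R2009_pud_nsaid", 2009, lambda s: s.pud_history and s.on("nsaid")
        ),
        GuidelineRule("R2010_gi_bleed", 2010, lambda s: s.gi_bleed_history),
        GuidelineRule(
            "R2010_antiplatelet_plus",
            2010,
            lambda s: s.on("antiplatelet")
            and (s.age > 65 or s.on("anticoagulant") or s.on("nsaid") or s.on("aspirin")),
        ),
        GuidelineRule(
            "R2017_aspirin_antiplatelet",
            2017,
            lambda s: s.on("aspirin") and s.on("antiplatelet"),
        ),
        GuidelineRule(
            "R2018_aspirin_anticoagulant",
            2018,
            lambda s: s.on("aspirin") and s.on("anticoagulant"),
        ),
        GuidelineRule(
            "R2020_two_or_more", 2020, lambda s: s.n_antithrombotic_or_nsaid() >= 2
        ),
    ]
    if activation_overrides:
        rules = [
            GuidelineRule(r.rule_id, activation_overrides.get(r.rule_id, r.introduced_year), r.predicate)
            for r in rules
        ]
    return rules


def gastroprotection_qualifies(
    state: PatientState,
    year: int,
    rules: Sequence[GuidelineRule] | None = None,
) -> tuple[bool, str | None]:
    """Evaluate all active rules at a calendar year; returns the first match.

    Rules are checked in their declared (chronological) order; a rule is
    active when ``year >= introduced_year + 1``.
    """
    for rule in rules if rules is not None else default_guideline_rules():
        if year >= rule.activation_year and rule.predicate(state):
            return True, rule.rule_id
    return False, None


# ---------------------------------------------------------------------------
# per-patient qualification timing
# ---------------------------------------------------------------------------

GASTRO_CLASSES = ("aspirin", "nsaid", "anticoagulant", "antiplatelet")


def _class_windows(
    fills: pd.DataFrame, grace_days: int
) -> dict[str, list[tuple[float, float]]]:
    out: dict[str, list[tuple[float, float]]] = {}
    for cls, grp in fills.groupby("drug_class"):
        out[str(cls)] = active_windows(
            grp["day"].to_numpy(), grp["days_supply"].to_numpy(), grace_days
        )
    return out


def _state_at(
    day: float,
    windows: dict[str, list[tuple[float, float]]],
    age_at_index: float,
    index_day: int,
    gi_bleed_days: np.ndarray,
) -> PatientState:
    active = frozenset(
        cls
        for cls, ws in windows.items()
        if any(a <= day < b for a, b in ws)
    )
    return PatientState(
        age=age_at_index + (day - index_day) / 365.25,
        active_classes=active,
        pud_history=day >= index_day,
        gi_bleed_history=bool((gi_bleed_days <= day).any()),
    )


def first_qualification_day(
    patient_fills: pd.DataFrame,
    index_day: int,
    age_at_index: float,
    gi_bleed_days: Sequence[int] = (),
    horizon_day: int | None = None,
    rules: Sequence[GuidelineRule] | None = None,
    grace_days: int = DEFAULT_GRACE_DAYS,
    year_of: Callable[[float], int] | None = None,
) -> int | None:
    """First day on/after index when any active guideline predicate holds.

    The patient state is piecewise constant between *breakpoints* —
    medication window edges, GI-bleed dates, rule activation days and the
    day the patient turns 66 — so scanning breakpoints finds the exact
    first qualification time.  Returns ``None`` when the patient never
    qualifies before ``horizon_day``.
    """
    if rules is None:
        rules = default_guideline_rules()
    if year_of is None:  # default epoch 1999-01-01
        import datetime as dt

        epoch = dt.date(1999, 1, 1)
        year_of = lambda d: (epoch + dt.timedelta(days=int(d))).year
    gi = np.asarray(sorted(gi_bleed_days), dtype=float)
    med = patient_fills[patient_fills["drug_class"].isin(GASTRO_CLASSES)]
    windows = _class_windows(med, grace_days)

    points: set[float] = {float(index_day)}
    for ws in windows.values():
        for a, b in ws:
            points.add(a)
            points.add(b)
    points.update(float(d) for d in gi)
    # rule activations: first day of each activation year
    import datetime as dt

    epoch_guess = None
    for r in rules:
        # convert Jan 1 of activation year to a day via the supplied year_of
        # by bisection over a wide day range
        lo, hi = -40000.0, 80000.0
        target = r.activation_year
        if year_of(lo) >= target or year_of(hi) < target:
            continue
        while hi - lo > 0.5:
            mid = (lo + hi) / 2
            if year_of(mid) >= target:
                hi = mid
            else:
                lo = mid
        points.add(float(np.floor(hi)))
    # day the patient turns 66 (age > 65 threshold of the antiplatelet rule)
    turn66 = index_day + (66.0 - age_at_index) * 365.25
    points.add(float(np.ceil(turn66)))

    hi_day = horizon_day if horizon_day is not None else index_day + 10 * 365
    cand = sorted(p for p in points if index_day <= p <= hi_day)
    for day in cand:
        state = _state_at(day, windows, age_at_index, index_day, gi)
        ok, _ = gastroprotection_qualifies(state, year_of(day), rules)
        if ok:
            return int(day)
    return None


# ---------------------------------------------------------------------------
# cohort-level classification
# ---------------------------------------------------------------------------


def classify_fills(
    fills: pd.DataFrame,
    cohort: pd.DataFrame,
    tests: pd.DataFrame,
    threshold_days: int = APPROVED_THRESHOLD_DAYS,
    hp_margin_days: int = HP_MARGIN_DAYS,
    gastroprotection_days: dict[int, int] | None = None,
    post_endoscopy_windows: dict[int, list[tuple[int, int]]] | None = None,
) -> pd.DataFrame:
    """Classify every PPI fill of eligible cohort patients.

    Parameters
    ----------
    gastroprotection_days:
        Optional map patient_id -> first guideline-qualification day;
        fills on/after that day are reclassified as approved
        (secondary analysis).
    post_endoscopy_windows:
        Optional map patient_id -> list of ``(endo_day, endo_day + 60]``
        follow-up endoscopy windows; fills inside a window are approved
        (delayed-healing sensitivity analysis).

    Returns the classified-fills table with columns ``patient_id, day,
    days_supply, supply_end, status, reason, prescriber_type``.
    """
    elig = cohort[cohort["eligible"].astype(bool)]
    index_by_pid = pd.Series(
        elig["index_day"].to_numpy(), index=elig["patient_id"].to_numpy()
    )

    hp_by_pid = pd.Series(dtype=float)
    if len(tests):
        hp = tests[tests["test_type"] == "h_pylori"] if "test_type" in tests else tests
        pos = hp[hp["result"].astype(str).str.lower() == "positive"]
        if len(pos):
            hp_by_pid = pos.groupby("patient_id")["day"].min()

    ppi = fills[fills["drug_class"] == "ppi"].copy()
    ppi["index_day"] = ppi["patient_id"].map(index_by_pid)
    ppi = ppi[ppi["index_day"].notna()]
    ppi = ppi[ppi["day"] >= ppi["index_day"]]  # pre-index fills handled by eligibility
    if (ppi["days_supply"] <= 0).any():
        bad = ppi[ppi["days_supply"] <= 0].iloc[0]
        raise DataError(
            f"non-positive days_supply for patient {int(bad['patient_id'])} "
            f"on day {int(bad['day'])}"
        )

    day = ppi["day"].to_numpy(np.int64)
    supply = ppi["days_supply"].to_numpy(np.int64)
    supply_end = day + supply
    index_day = ppi["index_day"].to_numpy(np.int64)
    hp_day = ppi["patient_id"].map(hp_by_pid).to_numpy(float)

    within = supply_end <= index_day + threshold_days
    hp_ok = ~within & ~np.isnan(hp_day) & (supply_end <= hp_day + hp_margin_days)
    exceeds = ~within & ~hp_ok
    reason = np.where(
        within, "within_60d", np.where(hp_ok, "hp_exception", "exceeds")
    ).astype(object)

    if post_endoscopy_windows:
        pids = ppi["patient_id"].to_numpy()
        for i in np.flatnonzero(exceeds):
            for a, b in post_endoscopy_windows.get(int(pids[i]), ()):
                if a <= day[i] <= b:
                    exceeds[i] = False
                    reason[i] = "post_endoscopy"
                    break
    if gastroprotection_days:
        qday = ppi["patient_id"].map(pd.Series(gastroprotection_days)).to_numpy(float)
        gastro = exceeds & ~np.isnan(qday) & (day >= qday)
        exceeds &= ~gastro
        reason = np.where(gastro, "gastroprotection", reason)

    out = pd.DataFrame(
        {
            "patient_id": ppi["patient_id"].to_numpy(np.int64),
            "day": day,
            "days_supply": supply,
            "supply_end": supply_end,
            "status": np.where(exceeds, "exceeds", "approved"),
            "reason": reason,
            "prescriber_type": ppi["prescriber_type"].astype(str).to_numpy()
            if "prescriber_type" in ppi
            else "",
        }
    )
    return out.sort_values(["patient_id", "day"], kind="stable").reset_index(drop=True)
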