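"""Configuration objects shared across the pipeline.

All dates in the flat tables are integer day offsets from a configurable
study start date (``StudyCalendar.study_start``).  Calendar years — needed
by the gastroprotection rule engine and the regional deprescribing cutoff —
are derived from that epoch, so the whole pipeline works on plain integers.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import math
from dataclasses import dataclass, field
from typing import Mapping

import yaml


class ConfigurationError(ValueError):
    """Raised when a configuration value is out of its valid range."""


# ---------------------------------------------------------------------------
# calendar
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StudyCalendar:
    """Maps integer day offsets to calendar dates.

    Parameters
    ----------
    study_start:
        Day 0 of the simulated/observed record.
    end_of_data:
        Last day with data; acts as administrative censoring.
    """

    study_start: dt.date = dt.date(1999, 1, 1)
    end_of_data: dt.date = dt.date(2022, 12, 31)

    def to_day(self, date: dt.date) -> int:
        return (date - self.study_start).days

    def to_date(self, day: int) -> dt.date:
        return self.study_start + dt.timedelta(days=int(day))

    def year_of(self, day: int) -> int:
        return self.to_date(day).year

    @property
    def end_of_data_day(self) -> int:
        return self.to_day(self.end_of_data)


# ---------------------------------------------------------------------------
# synthetic cohort generator
# ---------------------------------------------------------------------------

#: Generative log-hazards for the recurrent exceeding-fill intensity.  The
#: defaults are the adjusted hazard ratios of the final multivariable model
#: (inpatient diagnosis 1.32, NSAIDs 1.26, anticoagulants 1.25, aspirin 1.15,
#: Black race 0.83, female sex 0.91, frailty levels vs. nonfrail).
DEFAULT_LOG_HAZARDS: dict[str, float] = {
    "inpatient": math.log(1.32),
    "black": math.log(0.83),
    "female": math.log(0.91),
    "prefrail": math.log(1.06),
    "mildly_frail": math.log(1.11),
    "moderately_frail": math.log(1.15),
    "severely_frail": math.log(1.08),
    "nsaid": math.log(1.26),
    "aspirin": math.log(1.15),
    "anticoagulant": math.log(1.25),
}

#: Baseline binary-factor prevalences (analytic-cohort marginals: 18%
#: inpatient diagnoses, 18% Black race, 7% female).
DEFAULT_PREVALENCES: dict[str, float] = {
    "inpatient": 0.18,
    "black": 0.18,
    "female": 0.07,
}

#: Frailty category distribution (nonfrail is the reference level).
DEFAULT_FRAILTY_DIST: dict[str, float] = {
    "nonfrail": 0.24,
    "prefrail": 0.43,
    "mildly_frail": 0.22,
    "moderately_frail": 0.08,
    "severely_frail": 0.03,
}

#: Episode onset rates (episodes / person-year) for co-medications.
DEFAULT_MED_EPISODE_RATES: dict[str, float] = {
    "nsaid": 0.9,
    "aspirin": 0.35,
    "anticoagulant": 0.25,
    "antiplatelet": 0.15,
    "h2ra": 0.10,
}

#: Episode durations in days.  Analgesic courses are short; antithrombotic
#: therapy tends to run for months once started.
DEFAULT_MED_EPISODE_DURATIONS: dict[str, float] = {
    "nsaid": 60.0,
    "aspirin": 180.0,
    "anticoagulant": 180.0,
    "antiplatelet": 180.0,
    "h2ra": 60.0,
}

#: Rates (events / person-year) of post-index censoring/qualifying events.
DEFAULT_CENSOR_RATES: dict[str, float] = {
    "new_ppi_indication": 0.04,
    "gi_bleed": 0.02,
}

#: Prescriber mix for PPI fills (44% primary care, 18% residents/fellows,
#: 16% advanced practice providers, 16% gastroenterologists).
DEFAULT_PRESCRIBER_DIST: dict[str, float] = {
    "primary_care": 0.44,
    "resident_fellow": 0.18,
    "advanced_practice": 0.16,
    "gastroenterology": 0.16,
    "other": 0.06,
}

DEFAULT_RACE_DIST: dict[str, float] = {
    "white": 0.72,
    "black": 0.18,
    "other": 0.10,
}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic EHR cohort generator.

    The generator draws recurrent PPI fills from a multiplicative intensity
    ``lambda_i(t) = baseline_intensity * exp(sum_k beta_k Z_ik(t))`` by
    thinning, where ``Z`` collects baseline indicators and time-varying
    co-medication exposure.  Identical seeds yield bit-identical tables.
    """

    n_patients: int = 2000
    horizon_days: int = 1095
    true_log_hazards: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LOG_HAZARDS)
    )
    factor_prevalences: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCES)
    )
    frailty_distribution: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FRAILTY_DIST)
    )
    baseline_intensity: float = 0.0009  # fills / day  (~0.33 / person-year)
    med_episode_rates: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MED_EPISODE_RATES)
    )
    med_episode_duration: dict[str, float] | float = field(
        default_factory=lambda: dict(DEFAULT_MED_EPISODE_DURATIONS)
    )
    censor_rates: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CENSOR_RATES)
    )
    hp_positive_fraction: float = 0.20
    seed: int = 0

    # dispensing conventions
    days_supply_choices: tuple[int, ...] = (30, 60, 90)
    days_supply_probs: tuple[float, ...] = (0.85, 0.10, 0.05)
    exposure_grace_days: int = 30  # must match the analysis ascertainment rule

    # calendar structure
    calendar: StudyCalendar = field(default_factory=StudyCalendar)
    index_start: dt.date = dt.date(2000, 1, 1)
    index_end: dt.date = dt.date(2019, 12, 31)

    # demographic structure
    age_mean: float = 78.0
    age_sd: float = 8.0
    age_min: int = 40
    age_max: int = 100
    race_distribution: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RACE_DIST)
    )
    n_visn: int = 18
    visn17_fraction: float = 0.05
    prescriber_distribution: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PRESCRIBER_DIST)
    )

    # follow-up endoscopies (used by the delayed-healing sensitivity analysis)
    followup_endoscopy_rate: float = 0.15  # per person-year

    # fractions of deliberately ineligible patients, to exercise attrition
    ineligible_fractions: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ConfigurationError("n_patients must be positive")
        if self.horizon_days <= 0:
            raise ConfigurationError("horizon_days must be positive")
        if self.baseline_intensity < 0:
            raise ConfigurationError("baseline_intensity must be >= 0")
        for name, p in {
            **self.factor_prevalences,
            **self.frailty_distribution,
            "hp_positive_fraction": self.hp_positive_fraction,
            "visn17_fraction": self.visn17_fraction,
            **self.ineligible_fractions,
        }.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"probability {name}={p} outside [0, 1]")
        for name, r in {**self.med_episode_rates, **self.censor_rates}.items():
            if r < 0:
                raise ConfigurationError(f"rate {name}={r} must be >= 0")

    def episode_duration(self, drug_class: str) -> float:
        if isinstance(self.med_episode_duration, Mapping):
            return float(
                self.med_episode_duration.get(
                    drug_class, DEFAULT_MED_EPISODE_DURATIONS.get(drug_class, 90.0)
                )
            )
        return float(self.med_episode_duration)

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)


# ---------------------------------------------------------------------------
# censoring plan
# ---------------------------------------------------------------------------


@dataclass
class CensorPlan:
    """Censoring rules applied when building the counting-process data.

    Follow-up ends at the earliest of: a new indication for long-term PPI
    use, the administrative follow-up cap (3 years; 5 in sensitivity), the
    regional deprescribing-program cutoff for patients diagnosed in the
    flagged network (VISN 17, 2013-08-01), the end of data, and — in the
    secondary analysis — the first date the patient qualifies under any
    gastroprotection guideline.
    """

    max_followup: int = 1095
    visn17_cutoff: dt.date = dt.date(2013, 8, 1)
    visn17_network: int = 17
    indication_censoring: bool = True
    guideline_censoring: bool = False

    def __post_init__(self) -> None:
        if self.max_followup <= 0:
            raise ConfigurationError("max_followup must be positive")


# ---------------------------------------------------------------------------
# analysis run configuration
# ---------------------------------------------------------------------------

SENSITIVITY_MODES = (
    "none",
    "followup_5y",
    "post_endoscopy_60d_approved",
    "restrict_2010_plus",
    "frailty_recomputed",
)


@dataclass
class RunConfig:
    """End-to-end pipeline configuration."""

    input_dir: str = "."
    output_dir: str = "results"
    analysis: str = "primary"  # or "gastroprotection_secondary"
    sensitivity: str = "none"
    seed: int = 0

    endoscopy_window_days: int = 30  # "in conjunction with" window, +/- days
    washout_days: tuple[int, int] = (365, 14)
    initiation_window_days: int = 14
    approved_threshold_days: int = 60
    hp_margin_days: int = 60
    grace_days: int = 30
    excess_days_definition: str = "supply_sum"  # or "covered_after_60"
    guideline_activation: dict[str, int] | None = None

    # model specification
    model_baseline_factors: tuple[str, ...] = ("inpatient", "black", "female", "frailty")
    model_tv_classes: tuple[str, ...] = ("nsaid", "aspirin", "anticoagulant")
    parsimonious: bool = False
    paf_factors: tuple[str, ...] = ("inpatient", "nsaid", "anticoagulant", "aspirin")
    paf_variant: str = "cumulative_incidence"
    n_bootstrap: int = 0  # 0 disables PAF bootstrap bands

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    censoring: CensorPlan = field(default_factory=CensorPlan)

    def __post_init__(self) -> None:
        if self.analysis not in ("primary", "gastroprotection_secondary"):
            raise ConfigurationError(f"unknown analysis mode {self.analysis!r}")
        if self.sensitivity not in SENSITIVITY_MODES:
            raise ConfigurationError(f"unknown sensitivity mode {self.sensitivity!r}")
        if self.excess_days_definition not in ("supply_sum", "covered_after_60"):
            raise ConfigurationError(
                f"unknown excess-days definition {self.excess_days_definition!r}"
            )

    def effective_censoring(self) -> CensorPlan:
        """Censoring plan after applying analysis/sensitivity modes."""
        plan = dataclasses.replace(self.censoring)
        if self.sensitivity == "followup_5y":
            plan.max_followup = 1825
        if self.analysis == "gastroprotection_secondary":
            plan.guideline_censoring = True
        return plan


# ---------------------------------------------------------------------------
# YAML round-trip
# ---------------------------------------------------------------------------

_DATE_FIELDS = {"study_start", "end_of_data", "index_start", "index_end", "visn17_cutoff"}


def _parse_dates(d: dict) -> dict:
    out = {}
    for k, v in d.items():
        if k in _DATE_FIELDS and isinstance(v, str):
            out[k] = dt.date.fromisoformat(v)
        else:
            out[k] = v
    return out


def load_run_config(path: str, seed: int | None = None) -> RunConfig:
    """Load a :class:`RunConfig` from a YAML file.

    ``seed``, when given (e.g. from a ``--seed`` CLI flag), overrides both
    the run seed and the simulation seed in the file.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim_raw = _parse_dates(raw.pop("simulation", {}) or {})
    cal_raw = {k: sim_raw.pop(k) for k in ("study_start", "end_of_data") if k in sim_raw}
    if cal_raw:
        sim_raw["calendar"] = StudyCalendar(**cal_raw)
    cens_raw = _parse_dates(raw.pop("censoring", {}) or {})
    cfg = RunConfig(
        simulation=SimulationConfig(**sim_raw),
        censoring=CensorPlan(**cens_raw),
        **{k: tuple(v) if k == "washout_days" else v for k, v in _parse_dates(raw).items()},
    )
    if seed is not None:
        cfg.seed = seed
        cfg.simulation.seed = seed
    return cfg
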