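"""Seeded synthetic EHR/claims cohort generator.

Emulates the longitudinal structure the downstream analysis assumes: a
new-user cohort of patients with an acute peptic ulcer disease (PUD)
diagnosis, an index endoscopy, a qualifying PPI fill shortly after
diagnosis, recurrent PPI fills whose intensity depends multiplicatively on
baseline factors and time-varying co-medication exposure, co-medication
dispensing episodes, *H. pylori* test results, and post-index events that
censor follow-up (new PPI indications) or qualify patients under
gastroprotection guidelines (GI bleeds).

Recurrent PPI fills are drawn from the proportional-intensity model

    lambda_i(t) = lambda0 * exp(sum_k beta_k * Z_ik(t)),   t in (0, horizon]

by thinning against the patient-specific bound
``lambda0 * exp(eta_base_i + sum_k max(beta_k, 0))``.  Covariate paths are
piecewise constant, so the acceptance step only needs interval membership
tests.  The *time-varying* covariate used during generation is the same
operational exposure definition the analysis reconstructs: days covered by
dispensed supply plus a grace window (see :func:`classify.active_windows`),
which keeps generation and ascertainment self-consistent.

All dates are integer day offsets from ``config.calendar.study_start``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import SimulationConfig

DAYS_PER_YEAR = 365.25

#: co-medication drug classes with a generative effect on the fill intensity
TIME_VARYING_CLASSES = ("nsaid", "aspirin", "anticoagulant")

FRAILTY_LEVELS = (
    "nonfrail",
    "prefrail",
    "mildly_frail",
    "moderately_frail",
    "severely_frail",
)


def _rng(config: SimulationConfig, rng: np.random.Generator | None) -> np.random.Generator:
    return rng if rng is not None else np.random.default_rng(config.seed)


# ---------------------------------------------------------------------------
# patients
# ---------------------------------------------------------------------------


def generate_patients(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Draw the baseline patient table.

    Binary factor indicators are drawn independently at the configured
    prevalences; every key of ``config.factor_prevalences`` becomes a 0/1
    column, so ad-hoc factors (e.g. a pure-noise covariate for calibration
    studies) need no code change.  Frailty is a five-level category drawn
    from ``config.frailty_distribution``.
    """
    config.validate()
    rng = _rng(config, rng)
    n = config.n_patients
    cal = config.calendar

    df = pd.DataFrame({"patient_id": np.arange(n, dtype=np.int64)})
    lo, hi = cal.to_day(config.index_start), cal.to_day(config.index_end)
    df["index_day"] = rng.integers(lo, hi + 1, size=n)

    age = rng.normal(config.age_mean, config.age_sd, size=n)
    df["age"] = np.clip(np.round(age), config.age_min, config.age_max).astype(int)

    for factor, prev in config.factor_prevalences.items():
        df[factor] = (rng.random(n) < prev).astype(np.int8)

    # race category consistent with the 'black' indicator when present
    if "black" in df.columns:
        other = [r for r in config.race_distribution if r != "black"]
        w = np.array([config.race_distribution[r] for r in other], dtype=float)
        w = w / w.sum() if w.sum() > 0 else np.full(len(other), 1 / len(other))
        alt = rng.choice(other, size=n, p=w)
        df["race"] = np.where(df["black"] == 1, "black", alt)
    else:
        races = list(config.race_distribution)
        w = np.array(list(config.race_distribution.values()), dtype=float)
        df["race"] = rng.choice(races, size=n, p=w / w.sum())

    levels = list(config.frailty_distribution)
    w = np.array(list(config.frailty_distribution.values()), dtype=float)
    df["frailty"] = rng.choice(levels, size=n, p=w / w.sum())
    # alternative frailty, recomputed without antithrombotic indications:
    # a random 15% of non-reference patients drop one level
    order = {lev: i for i, lev in enumerate(FRAILTY_LEVELS)}
    idx = df["frailty"].map(order).to_numpy()
    drop = (rng.random(n) < 0.15) & (idx > 0)
    df["frailty_alt"] = [FRAILTY_LEVELS[i - 1] if d else FRAILTY_LEVELS[i]
                         for i, d in zip(idx, drop)]

    df["charlson"] = rng.poisson(2.5, size=n)
    df["concurrent_rx"] = rng.negative_binomial(3, 3 / (3 + 6.5), size=n)

    visn = rng.integers(1, config.n_visn + 1, size=n)
    in17 = rng.random(n) < config.visn17_fraction
    df["visn"] = np.where(in17, 17, np.where(visn == 17, 1, visn))
    df["facility"] = df["visn"] * 100 + rng.integers(0, 10, size=n)
    return df


def _patient_eta_base(patients: pd.DataFrame, config: SimulationConfig) -> np.ndarray:
    """Baseline (time-fixed) linear predictor per patient."""
    eta = np.zeros(len(patients))
    for factor, beta in config.true_log_hazards.items():
        if factor in TIME_VARYING_CLASSES:
            continue
        if factor in FRAILTY_LEVELS:
            eta += beta * (patients["frailty"] == factor).to_numpy(float)
        elif factor in patients.columns:
            eta += beta * patients[factor].to_numpy(float)
        # unknown factors without a column contribute nothing
    return eta


# ---------------------------------------------------------------------------
# co-medication episodes and exposure paths
# ---------------------------------------------------------------------------


def _merge_windows(windows: list[tuple[float, float]]) -> list[tuple[float, float]]:
    """Union of half-open [a, b) windows."""
    if not windows:
        return []
    windows = sorted(windows)
    merged = [list(windows[0])]
    for a, b in windows[1:]:
        if a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return [(a, b) for a, b in merged]


def _episode_fills(
    start: float, duration: float, supply: int = 30
) -> list[tuple[int, int]]:
    """Successive 30-day fills covering one dispensing episode."""
    n_fills = max(1, int(np.ceil(duration / supply)))
    return [(int(round(start)) + k * supply, supply) for k in range(n_fills)]


def simulate_fill_process(
    patients: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate all prescription fills (PPI and co-medications).

    Returns a fills table with columns ``patient_id, day, drug_class,
    days_supply, prescriber_type``.  Per patient:

    1. co-medication episodes per drug class arrive as a Poisson process
       (rate ``med_episode_rates``/year) over ``[index - 180, index +
       horizon]`` and are dispensed as successive 30-day fills covering the
       episode duration;
    2. the PPI exposure-relevant covariate path is the union of supply
       windows extended by ``exposure_grace_days``;
    3. the initial qualifying PPI fill lands uniformly in ``[index,
       index + 14]`` (always emitted unless the patient carries the
       ``no_initial_fill`` ineligibility flag);
    4. further PPI fills are drawn by thinning from the multiplicative
       intensity on ``(0, horizon]`` (days since index).
    """
    config.validate()
    rng = _rng(config, rng)
    n = len(patients)
    horizon = float(config.horizon_days)
    grace = float(config.exposure_grace_days)
    eta_base = _patient_eta_base(patients, config)

    tv_classes = [c for c in TIME_VARYING_CLASSES if c in config.true_log_hazards]
    tv_betas = np.array([config.true_log_hazards[c] for c in tv_classes])
    eta_bound = eta_base + tv_betas.clip(min=0.0).sum() if len(tv_betas) else eta_base

    no_init = patients["no_initial_fill"].to_numpy(bool) if "no_initial_fill" in patients else np.zeros(n, bool)

    supply_choices = np.asarray(config.days_supply_choices)
    supply_probs = np.asarray(config.days_supply_probs, dtype=float)
    supply_probs = supply_probs / supply_probs.sum()
    presc_types = list(config.prescriber_distribution)
    presc_w = np.array(list(config.prescriber_distribution.values()), dtype=float)
    presc_w /= presc_w.sum()

    pid_out: list[int] = []
    day_out: list[int] = []
    class_out: list[str] = []
    supply_out: list[int] = []

    index_days = patients["index_day"].to_numpy()
    # windows[c][i]: merged exposure windows in days-since-index, incl. grace
    exposure: dict[str, list[list[tuple[float, float]]]] = {c: [] for c in tv_classes}

    class_rates = dict(config.med_episode_rates)
    for c in tv_classes:  # a modelled class with no configured rate has rate 0
        class_rates.setdefault(c, 0.0)

    for i in range(n):
        pid = int(patients["patient_id"].iloc[i])
        idx = int(index_days[i])

        for cls, rate in class_rates.items():
            span = horizon + 180.0
            k = rng.poisson(rate * span / DAYS_PER_YEAR)
            if k == 0:
                if cls in exposure:
                    exposure[cls].append([])
                continue
            starts = np.sort(rng.uniform(-180.0, horizon, size=k))
            dur = config.episode_duration(cls)
            wins = []
            for s in starts:
                for d, sup in _episode_fills(s, dur):
                    pid_out.append(pid)
                    day_out.append(idx + d)
                    class_out.append(cls)
                    supply_out.append(sup)
                    wins.append((float(d), float(d + sup + grace)))
            if cls in exposure:
                exposure[cls].append(_merge_windows(wins))

    # initial qualifying PPI fill
    init_offsets = rng.integers(0, 15, size=n)
    # recurrent PPI fills by thinning
    lam0 = config.baseline_intensity
    for i in range(n):
        pid = int(patients["patient_id"].iloc[i])
        idx = int(index_days[i])
        if not no_init[i]:
            pid_out.append(pid)
            day_out.append(idx + int(init_offsets[i]))
            class_out.append("ppi")
            supply_out.append(30)
        lam_max = lam0 * np.exp(eta_bound[i])
        if lam_max <= 0:
            continue
        n_cand = rng.poisson(lam_max * horizon)
        if n_cand == 0:
            continue
        cand = np.sort(rng.uniform(0.0, horizon, size=n_cand))
        eta_t = np.full(n_cand, eta_base[i])
        for c, beta in zip(tv_classes, tv_betas):
            wins = exposure[c][i]
            if not wins:
                continue
            active = np.zeros(n_cand, bool)
            for a, b in wins:
                active |= (cand >= a) & (cand < b)
            eta_t += beta * active
        accept = rng.random(n_cand) < np.exp(eta_t - eta_bound[i])
        for t in cand[accept]:
            pid_out.append(pid)
            day_out.append(idx + int(np.ceil(t)))
            class_out.append("ppi")
            supply_out.append(int(rng.choice(supply_choices, p=supply_probs)))

    fills = pd.DataFrame(
        {
            "patient_id": np.array(pid_out, dtype=np.int64),
            "day": np.array(day_out, dtype=np.int64),
            "drug_class": class_out,
            "days_supply": np.array(supply_out, dtype=np.int64),
        }
    )
    fills["prescriber_type"] = rng.choice(presc_types, size=len(fills), p=presc_w)
    fills = fills.sort_values(["patient_id", "day", "drug_class"], kind="stable")
    return fills.reset_index(drop=True)


# ---------------------------------------------------------------------------
# censoring / qualifying events
# ---------------------------------------------------------------------------


def simulate_censoring_events(
    patients: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Post-index events that end or re-qualify follow-up.

    New long-term PPI indications (e.g. GERD or Barrett's esophagus) and GI
    bleeds arrive with exponential times at the configured yearly rates;
    a configured fraction of patients receives a positive *H. pylori*
    result within two weeks of the index diagnosis.  Returns an events
    table ``patient_id, day, condition, inpatient`` where every day is
    strictly on/after the patient's index day.
    """
    config.validate()
    rng = _rng(config, rng)
    n = len(patients)
    idx = patients["index_day"].to_numpy()
    rows: list[pd.DataFrame] = []

    for cause, rate in config.censor_rates.items():
        cond = "ppi_indication" if cause == "new_ppi_indication" else cause
        if rate <= 0:
            continue
        t = rng.exponential(DAYS_PER_YEAR / rate, size=n)
        keep = t <= config.horizon_days
        if keep.any():
            rows.append(
                pd.DataFrame(
                    {
                        "patient_id": patients["patient_id"].to_numpy()[keep],
                        "day": (idx[keep] + np.ceil(t[keep])).astype(np.int64),
                        "condition": cond,
                        "inpatient": 0,
                    }
                )
            )

    hp = rng.random(n) < config.hp_positive_fraction
    if hp.any():
        offs = rng.integers(0, 15, size=int(hp.sum()))
        rows.append(
            pd.DataFrame(
                {
                    "patient_id": patients["patient_id"].to_numpy()[hp],
                    "day": (idx[hp] + offs).astype(np.int64),
                    "condition": "h_pylori",
                    "inpatient": 0,
                }
            )
        )

    if not rows:
        return pd.DataFrame(
            columns=["patient_id", "day", "condition", "inpatient"]
        ).astype({"patient_id": np.int64, "day": np.int64, "inpatient": np.int64})
    out = pd.concat(rows, ignore_index=True)
    return out.sort_values(["patient_id", "day"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# full table bundle
# ---------------------------------------------------------------------------


def simulate_tables(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> dict[str, pd.DataFrame]:
    """Generate the four flat input tables: patients, diagnoses, fills, tests.

    ``config.ineligible_fractions`` can flag random patient subsets that
    violate one eligibility rule each (``no_endoscopy``,
    ``prior_chronic_pud``, ``prior_indication``, ``washout_ppi``,
    ``no_initial_fill``) so cohort attrition has work to do; all default
    to zero, i.e. by default the generator emits the analytic cohort.
    """
    config.validate()
    rng = _rng(config, rng)
    patients = generate_patients(config, rng)
    n = len(patients)
    idx = patients["index_day"].to_numpy()

    flags: dict[str, np.ndarray] = {}
    for knob, frac in config.ineligible_fractions.items():
        flags[knob] = rng.random(n) < frac
    if "no_initial_fill" in flags:
        patients = patients.copy()
        patients["no_initial_fill"] = flags["no_initial_fill"].astype(np.int8)

    censor_events = simulate_censoring_events(patients, config, rng)
    fills = simulate_fill_process(patients, config, rng)

    diag_rows = [
        pd.DataFrame(
            {
                "patient_id": patients["patient_id"],
                "day": idx,
                "condition": "acute_pud",
                "inpatient": patients["inpatient"].astype(np.int64)
                if "inpatient" in patients
                else 0,
            }
        )
    ]

    # index endoscopy within a few days of diagnosis
    endo_off = rng.integers(-3, 4, size=n)
    has_endo = ~flags.get("no_endoscopy", np.zeros(n, bool))
    diag_rows.append(
        pd.DataFrame(
            {
                "patient_id": patients["patient_id"].to_numpy()[has_endo],
                "day": (idx + endo_off)[has_endo].astype(np.int64),
                "condition": "endoscopy",
                "inpatient": 0,
            }
        )
    )

    # follow-up endoscopies (delayed-healing sensitivity analysis)
    if config.followup_endoscopy_rate > 0:
        k = rng.poisson(
            config.followup_endoscopy_rate * config.horizon_days / DAYS_PER_YEAR, size=n
        )
        rep = np.repeat(np.arange(n), k)
        if len(rep):
            offs = rng.integers(30, config.horizon_days + 1, size=len(rep))
            diag_rows.append(
                pd.DataFrame(
                    {
                        "patient_id": patients["patient_id"].to_numpy()[rep],
                        "day": (idx[rep] + offs).astype(np.int64),
                        "condition": "endoscopy",
                        "inpatient": 0,
                    }
                )
            )

    for knob, cond, lo, hi in [
        ("prior_chronic_pud", "chronic_pud", 30, 365),
        ("prior_indication", "ppi_indication", 30, 1000),
    ]:
        m = flags.get(knob, np.zeros(n, bool))
        if m.any():
            offs = rng.integers(lo, hi + 1, size=int(m.sum()))
            diag_rows.append(
                pd.DataFrame(
                    {
                        "patient_id": patients["patient_id"].to_numpy()[m],
                        "day": (idx[m] - offs).astype(np.int64),
                        "condition": cond,
                        "inpatient": 0,
                    }
                )
            )

    m = flags.get("washout_ppi", np.zeros(n, bool))
    if m.any():
        offs = rng.integers(14, 366, size=int(m.sum()))
        wash = pd.DataFrame(
            {
                "patient_id": patients["patient_id"].to_numpy()[m],
                "day": (idx[m] - offs).astype(np.int64),
                "drug_class": "ppi",
                "days_supply": 30,
                "prescriber_type": "primary_care",
            }
        )
        fills = pd.concat([fills, wash], ignore_index=True)
        fills = fills.sort_values(["patient_id", "day", "drug_class"], kind="stable")
        fills = fills.reset_index(drop=True)

    hp_mask = censor_events["condition"] == "h_pylori"
    tests = pd.DataFrame(
        {
            "patient_id": censor_events.loc[hp_mask, "patient_id"].to_numpy(),
            "day": censor_events.loc[hp_mask, "day"].to_numpy(),
            "test_type": "h_pylori",
            "result": "positive",
        }
    )

    diagnoses = pd.concat(
        diag_rows + [censor_events.loc[~hp_mask]], ignore_index=True
    ).astype({"patient_id": np.int64, "day": np.int64, "inpatient": np.int64})
    diagnoses = diagnoses.sort_values(
        ["patient_id", "day", "condition"], kind="stable"
    ).reset_index(drop=True)

    patients = patients.drop(columns=["no_initial_fill"], errors="ignore")
    return {
        "patients": patients.reset_index(drop=True),
        "diagnoses": diagnoses,
        "fills": fills,
        "tests": tests.reset_index(drop=True),
    }


def write_tables(tables: dict[str, pd.DataFrame], out_dir) -> None:
    """Write the four flat tables as headered CSV under ``out_dir``."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, df in tables.items():
        df.to_csv(out / f"{name}.csv", index=False)


def read_tables(in_dir) -> dict[str, pd.DataFrame]:
    """Read the four flat tables written by :func:`write_tables`."""
    from pathlib import Path

    src = Path(in_dir)
    return {
        name: pd.read_csv(src / f"{name}.csv")
        for name in ("patients", "diagnoses", "fills", "tests")
    }
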