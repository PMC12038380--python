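"""Shared fixtures: a hand-built 12-patient golden cohort and a tie-free
continuous-time counting-process dataset for cross-implementation checks."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ppi_overuse.config import RunConfig, SimulationConfig


def _diag(pid, day, condition, inpatient=0):
    return dict(patient_id=pid, day=day, condition=condition, inpatient=inpatient)


def _fill(pid, day, drug_class="ppi", days_supply=30, prescriber_type="primary_care"):
    return dict(
        patient_id=pid, day=day, drug_class=drug_class,
        days_supply=days_supply, prescriber_type=prescriber_type,
    )


@pytest.fixture(scope="session")
def golden_tables() -> dict:
    """Twelve hand-built patients covering every eligibility rule and the
    classification boundaries (washout at exactly index-14; supply ending
    exactly at the *H. pylori* margin).

    Index day for patient ``i`` is ``3000 + 10*i``.  Expected outcomes are
    frozen in ``golden_expected``.
    """
    idx = {i: 3000 + 10 * i for i in range(12)}
    diagnoses, fills, tests = [], [], []

    def eligible_base(i, endo_off=0):
        diagnoses.append(_diag(i, idx[i], "acute_pud"))
        diagnoses.append(_diag(i, idx[i] + endo_off, "endoscopy"))

    # P0: eligible; one within-60d fill and one exceeding fill
    eligible_base(0)
    fills += [_fill(0, idx[0] + 0), _fill(0, idx[0] + 45)]

    # P1: eligible; H. pylori on day index+40; fills probing the hp margin
    eligible_base(1)
    tests.append(dict(patient_id=1, day=idx[1] + 40, test_type="h_pylori", result="positive"))
    fills += [
        _fill(1, idx[1] + 2),    # end 32  -> within_60d
        _fill(1, idx[1] + 50),   # end 80  -> hp_exception (<= 100)
        _fill(1, idx[1] + 70),   # end 100 -> hp_exception (== hp+60, inclusive)
        _fill(1, idx[1] + 80),   # end 110 -> exceeds
    ]

    # P2: washout boundary: PPI fill exactly at index-14 -> excluded
    eligible_base(2)
    fills += [_fill(2, idx[2] - 14), _fill(2, idx[2] + 3)]

    # P3: fill at index-10 (outside the washout interval) -> eligible
    eligible_base(3)
    fills += [_fill(3, idx[3] - 10), _fill(3, idx[3] + 3)]

    # P4: washout far boundary: fill exactly at index-365 -> excluded
    eligible_base(4)
    fills += [_fill(4, idx[4] - 365), _fill(4, idx[4] + 5)]

    # P5: no endoscopy at all -> excluded
    diagnoses.append(_diag(5, idx[5], "acute_pud"))
    fills += [_fill(5, idx[5] + 0)]

    # P6: endoscopy at index+30 (window boundary) and fill at index+14 -> eligible
    eligible_base(6, endo_off=30)
    fills += [_fill(6, idx[6] + 14)]

    # P7: endoscopy at index-31 (just outside the window) -> excluded
    eligible_base(7, endo_off=-31)
    fills += [_fill(7, idx[7] + 1)]

    # P8: prior chronic PUD (and also a washout fill: first failing rule wins)
    eligible_base(8)
    diagnoses.append(_diag(8, idx[8] - 100, "chronic_pud"))
    fills += [_fill(8, idx[8] - 100), _fill(8, idx[8] + 1)]

    # P9: prior PPI indication -> excluded
    eligible_base(9)
    diagnoses.append(_diag(9, idx[9] - 500, "ppi_indication"))
    fills += [_fill(9, idx[9] + 1)]

    # P10: first PPI fill on day index+15 (outside the 14-day window) -> excluded
    eligible_base(10)
    fills += [_fill(10, idx[10] + 15)]

    # P11: chronic PUD only, never acute -> not emitted at all
    diagnoses.append(_diag(11, idx[11], "chronic_pud"))
    diagnoses.append(_diag(11, idx[11], "endoscopy"))
    fills += [_fill(11, idx[11] + 1)]

    patients = pd.DataFrame(
        {
            "patient_id": list(range(12)),
            "index_day": [idx[i] for i in range(12)],
            "age": 75,
            "visn": 1,
            "frailty": "nonfrail",
        }
    )
    return {
        "patients": patients,
        "diagnoses": pd.DataFrame(diagnoses),
        "fills": pd.DataFrame(fills),
        "tests": pd.DataFrame(tests),
    }


@pytest.fixture(scope="session")
def golden_expected() -> dict:
    """Hand-computed attrition and classification counts for the fixture."""
    return {
        "attrition": {
            "patients_with_acute_pud": 11,
            "excluded_no_endoscopy": 2,       # P5, P7
            "excluded_prior_chronic_pud": 1,  # P8
            "excluded_prior_ppi_indication": 1,  # P9
            "excluded_washout_ppi_fill": 2,   # P2, P4
            "excluded_no_initial_ppi_fill": 1,  # P10
            "eligible": 4,                    # P0, P1, P3, P6
        },
        "eligible_ids": [0, 1, 3, 6],
        "n_classified": 8,
        "reason_counts": {"within_60d": 4, "hp_exception": 2, "exceeds": 2},
        "exceed_by_patient": {0: 1, 1: 1, 3: 0, 6: 0},
    }


def make_continuous_ctv_dataset(seed: int = 42, n_patients: int = 200) -> pd.DataFrame:
    """Tie-free continuous-time counting-process data: one binary baseline
    covariate and one time-varying covariate that switches on at a random
    time, events thinned from a proportional intensity.  With no tied event
    times, Breslow and Efron partial likelihoods coincide, so any correct
    implementation must agree exactly."""
    rng = np.random.default_rng(seed)
    beta = np.array([0.4, 0.3])
    lam0 = 0.004
    rows = []
    for pid in range(n_patients):
        x = float(rng.random() < 0.3)
        switch = rng.uniform(50, 800)
        cens = rng.uniform(400, 1095)
        t, events = 0.0, []
        lmax = lam0 * np.exp(beta[0] * x + max(beta[1], 0.0))
        while True:
            t += rng.exponential(1 / lmax)
            if t > cens:
                break
            eta = beta[0] * x + beta[1] * (t >= switch)
            if rng.random() < np.exp(eta) * lam0 / lmax:
                events.append(t)
        cuts = sorted(set(events) | ({switch} if switch < cens else set()) | {cens})
        start = 0.0
        for c in cuts:
            rows.append(
                dict(patient_id=pid, start=start, stop=c, event=int(c in events),
                     x=x, tv=float((start + c) / 2 >= switch))
            )
            start = c
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def ctv_dataset() -> pd.DataFrame:
    return make_continuous_ctv_dataset()


@pytest.fixture()
def small_run_config() -> RunConfig:
    cfg = RunConfig(seed=7, paf_factors=("inpatient",), n_bootstrap=0)
    cfg.simulation = SimulationConfig(n_patients=250, seed=7)
    return cfg
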