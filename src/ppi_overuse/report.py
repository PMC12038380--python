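"""Descriptive summaries and end-to-end pipeline orchestration.

``run_pipeline`` chains the stages — simulate (or load) the four flat
tables, build the eligible cohort, classify PPI fills, construct the
counting-process data, fit the Andersen-Gill model and compute PAF curves
— under a single :class:`~ppi_overuse.config.RunConfig`, including the
secondary (gastroprotection) analysis and the four sensitivity-analysis
variants.  A fixed seed and configuration yield a byte-identical artifact
bundle; stage timings go to the logger, never into the written artifacts.
"""

from __future__ import annotations

import datetime as dt
import logging
import time
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import classify as _classify
from .agmodel import FitResult, fit_andersen_gill, parsimonious_select
from .classify import (
    classify_fills,
    default_guideline_rules,
    first_qualification_day,
    merge_windows,
)
from .cohort import attrition_table, build_cohort
from .config import RunConfig, StudyCalendar
from .counting import build_counting_data
from .paf import PAFCurve, bootstrap_ci, default_grid, paf_curve

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# descriptives
# ---------------------------------------------------------------------------


def describe(
    cohort: pd.DataFrame,
    classified: pd.DataFrame,
    excess_definition: str = "supply_sum",
    threshold_days: int = 60,
) -> dict:
    """Cohort-level description of exceeding-fill burden.

    Per patient: an any-exceed flag, the number of exceeding fills, and
    days of excess PPI exposure — by default the summed days supply of
    exceeding fills; alternatively (``excess_definition=
    "covered_after_60"``) the union of supply days falling after
    ``index + 60``.  Cohort level: the proportion with any exceeding fill,
    medians with IQRs among patients with at least one (reported as
    missing when there are none), and the prescriber-type mix of exceeding
    fills.
    """
    elig = cohort[cohort["eligible"].astype(bool)]
    idx_by_pid = dict(zip(elig["patient_id"], elig["index_day"]))
    exceed = classified[classified["status"] == "exceeds"] if len(classified) else classified

    per = pd.DataFrame({"patient_id": sorted(idx_by_pid)})
    if len(exceed):
        counts = exceed.groupby("patient_id").size()
        if excess_definition == "supply_sum":
            excess = exceed.groupby("patient_id")["days_supply"].sum()
        else:
            excess = {}
            for pid, grp in exceed.groupby("patient_id"):
                lo = idx_by_pid[int(pid)] + threshold_days
                wins = merge_windows(
                    (max(float(d), float(lo)), float(d + s))
                    for d, s in zip(grp["day"], grp["supply_end"] - grp["day"])
                    if d + s > lo
                )
                excess[pid] = sum(b - a for a, b in wins)
            excess = pd.Series(excess, dtype=float)
    else:
        counts = pd.Series(dtype=int)
        excess = pd.Series(dtype=float)
    per["n_exceeding_fills"] = per["patient_id"].map(counts).fillna(0).astype(int)
    per["any_exceed"] = per["n_exceeding_fills"] > 0
    per["excess_days"] = per["patient_id"].map(excess).fillna(0.0)

    with_any = per[per["any_exceed"]]

    def _iqr(s: pd.Series) -> tuple[float, float, float]:
        if len(s) == 0:
            return float("nan"), float("nan"), float("nan")
        return float(s.median()), float(s.quantile(0.25)), float(s.quantile(0.75))

    m_n, q1_n, q3_n = _iqr(with_any["n_exceeding_fills"])
    m_d, q1_d, q3_d = _iqr(with_any["excess_days"])
    summary = {
        "n_eligible": int(len(per)),
        "n_any_exceed": int(per["any_exceed"].sum()),
        "proportion_any_exceed": float(per["any_exceed"].mean()) if len(per) else 0.0,
        "median_exceeding_fills": m_n,
        "iqr_exceeding_fills": (q1_n, q3_n),
        "median_excess_days": m_d,
        "iqr_excess_days": (q1_d, q3_d),
    }
    if len(exceed) and "prescriber_type" in exceed:
        presc = (
            exceed["prescriber_type"].value_counts(normalize=True).rename("fraction").reset_index()
        )
        presc.columns = ["prescriber_type", "fraction"]
    else:
        presc = pd.DataFrame(columns=["prescriber_type", "fraction"])
    return {"per_patient": per, "summary": summary, "prescriber_breakdown": presc}


# ---------------------------------------------------------------------------
# helpers shared by the pipeline stages
# ---------------------------------------------------------------------------


def guideline_qualification_days(
    tables: Mapping[str, pd.DataFrame],
    cohort: pd.DataFrame,
    config: RunConfig,
) -> dict[int, int]:
    """First guideline-qualification day (absolute) per eligible patient."""
    cal = config.simulation.calendar
    rules = default_guideline_rules(config.guideline_activation)
    fills = tables["fills"]
    diag = tables["diagnoses"]
    pts = tables["patients"].set_index("patient_id")
    gi = diag[diag["condition"] == "gi_bleed"]
    gi_by_pid = {int(p): g["day"].to_numpy() for p, g in gi.groupby("patient_id")}
    out: dict[int, int] = {}
    elig = cohort[cohort["eligible"].astype(bool)]
    horizon = config.effective_censoring().max_followup
    fills_by_pid = dict(tuple(fills.groupby("patient_id")))
    empty = fills.iloc[0:0]
    for pid, index_day in zip(elig["patient_id"], elig["index_day"]):
        pid = int(pid)
        q = first_qualification_day(
            fills_by_pid.get(pid, empty),
            int(index_day),
            float(pts.loc[pid, "age"]) if pid in pts.index else 70.0,
            gi_bleed_days=gi_by_pid.get(pid, ()),
            horizon_day=int(index_day) + horizon,
            rules=rules,
            grace_days=config.grace_days,
            year_of=cal.year_of,
        )
        if q is not None:
            out[pid] = q
    return out


def post_endoscopy_windows(
    tables: Mapping[str, pd.DataFrame],
    cohort: pd.DataFrame,
    config: RunConfig,
    window_days: int = 60,
) -> dict[int, list[tuple[int, int]]]:
    """Follow-up endoscopy approval windows (delayed-healing sensitivity).

    A follow-up endoscopy is one more than ``endoscopy_window_days`` after
    index (the index endoscopy itself does not count); fills within 60
    days on/after it are treated as approved.
    """
    diag = tables["diagnoses"]
    endo = diag[diag["condition"] == "endoscopy"]
    elig = cohort[cohort["eligible"].astype(bool)]
    idx_by_pid = dict(zip(elig["patient_id"].astype(int), elig["index_day"].astype(int)))
    out: dict[int, list[tuple[int, int]]] = {}
    for pid, grp in endo.groupby("patient_id"):
        pid = int(pid)
        if pid not in idx_by_pid:
            continue
        cut = idx_by_pid[pid] + config.endoscopy_window_days
        days = sorted(int(d) for d in grp["day"] if d > cut)
        if days:
            out[pid] = [(d, d + window_days) for d in days]
    return out


# ---------------------------------------------------------------------------
# PAF with bootstrap
# ---------------------------------------------------------------------------


def paf_with_bootstrap(
    intervals: pd.DataFrame,
    covariates: Sequence[str],
    factor: str,
    grid: np.ndarray,
    variant: str = "cumulative_incidence",
    n_boot: int = 0,
    seed: int = 0,
) -> PAFCurve:
    """Fit + PAF on the full data, with optional patient-resampling bands.

    Each bootstrap replicate resamples patients with replacement, relabels
    them, refits the model and recomputes the curve; failed replicates are
    dropped and counted.
    """
    fit = fit_andersen_gill(intervals, list(covariates))
    curve = paf_curve(fit, intervals, factor, grid, variant)
    if n_boot >= 2:
        by_pid = dict(tuple(intervals.groupby("patient_id")))
        ids = np.array(sorted(by_pid))

        def replicate(sample: np.ndarray, b: int) -> np.ndarray:
            parts = []
            for new_id, pid in enumerate(sample):
                part = by_pid[pid].copy()
                part["patient_id"] = new_id
                parts.append(part)
            df = pd.concat(parts, ignore_index=True)
            f = fit_andersen_gill(df, list(covariates))
            return paf_curve(f, df, factor, grid, variant).paf

        low, high, dropped = bootstrap_ci(replicate, ids, n_boot, seed)
        curve.ci_low, curve.ci_high = low, high
        curve.n_bootstrap = n_boot - dropped
        curve.seed = seed
    return curve


# ---------------------------------------------------------------------------
# end-to-end run
# ---------------------------------------------------------------------------


def run_pipeline(
    config: RunConfig,
    tables: Mapping[str, pd.DataFrame] | None = None,
) -> dict:
    """Run all stages and return the artifact bundle as a dict.

    Stages: simulate (when no ``tables`` are passed) -> cohort eligibility
    -> fill classification -> counting process -> Andersen-Gill fit ->
    descriptives and PAF curves.  Any stage failure is re-raised with the
    stage name attached.
    """
    from .simulate import simulate_tables

    stage = "simulate"
    t0 = time.perf_counter()
    try:
        if tables is None:
            tables = simulate_tables(config.simulation)
        cal = config.simulation.calendar
        logger.info("stage %s done (%.2fs)", stage, time.perf_counter() - t0)

        stage = "build_cohort"
        min_index_day = (
            cal.to_day(dt.date(2010, 1, 1)) if config.sensitivity == "restrict_2010_plus" else None
        )
        cohort = build_cohort(
            tables["diagnoses"],
            tables["fills"],
            endoscopy_window=config.endoscopy_window_days,
            washout=config.washout_days,
            initiation_window=config.initiation_window_days,
            min_index_day=min_index_day,
        )
        attrition = attrition_table(cohort, min_index_day=min_index_day)

        stage = "classify"
        secondary = config.analysis == "gastroprotection_secondary"
        qual_days = (
            guideline_qualification_days(tables, cohort, config) if secondary else None
        )
        endo_windows = (
            post_endoscopy_windows(tables, cohort, config)
            if config.sensitivity == "post_endoscopy_60d_approved"
            else None
        )
        classified = classify_fills(
            tables["fills"],
            cohort,
            tables["tests"],
            threshold_days=config.approved_threshold_days,
            hp_margin_days=config.hp_margin_days,
            gastroprotection_days=qual_days,
            post_endoscopy_windows=endo_windows,
        )

        stage = "describe"
        desc = describe(cohort, classified, config.excess_days_definition,
                        config.approved_threshold_days)

        stage = "counting_process"
        frailty_col = "frailty_alt" if config.sensitivity == "frailty_recomputed" else "frailty"
        plan = config.effective_censoring()
        intervals = build_counting_data(
            cohort,
            classified,
            tables["fills"],
            tables["diagnoses"],
            tables["patients"].rename(columns={}).assign(
                frailty=tables["patients"][frailty_col]
                if frailty_col in tables["patients"].columns
                else tables["patients"].get("frailty")
            ),
            plan,
            calendar=cal,
            baseline_factors=config.model_baseline_factors,
            tv_classes=config.model_tv_classes,
            grace_days=config.grace_days,
            guideline_days=qual_days if secondary else None,
        )

        stage = "fit"
        covs = [c for c in intervals.columns
                if c not in ("patient_id", "start", "stop", "event", "censor_cause")]
        if config.parsimonious:
            retained, fit, path = parsimonious_select(intervals, covs)
        else:
            fit, path = fit_andersen_gill(intervals, covs), []
        table2 = fit.summary() if fit is not None else pd.DataFrame()

        stage = "paf"
        grid = default_grid(plan.max_followup)
        curves: dict[str, PAFCurve] = {}
        if fit is not None:
            for factor in config.paf_factors:
                if factor in fit.covariates:
                    curves[factor] = paf_with_bootstrap(
                        intervals, fit.covariates, factor, grid,
                        config.paf_variant, config.n_bootstrap, config.seed,
                    )

        logger.info("pipeline complete (%.2fs)", time.perf_counter() - t0)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    return {
        "tables": dict(tables),
        "cohort": cohort,
        "attrition": attrition,
        "classified": classified,
        "describe": desc,
        "intervals": intervals,
        "fit": fit,
        "table2": table2,
        "selection_path": path,
        "paf_curves": curves,
        "meta": {
            "analysis": config.analysis,
            "sensitivity": config.sensitivity,
            "seed": config.seed,
            "simulation_seed": config.simulation.seed,
            "max_followup": plan.max_followup,
            "covariates": covs,
        },
    }


def write_bundle(bundle: dict, out_dir) -> None:
    """Serialize a pipeline bundle as delimited text + YAML metadata."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, df in bundle["tables"].items():
        df.to_csv(out / f"input_{name}.csv", index=False)
    bundle["cohort"].to_csv(out / "cohort.csv", index=False)
    bundle["attrition"].to_csv(out / "attrition.csv", index=False)
    bundle["classified"].to_csv(out / "classified_fills.csv", index=False)
    bundle["intervals"].to_csv(out / "counting_process.csv", index=False)
    bundle["table2"].to_csv(out / "model_aHR.csv", index=False)
    bundle["describe"]["per_patient"].to_csv(out / "per_patient_summary.csv", index=False)
    bundle["describe"]["prescriber_breakdown"].to_csv(
        out / "prescriber_breakdown.csv", index=False
    )
    paf_frames = [c.to_frame() for c in bundle["paf_curves"].values()]
    if paf_frames:
        pd.concat(paf_frames, ignore_index=True).to_csv(out / "paf_curves.csv", index=False)
    meta = dict(bundle["meta"])
    meta["cohort_summary"] = {
        k: (list(v) if isinstance(v, tuple) else v)
        for k, v in bundle["describe"]["summary"].items()
    }
    with open(out / "run_meta.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)
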