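"""Adjusted time-to-event population attributable fraction (PAF) curves.

The PAF of a factor at time ``t`` is the proportional reduction in the
standardized outcome quantity if every patient with the factor were
treated like patients at the factor's reference level:

    PAF(t) = 1 - Fbar_0(t) / Fbar(t),

where the factual quantity ``Fbar(t) = n^-1 sum_i g(Lambda_i(t))``
standardizes each patient's cumulative intensity
``Lambda_i(t) = int_0^t exp(beta' Z_i(s)) dLambda_0(s)`` over the analytic
cohort, and the counterfactual ``Fbar_0`` repeats the computation with the
factor set to its reference level in every covariate path.  Two estimator
variants are provided:

* ``cumulative_incidence`` — ``g(x) = 1 - exp(-x)``, the probability of at
  least one exceeding fill by ``t`` (rises then falls back as both arms
  saturate, matching the peaked shape of attributable-fraction curves);
* ``expected_events`` — ``g(x) = x``, the mean cumulative count (constant
  in ``t`` for purely baseline covariates).

Time-varying covariates enter through piecewise accumulation of
``Lambda_i`` along the patient's observed interval path; past the end of a
patient's observed path the last covariate values are carried forward.
Uncertainty bands come from a seeded patient-resampling bootstrap.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .agmodel import FitResult, StepFunction

logger = logging.getLogger(__name__)

VARIANTS = ("cumulative_incidence", "expected_events")


@dataclass
class PAFCurve:
    factor: str
    grid: np.ndarray
    paf: np.ndarray
    ci_low: np.ndarray | None = None
    ci_high: np.ndarray | None = None
    estimator_variant: str = "cumulative_incidence"
    n_bootstrap: int = 0
    seed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"factor": self.factor, "t": self.grid, "paf": self.paf})
        if self.ci_low is not None:
            df["ci_low"] = self.ci_low
            df["ci_high"] = self.ci_high
        return df


def default_grid(horizon_days: int = 1095) -> np.ndarray:
    """Daily to 180 days, weekly thereafter."""
    daily = np.arange(1, min(180, horizon_days) + 1)
    if horizon_days <= 180:
        return daily.astype(float)
    weekly = np.arange(187, horizon_days + 1, 7)
    return np.concatenate([daily, weekly]).astype(float)


@dataclass
class ManualFit:
    """Minimal stand-in for :class:`agmodel.FitResult` built from known
    coefficients and a supplied baseline — used for analytic checks."""

    covariates: list[str]
    beta: np.ndarray
    baseline: StepFunction


# ---------------------------------------------------------------------------
# standardized cumulative intensities
# ---------------------------------------------------------------------------


def _patient_cum_intensity(
    fit: FitResult | ManualFit,
    paths: pd.DataFrame,
    grid: np.ndarray,
    zero_factor: str | None,
) -> np.ndarray:
    """(n_patients, len(grid)) matrix of Lambda_i(t), optionally with one
    factor column zeroed in every path row (the counterfactual)."""
    paths = paths.sort_values(["patient_id", "start"], kind="stable")
    beta = np.asarray(fit.beta, dtype=float)
    cols = list(fit.covariates)
    Z = paths[cols].to_numpy(dtype=float)
    if zero_factor is not None:
        Z = Z.copy()
        Z[:, cols.index(zero_factor)] = 0.0
    eta = Z @ beta
    w = np.exp(eta)

    start = paths["start"].to_numpy(dtype=float)
    stop = paths["stop"].to_numpy(dtype=float)
    # carry the last observed covariate values forward past the path end
    last = ~np.concatenate(
        [paths["patient_id"].to_numpy()[:-1] == paths["patient_id"].to_numpy()[1:], [False]]
    )
    stop = stop.copy()
    stop[last] = np.inf

    L = fit.baseline
    # Lambda contribution of row r at grid time t:
    #   w_r * [L(clip(t, start_r, stop_r)) - L(start_r)]
    t_eff = np.clip(grid[None, :], start[:, None], stop[:, None])
    contrib = w[:, None] * (L(t_eff) - L(start)[:, None])

    pids, codes = np.unique(paths["patient_id"].to_numpy(), return_inverse=True)
    out = np.zeros((len(pids), len(grid)))
    np.add.at(out, codes, contrib)
    return out


def _g(x: np.ndarray, variant: str) -> np.ndarray:
    if variant == "cumulative_incidence":
        return -np.expm1(-x)
    if variant == "expected_events":
        return x
    raise ValueError(f"unknown estimator variant {variant!r}; expected one of {VARIANTS}")


def paf_curve(
    fit: FitResult | ManualFit,
    paths: pd.DataFrame,
    factor: str,
    grid: np.ndarray | None = None,
    variant: str = "cumulative_incidence",
) -> PAFCurve:
    """Adjusted PAF curve of one model factor over a time grid.

    ``paths`` is the counting-process table (or any ``patient_id, start,
    stop`` + covariate frame, sorted by patient and start): one row per
    constant-covariate stretch.  Grid points where the factual standardized
    quantity is zero yield ``NaN`` (the fraction is undefined there, which
    is reported as missing rather than zero).
    """
    if factor not in fit.covariates:
        raise ValueError(f"{factor!r} is not a model covariate")
    if grid is None:
        grid = default_grid(int(paths["stop"].max()))
    grid = np.asarray(grid, dtype=float)

    lam = _patient_cum_intensity(fit, paths, grid, zero_factor=None)
    lam0 = _patient_cum_intensity(fit, paths, grid, zero_factor=factor)
    fbar = _g(lam, variant).mean(axis=0)
    fbar0 = _g(lam0, variant).mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        paf = np.where(fbar > 0, 1.0 - fbar0 / fbar, np.nan)
    return PAFCurve(factor=factor, grid=grid, paf=paf, estimator_variant=variant)


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------


def bootstrap_ci(
    replicate: Callable[[np.ndarray, int], np.ndarray],
    patient_ids: Sequence,
    n_boot: int,
    seed: int,
    drop_warn_fraction: float = 0.05,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Patient-resampling percentile bootstrap bands.

    ``replicate(resampled_ids, b)`` must rerun the full pipeline (refit +
    PAF) on the given patient multiset and return the PAF values on the
    common grid; replicates that raise are dropped and counted, with a
    warning when more than ``drop_warn_fraction`` of them fail.
    Deterministic for a fixed seed.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    rng = np.random.default_rng(seed)
    ids = np.asarray(patient_ids)
    curves = []
    dropped = 0
    for b in range(n_boot):
        sample = rng.choice(ids, size=len(ids), replace=True)
        try:
            curves.append(np.asarray(replicate(sample, b), dtype=float))
        except Exception as exc:  # degenerate resample (e.g. zero events)
            dropped += 1
            logger.debug("bootstrap replicate %d dropped: %s", b, exc)
    if not curves:
        raise RuntimeError("all bootstrap replicates failed")
    if dropped > drop_warn_fraction * n_boot:
        logger.warning("%d/%d bootstrap replicates dropped", dropped, n_boot)
    arr = np.vstack(curves)
    with warnings.catch_warnings():
        # grid points before the first event are NaN in every replicate
        warnings.simplefilter("ignore", category=RuntimeWarning)
        low = np.nanpercentile(arr, 2.5, axis=0)
        high = np.nanpercentile(arr, 97.5, axis=0)
    return low, high, dropped


def peak(curve: PAFCurve) -> tuple[float, float]:
    """(time, value) of the curve maximum; first occurrence wins ties.

    ``NaN`` grid points (undefined PAF) are ignored.
    """
    paf = np.asarray(curve.paf, dtype=float)
    if np.all(np.isnan(paf)):
        raise ValueError("PAF undefined on the whole grid")
    k = int(np.nanargmax(paf))
    # nanargmax returns the first maximal index among non-NaN entries
    return float(curve.grid[k]), float(paf[k])
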