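"""Andersen-Gill multiplicative-intensity model on counting-process data.

The recurrent-event intensity for patient ``i`` is
``lambda_i(t) = lambda_0(t) exp(beta' Z_i(t))`` with ``Z_i`` piecewise
constant over ``(start, stop]`` risk intervals.  ``beta`` maximises the Cox
partial likelihood with Breslow handling of tied event times,

    l(beta) = sum_j [ s_j' beta - d_j log S0(t_j; beta) ],

where at each distinct event time ``t_j``, ``d_j`` events occur, ``s_j`` is
the covariate sum over those events, and
``S0 = sum_{i in risk set} exp(beta' Z_i)`` with risk set
``{i : start_i < t_j <= stop_i}``.  Optimisation is Newton-Raphson with
step-halving on internally standardised covariates.

Because one patient contributes several correlated intervals and events,
reported confidence intervals use the cluster-robust (sandwich) variance:
score residuals are aggregated within patient before forming the
middle matrix.  The naive (inverse-information) covariance is kept for
diagnostics.

All sums over risk sets are evaluated in O(R log R) per Newton step by
sorting interval starts and stops once and taking suffix cumulative sums,
using that ``{i : start_i < t} = all - {i : start_i >= t}`` and
``{i : stop_i >= t}`` are suffix sets of the sorted arrays.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

Z975 = 1.959963984540054


class ConvergenceError(RuntimeError):
    """Newton-Raphson failed; carries iteration diagnostics."""

    def __init__(self, msg: str, n_iter: int, grad_norm: float, loglik: float):
        super().__init__(f"{msg} (iter={n_iter}, |grad|={grad_norm:.3e}, loglik={loglik:.6f})")
        self.n_iter = n_iter
        self.grad_norm = grad_norm
        self.loglik = loglik


@dataclass
class StepFunction:
    """Right-continuous nondecreasing step function, zero before the first jump."""

    times: np.ndarray
    jumps: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.jumps = np.asarray(self.jumps, dtype=float)
        self._cum = np.cumsum(self.jumps)

    def __call__(self, t) -> np.ndarray:
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float), side="right")
        return np.where(idx > 0, self._cum[np.maximum(idx - 1, 0)], 0.0)

    @property
    def cumulative(self) -> np.ndarray:
        return self._cum


@dataclass
class FitResult:
    covariates: list[str]
    beta: np.ndarray
    naive_cov: np.ndarray
    robust_cov: np.ndarray
    loglik: float
    baseline: StepFunction
    n_iter: int
    grad_norm: float
    converged: bool = True
    n_events: int = 0
    n_patients: int = 0
    flags: list[str] = field(default_factory=list)

    @property
    def hr(self) -> np.ndarray:
        return np.exp(self.beta)

    @property
    def se_robust(self) -> np.ndarray:
        return np.sqrt(np.diag(self.robust_cov))

    @property
    def se_naive(self) -> np.ndarray:
        return np.sqrt(np.diag(self.naive_cov))

    def summary(self) -> pd.DataFrame:
        """Factor / aHR / robust 95% CI table."""
        se = self.se_robust
        return pd.DataFrame(
            {
                "factor": self.covariates,
                "coef": self.beta,
                "aHR": np.exp(self.beta),
                "ci_low": np.exp(self.beta - Z975 * se),
                "ci_high": np.exp(self.beta + Z975 * se),
                "se_robust": se,
                "se_naive": self.se_naive,
                "p_wald": _wald_p(self.beta, se),
            }
        )


def _wald_p(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    from scipy import stats

    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / se, np.inf)
    return 2.0 * stats.norm.sf(np.abs(z))


# ---------------------------------------------------------------------------
# risk-set machinery
# ---------------------------------------------------------------------------


class _CoxData:
    """Pre-sorted arrays reused across Newton iterations."""

    def __init__(self, start, stop, event, Z):
        self.start = np.asarray(start, dtype=float)
        self.stop = np.asarray(stop, dtype=float)
        self.event = np.asarray(event, dtype=int)
        self.Z = np.asarray(Z, dtype=float)
        if np.any(self.start >= self.stop):
            raise ValueError("risk intervals must satisfy start < stop")
        ev_rows = np.flatnonzero(self.event == 1)
        if len(ev_rows) == 0:
            raise ValueError("no events in the counting-process data")
        ev_times = self.stop[ev_rows]
        self.times, inv = np.unique(ev_times, return_inverse=True)  # ascending
        self.d = np.bincount(inv).astype(float)
        p = self.Z.shape[1]
        self.s = np.zeros((len(self.times), p))
        np.add.at(self.s, inv, self.Z[ev_rows])
        self.ev_rows = ev_rows
        self.ev_time_idx = inv
        self.o_stop = np.argsort(self.stop, kind="stable")
        self.o_start = np.argsort(self.start, kind="stable")
        self.sorted_stop = self.stop[self.o_stop]
        self.sorted_start = self.start[self.o_start]
        self.i_stop = np.searchsorted(self.sorted_stop, self.times, side="left")
        self.i_start = np.searchsorted(self.sorted_start, self.times, side="left")

    def _suffix(self, values: np.ndarray, order: np.ndarray, idx: np.ndarray) -> np.ndarray:
        """Suffix sums of `values` (row-aligned) at sorted positions `idx`."""
        v = values[order]
        pref = np.concatenate([np.zeros((1,) + v.shape[1:]), np.cumsum(v, axis=0)])
        total = pref[-1]
        return total - pref[idx]

    def risk_sums(self, w: np.ndarray, with_outer: bool = True):
        """S0, S1 (and S2) over the risk set at each distinct event time."""
        Z = self.Z
        wZ = w[:, None] * Z
        S0 = self._suffix(w, self.o_stop, self.i_stop) - self._suffix(
            w, self.o_start, self.i_start
        )
        S1 = self._suffix(wZ, self.o_stop, self.i_stop) - self._suffix(
            wZ, self.o_start, self.i_start
        )
        if not with_outer:
            return S0, S1, None
        wZZ = wZ[:, :, None] * Z[:, None, :]
        S2 = self._suffix(wZZ, self.o_stop, self.i_stop) - self._suffix(
            wZZ, self.o_start, self.i_start
        )
        return S0, S1, S2

    def loglik_only(self, beta: np.ndarray) -> float:
        w = np.exp(self.Z @ beta)
        S0, _, _ = self.risk_sums(w, with_outer=False)
        return float(np.sum(self.s @ beta) - np.sum(self.d * np.log(S0)))

    def derivatives(self, beta: np.ndarray):
        w = np.exp(self.Z @ beta)
        S0, S1, S2 = self.risk_sums(w)
        ll = float(np.sum(self.s @ beta) - np.sum(self.d * np.log(S0)))
        zbar = S1 / S0[:, None]
        grad = self.s.sum(axis=0) - (self.d[:, None] * zbar).sum(axis=0)
        info = np.einsum("j,jkl->kl", self.d, S2 / S0[:, None, None]) - np.einsum(
            "j,jk,jl->kl", self.d, zbar, zbar
        )
        return ll, grad, info, w, S0, zbar


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def fit_andersen_gill(
    data: pd.DataFrame,
    covariates: list[str],
    cluster_col: str = "patient_id",
    start_col: str = "start",
    stop_col: str = "stop",
    event_col: str = "event",
    max_iter: int = 50,
    grad_tol: float = 1e-8,
    loglik_tol: float = 1e-10,
) -> FitResult:
    """Fit the Andersen-Gill model by Newton-Raphson with step-halving.

    Covariates are standardised internally for optimisation and results are
    back-transformed; convergence requires the standardised score sup-norm
    below ``grad_tol`` or a relative log-likelihood change below
    ``loglik_tol``.  Raises :class:`ConvergenceError` on failure and
    ``ValueError`` when a covariate is constant across all rows (such a
    column cannot enter the partial likelihood).
    """
    Z = data[list(covariates)].to_numpy(dtype=float)
    mu = Z.mean(axis=0)
    sd = Z.std(axis=0)
    const = np.flatnonzero(sd == 0)
    if len(const):
        bad = [covariates[int(k)] for k in const]
        raise ValueError(f"covariate(s) constant across all risk sets: {bad}")
    Zs = (Z - mu) / sd

    cd = _CoxData(data[start_col], data[stop_col], data[event_col], Zs)
    p = Zs.shape[1]
    beta = np.zeros(p)
    ll, grad, info, w, S0, zbar = cd.derivatives(beta)
    n_iter = 0
    flags: list[str] = []
    for n_iter in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            flags.append("singular_information")
            step = np.linalg.lstsq(info, grad, rcond=None)[0]
        # step-halving
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            ll_new = cd.loglik_only(cand)
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        else:
            raise ConvergenceError(
                "step-halving failed to improve the partial likelihood",
                n_iter, float(np.max(np.abs(grad))), ll,
            )
        beta = beta + scale * step
        ll_prev = ll
        ll, grad, info, w, S0, zbar = cd.derivatives(beta)
        gnorm = float(np.max(np.abs(grad)))
        if gnorm < grad_tol:
            break
        if abs(ll - ll_prev) < loglik_tol * (abs(ll_prev) + 1e-300):
            break
    else:
        raise ConvergenceError(
            "Newton-Raphson did not converge", max_iter, float(np.max(np.abs(grad))), ll
        )

    if np.max(np.abs(beta)) > 10:
        flags.append("separation_suspected")
        logger.warning("very large standardised coefficient: possible monotone likelihood")

    naive_std = np.linalg.inv(info)

    # --- cluster-robust sandwich -----------------------------------------
    resid = _score_residuals(cd, w, S0, zbar)
    clusters, cidx = np.unique(data[cluster_col].to_numpy(), return_inverse=True)
    D = np.zeros((len(clusters), p))
    np.add.at(D, cidx, resid)
    middle = D.T @ D
    robust_std = naive_std @ middle @ naive_std

    # --- back-transform to the original covariate scale -------------------
    Dinv = np.diag(1.0 / sd)
    beta_orig = beta / sd
    naive_cov = Dinv @ naive_std @ Dinv
    robust_cov = Dinv @ robust_std @ Dinv

    # Breslow baseline on the original scale: standardisation rescales
    # exp(eta) by the constant exp(-mu' beta_orig)
    jumps = cd.d / S0 * np.exp(-float(mu @ beta_orig))
    baseline = StepFunction(cd.times.copy(), jumps)

    return FitResult(
        covariates=list(covariates),
        beta=beta_orig,
        naive_cov=naive_cov,
        robust_cov=robust_cov,
        loglik=ll,
        baseline=baseline,
        n_iter=n_iter,
        grad_norm=float(np.max(np.abs(grad))),
        converged=True,
        n_events=int(cd.d.sum()),
        n_patients=int(len(clusters)),
        flags=flags,
    )


def _score_residuals(cd: _CoxData, w: np.ndarray, S0: np.ndarray, zbar: np.ndarray) -> np.ndarray:
    """Per-row score residuals (standardised scale) at the fitted beta.

    ``r_i = e_i (Z_i - zbar(t_i)) - w_i [Z_i dC0_i - dC1_i]`` where
    ``C0(t) = sum_{t_j <= t} d_j / S0_j`` (the Breslow cumulative hazard on
    this scale) and ``C1(t) = sum_{t_j <= t} d_j zbar_j / S0_j``, with the
    increments taken over the row's at-risk window ``(start_i, stop_i]``.
    """
    h = cd.d / S0
    C0 = np.concatenate([[0.0], np.cumsum(h)])
    C1 = np.concatenate([np.zeros((1, zbar.shape[1])), np.cumsum(h[:, None] * zbar, axis=0)])
    hi = np.searchsorted(cd.times, cd.stop, side="right")
    lo = np.searchsorted(cd.times, cd.start, side="right")
    dC0 = C0[hi] - C0[lo]
    dC1 = C1[hi] - C1[lo]
    resid = -w[:, None] * (cd.Z * dC0[:, None] - dC1)
    resid[cd.ev_rows] += cd.Z[cd.ev_rows] - zbar[cd.ev_time_idx]
    return resid


def breslow_baseline(fit: FitResult) -> StepFunction:
    """Breslow cumulative baseline intensity of a converged fit.

    ``Lambda0(t) = sum_{t_j <= t} d_j / sum_{at risk} exp(beta' Z_i)``;
    nondecreasing with ``Lambda0(0) = 0``.
    """
    return fit.baseline


# ---------------------------------------------------------------------------
# backward elimination
# ---------------------------------------------------------------------------


def parsimonious_select(
    data: pd.DataFrame,
    candidates: list[str],
    alpha: float = 0.05,
    use_robust: bool = True,
    **fit_kwargs,
) -> tuple[list[str], FitResult | None, list[dict]]:
    """Backward elimination on Wald p-values.

    Repeatedly drops the covariate with the largest p-value above ``alpha``
    until all retained covariates are significant.  Returns the retained
    set, the final fit (``None`` when nothing is retained) and the
    elimination path.
    """
    retained = list(candidates)
    path: list[dict] = []
    fit: FitResult | None = None
    while retained:
        fit = fit_andersen_gill(data, retained, **fit_kwargs)
        se = fit.se_robust if use_robust else fit.se_naive
        pvals = _wald_p(fit.beta, se)
        worst = int(np.argmax(pvals))
        if pvals[worst] <= alpha:
            return retained, fit, path
        path.append({"dropped": retained[worst], "p": float(pvals[worst])})
        logger.info("dropping %s (p=%.4f)", retained[worst], pvals[worst])
        retained = [c for i, c in enumerate(retained) if i != worst]
    return [], None, path
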