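"""Andersen-Gill fitter tests: brute-force risk-set enumeration oracle on a
toy dataset, agreement with independent implementations (lifelines, R
survival), rank-based invariances, and backward elimination."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from ppi_overuse.agmodel import (
    ConvergenceError,
    StepFunction,
    fit_andersen_gill,
    parsimonious_select,
)
from ppi_overuse.report import run_pipeline
from ppi_overuse.validation import null_calibration_config, recovery_config


# ---------------------------------------------------------------------------
# independent oracle: risk sets enumerated from the definition
# ---------------------------------------------------------------------------


def brute_force_loglik(df: pd.DataFrame, covs: list[str], beta: np.ndarray) -> float:
    """Breslow partial log-likelihood by direct enumeration of risk sets."""
    beta = np.asarray(beta, dtype=float)
    ll = 0.0
    ev = df[df["event"] == 1]
    for t in sorted(ev["stop"].unique()):
        d_rows = ev[ev["stop"] == t]
        risk = df[(df["start"] < t) & (t <= df["stop"])]
        denom = float(np.exp(risk[covs].to_numpy() @ beta).sum())
        ll += float((d_rows[covs].to_numpy() @ beta).sum())
        ll -= len(d_rows) * np.log(denom)
    return ll


def toy_dataset() -> pd.DataFrame:
    """Four patients, one binary covariate, finite MLE.

    A: event at t=2 (Z=1); B: event at t=3 (Z=0); C: event at t=4 (Z=0);
    D: event at t=5 (Z=1).  Hand-enumerated risk sets:
    t=2 -> {A,B,C,D}, t=3 -> {B,C,D}, t=4 -> {C,D}, t=5 -> {D}.
    """
    return pd.DataFrame(
        [
            dict(patient_id="A", start=0.0, stop=2.0, event=1, z=1.0),
            dict(patient_id="B", start=0.0, stop=3.0, event=1, z=0.0),
            dict(patient_id="C", start=0.0, stop=4.0, event=1, z=0.0),
            dict(patient_id="D", start=0.0, stop=5.0, event=1, z=1.0),
        ]
    )


class TestToyOracle:
    def test_partial_likelihood_matches_hand_enumeration(self):
        df = toy_dataset()
        # closed form from the enumerated risk sets:
        # l = 2b - log(2e^b+2) - log(e^b+2) - log(e^b+1) - b
        for b in (-0.8, -0.3, 0.0, 0.5, 1.2):
            expected = (
                2 * b
                - np.log(2 * np.exp(b) + 2)
                - np.log(np.exp(b) + 2)
                - np.log(np.exp(b) + 1)
                - b
            )
            assert brute_force_loglik(df, ["z"], np.array([b])) == pytest.approx(expected, abs=1e-12)

    def test_fitted_beta_matches_grid_search(self):
        df = toy_dataset()
        fit = fit_andersen_gill(df, ["z"])
        res = optimize.minimize_scalar(
            lambda b: -brute_force_loglik(df, ["z"], np.array([b])),
            bounds=(-5, 5), method="bounded",
            options={"xatol": 1e-10},
        )
        assert abs(fit.beta[0] - res.x) < 1e-6
        assert fit.loglik == pytest.approx(-res.fun, abs=1e-9)

    def test_breslow_jumps_match_hand_computation(self):
        df = toy_dataset()
        fit = fit_andersen_gill(df, ["z"])
        b = fit.beta[0]
        e = np.exp(b)
        expected = [1 / (2 * e + 2), 1 / (e + 2), 1 / (e + 1), 1 / e]
        assert np.allclose(fit.baseline.jumps, expected, atol=1e-10)
        assert list(fit.baseline.times) == [2.0, 3.0, 4.0, 5.0]
        # nondecreasing step function starting at zero
        assert fit.baseline(0.0) == 0.0
        t = np.linspace(0, 6, 50)
        assert (np.diff(fit.baseline(t)) >= 0).all()

    def test_recurrent_intervals_and_ties_match_brute_force(self):
        # two patients with recurrent events, tied event times across patients
        df = pd.DataFrame(
            [
                dict(patient_id=1, start=0.0, stop=2.0, event=1, z=1.0),
                dict(patient_id=1, start=2.0, stop=6.0, event=1, z=1.0),
                dict(patient_id=2, start=0.0, stop=2.0, event=1, z=0.0),
                dict(patient_id=2, start=2.0, stop=7.0, event=0, z=0.0),
                dict(patient_id=3, start=0.0, stop=6.0, event=1, z=0.0),
            ]
        )
        from ppi_overuse.agmodel import _CoxData

        for b in (-0.4, 0.0, 0.9):
            cd = _CoxData(df["start"], df["stop"], df["event"], df[["z"]].to_numpy())
            assert cd.loglik_only(np.array([b])) == pytest.approx(
                brute_force_loglik(df, ["z"], np.array([b])), abs=1e-10
            )

    def test_null_baseline_is_nelson_aalen(self):
        # beta = 0 (single constant-free covariate unused): Breslow jumps
        # reduce to d_j / (risk set size)
        df = toy_dataset()
        from ppi_overuse.agmodel import _CoxData

        cd = _CoxData(df["start"], df["stop"], df["event"], df[["z"]].to_numpy())
        S0, _, _ = cd.risk_sums(np.ones(len(df)), with_outer=False)
        assert np.allclose(cd.d / S0, [1 / 4, 1 / 3, 1 / 2, 1 / 1])


class TestAgreementWithEstablishedImplementations:
    def test_lifelines_beta_and_naive_se(self, ctv_dataset):
        lifelines = pytest.importorskip("lifelines")
        fit = fit_andersen_gill(ctv_dataset, ["x", "tv"])
        ctv = lifelines.CoxTimeVaryingFitter()
        ctv.fit(
            ctv_dataset[["patient_id", "start", "stop", "event", "x", "tv"]],
            id_col="patient_id", event_col="event", start_col="start", stop_col="stop",
        )
        # no tied event times -> Breslow and Efron coincide exactly
        assert np.max(np.abs(fit.beta - ctv.params_.to_numpy())) < 1e-6
        assert np.max(np.abs(fit.se_naive - ctv.standard_errors_.to_numpy())) < 1e-5
        assert fit.loglik == pytest.approx(ctv.log_likelihood_, abs=1e-4)

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript not on PATH")
    def test_r_survival_beta_and_robust_se(self, ctv_dataset, tmp_path):
        """R survival::coxph with cluster(id) and Breslow ties is the
        reference for the cluster-robust sandwich variance."""
        fit = fit_andersen_gill(ctv_dataset, ["x", "tv"])
        csv = tmp_path / "ctv.csv"
        ctv_dataset.to_csv(csv, index=False)
        script = (
            'suppressMessages(library(survival));'
            f'd <- read.csv("{csv}");'
            'f <- coxph(Surv(start, stop, event) ~ x + tv + cluster(patient_id),'
            '           data=d, ties="breslow");'
            'cat(sprintf("%.12f ", c(coef(f), sqrt(diag(f$var)), f$loglik[2])))'
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        vals = np.array([float(v) for v in out.stdout.split()])
        r_beta, r_rse, r_ll = vals[:2], vals[2:4], vals[4]
        assert np.max(np.abs(fit.beta - r_beta)) < 1e-6
        assert np.max(np.abs(fit.se_robust - r_rse)) < 1e-5
        assert fit.loglik == pytest.approx(r_ll, abs=1e-6)


class TestInvariances:
    def test_time_rescaling_leaves_beta_unchanged(self, ctv_dataset):
        fit0 = fit_andersen_gill(ctv_dataset, ["x", "tv"])
        scaled = ctv_dataset.assign(
            start=ctv_dataset["start"] * 2.0, stop=ctv_dataset["stop"] * 2.0
        )
        fit1 = fit_andersen_gill(scaled, ["x", "tv"])
        assert np.max(np.abs(fit0.beta - fit1.beta)) < 1e-8
        assert fit0.loglik == pytest.approx(fit1.loglik, abs=1e-8)

    def test_score_sup_norm_at_convergence(self, ctv_dataset):
        fit = fit_andersen_gill(ctv_dataset, ["x", "tv"])
        assert fit.grad_norm < 1e-6

    def test_robust_cov_symmetric_psd_and_ci_identity(self, ctv_dataset):
        fit = fit_andersen_gill(ctv_dataset, ["x", "tv"])
        assert np.allclose(fit.robust_cov, fit.robust_cov.T)
        assert (np.linalg.eigvalsh(fit.robust_cov) > -1e-12).all()
        tab = fit.summary()
        assert np.allclose(tab["aHR"], np.exp(fit.beta))
        assert np.allclose(
            tab["ci_low"], np.exp(fit.beta - 1.959963984540054 * fit.se_robust)
        )

    def test_constant_covariate_detected(self, ctv_dataset):
        df = ctv_dataset.assign(const=1.0)
        with pytest.raises(ValueError, match="constant"):
            fit_andersen_gill(df, ["x", "const"])

    def test_separation_flagged(self):
        # the only exposed subject has the earliest event: monotone likelihood
        df = pd.DataFrame(
            [
                dict(patient_id=1, start=0.0, stop=2.0, event=1, z=1.0),
                dict(patient_id=2, start=0.0, stop=3.0, event=0, z=0.0),
                dict(patient_id=3, start=0.0, stop=4.0, event=1, z=0.0),
            ]
        )
        try:
            fit = fit_andersen_gill(df, ["z"], max_iter=200)
            assert "separation_suspected" in fit.flags
        except ConvergenceError:
            pass  # explicit failure with diagnostics is also acceptable


class TestParsimoniousSelection:
    def test_noise_dropped_signals_retained(self):
        cfg = recovery_config(n_patients=1500, seed=12)
        cfg.simulation.factor_prevalences["noise"] = 0.3  # pure noise: no effect
        cfg.model_baseline_factors = ("inpatient", "noise")
        cfg.model_tv_classes = ("nsaid",)
        bundle = run_pipeline(cfg)
        retained, fit, path = parsimonious_select(
            bundle["intervals"], ["inpatient", "noise", "nsaid"]
        )
        assert "noise" not in retained
        assert {"inpatient", "nsaid"} <= set(retained)
        assert any(step["dropped"] == "noise" for step in path)

    def test_single_insignificant_candidate_empty_set(self):
        cfg = null_calibration_config(n_patients=400, seed=5)
        bundle = run_pipeline(cfg)
        retained, fit, path = parsimonious_select(bundle["intervals"], ["null_factor"])
        assert retained == [] and fit is None
        assert len(path) == 1
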