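"""Logistic fitting: closed forms, score conditions, checks, simulations."""

import dataclasses
import math
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from medcf import (
    ModelError,
    ModelSpec,
    SeparationError,
    fit_logistic,
    generate_trial,
    hosmer_lemeshow,
    lr_interaction_test,
    parse_formula,
    predict_prob,
    stress_dgps,
)
from medcf.glm_core import FittedModel, design_matrix


def frame(**cols) -> pd.DataFrame:
    return pd.DataFrame(cols)


class TestSpecGrammar:
    def test_parse_formula(self):
        spec = parse_formula("vf_i ~ 1 + T + M + age + T:age + age^2")
        assert spec.response == "vf_i"
        assert spec.terms == ("1", "T", "M", "age", "T:age", "age^2")

    @pytest.mark.parametrize(
        "formula",
        ["y ~ T + M", "y ~ 1 + T + T", "m ~ 1 + T + M"],
        ids=["no-intercept", "duplicate", "mediator-in-mediator-model"],
    )
    def test_invalid_specs_rejected(self, formula):
        with pytest.raises(ModelError):
            parse_formula(formula)

    def test_squared_term_centered(self):
        df = frame(y=[0, 1, 0, 1], t=[0, 1, 0, 1], x=[1.0, 2.0, 3.0, 4.0])
        X, centers = design_matrix(ModelSpec("y", ("1", "x^2")), df, fit=True)
        assert centers["x"] == pytest.approx(2.5)
        np.testing.assert_allclose(X[:, 1], (df["x"] - 2.5) ** 2)

    def test_squared_binary_rejected(self):
        df = frame(y=[0, 1], t=[0, 1], b=[0.0, 1.0])
        with pytest.raises(ModelError, match="binary"):
            design_matrix(ModelSpec("y", ("1", "b^2")), df, fit=True)


class TestFit:
    def test_intercept_only_closed_form(self):
        y = np.r_[np.ones(30), np.zeros(70)]
        fit = fit_logistic(frame(y=y, t=np.zeros(100)), ModelSpec("y", ("1",)))
        assert fit.beta[0] == pytest.approx(logit(0.3), abs=1e-6)

    def test_two_by_two_log_odds_ratio(self):
        # T=1: 30/100 success, T=0: 10/100 -> beta_T = log((30*90)/(70*10))
        y = np.r_[np.ones(30), np.zeros(70), np.ones(10), np.zeros(90)]
        t = np.r_[np.ones(100), np.zeros(100)]
        fit = fit_logistic(frame(y=y, t=t), ModelSpec("y", ("1", "T")))
        assert fit.beta[1] == pytest.approx(math.log(27 / 7), abs=1e-6)

    def test_refit_deterministic(self, mixed_trial):
        spec = parse_formula("y ~ 1 + T + M + c")
        a, b = fit_logistic(mixed_trial, spec), fit_logistic(mixed_trial, spec)
        np.testing.assert_array_equal(a.beta, b.beta)
        np.testing.assert_array_equal(a.vcov, b.vcov)

    def test_score_vanishes_at_mle(self, mixed_trial):
        spec = parse_formula("y ~ 1 + T + M + c + T:c")
        fit = fit_logistic(mixed_trial, spec)
        X, _ = design_matrix(spec, mixed_trial, centers=fit.centers)
        resid = mixed_trial.data["y"].to_numpy() - expit(X @ fit.beta)
        assert np.max(np.abs(X.T @ resid)) < 1e-6

    def test_vcov_symmetric(self, mixed_trial):
        fit = fit_logistic(mixed_trial, parse_formula("y ~ 1 + T + M + c"))
        assert np.max(np.abs(fit.vcov - fit.vcov.T)) < 1e-8

    def test_collinear_design_names_terms(self, mixed_trial):
        df = mixed_trial.data.assign(c2=lambda d: d["c"])
        with pytest.raises(ModelError, match="collinear"):
            fit_logistic(df, parse_formula("y ~ 1 + T + c + c2"))

    def test_separation_raises_then_ridge_recovers(self):
        y = np.r_[np.ones(20), np.zeros(20)]
        df = frame(y=y, t=y.copy())
        spec = ModelSpec("y", ("1", "T"))
        with pytest.raises(SeparationError):
            fit_logistic(df, spec)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_logistic(df, spec, ridge=True)
        assert np.all(np.isfinite(fit.beta)) and np.all(np.isfinite(fit.vcov))

    def test_nonbinary_response_rejected(self):
        with pytest.raises(ModelError, match="binary"):
            fit_logistic(frame(y=[0, 1, 2], t=[0, 1, 0]), ModelSpec("y", ("1",)))


class TestPredict:
    def test_direct_evaluation(self):
        model = FittedModel(
            spec=ModelSpec("m", ("1", "T")),
            beta=np.array([-2.2, 1.9]),
            vcov=np.zeros((2, 2)),
            loglik=0.0,
            n_obs=0,
            term_names=("1", "T"),
        )
        assert predict_prob(model, t=1) == pytest.approx(expit(-0.3), abs=1e-5)
        assert predict_prob(model, t=0) == pytest.approx(expit(-2.2), abs=1e-5)

    def test_monotone_in_mediator_coefficient(self):
        def prob(cm):
            model = FittedModel(
                spec=ModelSpec("y", ("1", "T", "M")),
                beta=np.array([-1.0, 0.5, cm]),
                vcov=np.zeros((3, 3)),
                loglik=0.0,
                n_obs=0,
                term_names=("1", "T", "M"),
            )
            return predict_prob(model, t=1, m=1)

        probs = [prob(c) for c in (0.0, 0.5, 1.0, 2.0)]
        assert all(a < b for a, b in zip(probs, probs[1:]))

    def test_missing_covariate_named(self, mixed_trial):
        fit = fit_logistic(mixed_trial, parse_formula("y ~ 1 + T + M + c"))
        with pytest.raises(ModelError, match="c"):
            predict_prob(fit, t=1, m=0, covariates={})


class TestHosmerLemeshow:
    def test_perfect_calibration_gives_zero(self):
        # empirical rates match predictions exactly within each covariate cell
        y = np.r_[np.ones(20), np.zeros(30), np.ones(40), np.zeros(10)]
        c = np.r_[np.zeros(50), np.ones(50)]
        df = frame(y=y, t=np.zeros(100), c=c)
        fit = fit_logistic(df, ModelSpec("y", ("1", "c")))
        stat, dfree, p = hosmer_lemeshow(fit, df)
        assert stat == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0)

    def test_tied_predictions_partition_deterministic(self):
        # only two distinct predicted values -> ties collapse the deciles
        y = np.r_[np.ones(20), np.zeros(30), np.ones(35), np.zeros(15)]
        c = np.r_[np.zeros(50), np.ones(50)]
        df = frame(y=y, t=np.zeros(100), c=c)
        fit = fit_logistic(df, ModelSpec("y", ("1", "c")))
        res1 = hosmer_lemeshow(fit, df)
        res2 = hosmer_lemeshow(fit, df)
        assert res1 == res2
        assert res1[1] >= 1

    def test_null_rejection_rate(self):
        # correctly specified model: rejection at alpha=0.05 near nominal
        rng = np.random.default_rng(2024)
        rejections = 0
        n, reps = 400, 500
        spec = ModelSpec("y", ("1", "T", "x"))
        for _ in range(reps):
            t = rng.integers(0, 2, n)
            x = rng.standard_normal(n)
            p = expit(-0.5 + 0.8 * t + 0.6 * x)
            df = frame(y=(rng.random(n) < p).astype(float), t=t, x=x)
            fit = fit_logistic(df, spec)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, _, pval = hosmer_lemeshow(fit, df)
            rejections += pval < 0.05
        assert 0.02 <= rejections / reps <= 0.09

    def test_bad_group_count(self, mixed_trial):
        fit = fit_logistic(mixed_trial, parse_formula("y ~ 1 + T + M + c"))
        with pytest.raises(ModelError):
            hosmer_lemeshow(fit, mixed_trial, groups=1)


class TestLRInteraction:
    def test_requires_main_effects_without_interaction(self, mixed_trial):
        with pytest.raises(ModelError):
            lr_interaction_test(mixed_trial, parse_formula("y ~ 1 + T + c"))
        with pytest.raises(ModelError):
            lr_interaction_test(mixed_trial, parse_formula("y ~ 1 + T + M + T:M"))

    def test_degenerate_nesting_gives_zero(self):
        # balanced 50% success in every (t, m) cell: interaction MLE is 0
        cells = [(t, m) for t in (0, 1) for m in (0, 1)]
        rows = []
        for t, m in cells:
            rows += [(t, m, 1)] * 10 + [(t, m, 0)] * 10
        df = pd.DataFrame(rows, columns=["t", "m", "y"])
        stat, dfree, p = lr_interaction_test(df, ModelSpec("y", ("1", "T", "M")))
        assert stat == pytest.approx(0.0, abs=1e-8)
        assert (dfree, p) == (1, pytest.approx(1.0))

    def test_power_against_true_interaction(self):
        dgp = dataclasses.replace(stress_dgps()["interaction"], n=2000)
        spec = ModelSpec("y", ("1", "T", "M", "c"))
        rng = np.random.default_rng(7)
        rejections = 0
        reps = 200
        for _ in range(reps):
            data = generate_trial(dgp, seed=int(rng.integers(2**31)))
            _, _, p = lr_interaction_test(data, spec)
            rejections += p < 0.05
        assert rejections / reps > 0.5

    def test_invariant_to_affine_recoding(self, mixed_trial):
        df = mixed_trial.data.assign(x=lambda d: d["c"] + np.random.default_rng(0).standard_normal(len(d)))
        spec = ModelSpec("y", ("1", "T", "M", "x"))
        stat1, _, _ = lr_interaction_test(df, spec)
        df2 = df.assign(x=lambda d: 3.5 * d["x"] - 11.0)
        stat2, _, _ = lr_interaction_test(df2, spec)
        assert stat1 == pytest.approx(stat2, abs=1e-6)


class TestSimulationProperties:
    def test_estimator_consistency(self):
        # each fitted coefficient within 3 SE of truth in >= 95% of replicates
        truth = {"1": -1.0, "T": 0.5, "M": 1.5, "c": 0.5}
        dgp = dataclasses.replace(stress_dgps()["mixed"], n=20000)
        spec = ModelSpec("y", ("1", "T", "M", "c"))
        rng = np.random.default_rng(99)
        hits = []
        for _ in range(100):
            data = generate_trial(dgp, seed=int(rng.integers(2**31)))
            fit = fit_logistic(data, spec)
            se = np.sqrt(np.diag(fit.vcov))
            tv = np.array([truth[t] for t in spec.terms])
            hits.append(np.all(np.abs(fit.beta - tv) <= 3 * se))
        assert np.mean(hits) >= 0.95

    def test_model_se_matches_empirical_sd(self):
        dgp = dataclasses.replace(stress_dgps()["mixed"], n=2000)
        spec = ModelSpec("y", ("1", "T", "M", "c"))
        rng = np.random.default_rng(123)
        betas, ses = [], []
        for _ in range(500):
            data = generate_trial(dgp, seed=int(rng.integers(2**31)))
            fit = fit_logistic(data, spec)
            betas.append(fit.beta)
            ses.append(np.sqrt(np.diag(fit.vcov)))
        emp_sd = np.std(np.array(betas), axis=0, ddof=1)
        model_se = np.mean(np.array(ses), axis=0)
        assert np.all(np.abs(model_se / emp_sd - 1.0) < 0.15)
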