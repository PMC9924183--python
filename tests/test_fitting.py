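"""Estimator correctness against closed-form, brute-force and GLM oracles."""

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize

from rctadjust.config import TrialConfig
from rctadjust.fitting import (
    FitResult,
    fit_sample_adjusted,
    fit_true_adjusted,
    fit_unadjusted,
    significance,
)
from rctadjust.generate import TrialSample, generate_trial

from conftest import make_counts_sample


def _loglik(sample, b0, b1, b2=0.0, offset=0.0):
    """Exact Bernoulli log-likelihood, written independently of the fitter."""
    eta = b0 + b1 * sample.treatment + b2 * sample.covariate + offset
    p = 1.0 / (1.0 + np.exp(-eta))
    return float(np.sum(sample.outcome * np.log(p) + (1 - sample.outcome) * np.log(1 - p)))


def _random_sample(seed, n=30, kind="binary", beta1=0.5, beta2=-1.0):
    cfg = TrialConfig(n, beta1, beta2, kind)
    return generate_trial(cfg, np.random.default_rng(seed)), cfg


class TestUnadjustedClosedForm:
    def test_log_odds_ratio_of_2x2_table(self):
        """The MLE with one binary regressor is the 2x2 log odds ratio."""
        fit = fit_unadjusted(make_counts_sample(30, 50, 20, 50))
        assert fit.converged
        assert fit.treatment_coef == pytest.approx(np.log(2.25), abs=1e-7)
        assert fit.intercept == pytest.approx(np.log(20 / 30), abs=1e-7)
        # Woolf standard error of the log odds ratio
        assert fit.std_error == pytest.approx(
            np.sqrt(1 / 30 + 1 / 20 + 1 / 20 + 1 / 30), abs=1e-6
        )

    def test_equal_event_counts_give_zero_effect(self):
        fit = fit_unadjusted(make_counts_sample(17, 40, 17, 40))
        assert fit.treatment_coef == pytest.approx(0.0, abs=1e-10)

    def test_zero_cell_flags_nonconvergence(self):
        """All events in one arm => infinite MLE => converged False."""
        assert not fit_unadjusted(make_counts_sample(50, 50, 20, 50)).converged
        assert not fit_unadjusted(make_counts_sample(0, 50, 20, 50)).converged

    def test_degenerate_outcome_flags_nonconvergence(self):
        sample, _ = _random_sample(5)
        dead = TrialSample(
            treatment=sample.treatment,
            covariate=sample.covariate,
            outcome=np.zeros_like(sample.outcome),
            risk=sample.risk,
        )
        assert not fit_unadjusted(dead).converged
        assert not fit_sample_adjusted(dead).converged


class TestBruteForceOracle:
    """Agreement with direct Nelder-Mead maximization of the likelihood."""

    @pytest.mark.parametrize("seed", [1, 2, 3, 4])
    def test_all_three_models_on_tiny_samples(self, seed):
        sample, cfg = _random_sample(seed, n=20, kind="binary")

        def nm(fun, p):
            res = minimize(
                fun,
                np.zeros(p),
                method="Nelder-Mead",
                options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000},
            )
            return res.x

        fit = fit_unadjusted(sample)
        ref = nm(lambda b: -_loglik(sample, b[0], b[1]), 2)
        if fit.converged:
            assert fit.treatment_coef == pytest.approx(ref[1], abs=1e-4)
            assert fit.intercept == pytest.approx(ref[0], abs=1e-4)

        fit = fit_sample_adjusted(sample)
        ref = nm(lambda b: -_loglik(sample, b[0], b[1], b2=b[2]), 3)
        if fit.converged:
            assert fit.treatment_coef == pytest.approx(ref[1], abs=1e-4)
            assert fit.covariate_coef == pytest.approx(ref[2], abs=1e-4)
        else:
            # flagged quasi-separation: the brute-force optimum diverges too
            assert np.abs(ref).max() > 8

        fit = fit_true_adjusted(sample, cfg.beta2)
        ref = nm(
            lambda b: -_loglik(sample, b[0], b[1], offset=cfg.beta2 * sample.covariate),
            2,
        )
        if fit.converged:
            assert fit.treatment_coef == pytest.approx(ref[1], abs=1e-4)


class TestGLMCrossCheck:
    """Coefficients, standard errors and Wald p-values match statsmodels GLM."""

    @pytest.mark.parametrize("seed", [11, 12])
    def test_sample_adjusted(self, seed):
        sample, _ = _random_sample(seed, n=60, kind="continuous")
        fit = fit_sample_adjusted(sample)
        X = sm.add_constant(np.column_stack([sample.treatment, sample.covariate]))
        ref = sm.GLM(sample.outcome, X, family=sm.families.Binomial()).fit()
        assert fit.intercept == pytest.approx(ref.params[0], abs=1e-6)
        assert fit.treatment_coef == pytest.approx(ref.params[1], abs=1e-6)
        assert fit.covariate_coef == pytest.approx(ref.params[2], abs=1e-6)
        assert fit.std_error == pytest.approx(ref.bse[1], rel=1e-5)
        assert fit.p_value == pytest.approx(ref.pvalues[1], rel=1e-5)

    def test_true_adjusted_offset_model(self):
        sample, cfg = _random_sample(21, n=60, kind="continuous")
        fit = fit_true_adjusted(sample, cfg.beta2)
        X = sm.add_constant(sample.treatment.astype(float))
        ref = sm.GLM(
            sample.outcome,
            X,
            family=sm.families.Binomial(),
            offset=cfg.beta2 * sample.covariate,
        ).fit()
        assert fit.treatment_coef == pytest.approx(ref.params[1], abs=1e-6)
        assert fit.std_error == pytest.approx(ref.bse[1], rel=1e-5)
        assert fit.p_value == pytest.approx(ref.pvalues[1], rel=1e-5)


class TestProperties:
    @given(seed=st.integers(0, 10_000))
    @settings(derandomize=True, max_examples=30, deadline=None)
    def test_zero_offset_identity(self, seed):
        """Imposing a zero covariate effect is a no-op relative to no adjustment."""
        sample, _ = _random_sample(seed, n=25, kind="continuous", beta2=-0.5)
        a = fit_unadjusted(sample)
        b = fit_true_adjusted(sample, 0.0)
        if not a.converged:
            assert not b.converged
            return
        for fld in ("intercept", "treatment_coef", "std_error", "p_value", "loglik"):
            assert getattr(a, fld) == pytest.approx(getattr(b, fld), abs=1e-8)

    def test_zero_covariate_vector_makes_offset_vacuous(self):
        sample = make_counts_sample(28, 50, 21, 50)
        a = fit_unadjusted(sample)
        b = fit_true_adjusted(sample, beta2_true=-1.0)
        assert a.treatment_coef == pytest.approx(b.treatment_coef, abs=1e-10)
        assert a.std_error == pytest.approx(b.std_error, abs=1e-10)

    @given(seed=st.integers(0, 10_000))
    @settings(derandomize=True, max_examples=20, deadline=None)
    def test_mle_dominates_true_parameters(self, seed):
        """Fitted log-likelihood is at least that of the generating values."""
        sample, cfg = _random_sample(seed, n=40, kind="continuous", beta1=1.0)
        fit = fit_sample_adjusted(sample)
        if fit.converged:
            assert fit.loglik >= _loglik(sample, 0.0, cfg.beta1, b2=cfg.beta2) - 1e-9
        fit = fit_unadjusted(sample)
        if fit.converged:
            assert fit.loglik >= _loglik(sample, 0.0, cfg.beta1) - 1e-9

    def test_sign_equivariance_under_arm_relabel(self):
        sample, cfg = _random_sample(33, n=40)
        flipped = TrialSample(
            treatment=1 - sample.treatment,
            covariate=sample.covariate,
            outcome=sample.outcome,
            risk=sample.risk,
        )
        a, b = fit_unadjusted(sample), fit_unadjusted(flipped)
        assert b.treatment_coef == pytest.approx(-a.treatment_coef, abs=1e-8)
        assert b.intercept == pytest.approx(a.intercept + a.treatment_coef, abs=1e-8)
        assert b.p_value == pytest.approx(a.p_value, abs=1e-8)


class TestConsistency:
    """Large-sample recovery of the generating parameters."""

    def test_sample_adjustment_recovers_beta2(self):
        cfg = TrialConfig(100_000, 1.0, -1.0, "continuous")
        sample = generate_trial(cfg, np.random.default_rng(42))
        fit = fit_sample_adjusted(sample)
        assert fit.covariate_coef == pytest.approx(-1.0, abs=0.05)
        assert fit.treatment_coef == pytest.approx(1.0, abs=0.05)

    def test_true_model_recovers_beta1(self):
        cfg = TrialConfig(100_000, 1.0, -1.0, "continuous")
        sample = generate_trial(cfg, np.random.default_rng(43))
        fit = fit_true_adjusted(sample, -1.0)
        assert fit.treatment_coef == pytest.approx(1.0, abs=0.03)

    def test_irrelevant_covariate_leaves_effect_unchanged(self):
        cfg = TrialConfig(50_000, 1.0, 0.0, "continuous")
        sample = generate_trial(cfg, np.random.default_rng(44))
        adj = fit_sample_adjusted(sample)
        unadj = fit_unadjusted(sample)
        assert adj.covariate_coef == pytest.approx(0.0, abs=0.05)
        assert adj.treatment_coef == pytest.approx(unadj.treatment_coef, abs=0.02)


class TestSignificance:
    def test_strict_threshold(self):
        base = dict(
            model_kind="unadjusted",
            intercept=0.0,
            treatment_coef=0.5,
            std_error=0.25,
            converged=True,
            loglik=-10.0,
        )
        assert significance(FitResult(p_value=0.049, **base), 0.05)
        assert not significance(FitResult(p_value=0.05, **base), 0.05)
        assert not significance(FitResult(p_value=0.50, **base), 0.05)

    def test_nonconverged_fit_rejected(self):
        fit = FitResult(
            model_kind="unadjusted",
            intercept=np.nan,
            treatment_coef=np.nan,
            std_error=np.nan,
            p_value=np.nan,
            converged=False,
            loglik=np.nan,
        )
        with pytest.raises(ValueError):
            significance(fit, 0.05)
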