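"""Parametric survival families, censored MLE, selection, hazard ratios."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from psmcea.curves import (
    FAMILIES,
    CurveError,
    FitError,
    ParametricFit,
    SurvivalFunction,
    apply_hazard_ratio,
    fit_all_families,
    fit_parametric,
    select_distribution,
    survival_at,
)

EXAMPLE_PARAMS = {
    "exponential": {"rate": 0.0753},
    "weibull": {"shape": 1.2, "scale": 13.27},
    "gompertz": {"shape": 0.03, "rate": 0.05},
    "gengamma": {"mu": 2.3, "sigma": 0.8, "q": 0.7},
    "loglogistic": {"scale": 9.2, "shape": 1.4},
    "lognormal": {"mu": 2.2, "sigma": 0.9},
}


@pytest.mark.parametrize("family", FAMILIES)
def test_survival_boundary_and_monotone(family):
    """S(0)=1, S in [0,1], nonincreasing on a dense grid — every family."""
    fn = SurvivalFunction(family, EXAMPLE_PARAMS[family])
    assert survival_at(fn, 0.0) == 1.0
    grid = np.linspace(0.0, 120.0, 1000)
    s = fn.survival(grid)
    assert np.all((s >= 0) & (s <= 1))
    assert np.all(np.diff(s) <= 1e-12)


@pytest.mark.parametrize("family", FAMILIES)
def test_inverse_survival_round_trip(family):
    fn = SurvivalFunction(family, EXAMPLE_PARAMS[family])
    u = np.array([0.9, 0.5, 0.2, 0.05])
    t = fn.inverse_survival(u)
    np.testing.assert_allclose(fn.survival(t), u, rtol=1e-8)


def test_survival_at_closed_form_examples():
    # exponential: median at ln(2)/rate
    exp = SurvivalFunction("exponential", {"rate": math.log(2) / 13.27})
    assert survival_at(exp, 13.27) == pytest.approx(0.5, abs=1e-12)
    # log-logistic scale parameter is the median by definition
    ll = SurvivalFunction("loglogistic", {"scale": 9.2, "shape": 1.0})
    assert survival_at(ll, 9.2) == pytest.approx(0.5, abs=1e-12)


def test_negative_gompertz_shape_plateaus():
    """Improper survival (plateau) is allowed for negative Gompertz shape."""
    fn = SurvivalFunction("gompertz", {"shape": -0.1, "rate": 0.05})
    plateau = math.exp(-0.05 / 0.1)
    assert survival_at(fn, 1e6) == pytest.approx(plateau, rel=1e-9)


def test_invalid_parameters_rejected():
    with pytest.raises(CurveError):
        SurvivalFunction("weibull", {"shape": -1.0, "scale": 10.0})
    with pytest.raises(CurveError):
        SurvivalFunction("weibull", {"shape": 1.0})
    with pytest.raises(CurveError):
        survival_at(SurvivalFunction("exponential", {"rate": 0.1}), -1.0)


class TestHazardRatio:
    def test_identity_and_example(self):
        base = SurvivalFunction("weibull", {"shape": 1.2, "scale": 13.27})
        same = apply_hazard_ratio(base, 1.0)
        t = np.linspace(0, 60, 50)
        np.testing.assert_allclose(same.survival(t), base.survival(t))
        # S=0.5 shifted by hr=0.39 -> 0.5**0.39
        exp = SurvivalFunction("exponential", {"rate": math.log(2) / 9.2})
        shifted = apply_hazard_ratio(exp, 0.39)
        assert float(shifted.survival(9.2)) == pytest.approx(0.7631296, abs=1e-6)

    def test_exponential_median_scales_inversely(self):
        exp = SurvivalFunction("exponential", {"rate": math.log(2) / 9.2})
        shifted = apply_hazard_ratio(exp, 0.39)
        new_median = float(shifted.inverse_survival(0.5))
        assert new_median == pytest.approx(9.2 / 0.39, rel=1e-9)

    def test_cumulative_hazard_ratio_exact(self):
        """H'(t)/H(t) = hr identically, and S(0)=1 / monotonicity survive."""
        base = SurvivalFunction("loglogistic", {"scale": 9.2, "shape": 1.4})
        fn = apply_hazard_ratio(base, 0.66)
        t = np.linspace(0.5, 100, 200)
        np.testing.assert_allclose(
            fn.cumulative_hazard(t) / base.cumulative_hazard(t), 0.66, rtol=1e-12
        )
        s = fn.survival(np.linspace(0, 100, 500))
        assert s[0] == 1.0 and np.all(np.diff(s) <= 1e-12)

    def test_invalid_hr(self):
        base = SurvivalFunction("exponential", {"rate": 0.1})
        with pytest.raises(CurveError):
            apply_hazard_ratio(base, 0.0)


class TestFitting:
    def test_exponential_mle_closed_form(self):
        """lambda-hat = events / person-time, exactly; AIC/BIC identities."""
        time = np.r_[np.full(20, 2.5), np.full(10, 5.0)]  # person-time 100
        event = np.r_[np.ones(20, int), np.zeros(10, int)]
        fit = fit_parametric((time, event), "exponential")
        assert fit.function.params["rate"] == pytest.approx(0.2, abs=1e-8)
        assert fit.loglik == pytest.approx(-52.18875824868201, abs=1e-6)
        assert fit.aic == pytest.approx(106.37751649736401, abs=1e-5)
        assert fit.bic == pytest.approx(107.77871387902617, abs=1e-5)
        assert fit.n_obs == 30 and fit.n_events == 20
        assert fit.converged

    def test_weibull_parameter_recovery(self, rng):
        """Estimates within 10% of truth at n=1000 with ~20% censoring."""
        truth = SurvivalFunction("weibull", {"shape": 1.2, "scale": 13.27})
        t = truth.inverse_survival(rng.uniform(size=1000))
        censor = 20.0
        event = (t <= censor).astype(int)
        obs = np.minimum(t, censor)
        fit = fit_parametric((obs, event), "weibull")
        assert fit.function.params["shape"] == pytest.approx(1.2, rel=0.10)
        assert fit.function.params["scale"] == pytest.approx(13.27, rel=0.10)

    def test_mle_beats_perturbed_parameters(self, rng):
        """Local-optimum check: no random perturbation improves the loglik."""
        truth = SurvivalFunction("loglogistic", {"scale": 9.2, "shape": 1.4})
        t = truth.inverse_survival(rng.uniform(size=400))
        event = (t <= 30.0).astype(int)
        obs = np.minimum(t, 30.0)
        fit = fit_parametric((obs, event), "loglogistic")

        def loglik(params):
            fn = SurvivalFunction("loglogistic", params)
            s = np.clip(fn.survival(obs), 1e-300, 1)
            return float(np.where(event == 1, fn.log_density(obs), np.log(s)).sum())

        base = loglik(fit.function.params)
        for _ in range(100):
            pert = {
                k: v * math.exp(rng.normal(0, 0.1))
                for k, v in fit.function.params.items()
            }
            assert loglik(pert) <= base + 1e-9

    def test_zero_events_raises(self):
        with pytest.raises(FitError):
            fit_parametric((np.array([1.0, 2.0]), np.array([0, 0])), "exponential")

    def test_agrees_with_lifelines(self, rng):
        """Independent oracle: lifelines' Weibull MLE on the same records."""
        from lifelines import WeibullFitter

        truth = SurvivalFunction("weibull", {"shape": 1.4, "scale": 10.0})
        t = truth.inverse_survival(rng.uniform(size=600))
        event = (t <= 25.0).astype(int)
        obs = np.minimum(t, 25.0)
        ours = fit_parametric((obs, event), "weibull")
        wf = WeibullFitter().fit(obs, event)
        assert ours.function.params["scale"] == pytest.approx(wf.lambda_, rel=1e-3)
        assert ours.function.params["shape"] == pytest.approx(wf.rho_, rel=1e-3)
        assert ours.loglik == pytest.approx(wf.log_likelihood_, rel=1e-6)


class TestSelection:
    @staticmethod
    def _fit(family, aic, bic, converged=True):
        fn = SurvivalFunction(family, EXAMPLE_PARAMS[family])
        return ParametricFit(fn, 0.0, aic, bic, 100, 50, converged)

    def test_minimum_criterion_wins(self):
        fits = [
            self._fit("weibull", 100, 101),
            self._fit("lognormal", 98, 99),
            self._fit("gompertz", 103, 104),
        ]
        assert select_distribution(fits, "aic").function.family == "lognormal"

    def test_tie_prefers_fewer_parameters(self):
        fits = [self._fit("weibull", 98, 99), self._fit("exponential", 98, 99)]
        assert select_distribution(fits, "aic").function.family == "exponential"

    def test_nonconverged_excluded(self):
        fits = [self._fit("weibull", 90, 91, converged=False), self._fit("exponential", 98, 99)]
        assert select_distribution(fits, "aic").function.family == "exponential"

    def test_exponential_truth_recovered_among_families(self, rng):
        """Nested-model sanity: simulated exponential data select exp/Weibull."""
        truth = SurvivalFunction("exponential", {"rate": 0.08})
        t = truth.inverse_survival(rng.uniform(size=2000))
        event = (t <= 40.0).astype(int)
        obs = np.minimum(t, 40.0)
        fits = fit_all_families((obs, event))
        best = select_distribution(fits, "aic")
        assert best.function.family in ("exponential", "weibull")


@settings(max_examples=30, deadline=None)
@given(
    shape=st.floats(0.5, 3.0),
    scale=st.floats(1.0, 50.0),
    hr=st.floats(0.1, 3.0),
)
def test_hazard_ratio_preserves_monotone_unit_range(shape, scale, hr):
    fn = apply_hazard_ratio(SurvivalFunction("weibull", {"shape": shape, "scale": scale}), hr)
    t = np.linspace(0.0, 100.0, 200)
    s = fn.survival(t)
    assert s[0] == 1.0
    assert np.all((s >= 0) & (s <= 1))
    assert np.all(np.diff(s) <= 1e-12)
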