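"""Survival-law evaluation, sampling, censored MLE and AIC selection."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from lifelines import LogLogisticFitter, WeibullFitter
from scipy import stats

from rccsim.survival import (
    FAMILIES,
    FitError,
    PseudoIPD,
    SurvivalModel,
    cycle_transition_prob,
    fit_mle,
    sample_time,
    select_best,
    survival_at,
)

CYCLE_MONTHS = 42.0 / 30.4375

MODELS = [
    SurvivalModel("weibull", 1.176426, 28.71649),
    SurvivalModel("loglogistic", 1.4257, 9.3505),
    SurvivalModel("lognormal", 1.3, 11.0),
    SurvivalModel("exponential", 2.281),
]


def _simulate_ipd(model, n, censor_frac, seed):
    rng = np.random.default_rng(seed)
    t = np.asarray(model.isf(rng.uniform(1e-12, 1 - 1e-12, n)))
    event = np.ones(n, dtype=int)
    if censor_frac > 0:
        cut = np.quantile(t, 1 - censor_frac)
        c = rng.uniform(0, 2 * cut, n)
        event = (t <= c).astype(int)
        t = np.minimum(t, c)
    return PseudoIPD(t, event)


class TestEvaluation:
    @pytest.mark.parametrize("model", MODELS, ids=lambda m: m.family)
    def test_survival_starts_at_one_and_decreases_to_zero(self, model):
        assert survival_at(model, 0.0) == pytest.approx(1.0)
        t = np.linspace(0.0, 1e4, 500)
        s = model.sf(t)
        assert np.all(np.diff(s) <= 1e-12)
        assert s[-1] < 1e-3

    def test_loglogistic_median_equals_scale(self):
        m = SurvivalModel("loglogistic", 1.4257, 9.3505)
        assert survival_at(m, 9.3505) == pytest.approx(0.5)

    def test_weibull_survival_at_scale_is_inverse_e(self):
        m = SurvivalModel("weibull", 1.176426, 28.71649)
        assert survival_at(m, 28.71649) == pytest.approx(math.exp(-1.0))

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            survival_at(MODELS[0], -1.0)

    def test_exponential_interpretation_switch(self):
        mean = SurvivalModel("exponential", 2.281, exp_as="mean_months")
        rate = SurvivalModel("exponential", 2.281, exp_as="rate_per_month")
        yearly = SurvivalModel("exponential", 2.281, exp_as="rate_per_year")
        assert mean.sf(2.281) == pytest.approx(math.exp(-1.0))
        assert rate.exp_mean == pytest.approx(1.0 / 2.281)
        assert yearly.exp_mean == pytest.approx(12.0 / 2.281)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            SurvivalModel("weibull", -1.0, 2.0)
        with pytest.raises(ValueError):
            SurvivalModel("weibull", 1.0, None)
        with pytest.raises(ValueError):
            SurvivalModel("gamma", 1.0, 2.0)


class TestCycleTransition:
    def test_exponential_is_memoryless(self):
        m = SurvivalModel("exponential", 2.281)
        p0 = cycle_transition_prob(m, 0.0, CYCLE_MONTHS)
        p5 = cycle_transition_prob(m, 5.0, CYCLE_MONTHS)
        assert p0 == pytest.approx(p5)

    def test_vanishes_as_dt_shrinks(self):
        m = SurvivalModel("loglogistic", 1.569, 15.064)
        assert cycle_transition_prob(m, 3.0, 1e-9) == pytest.approx(0.0, abs=1e-6)

    def test_first_cycle_probability_matches_survival(self):
        m = SurvivalModel("loglogistic", 1.569, 15.064)
        assert cycle_transition_prob(m, 0.0, CYCLE_MONTHS) == pytest.approx(
            1.0 - m.sf(CYCLE_MONTHS)
        )

    @settings(derandomize=True, max_examples=40)
    @given(
        t=st.floats(0.0, 50.0),
        d1=st.floats(0.1, 5.0),
        d2=st.floats(0.1, 5.0),
    )
    def test_chain_rule_over_consecutive_intervals(self, t, d1, d2):
        m = SurvivalModel("weibull", 1.3, 12.0)
        p1 = cycle_transition_prob(m, t, d1)
        p2 = cycle_transition_prob(m, t + d1, d2)
        combined = cycle_transition_prob(m, t, d1 + d2)
        assert combined == pytest.approx(1.0 - (1.0 - p1) * (1.0 - p2), abs=1e-12)

    def test_exhausted_survival_means_certain_transition(self):
        m = SurvivalModel("weibull", 3.0, 1.0)
        assert cycle_transition_prob(m, 1e4, 1.0) == pytest.approx(1.0)


class TestSampling:
    def test_median_identity(self):
        m = SurvivalModel("loglogistic", 1.4257, 9.3505)
        assert sample_time(m, 0.5) == pytest.approx(m.scale)

    def test_boundary_behaviour(self):
        m = SurvivalModel("weibull", 1.3, 12.0)
        assert sample_time(m, 1 - 1e-12) < 1e-6
        with pytest.raises(ValueError):
            sample_time(m, 0.0)

    @pytest.mark.parametrize(
        "model",
        [SurvivalModel("weibull", 1.3, 12.0), SurvivalModel("loglogistic", 1.6, 15.0)],
        ids=lambda m: m.family,
    )
    def test_draws_match_survival_function(self, model):
        rng = np.random.default_rng(7)
        draws = sample_time(model, rng.uniform(1e-12, 1 - 1e-12, 100_000))
        res = stats.kstest(draws, lambda t: 1.0 - np.asarray(model.sf(t)))
        assert res.statistic < 0.01


class TestFitting:
    def test_weibull_parameter_recovery(self):
        ipd = _simulate_ipd(SurvivalModel("weibull", 1.5, 10.0), 2000, 0.0, 11)
        fit = fit_mle(ipd, "weibull")
        assert 1.4 <= fit.model.shape <= 1.6
        assert 9.5 <= fit.model.scale <= 10.5

    def test_exponential_mle_is_sample_mean(self):
        ipd = _simulate_ipd(SurvivalModel("exponential", 4.0), 1500, 0.0, 3)
        fit = fit_mle(ipd, "exponential")
        assert fit.model.exp_mean == pytest.approx(ipd.time.mean(), rel=1e-3)
        assert fit.aic == pytest.approx(2.0 - 2.0 * fit.log_likelihood)

    def test_loglogistic_beats_weibull_on_heavy_tails(self):
        ipd = _simulate_ipd(SurvivalModel("loglogistic", 1.2, 10.0), 2000, 0.0, 5)
        assert fit_mle(ipd, "loglogistic").aic < fit_mle(ipd, "weibull").aic

    @pytest.mark.parametrize("family", FAMILIES)
    def test_recovery_within_ten_percent_under_censoring(self, family):
        true = (
            SurvivalModel("exponential", 6.0)
            if family == "exponential"
            else SurvivalModel(family, 1.5, 12.0)
        )
        ipd = _simulate_ipd(true, 2000, 0.2, 29)
        fit = fit_mle(ipd, family)
        assert fit.model.shape == pytest.approx(true.shape, rel=0.1)
        if family != "exponential":
            assert fit.model.scale == pytest.approx(true.scale, rel=0.1)

    def test_matches_lifelines_estimates(self):
        # independent route: the same censored likelihood maximized by lifelines
        ipd = _simulate_ipd(SurvivalModel("weibull", 1.4, 9.0), 1500, 0.15, 17)
        ours = fit_mle(ipd, "weibull").model
        ll = WeibullFitter().fit(ipd.time, ipd.event)
        assert ours.scale == pytest.approx(ll.lambda_, rel=1e-3)
        assert ours.shape == pytest.approx(ll.rho_, rel=1e-3)
        ipd2 = _simulate_ipd(SurvivalModel("loglogistic", 1.7, 14.0), 1500, 0.15, 19)
        ours2 = fit_mle(ipd2, "loglogistic").model
        ll2 = LogLogisticFitter().fit(ipd2.time, ipd2.event)
        assert ours2.scale == pytest.approx(ll2.alpha_, rel=1e-3)
        assert ours2.shape == pytest.approx(ll2.beta_, rel=1e-3)

    def test_requires_events(self):
        ipd = PseudoIPD(np.array([1.0, 2.0]), np.array([0, 0]))
        with pytest.raises(FitError):
            fit_mle(ipd, "weibull")


class TestSelection:
    def test_exponential_data_selects_exponential(self):
        ipd = _simulate_ipd(SurvivalModel("exponential", 5.0), 4000, 0.0, 4)
        assert select_best(ipd).model.family == "exponential"

    def test_loglogistic_data_selects_loglogistic(self):
        ipd = _simulate_ipd(SurvivalModel("loglogistic", 1.6, 15.0), 3000, 0.0, 31)
        assert select_best(ipd).model.family == "loglogistic"

    def test_single_family_returned(self):
        ipd = _simulate_ipd(SurvivalModel("weibull", 1.5, 10.0), 500, 0.0, 7)
        assert select_best(ipd, families=("lognormal",)).model.family == "lognormal"


class TestPseudoIPDIO:
    def test_tsv_round_trip(self, tmp_path):
        ipd = PseudoIPD(np.array([1.5, 2.0, 3.25]), np.array([1, 0, 1]))
        path = tmp_path / "ipd.tsv"
        ipd.write_tsv(path)
        back = PseudoIPD.read_tsv(path)
        np.testing.assert_array_equal(back.time, ipd.time)
        np.testing.assert_array_equal(back.event, ipd.event)
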