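"""Generative observer: per-trial contracts, steady state, mechanism table."""

import dataclasses
import math

import numpy as np
import pytest

from avtoj.observer import (
    ObserverParams,
    ObserverState,
    SerialModelParams,
    judge,
    posterior_estimate,
    predict_mixed_shifts,
    run_experiment,
    sense_interval,
    steady_state_pse,
    update_lag,
    update_prior,
)
from avtoj.psychometric import bin_responses, fit_psychometric
from avtoj.schedules import exp1_schedule, exp2_block

DESIGN = {"low": "sound_first", "high": "light_first"}


class TestSenseInterval:
    def test_full_adjustment_leaves_nothing(self, rng):
        assert abs(sense_interval(80.0, 80.0, 1e-12, rng)) < 1e-6

    def test_noise_moments(self):
        rng = np.random.default_rng(0)
        draws = np.array([sense_interval(0.0, 0.0, 100.0, rng)
                          for _ in range(100_000)])
        assert abs(draws.mean()) < 1.0
        assert abs(draws.std() - 100.0) < 1.0

    def test_nonfinite_rejected(self, rng):
        with pytest.raises(ValueError):
            sense_interval(float("nan"), 0.0, 10.0, rng)
        with pytest.raises(ValueError):
            sense_interval(0.0, 0.0, 0.0, rng)


class TestLagUpdate:
    def test_full_step(self):
        params = ObserverParams(alpha_lag=1.0)
        state = update_lag(ObserverState(), -235.0, "low", params)
        assert state.c["all"] == -235.0

    def test_frozen(self):
        params = ObserverParams(alpha_lag=0.0)
        state = update_lag(ObserverState(c={"all": 5.0}), 500.0, "low", params)
        assert state.c["all"] == 5.0

    def test_shared_channel_zeroes_out_on_alternating_stream(self):
        params = ObserverParams(alpha_lag=0.05)
        state = ObserverState()
        for i in range(10_000):
            update_lag(state, -235.0 if i % 2 else 235.0, "low", params)
        assert abs(state.c["all"]) < 20.0

    def test_per_pitch_channels_are_independent(self):
        params = ObserverParams(alpha_lag=1.0, lag_channels="per_pitch")
        state = ObserverState()
        update_lag(state, -235.0, "low", params)
        update_lag(state, 235.0, "high", params)
        assert state.c == {"low": -235.0, "high": 235.0}
        with pytest.raises(ValueError):
            update_lag(state, 0.0, "mid", params)


class TestPriorUpdate:
    def test_rate_one_jumps_to_sample(self):
        params = ObserverParams(prior_mode="online", online_rate=1.0)
        state = update_prior(ObserverState(), 42.0, "low", params)
        assert state.prior_mu["low"] == 42.0

    def test_oracle_mode_is_noop(self):
        params = ObserverParams(prior_mode="oracle")
        state = ObserverState(prior_mu={"low": 1.0}, prior_var={"low": 2.0})
        update_prior(state, 99.0, "low", params)
        assert state.prior_mu == {"low": 1.0}

    def test_no_channel_rejected(self):
        params = ObserverParams(prior_channels="none")
        with pytest.raises(ValueError):
            update_prior(ObserverState(), 0.0, "low", params)

    def test_ewma_converges_to_generating_moments(self):
        params = ObserverParams(prior_mode="online", online_rate=0.05)
        rng = np.random.default_rng(3)
        state = ObserverState()
        for x in rng.normal(80.0, 80.0, size=10_000):
            update_prior(state, float(x), "low", params)
        # stationary EWMA jitter: SD ~ 80*sqrt(r/(2-r)) ~ 13 ms
        assert abs(state.prior_mu["low"] - 80.0) < 40.0
        assert 0.5 * 80.0**2 < state.prior_var["low"] < 2.0 * 80.0**2


class TestPosteriorAndJudge:
    def test_equal_weight_average(self):
        assert posterior_estimate(0.0, 80.0, 50.0**2, 50.0) == pytest.approx(40.0)

    def test_flat_centre_shrinks_toward_zero(self):
        t_hat = posterior_estimate(100.0, 0.0, 30.0**2, 60.0)
        assert 0.0 < t_hat < 100.0

    def test_sharp_sensor_trusts_the_sample(self):
        assert posterior_estimate(33.0, 500.0, 100.0**2, 1e-6) == pytest.approx(
            33.0, abs=1e-6
        )
        with pytest.raises(ValueError):
            posterior_estimate(0.0, 0.0, -1.0, 10.0)

    def test_judge_signs_and_reproducible_tie(self):
        rng = np.random.default_rng(0)
        assert judge(5.0, rng) == "light_first"
        assert judge(-5.0, rng) == "sound_first"
        ties = [judge(0.0, np.random.default_rng(9)) for _ in range(3)]
        assert len(set(ties)) == 1
        with pytest.raises(ValueError):
            judge(float("inf"), rng)


class TestRunExperiment:
    def test_bit_identical_under_same_seed(self):
        blocks = exp1_schedule("sound_first", "low", 2, seed=0)
        params = ObserverParams()
        a = run_experiment(blocks, params, n_participants=2, seed=17)
        b = run_experiment(blocks, params, n_participants=2, seed=17)
        assert a.equals(b)
        c = run_experiment(blocks, params, n_participants=2, seed=18)
        assert not a["response"].equals(c["response"])

    def test_empty_schedule_rejected(self):
        with pytest.raises(ValueError):
            run_experiment([], ObserverParams(), seed=0)

    def test_pure_noise_observer_recovers_flat_psychometric(self):
        # no prior, frozen adaptation: P(light|tau) = Phi(tau / sigma_sensed)
        blocks = exp1_schedule("sound_first", "low", 32, seed=5)
        params = ObserverParams(prior_channels="none", alpha_lag=0.0)
        df = run_experiment(blocks, params, seed=11, initial_c=0.0)
        fit = fit_psychometric(bin_responses(df))
        assert abs(fit.d) < 8.0
        assert abs(fit.sigma - 80.0) < 8.0

    def test_blocked_bias_with_adapting_lag_shifts_toward_peak(self):
        blocks = exp1_schedule("sound_first", "low", 16, seed=2)
        params = ObserverParams(prior_channels="none", alpha_lag=0.2)
        df = run_experiment(blocks, params, seed=4)
        fit = fit_psychometric(bin_responses(df))
        assert fit.d < -50.0  # approaches the -80 ms exposure peak

    def test_mixed_design_reverses_the_tone_ordering(self):
        rng = np.random.default_rng(0)
        blocks = [exp2_block(DESIGN, rng) for _ in range(24)]
        params = ObserverParams()  # shared lag + per-pitch oracle priors
        df = run_experiment(blocks, params, seed=6)
        d = {p: fit_psychometric(bin_responses(df, pitch=p)).d
             for p in ("low", "high")}
        assert d["low"] > d["high"]  # sound-first tone above light-first tone

    def test_monotone_response_probability(self):
        blocks = exp1_schedule("sound_first", "low", 32, seed=1)
        df = run_experiment(blocks, ObserverParams(), seed=9)
        binned = bin_responses(df)
        rate = binned.k / binned.n
        # allow small Monte-Carlo wiggle on neighbouring bins
        assert np.all(np.diff(rate) > -0.12)


class TestSteadyStatePSE:
    def test_full_adaptation_limit_is_exact(self):
        for mu in (-80.0, 80.0, 13.0):
            p = SerialModelParams(mu, 80.0, 120.0, c=mu)
            assert steady_state_pse(p) == pytest.approx(mu)

    def test_pure_bayesian_term_opposes_the_prior(self):
        p = SerialModelParams(80.0, 80.0, 80.0, c=0.0)
        assert steady_state_pse(p) == pytest.approx(-40.0)
        sharper = dataclasses.replace(p, sigma_sensed=1e-6)
        assert steady_state_pse(sharper) == pytest.approx(0.0, abs=1e-9)
        noisier = dataclasses.replace(p, sigma_sensed=160.0)
        assert steady_state_pse(noisier) < steady_state_pse(p) < 0.0

    def test_linear_and_monotone_in_c(self):
        p = SerialModelParams(80.0, 80.0, 80.0)
        cs = np.linspace(0.0, 80.0, 9)
        vals = [steady_state_pse(dataclasses.replace(p, c=c)) for c in cs]
        assert all(b > a for a, b in zip(vals, vals[1:]))
        # linear interpolation between the two limits
        assert vals[4] == pytest.approx((vals[0] + vals[8]) / 2)

    def test_invalid_sigmas_rejected(self):
        with pytest.raises(ValueError):
            SerialModelParams(80.0, 0.0, 80.0)


class TestMixedPredictions:
    @pytest.mark.parametrize(
        "lag_specific,bayes,label",
        [
            (True, "none", "lag_adaptation"),
            (True, "shared", "lag_adaptation"),
            (True, "per_pitch", "lag_adaptation"),
            (False, "none", "null"),
            (False, "shared", "null"),
            (False, "per_pitch", "bayesian"),
        ],
    )
    def test_two_by_three_table(self, lag_specific, bayes, label):
        p = SerialModelParams(80.0, 80.0, 80.0)
        pred = predict_mixed_shifts(lag_specific, bayes, DESIGN, p)
        assert pred.label == label
        if lag_specific:
            assert pred.d_u == {"low": -80.0, "high": 80.0}
        elif bayes == "per_pitch":
            assert pred.d_u["low"] > 0.0 > pred.d_u["high"]
        else:
            assert pred.d_u == {"low": 0.0, "high": 0.0}

    def test_bad_inputs_rejected(self):
        p = SerialModelParams(80.0, 80.0, 80.0)
        with pytest.raises(ValueError):
            predict_mixed_shifts(True, "sometimes", DESIGN, p)
        with pytest.raises(ValueError):
            predict_mixed_shifts(True, "none",
                                 {"low": "sound_first", "high": "sound_first"}, p)


class TestOracleEquivalence:
    @pytest.mark.parametrize("mu,c", [(80.0, 0.0), (80.0, 40.0), (-80.0, -80.0)])
    def test_closed_form_matches_simulation(self, mu, c):
        cond = "light_first" if mu > 0 else "sound_first"
        pitch = "high" if mu > 0 else "low"
        blocks = exp1_schedule(cond, pitch, 32, seed=1)
        params = ObserverParams(alpha_lag=0.0)  # freeze c at its initial value
        d_hats = []
        for rep in range(6):
            df = run_experiment(blocks, params, seed=100 + rep, initial_c=c)
            d_hats.append(fit_psychometric(bin_responses(df)).d)
        expected = steady_state_pse(
            SerialModelParams(mu, math.sqrt(6464.0), 80.0, c=c)
        )
        se = np.std(d_hats, ddof=1) / math.sqrt(len(d_hats))
        assert abs(np.mean(d_hats) - expected) < 3.0 * max(se, 1.0)
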