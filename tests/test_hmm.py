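"""Exact-algorithm tests: closed forms, brute-force path enumeration, EM laws."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

import oracles
from blockhmm import (
    HMMModel,
    backward,
    baum_welch,
    forward,
    log_emission,
    posterior_stats,
    reestimate,
    viterbi,
)
from conftest import random_model


class TestModelValidation:
    def test_rejects_non_stochastic_rows(self):
        with pytest.raises(ValueError, match="row"):
            HMMModel(trans=[[0.5, 0.4], [0.5, 0.5]], means=[0, 1], variances=[1, 1], init=[0.5, 0.5])

    def test_rejects_bad_init(self):
        with pytest.raises(ValueError, match="initial"):
            HMMModel(trans=[[1.0]], means=[0], variances=[1], init=[0.9])

    def test_rejects_non_positive_variance(self):
        with pytest.raises(ValueError, match="variance"):
            HMMModel(trans=[[1.0]], means=[0], variances=[0.0], init=[1.0])


class TestLogEmission:
    def test_standard_normal_at_mode(self):
        assert log_emission(0.0, 0.0, 1.0) == pytest.approx(-0.5 * np.log(2 * np.pi), abs=1e-12)

    @pytest.mark.parametrize("mean,var", [(0.0, 1.0), (-2.5, 0.4), (7.0, 3.0)])
    def test_value_at_mean_depends_only_on_variance(self, mean, var):
        assert log_emission(mean, mean, var) == pytest.approx(-0.5 * np.log(2 * np.pi * var), abs=1e-12)

    @pytest.mark.parametrize("y,mean,var", [(1.5, 0.2, 0.7), (-3.0, 1.0, 2.5), (0.0, 0.0, 1e-4)])
    def test_matches_scipy_density(self, y, mean, var):
        assert log_emission(y, mean, var) == pytest.approx(
            norm.logpdf(y, mean, np.sqrt(var)), abs=1e-12
        )

    def test_rejects_non_positive_variance(self):
        with pytest.raises(ValueError):
            log_emission(0.0, 0.0, 0.0)


class TestForwardBackward:
    def test_single_state_chain_is_product_of_densities(self):
        m = HMMModel(trans=[[1.0]], means=[0.0], variances=[1.0], init=[1.0])
        res = forward(m, [0.0, 0.0])
        assert res.log_likelihood == pytest.approx(2 * (-0.5 * np.log(2 * np.pi)), abs=1e-12)

    def test_indistinguishable_states_collapse_to_single_gaussian(self, rng):
        # identical emissions in both states: transition structure is irrelevant
        m = HMMModel(trans=[[0.3, 0.7], [0.8, 0.2]], means=[1.0, 1.0],
                     variances=[0.5, 0.5], init=[0.4, 0.6])
        y = rng.normal(1.0, 0.7, 6)
        expected = norm.logpdf(y, 1.0, np.sqrt(0.5)).sum()
        assert forward(m, y).log_likelihood == pytest.approx(expected, abs=1e-10)

    def test_forward_matches_path_enumeration(self, two_state_model, two_state_obs):
        res = forward(two_state_model, two_state_obs)
        expected = oracles.enum_log_likelihood(two_state_model, two_state_obs)
        assert res.log_likelihood == pytest.approx(expected, rel=1e-10)

    def test_backward_terminal_is_one(self, two_state_model, two_state_obs):
        res = backward(two_state_model, two_state_obs)
        assert np.all(res.log_beta[-1] == 0.0)

    def test_backward_agrees_with_forward(self, two_state_model, two_state_obs):
        f = forward(two_state_model, two_state_obs)
        b = backward(two_state_model, two_state_obs)
        assert b.log_likelihood == pytest.approx(f.log_likelihood, abs=1e-8)

    @pytest.mark.parametrize("n_states,T", [(2, 5), (3, 5), (3, 8)])
    def test_random_models_match_enumeration(self, rng, n_states, T):
        m = random_model(rng, n_states)
        y = rng.normal(0, 2, T)
        assert forward(m, y).log_likelihood == pytest.approx(
            oracles.enum_log_likelihood(m, y), rel=1e-10
        )

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1), n_states=st.integers(1, 5), T=st.integers(1, 200))
    def test_alpha_beta_product_constant_over_time(self, seed, n_states, T):
        rng = np.random.default_rng(seed)
        m = random_model(rng, n_states)
        y = rng.normal(0, 2, T)
        f, b = forward(m, y), backward(m, y)
        per_t = [oracles._logsum(f.log_alpha[t] + b.log_beta[t]) for t in range(T)]
        assert np.allclose(per_t, f.log_likelihood, atol=1e-8)

    def test_rejects_empty_sequence(self, two_state_model):
        with pytest.raises(ValueError):
            forward(two_state_model, [])

    def test_agrees_with_hmmlearn_on_long_sequence(self, rng):
        # independent dynamic-programming implementation as cross-check
        from hmmlearn.hmm import GaussianHMM

        m = random_model(rng, 3)
        y = rng.normal(0, 2, 500)
        ref = GaussianHMM(n_components=3, covariance_type="diag", init_params="")
        ref.startprob_ = m.init
        ref.transmat_ = m.trans
        ref.means_ = m.means[:, None]
        ref.covars_ = m.variances[:, None]
        assert forward(m, y).log_likelihood == pytest.approx(
            ref.score(y[:, None]), rel=1e-10
        )
        _, path = viterbi(m, y)
        _, ref_path = ref.decode(y[:, None], algorithm="viterbi")
        assert np.array_equal(path, ref_path)


class TestViterbi:
    def test_single_state_path_scores_the_likelihood(self):
        m = HMMModel(trans=[[1.0]], means=[0.0], variances=[1.0], init=[1.0])
        y = [0.3, -0.2, 1.1]
        score, path = viterbi(m, y)
        assert np.all(path == 0)
        assert score == pytest.approx(forward(m, y).log_likelihood, abs=1e-12)

    def test_well_separated_means_follow_nearest_state(self):
        m = HMMModel(trans=[[0.5, 0.5], [0.5, 0.5]], means=[0.0, 10.0],
                     variances=[1.0, 1.0], init=[0.5, 0.5])
        y = np.array([0.0, 10.0, 10.0, 0.0, 10.0])
        _, path = viterbi(m, y)
        assert np.array_equal(path, [0, 1, 1, 0, 1])

    @pytest.mark.parametrize("n_states,T", [(2, 3), (2, 6), (3, 6)])
    def test_matches_exhaustive_maximization(self, rng, n_states, T):
        m = random_model(rng, n_states)
        y = rng.normal(0, 2, T)
        score, path = viterbi(m, y)
        exp_score, exp_path = oracles.enum_viterbi(m, y)
        assert score == pytest.approx(exp_score, rel=1e-10)
        assert np.array_equal(path, exp_path)

    def test_score_never_exceeds_total_likelihood(self, rng):
        for _ in range(10):
            m = random_model(rng, 3)
            y = rng.normal(0, 2, 20)
            score, _ = viterbi(m, y)
            assert score <= forward(m, y).log_likelihood + 1e-10


class TestPosteriors:
    def test_gamma_normalized_and_xi_marginalizes(self, rng):
        m = random_model(rng, 3)
        y = rng.normal(0, 2, 30)
        stats = posterior_stats(m, y, forward(m, y), backward(m, y))
        assert np.allclose(stats.gamma.sum(axis=1), 1.0, atol=1e-8)
        assert np.allclose(stats.xi.sum(axis=(1, 2)), 1.0, atol=1e-8)
        assert np.allclose(stats.xi.sum(axis=2), stats.gamma[:-1], atol=1e-8)

    def test_single_state_posteriors_are_one(self):
        m = HMMModel(trans=[[1.0]], means=[0.0], variances=[1.0], init=[1.0])
        y = [0.5, 1.5, -1.0]
        stats = posterior_stats(m, y, forward(m, y), backward(m, y))
        assert np.allclose(stats.gamma, 1.0) and np.allclose(stats.xi, 1.0)

    def test_matches_enumerated_posteriors(self, two_state_model, two_state_obs):
        stats = posterior_stats(
            two_state_model, two_state_obs,
            forward(two_state_model, two_state_obs),
            backward(two_state_model, two_state_obs),
        )
        gamma, xi = oracles.enum_posteriors(two_state_model, two_state_obs)
        assert np.allclose(stats.gamma, gamma, rtol=1e-10, atol=1e-12)
        assert np.allclose(stats.xi, xi, rtol=1e-10, atol=1e-12)


class TestReestimate:
    def test_single_state_collapses_to_sample_moments(self, rng):
        m = HMMModel(trans=[[1.0]], means=[5.0], variances=[4.0], init=[1.0])
        y = rng.normal(0, 1, 50)
        new = reestimate(m, y, posterior_stats(m, y, forward(m, y), backward(m, y)))
        assert new.init[0] == pytest.approx(1.0)
        assert new.trans[0, 0] == pytest.approx(1.0)
        assert new.means[0] == pytest.approx(y.mean(), abs=1e-10)
        assert new.variances[0] == pytest.approx(y.var(), abs=1e-10)  # biased /T

    def test_rows_stochastic_and_variances_positive(self, rng):
        for _ in range(5):
            m = random_model(rng, 3)
            y = rng.normal(0, 2, 40)
            new = reestimate(m, y, posterior_stats(m, y, forward(m, y), backward(m, y)))
            assert np.allclose(new.trans.sum(axis=1), 1.0, atol=1e-12)
            assert np.all(new.variances > 0)

    def test_zero_transitions_stay_zero(self, rng):
        A = np.array([[0.7, 0.3, 0.0], [0.0, 0.6, 0.4], [0.5, 0.0, 0.5]])
        m = HMMModel(trans=A, means=[0, 3, 6], variances=[1, 1, 1], init=[1 / 3] * 3)
        y = rng.normal(3, 3, 60)
        new = reestimate(m, y, posterior_stats(m, y, forward(m, y), backward(m, y)))
        assert np.all(new.trans[A == 0.0] == 0.0)

    def test_one_em_step_matches_enumerated_accumulation(self, two_state_model, two_state_obs):
        stats = posterior_stats(
            two_state_model, two_state_obs,
            forward(two_state_model, two_state_obs),
            backward(two_state_model, two_state_obs),
        )
        new = reestimate(two_state_model, two_state_obs, stats)
        gamma, xi = oracles.enum_posteriors(two_state_model, two_state_obs)
        e_init, e_trans, e_means, e_vars = oracles.enum_reestimate(
            two_state_model, two_state_obs, gamma, xi
        )
        assert np.allclose(new.init, e_init, rtol=1e-10)
        assert np.allclose(new.trans, e_trans, rtol=1e-10)
        assert np.allclose(new.means, e_means, rtol=1e-10)
        assert np.allclose(new.variances, e_vars, rtol=1e-9)


class TestBaumWelch:
    def test_critical_point_terminates_immediately(self, rng):
        y = rng.normal(2.0, 1.5, 100)
        # single-state model already fitted to its own sufficient statistics
        m = HMMModel(trans=[[1.0]], means=[y.mean()], variances=[y.var()], init=[1.0])
        _, trace = baum_welch(m, y, tol=1e-3, max_iter=100)
        assert len(trace) <= 3
        assert abs(trace[-1] - trace[0]) < 1e-3

    def test_likelihood_is_monotone(self, rng):
        for _ in range(5):
            m = random_model(rng, 2)
            y = rng.normal(0, 2, 120)
            _, trace = baum_welch(m, y, tol=1e-6, max_iter=20)
            assert np.all(np.diff(trace) >= -1e-8)

    def test_recovers_well_separated_means(self):
        from blockhmm.simulate import TopologySpec, build_model, kmeans_init, sample_sequence
        from blockhmm import match_means

        truth = build_model(TopologySpec("fully_connected", 2), 2000, 1.0)
        hits = 0
        for seed in range(10):
            _, y = sample_sequence(truth, 2000, 100 + seed)
            init = kmeans_init(y, 2, 2000, seed)
            fitted, _ = baum_welch(init, y, tol=1e-3, max_iter=100)
            if np.all(match_means(fitted.means, truth.means) < 0.15):
                hits += 1
        assert hits >= 9
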