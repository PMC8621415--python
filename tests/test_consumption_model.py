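"""Body weight, hierarchical amounts and consumption-frequency likelihoods."""

import math

import numpy as np
import pytest
from scipy import integrate, stats

from dietexpo.consumption_model import (
    AmountParams,
    BodyWeightParams,
    FrequencyParamsIndependent,
    FrequencyParamsMarkov,
    TransitionCounts,
    count_transitions,
    count_transitions_all,
    logit,
    loglik_amounts,
    loglik_bodyweight,
    loglik_frequency_independent,
    loglik_frequency_markov,
    markov_stationary,
)
from dietexpo.data_io import BodyWeightRecord, DiaryEntry

LOG_NORM_CONST = -0.5 * math.log(2 * math.pi)


class TestBodyWeight:
    def test_single_weight_at_mode(self):
        p = BodyWeightParams(mu_w=math.log(75.0), sigma_w=1.0)
        got = loglik_bodyweight(p, [BodyWeightRecord("r", 75.0)])
        assert got == pytest.approx(LOG_NORM_CONST)

    def test_additivity_for_identical_weights(self):
        p = BodyWeightParams(mu_w=4.0, sigma_w=0.3)
        one = loglik_bodyweight(p, [BodyWeightRecord("a", 60.0)])
        two = loglik_bodyweight(
            p, [BodyWeightRecord("a", 60.0), BodyWeightRecord("b", 60.0)]
        )
        assert two == pytest.approx(2 * one)

    def test_matches_direct_density(self, rng):
        w = rng.lognormal(4.3, 0.2, 10)
        p = BodyWeightParams(mu_w=4.25, sigma_w=0.25)
        expected = stats.norm.logpdf(np.log(w), 4.25, 0.25).sum()
        got = loglik_bodyweight(p, [BodyWeightRecord(f"r{i}", v) for i, v in enumerate(w)])
        assert got == pytest.approx(float(expected))


def _amount_params(nf, mu0=None, Cs=None, Cmu=None, nr=1):
    mu0 = np.zeros(nf) if mu0 is None else np.asarray(mu0, float)
    Cs = np.eye(nf) if Cs is None else np.asarray(Cs, float)
    Cmu = np.eye(nf) if Cmu is None else np.asarray(Cmu, float)
    return AmountParams(mu0=mu0, C_mu=Cmu, C_s=Cs, mu_r=np.tile(mu0, (nr, 1)))


class TestAmounts:
    def test_all_zero_day_contributes_nothing(self):
        p = _amount_params(2)
        weights = [BodyWeightRecord("a", 1.0)]
        with_day = loglik_amounts(
            p, [DiaryEntry("a", 1, (1.0, 1.0)), DiaryEntry("a", 2, (0.0, 0.0))], weights
        )
        without = loglik_amounts(p, [DiaryEntry("a", 1, (1.0, 1.0))], weights)
        assert with_day == pytest.approx(without)

    def test_single_food_reduces_to_univariate_normal(self):
        p = _amount_params(1, mu0=[0.5], Cs=[[0.8]])
        weights = [BodyWeightRecord("a", 1.0)]
        got = loglik_amounts(p, [DiaryEntry("a", 1, (2.0,))], weights)
        hier = stats.norm.logpdf(0.5, 0.5, 1.0)  # consumer mean at its prior mode
        expected = stats.norm.logpdf(math.log(2.0), 0.5, math.sqrt(0.8)) + hier
        assert got == pytest.approx(float(expected))

    def test_partial_day_equals_numerical_marginalization(self):
        """A day with one food unobserved equals the full bivariate density
        integrated over the missing coordinate."""
        Cs = np.array([[0.5, 0.3], [0.3, 0.9]])
        mu_r = np.array([0.2, -0.4])
        p = AmountParams(
            mu0=mu_r, C_mu=np.eye(2), C_s=Cs, mu_r=mu_r[None, :]
        )
        weights = [BodyWeightRecord("a", 1.0)]
        obs_amount = 1.7
        got = loglik_amounts(p, [DiaryEntry("a", 1, (obs_amount, 0.0))], weights)
        hier = stats.multivariate_normal.logpdf(mu_r, mu_r, np.eye(2))
        x0 = math.log(obs_amount)

        def joint(x1):
            return stats.multivariate_normal.pdf([x0, x1], mu_r, Cs)

        marg, _ = integrate.quad(joint, -30, 30, limit=200)
        assert got - hier == pytest.approx(math.log(marg), rel=1e-8)

    def test_non_pd_covariance_gives_neg_inf(self):
        p = _amount_params(2, Cs=[[1.0, 2.0], [2.0, 1.0]])
        got = loglik_amounts(
            p, [DiaryEntry("a", 1, (1.0, 1.0))], [BodyWeightRecord("a", 1.0)]
        )
        assert got == -math.inf


class TestFrequencyIndependent:
    def test_half_probability_two_days(self):
        p = FrequencyParamsIndependent(
            p0=np.array([0.5]), C_p=np.eye(1), p_r=np.array([[0.5]])
        )
        diaries = [DiaryEntry("a", 1, (1.0,)), DiaryEntry("a", 2, (0.0,))]
        got = loglik_frequency_independent(p, diaries)
        hier = stats.norm.logpdf(0.0, 0.0, 1.0)
        assert got == pytest.approx(2 * math.log(0.5) + float(hier))

    def test_consumption_with_zero_frequency_impossible(self):
        p = FrequencyParamsIndependent(
            p0=np.array([0.5]), C_p=np.eye(1), p_r=np.array([[0.0]])
        )
        got = loglik_frequency_independent(p, [DiaryEntry("a", 1, (1.0,))])
        assert got == -math.inf

    def test_matches_direct_pmf_product(self, rng):
        p_r = np.array([[0.3, 0.8], [0.6, 0.2]])
        p = FrequencyParamsIndependent(
            p0=np.array([0.4, 0.5]), C_p=np.eye(2) * 0.7, p_r=p_r
        )
        diaries = [
            DiaryEntry("a", 1, (1.0, 0.0)),
            DiaryEntry("a", 2, (0.0, 1.0)),
            DiaryEntry("b", 1, (1.0, 1.0)),
        ]
        bern = (
            math.log(0.3) + math.log(1 - 0.8)
            + math.log(1 - 0.3) + math.log(0.8)
            + math.log(0.6) + math.log(0.2)
        )
        theta0 = np.asarray(logit(np.array([0.4, 0.5])))
        hier = sum(
            stats.multivariate_normal.logpdf(
                np.asarray(logit(p_r[i])), theta0, np.eye(2) * 0.7
            )
            for i in range(2)
        )
        got = loglik_frequency_independent(p, diaries)
        assert got == pytest.approx(bern + float(hier), rel=1e-9)


class TestTransitions:
    def test_enumerated_example(self):
        c = count_transitions([0, 1, 1, 0])
        assert (c.x01, c.n0, c.x11, c.n1) == (1, 1, 1, 2)

    def test_no_consumption_days(self):
        c = count_transitions([0, 0])
        assert (c.x01, c.n0, c.x11, c.n1) == (0, 1, 0, 0)

    def test_pairs_partition(self, rng):
        for _ in range(20):
            seq = rng.integers(0, 2, size=10)
            c = count_transitions(seq)
            # brute-force enumeration over adjacent pairs
            pairs = list(zip(seq[:-1], seq[1:]))
            assert c.x01 == sum(1 for a, b in pairs if a == 0 and b == 1)
            assert c.x11 == sum(1 for a, b in pairs if a == 1 and b == 1)
            assert c.n0 == sum(1 for a, _ in pairs if a == 0)
            assert c.n0 + c.n1 == len(seq) - 1

    def test_pooling_across_respondents(self):
        diaries = [
            DiaryEntry("a", 1, (1.0,)), DiaryEntry("a", 2, (0.0,)),
            DiaryEntry("b", 1, (0.0,)), DiaryEntry("b", 2, (1.0,)),
            DiaryEntry("c", 1, (5.0,)),  # single day: no pairs
        ]
        (c,) = count_transitions_all(diaries)
        assert (c.x01, c.n0, c.x11, c.n1) == (1, 1, 0, 1)


class TestFrequencyMarkov:
    def test_sure_transition_contributes_zero(self):
        p = FrequencyParamsMarkov(p01=np.array([1.0]), p11=np.array([0.5]))
        counts = [TransitionCounts(x01=3, n0=3, x11=0, n1=0)]
        assert loglik_frequency_markov(p, counts) == 0.0

    def test_arithmetic_example(self):
        p = FrequencyParamsMarkov(p01=np.array([0.5]), p11=np.array([0.5]))
        counts = [TransitionCounts(x01=1, n0=2, x11=0, n1=0)]
        assert loglik_frequency_markov(p, counts) == pytest.approx(math.log(0.25))

    def test_posterior_is_conjugate_beta(self):
        """With a uniform prior the p01 kernel is Beta(x01+1, n0-x01+1)."""
        counts = [TransitionCounts(x01=4, n0=9, x11=2, n1=5)]
        grid = np.linspace(0.01, 0.99, 37)
        ref = stats.beta.logpdf(grid, 5, 6)
        got = np.array([
            loglik_frequency_markov(
                FrequencyParamsMarkov(p01=np.array([g]), p11=np.array([0.4])), counts
            )
            for g in grid
        ])
        # equal up to a constant in p01
        assert np.allclose(got - got[0], ref - ref[0], atol=1e-9)


class TestMarkovStationary:
    def test_direct_formula(self):
        assert markov_stationary(0.2, 0.7) == pytest.approx(0.4)

    def test_symmetric_chain_is_half(self):
        assert markov_stationary(0.25, 0.75) == pytest.approx(0.5)

    def test_absorbing_chain_rejected(self):
        with pytest.raises(ValueError):
            markov_stationary(0.0, 1.0)

    def test_long_run_occupancy_matches(self, rng):
        p01, p11 = 0.3, 0.6
        n = 100_000
        state = 0
        occ = 0
        u = rng.random(n)
        for i in range(n):
            p = p11 if state else p01
            state = 1 if u[i] < p else 0
            occ += state
        assert occ / n == pytest.approx(markov_stationary(p01, p11), abs=0.01)
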