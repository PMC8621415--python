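"""Exposure composition: closed forms, simulation, quantiles, adjustments."""

import math

import numpy as np
import pytest
from scipy import stats

from dietexpo.data_io import FrequencyOption
from dietexpo.exposure_engine import (
    QUANTILE_LEVELS,
    AcutePairDist,
    AdjustmentFactors,
    ParamDraw,
    acute_pair,
    acute_pair_mean_median,
    chronic_including_zeros,
    chronic_pair,
    exposure_frequency,
    mean_concentration,
    predictive_quantiles,
    simulate_acute_total,
    simulate_chronic_total,
    two_dim_summary,
    two_dim_summary_simulated,
)


def make_draw(
    mu_h=0.0, sigma_h=0.0, q=1.0, mu_w=0.0, sigma_w=0.0,
    mu0=(0.0, 0.0), Cs=None, Cmu=None, p0=(1.0, 1.0), Cp=None,
    p01=None, p11=None,
):
    nf = len(mu0)
    freq_opt = (
        FrequencyOption.MARKOV if p01 is not None
        else FrequencyOption.INDEPENDENT_DAYS
    )
    pairs = {("h", f): 0 for f in ("a", "b")[:nf]}
    return ParamDraw(
        foods=("a", "b")[:nf],
        occ_mu={p: mu_h for p in pairs},
        occ_sigma={p: sigma_h for p in pairs},
        occ_q={p: q for p in pairs},
        mu_w=mu_w, sigma_w=sigma_w,
        mu0=np.asarray(mu0, float),
        Cs=np.asarray(Cs if Cs is not None else np.zeros((nf, nf)), float),
        Cmu=np.asarray(Cmu if Cmu is not None else np.zeros((nf, nf)), float),
        p0=np.asarray(p0, float) if p01 is None else None,
        Cp=np.asarray(Cp if Cp is not None else np.zeros((nf, nf)), float)
        if p01 is None else None,
        p01=np.asarray(p01, float) if p01 is not None else None,
        p11=np.asarray(p11, float) if p11 is not None else None,
        frequency_option=freq_opt,
    )


RICH = dict(
    mu_h=-1.0, sigma_h=0.7, q=1.0, mu_w=math.log(75), sigma_w=0.2,
    mu0=(0.5, -0.2),
    Cs=[[0.3, 0.05], [0.05, 0.4]],
    Cmu=[[0.2, 0.02], [0.02, 0.25]],
)


class TestAcutePair:
    def test_degenerate_parameters_give_unit_exposure(self):
        d = acute_pair(make_draw(), "h", "a")
        assert d.ln_mu == 0.0 and d.ln_var == 0.0
        assert float(d.mean()) == float(d.median()) == 1.0

    def test_default_factors_are_identity(self):
        draw = make_draw(**RICH)
        d0 = acute_pair(draw, "h", "a")
        d1 = acute_pair(draw, "h", "a", AdjustmentFactors())
        assert d0.ln_mu == d1.ln_mu and d0.ln_var == d1.ln_var

    def test_mean_at_least_median(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            draw = make_draw(
                mu_h=rng.normal(), sigma_h=rng.uniform(0, 2),
                mu0=(rng.normal(), 0.0),
                Cs=np.diag(rng.uniform(0, 1, 2)), Cmu=np.diag(rng.uniform(0, 1, 2)),
                sigma_w=rng.uniform(0, 0.5),
            )
            mean, median = acute_pair_mean_median(draw, "h", "a")
            assert mean >= median

    def test_median_matches_product_of_lognormals_simulation(self):
        draw = make_draw(**RICH)
        d = acute_pair(draw, "h", "a")
        rng = np.random.default_rng(4)
        n = 10 ** 6
        s = rng.lognormal(draw.mu0[0], math.sqrt(draw.Cs[0, 0] + draw.Cmu[0, 0]), n)
        w = rng.lognormal(draw.mu_w, draw.sigma_w, n)
        c = rng.lognormal(-1.0, 0.7, n)
        emp_median = np.median(s * w * c)
        assert emp_median == pytest.approx(float(d.median()), rel=0.01)


class TestChronicPair:
    def test_zero_sigma_mean_concentration(self):
        draw = make_draw(mu_h=1.5, sigma_h=0.0)
        assert mean_concentration(draw, ("h", "a")) == pytest.approx(math.exp(1.5))

    def test_zero_between_consumer_variance_degenerate(self):
        draw = make_draw(**{**RICH, "Cmu": np.zeros((2, 2))})
        d = chronic_pair(draw, "h", "a")
        assert d.ln_var == 0.0
        assert float(d.mean()) == pytest.approx(float(d.median()))

    def test_mean_matches_two_stage_simulation(self):
        draw = make_draw(**RICH)
        d = chronic_pair(draw, "h", "a")
        rng = np.random.default_rng(5)
        n = 10 ** 6
        mu_r = rng.normal(draw.mu0[0], math.sqrt(draw.Cmu[0, 0]), n)
        e_s = np.exp(mu_r + 0.5 * draw.Cs[0, 0])
        e_c = mean_concentration(draw, ("h", "a"))
        assert np.mean(e_s * e_c) == pytest.approx(float(d.mean()), rel=0.01)


class TestChronicIncludingZeros:
    def test_zero_prevalence_gives_zero_exposure(self):
        draw = make_draw(**{**RICH, "q": 0.0, "Cp": np.eye(2) * 0.3, "p0": (0.5, 0.5)})
        rng = np.random.default_rng(0)
        assert np.all(chronic_including_zeros(draw, "h", "a", 1000, rng) == 0)

    def test_sure_consumption_reduces_to_positives_only(self):
        draw = make_draw(**RICH)  # p0 = 1, Cp = 0, q = 1
        rng = np.random.default_rng(1)
        x = chronic_including_zeros(draw, "h", "a", 50_000, rng)
        d = chronic_pair(draw, "h", "a")
        ref = stats.lognorm(math.sqrt(float(d.ln_var)), scale=math.exp(float(d.ln_mu)))
        assert stats.kstest(x, ref.cdf).pvalue > 0.01

    def test_mean_of_product_under_independence(self):
        draw = make_draw(**{**RICH, "q": 0.6, "p0": (0.4, 0.5), "Cp": np.eye(2) * 0.5})
        rng = np.random.default_rng(2)
        x = chronic_including_zeros(draw, "h", "a", 400_000, rng)
        d = chronic_pair(draw, "h", "a")
        theta = rng.normal(float(np.log(0.4 / 0.6)), math.sqrt(0.5), 400_000)
        mean_p = float(np.mean(1 / (1 + np.exp(-theta))))
        expected = 0.6 * mean_p * float(d.mean())
        assert np.mean(x) == pytest.approx(expected, rel=0.02)


class TestSimulateTotals:
    def test_zero_prevalence_all_zero_doses(self):
        draw = make_draw(**{**RICH, "q": 0.0})
        rng = np.random.default_rng(0)
        total, doses = simulate_acute_total(draw, "h", 5000, ["a", "b"], rng)
        assert np.all(total == 0) and np.all(doses == 0)

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError):
            simulate_acute_total(
                make_draw(**RICH), "h", 10, [], np.random.default_rng(0)
            )

    def test_single_food_sequence_matches_closed_form(self):
        """With p = q = 1 the conditional-sequence simulation reproduces the
        closed-form log-normal pair distribution."""
        draw = make_draw(**RICH)
        rng = np.random.default_rng(7)
        total, _ = simulate_acute_total(draw, "h", 100_000, ["a"], rng)
        d = acute_pair(draw, "h", "a")
        ref = stats.lognorm(math.sqrt(float(d.ln_var)), scale=math.exp(float(d.ln_mu)))
        assert stats.kstest(total, ref.cdf).pvalue > 0.01

    def test_chronic_single_food_matches_closed_form(self):
        draw = make_draw(**RICH)
        rng = np.random.default_rng(8)
        total = simulate_chronic_total(draw, "h", 100_000, ["a"], rng)
        d = chronic_pair(draw, "h", "a")
        ref = stats.lognorm(math.sqrt(float(d.ln_var)), scale=math.exp(float(d.ln_mu)))
        assert stats.kstest(total, ref.cdf).pvalue > 0.01

    def test_log_acute_positives_are_normal_with_matching_moments(self):
        draw = make_draw(**RICH)
        rng = np.random.default_rng(9)
        total, _ = simulate_acute_total(draw, "h", 100_000, ["a"], rng)
        d = acute_pair(draw, "h", "a")
        logs = np.log(total)
        se_mean = math.sqrt(float(d.ln_var) / logs.size)
        assert logs.mean() == pytest.approx(float(d.ln_mu), abs=4 * se_mean)
        assert logs.var() == pytest.approx(float(d.ln_var), rel=0.03)

    def test_poisson_dose_conserves_mean_intensity(self):
        draw = make_draw(**RICH)
        rng = np.random.default_rng(10)
        total, doses = simulate_acute_total(draw, "h", 200_000, ["a"], rng)
        assert doses.mean() == pytest.approx(
            total.mean(), abs=4 * total.std() / math.sqrt(total.size)
        )

    def test_markov_stationary_frequency_used(self):
        draw = make_draw(
            mu_h=0.0, sigma_h=0.0, q=1.0, mu0=(0.0, 0.0),
            p01=(0.2, 0.2), p11=(0.7, 0.7),  # stationary p = 0.4
        )
        rng = np.random.default_rng(11)
        total, _ = simulate_acute_total(draw, "h", 100_000, ["a"], rng)
        assert (total > 0).mean() == pytest.approx(0.4, abs=0.006)


class TestPredictiveQuantiles:
    def test_constant_sample_collapses(self):
        t = predictive_quantiles(np.full(1000, 3.5))
        assert tuple(t) == QUANTILE_LEVELS
        assert all(v == 3.5 for v in t.values())

    def test_standard_lognormal_median_is_one(self):
        x = np.random.default_rng(1).lognormal(0, 1, 200_000)
        t = predictive_quantiles(x)
        assert t[50] == pytest.approx(1.0, abs=0.02)

    def test_values_non_decreasing(self, rng):
        x = rng.exponential(2.0, 5000)
        vals = list(predictive_quantiles(x).values())
        assert vals == sorted(vals)


class TestTwoDimSummary:
    def test_lognormal_quantile_uses_z95(self):
        d = AcutePairDist(ln_mu=np.array([0.0]), ln_var=np.array([1.0]), exposure_freq=1.0)
        out = two_dim_summary(d, 0.95)
        z95 = float(stats.norm.ppf(0.95))
        assert out["samples"][0] == pytest.approx(math.exp(z95))
        assert round(z95, 2) == 1.64

    def test_zero_uncertainty_degenerate(self):
        d = AcutePairDist(
            ln_mu=np.zeros(50), ln_var=np.ones(50), exposure_freq=1.0
        )
        out = two_dim_summary(d, 0.95)
        assert out["bounds_90"][0] == pytest.approx(out["bounds_90"][1])

    def test_empirical_inner_quantile_matches_closed_form(self, chemical_fit):
        _, _, _, draws = chemical_fit
        sim = two_dim_summary_simulated(
            draws, "chem1", ["food_a"], 0.95, kind="chronic",
            n_inner=20_000, n_outer=20, seed=1, positives_only=True,
        )
        from dietexpo.exposure_engine import iter_param_draws

        all_draws = list(iter_param_draws(draws))
        pick = np.linspace(0, len(all_draws) - 1, 20).astype(int)
        closed = np.array([
            float(
                np.exp(
                    chronic_pair(all_draws[i], "chem1", "food_a").ln_mu
                    + stats.norm.ppf(0.95)
                    * math.sqrt(chronic_pair(all_draws[i], "chem1", "food_a").ln_var)
                )
            )
            for i in pick
        ])
        assert np.allclose(sim["samples"], closed, rtol=0.08)


class TestAdjustmentFactors:
    def test_unit_factors_reproduce_unadjusted_bitwise(self):
        draw = make_draw(**RICH)
        f1 = AdjustmentFactors(conc={("h", "a"): 1.0}, prev={("h", "a"): 1.0})
        d0 = acute_pair(draw, "h", "a")
        d1 = acute_pair(draw, "h", "a", f1)
        assert d0.ln_mu == d1.ln_mu and d0.ln_var == d1.ln_var
        rng0, rng1 = np.random.default_rng(3), np.random.default_rng(3)
        t0, z0 = simulate_acute_total(draw, "h", 1000, ["a"], rng0)
        t1, z1 = simulate_acute_total(draw, "h", 1000, ["a"], rng1, f1)
        np.testing.assert_array_equal(t0, t1)
        np.testing.assert_array_equal(z0, z1)

    def test_concentration_factor_shifts_log_exposure(self):
        draw = make_draw(**RICH)
        k = 3.7
        f = AdjustmentFactors(conc={("h", "a"): k})
        d0 = acute_pair(draw, "h", "a")
        dk = acute_pair(draw, "h", "a", f)
        assert float(dk.ln_mu) - float(d0.ln_mu) == pytest.approx(math.log(k))
        assert float(dk.ln_var) == float(d0.ln_var)

    def test_quantiles_monotone_in_concentration_factor(self):
        draw = make_draw(**{**RICH, "q": 0.8, "p0": (0.6, 0.6), "Cp": np.eye(2) * 0.2})
        prev_quantiles = None
        for k in (1.0, 2.0, 5.0):
            rng = np.random.default_rng(12)
            total, _ = simulate_acute_total(
                draw, "h", 20_000, ["a", "b"], rng,
                AdjustmentFactors(conc={("h", "a"): k, ("h", "b"): k}),
            )
            tq = np.array(list(predictive_quantiles(total).values()))
            if prev_quantiles is not None:
                assert np.all(tq >= prev_quantiles)
            prev_quantiles = tq

    def test_prevalence_factor_clipped_and_validated(self):
        with pytest.raises(ValueError):
            AdjustmentFactors(prev={("h", "a"): 1.5})
        with pytest.raises(ValueError):
            AdjustmentFactors(conc={("h", "a"): 0.0})


class TestExposureFrequency:
    def test_product_of_frequency_and_prevalence(self):
        draw = make_draw(**{**RICH, "q": 1.0, "p0": (0.5, 0.5), "Cp": np.eye(2)})
        assert exposure_frequency(draw, "h", "a") == pytest.approx(0.5)

    def test_zero_prevalence(self):
        draw = make_draw(**{**RICH, "q": 0.0, "p0": (0.5, 0.5), "Cp": np.eye(2)})
        assert exposure_frequency(draw, "h", "a") == 0.0

    def test_markov_option_uses_stationary_probability(self):
        draw = make_draw(mu_h=0.0, q=1.0, p01=(0.2, 0.2), p11=(0.7, 0.7))
        assert exposure_frequency(draw, "h", "a") == pytest.approx(0.4)
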