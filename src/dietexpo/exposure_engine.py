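"""Compose posterior draws into exposure distributions.

Acute exposure (microbiological hazards) is the single-day dose from a
serving: consumption amount x concentration, with the realized bacterial
count Poisson-distributed around the expected dose. Chronic exposure
(chemical hazards) is the long-run mean daily exposure per body weight,
with concentration variability replaced by its mean.

For a single hazard-food pair both exposures are log-normal in closed
form because products of log-normals are log-normal:

* acute positives:  LN(mu0_j + mu_h + mu_w,  Cs_jj + Cmu_jj + sigma_h^2 + sigma_w^2)
* chronic positives: LN(mu0_j + Cs_jj/2 + log E(c),  Cmu_jj) with
  E(c) = exp(mu_h + sigma_h^2 / 2).

Totals over several foods have no closed form and are simulated by the
conditional sequence (frequencies -> indicators -> consumer means -> day
amounts -> body weight -> concentrations -> contamination indicators).
Each posterior draw defines one variability distribution; evaluating a
variability summary per draw yields its uncertainty distribution (2D
simulation), while drawing one variability realization per posterior draw
yields the posterior predictive distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
from scipy import stats

from .consumption_model import logit, markov_stationary
from .data_io import FrequencyOption
from .posterior_sampler import PosteriorDraws

#: The reported posterior predictive quantile levels (percent).
QUANTILE_LEVELS = (1, 5, 10, 50, 90, 95, 99)


@dataclass
class AdjustmentFactors:
    """Constant processing factors per hazard-food pair (defaults 1).

    ``conc`` multiplies concentrations in absolute scale (addition of
    log factor on the log scale); ``prev`` multiplies prevalence, clipped
    into [0, 1]. No uncertainty is attached to either.
    """

    conc: dict[tuple[str, str], float] = field(default_factory=dict)
    prev: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for v in self.conc.values():
            if not v > 0:
                raise ValueError("concentration factors must be positive")
        for v in self.prev.values():
            if not 0.0 <= v <= 1.0:
                raise ValueError("prevalence factors must lie in [0, 1]")

    def conc_for(self, pair: tuple[str, str]) -> float:
        return self.conc.get(pair, 1.0)

    def prev_for(self, pair: tuple[str, str]) -> float:
        return self.prev.get(pair, 1.0)


@dataclass
class AcutePairDist:
    """Log-normal acute positive exposure for one hazard-food pair.

    Fields may be scalars (one posterior draw) or arrays (all draws).
    """

    ln_mu: np.ndarray | float
    ln_var: np.ndarray | float
    exposure_freq: np.ndarray | float

    def mean(self):
        return np.exp(self.ln_mu + 0.5 * np.asarray(self.ln_var))

    def median(self):
        return np.exp(np.asarray(self.ln_mu))


@dataclass
class ChronicPairDist:
    """Log-normal chronic positive exposure for one hazard-food pair."""

    ln_mu: np.ndarray | float
    ln_var: np.ndarray | float
    exposure_freq: np.ndarray | float = 1.0

    def mean(self):
        return np.exp(self.ln_mu + 0.5 * np.asarray(self.ln_var))

    def median(self):
        return np.exp(np.asarray(self.ln_mu))


@dataclass
class ParamDraw:
    """All parameters of one posterior draw, in exposure-ready form."""

    foods: tuple[str, ...]
    occ_mu: dict[tuple[str, str], float]
    occ_sigma: dict[tuple[str, str], float]
    occ_q: dict[tuple[str, str], float]
    mu_w: float = 0.0
    sigma_w: float = 0.0
    mu0: np.ndarray | None = None
    Cs: np.ndarray | None = None
    Cmu: np.ndarray | None = None
    p0: np.ndarray | None = None
    Cp: np.ndarray | None = None
    p01: np.ndarray | None = None
    p11: np.ndarray | None = None
    frequency_option: FrequencyOption = FrequencyOption.INDEPENDENT_DAYS

    def food_index(self, food: str) -> int:
        return self.foods.index(food)

    def population_freq(self, j: int) -> float:
        """Population-level daily consumption frequency of food j."""
        if self.frequency_option is FrequencyOption.MARKOV:
            return float(markov_stationary(self.p01[j], self.p11[j]))
        return float(self.p0[j])


def iter_param_draws(draws: PosteriorDraws) -> Iterator[ParamDraw]:
    """Yield one :class:`ParamDraw` per retained draw (chains stacked)."""
    n = draws.n_chains * draws.n_iter
    foods = draws.foods
    nf = len(foods)
    pairs = draws.pairs
    freq_opt = FrequencyOption(draws.meta.get("frequency_option", "independent_days"))

    occ = {
        p: (
            draws.stacked(f"occ[{p[0]}|{p[1]}].mu"),
            draws.stacked(f"occ[{p[0]}|{p[1]}].sigma"),
            draws.stacked(f"occ[{p[0]}|{p[1]}].q"),
        )
        for p in pairs
        if f"occ[{p[0]}|{p[1]}].mu" in draws.params
    }
    has_bw = "bw.mu_w" in draws.params
    mu_w = draws.stacked("bw.mu_w") if has_bw else None
    sg_w = draws.stacked("bw.sigma_w") if has_bw else None
    has_amt = f"amt.mu0[0]" in draws.params
    if has_amt:
        mu0 = draws.vector("amt.mu0", nf)
        Cs = draws.matrix("amt.Cs", nf)
        Cmu = draws.matrix("amt.Cmu", nf)
    has_ind = "freq.p0[0]" in draws.params
    if has_ind:
        p0 = draws.vector("freq.p0", nf)
        Cp = draws.matrix("freq.Cp", nf)
    has_mkv = "freq.p01[0]" in draws.params
    if has_mkv:
        p01 = draws.vector("freq.p01", nf)
        p11 = draws.vector("freq.p11", nf)

    for i in range(n):
        yield ParamDraw(
            foods=foods,
            occ_mu={p: float(v[0][i]) for p, v in occ.items()},
            occ_sigma={p: float(v[1][i]) for p, v in occ.items()},
            occ_q={p: float(v[2][i]) for p, v in occ.items()},
            mu_w=float(mu_w[i]) if has_bw else 0.0,
            sigma_w=float(sg_w[i]) if has_bw else 0.0,
            mu0=mu0[i] if has_amt else None,
            Cs=Cs[i] if has_amt else None,
            Cmu=Cmu[i] if has_amt else None,
            p0=p0[i] if has_ind else None,
            Cp=Cp[i] if has_ind else None,
            p01=p01[i] if has_mkv else None,
            p11=p11[i] if has_mkv else None,
            frequency_option=freq_opt,
        )


def _adjusted_occ(
    draw: ParamDraw, pair: tuple[str, str], factors: AdjustmentFactors | None
) -> tuple[float, float, float]:
    """(mu_h + log conc_factor, sigma_h, clipped q * prev_factor)."""
    f = factors or AdjustmentFactors()
    mu = draw.occ_mu[pair] + math.log(f.conc_for(pair))
    q = draw.occ_q[pair]
    q = float(np.clip((0.0 if math.isnan(q) else q) * f.prev_for(pair), 0.0, 1.0))
    return mu, draw.occ_sigma[pair], q


def acute_pair(
    draw: ParamDraw,
    hazard: str,
    food: str,
    factors: AdjustmentFactors | None = None,
) -> AcutePairDist:
    """Closed-form acute positive exposure distribution for one pair."""
    j = draw.food_index(food)
    mu_h, sigma_h, q = _adjusted_occ(draw, (hazard, food), factors)
    ln_mu = draw.mu0[j] + mu_h + draw.mu_w
    ln_var = (
        draw.Cs[j, j] + draw.Cmu[j, j] + sigma_h ** 2 + draw.sigma_w ** 2
    )
    return AcutePairDist(
        ln_mu=float(ln_mu),
        ln_var=float(ln_var),
        exposure_freq=draw.population_freq(j) * q,
    )


def acute_pair_mean_median(draw: ParamDraw, hazard: str, food: str) -> tuple[float, float]:
    """Per-draw (mean, median) of acute positive exposure.

    mean = exp(mu0_j + mu_h + mu_w + (Cs_jj + Cmu_jj + sigma_h^2 + sigma_w^2)/2),
    median = exp(mu0_j + mu_h + mu_w); evaluating these over the posterior
    sample gives their uncertainty distributions.
    """
    d = acute_pair(draw, hazard, food)
    return float(d.mean()), float(d.median())


def mean_concentration(draw: ParamDraw, pair: tuple[str, str]) -> float:
    """E(c) = exp(mu_h + sigma_h^2 / 2) of the positive concentrations."""
    return math.exp(draw.occ_mu[pair] + 0.5 * draw.occ_sigma[pair] ** 2)


def chronic_pair(
    draw: ParamDraw,
    hazard: str,
    food: str,
    factors: AdjustmentFactors | None = None,
) -> ChronicPairDist:
    """Closed-form chronic positive exposure distribution for one pair.

    The between-consumer variability of the long-run mean daily exposure
    per body weight: LN(mu0_j + Cs_jj/2 + log E(c), Cmu_jj).
    """
    j = draw.food_index(food)
    mu_h, sigma_h, q = _adjusted_occ(draw, (hazard, food), factors)
    log_Ec = mu_h + 0.5 * sigma_h ** 2
    return ChronicPairDist(
        ln_mu=float(draw.mu0[j] + 0.5 * draw.Cs[j, j] + log_Ec),
        ln_var=float(draw.Cmu[j, j]),
        exposure_freq=draw.population_freq(j) * q,
    )


def chronic_pair_mean_median(draw: ParamDraw, hazard: str, food: str) -> tuple[float, float]:
    d = chronic_pair(draw, hazard, food)
    return float(d.mean()), float(d.median())


def chronic_including_zeros(
    draw: ParamDraw,
    hazard: str,
    food: str,
    n_consumers: int,
    rng: np.random.Generator,
    factors: AdjustmentFactors | None = None,
) -> np.ndarray:
    """Per-consumer chronic exposure including zeros: q * p_jr * E(e+).

    p_jr is logit-normal across consumers (independent-days option) or the
    Markov stationary constant; the positive part is log-normal.
    """
    j = draw.food_index(food)
    mu_h, sigma_h, q = _adjusted_occ(draw, (hazard, food), factors)
    d = chronic_pair(draw, hazard, food, factors)
    e_plus = rng.lognormal(float(d.ln_mu), math.sqrt(float(d.ln_var)), n_consumers)
    if draw.frequency_option is FrequencyOption.MARKOV:
        p_jr = np.full(n_consumers, draw.population_freq(j))
    else:
        theta = rng.normal(
            float(logit(draw.p0[j])), math.sqrt(draw.Cp[j, j]), n_consumers
        )
        p_jr = 1.0 / (1.0 + np.exp(-theta))
    return q * p_jr * e_plus


def _consumer_frequencies(
    draw: ParamDraw, n: int, subset_idx: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """(n, len(subset)) daily consumption probabilities per consumer."""
    if draw.frequency_option is FrequencyOption.MARKOV:
        p = np.array([draw.population_freq(j) for j in subset_idx])
        return np.tile(p, (n, 1))
    theta0 = np.asarray(logit(draw.p0), dtype=float)
    L = np.linalg.cholesky(draw.Cp + 1e-12 * np.eye(len(draw.foods)))
    theta = theta0 + rng.standard_normal((n, len(draw.foods))) @ L.T
    return 1.0 / (1.0 + np.exp(-theta[:, subset_idx]))


def simulate_acute_total(
    draw: ParamDraw,
    hazard: str,
    n_consumers: int,
    subset: Sequence[str],
    rng: np.random.Generator,
    factors: AdjustmentFactors | None = None,
    *,
    positives_only: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate summed acute exposure and Poisson doses for one draw.

    Follows the conditional sequence: consumer logit-frequencies (or
    Markov stationary p), Bernoulli consumption indicators, consumer mean
    vectors, day amounts, body weight, concentrations, contamination
    indicators; e_ijr = I * U * s * c * w summed over the subset, dose ~
    Poisson(total). ``positives_only`` forces all consumption and
    contamination indicators to one. The full food set must have been used
    in fitting; the subset only selects which foods are summed.
    """
    if len(subset) == 0:
        raise ValueError("food subset must not be empty")
    nf = len(draw.foods)
    idx = np.array([draw.food_index(f) for f in subset])
    p_r = _consumer_frequencies(draw, n_consumers, idx, rng)
    U = np.ones_like(p_r) if positives_only else (rng.random(p_r.shape) < p_r)
    mu_r = draw.mu0 + rng.standard_normal((n_consumers, nf)) @ np.linalg.cholesky(
        draw.Cmu + 1e-12 * np.eye(nf)
    ).T
    log_s = mu_r + rng.standard_normal((n_consumers, nf)) @ np.linalg.cholesky(
        draw.Cs + 1e-12 * np.eye(nf)
    ).T
    s = np.exp(log_s[:, idx])
    w = rng.lognormal(draw.mu_w, draw.sigma_w, n_consumers)
    total = np.zeros(n_consumers)
    for col, (f, j) in enumerate(zip(subset, idx)):
        mu_h, sigma_h, q = _adjusted_occ(draw, (hazard, f), factors)
        c = rng.lognormal(mu_h, sigma_h, n_consumers)
        contaminated = (
            np.ones(n_consumers) if positives_only else (rng.random(n_consumers) < q)
        )
        total += contaminated * U[:, col] * s[:, col] * c * w
    doses = rng.poisson(total)
    return total, doses


def simulate_chronic_total(
    draw: ParamDraw,
    hazard: str,
    n_consumers: int,
    subset: Sequence[str],
    rng: np.random.Generator,
    factors: AdjustmentFactors | None = None,
    *,
    positives_only: bool = False,
) -> np.ndarray:
    """Simulate per-consumer chronic totals E(e_ir) for one draw.

    Per the conditional sequence: consumer frequencies and mean vectors,
    then E(e_ijr+) = exp(mu_jr + Cs_jj/2 + mu_h + sigma_h^2/2) and
    E(e_ijr) = q * p_jr * E(e_ijr+), summed over the subset. No Poisson
    step — chronic exposure is a long-run mean, not a count.
    """
    if len(subset) == 0:
        raise ValueError("food subset must not be empty")
    nf = len(draw.foods)
    idx = np.array([draw.food_index(f) for f in subset])
    p_r = _consumer_frequencies(draw, n_consumers, idx, rng)
    mu_r = draw.mu0 + rng.standard_normal((n_consumers, nf)) @ np.linalg.cholesky(
        draw.Cmu + 1e-12 * np.eye(nf)
    ).T
    total = np.zeros(n_consumers)
    for col, (f, j) in enumerate(zip(subset, idx)):
        mu_h, sigma_h, q = _adjusted_occ(draw, (hazard, f), factors)
        e_plus = np.exp(mu_r[:, j] + 0.5 * draw.Cs[j, j] + mu_h + 0.5 * sigma_h ** 2)
        if positives_only:
            total += e_plus
        else:
            total += q * p_r[:, col] * e_plus
    return total


def predictive_quantiles(samples: np.ndarray) -> dict[int, float]:
    """The 1/5/10/50/90/95/99 % quantiles of a predictive sample.

    Returned in increasing level order; values are non-decreasing by
    construction (monotone quantile levels on one sample).
    """
    x = np.asarray(samples, dtype=float)
    vals = np.percentile(x, QUANTILE_LEVELS)
    vals = np.maximum.accumulate(vals)
    return {lev: float(v) for lev, v in zip(QUANTILE_LEVELS, vals)}


def posterior_predictive(
    draws: PosteriorDraws,
    hazard: str,
    subset: Sequence[str],
    *,
    kind: str,
    seed: int = 0,
    factors: AdjustmentFactors | None = None,
    positives_only: bool = False,
) -> np.ndarray:
    """One variability realization per posterior draw (n_U samples total).

    ``kind`` is ``"acute"`` (returns Poisson doses) or ``"chronic"``
    (per-consumer mean exposure). This integrates parameter uncertainty
    and consumer variability into a single predictive distribution.
    """
    if kind not in ("acute", "chronic"):
        raise ValueError("kind must be 'acute' or 'chronic'")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    out = np.empty(draws.n_chains * draws.n_iter)
    for i, draw in enumerate(iter_param_draws(draws)):
        if kind == "acute":
            _, dose = simulate_acute_total(
                draw, hazard, 1, subset, rng, factors, positives_only=positives_only
            )
            out[i] = dose[0]
        else:
            out[i] = simulate_chronic_total(
                draw, hazard, 1, subset, rng, factors, positives_only=positives_only
            )[0]
    return out


def two_dim_summary(
    dist: AcutePairDist | ChronicPairDist,
    gamma: float,
) -> dict:
    """Uncertainty distribution of the variability gamma-quantile (closed form).

    For a log-normal pair the variability quantile per posterior draw is
    exp(mu + z_gamma * sigma) (z_0.95 ~ 1.64); its posterior sample and the
    90% uncertainty bounds (5th and 95th percentiles) are returned.
    """
    z = float(stats.norm.ppf(gamma))
    samples = np.exp(
        np.asarray(dist.ln_mu, dtype=float)
        + z * np.sqrt(np.asarray(dist.ln_var, dtype=float))
    )
    samples = np.atleast_1d(samples)
    lo, hi = np.percentile(samples, [5, 95])
    return {"gamma": gamma, "samples": samples, "bounds_90": (float(lo), float(hi))}


def two_dim_summary_simulated(
    draws: PosteriorDraws,
    hazard: str,
    subset: Sequence[str],
    gamma: float,
    *,
    kind: str = "acute",
    n_inner: int = 10_000,
    n_outer: int | None = None,
    seed: int = 0,
    factors: AdjustmentFactors | None = None,
    positives_only: bool = False,
) -> dict:
    """Empirical 2D summary for simulated multi-food totals.

    Per posterior draw (outer loop, optionally thinned to ``n_outer``),
    the variability gamma-quantile is estimated from ``n_inner`` simulated
    consumers; the posterior sample of that quantile and its 90% bounds
    are returned.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 8]))
    all_draws = list(iter_param_draws(draws))
    if n_outer is not None and n_outer < len(all_draws):
        pick = np.linspace(0, len(all_draws) - 1, n_outer).astype(int)
        all_draws = [all_draws[i] for i in pick]
    qs = np.empty(len(all_draws))
    for i, draw in enumerate(all_draws):
        if kind == "acute":
            total, _ = simulate_acute_total(
                draw, hazard, n_inner, subset, rng, factors,
                positives_only=positives_only,
            )
        else:
            total = simulate_chronic_total(
                draw, hazard, n_inner, subset, rng, factors,
                positives_only=positives_only,
            )
        qs[i] = np.quantile(total, gamma)
    lo, hi = np.percentile(qs, [5, 95])
    return {"gamma": gamma, "samples": qs, "bounds_90": (float(lo), float(hi))}


def exposure_frequency(
    draw: ParamDraw,
    hazard: str,
    food: str,
    factors: AdjustmentFactors | None = None,
) -> float:
    """Proportion of days a contaminated serving of the food is consumed.

    Population consumption frequency (stationary probability under the
    Markov option) times the adjusted prevalence.
    """
    j = draw.food_index(food)
    _, _, q = _adjusted_occ(draw, (hazard, food), factors)
    return draw.population_freq(j) * q
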