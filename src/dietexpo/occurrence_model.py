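"""Log-posterior components for hazard occurrence.

A hazard's concentration in a food is modelled log-normally among
contaminated units: ``log c ~ Normal(mu, sigma)``. Measurements may be
exact (above LOQ), interval-censored (between LOD and LOQ) or non-detects
(below LOD). Two estimation options are supported:

* **separate** (Option 1): all records represent true positives; the
  censored-normal likelihood estimates (mu, sigma), while prevalence q is
  estimated from a separate binomial sample of positives.
* **zero-inflated** (Option 2): non-detects may be true zeros; prevalence
  enters the concentration likelihood directly — a non-detect occurs with
  probability 1 - q(1 - F(log LOD)), a detected record carries a factor q.

All evaluation is in log space; impossible parameter/data combinations
return ``-inf`` (never NaN, never an exception) so samplers can reject
safely.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data_io import Censor, OccurrenceRecord, PrevalenceSample

_LOG_EPS = 1e-300


@dataclass(frozen=True)
class OccurrenceParams:
    """(mu, sigma) of log-concentration among positives, and prevalence q."""

    mu: float
    sigma: float
    q: float = 1.0


@dataclass(frozen=True)
class OccurrencePrior:
    """Priors for the occurrence block.

    ``mu`` gets a wide normal (sd defaults to 1000 on the log scale — flat
    in practice but proper). ``sigma`` gets either Uniform(0, U), with U
    from :func:`sigma_upper_bound`, or a Gamma(a, b) prior on the precision
    1/sigma^2. Prevalence q gets Beta(1, 1).
    """

    mu_loc: float = 0.0
    mu_scale: float = 1000.0
    sigma_prior: str = "uniform"  # "uniform" | "gamma_precision"
    sigma_upper: float = 10.0      # U for the uniform option
    gamma_a: float = 0.01
    gamma_b: float = 0.01

    def __post_init__(self) -> None:
        if self.sigma_prior not in ("uniform", "gamma_precision"):
            raise ValueError(f"unknown sigma prior {self.sigma_prior!r}")
        if self.sigma_upper <= 0 or self.gamma_a <= 0 or self.gamma_b <= 0:
            raise ValueError("prior hyperparameters must be positive")


def _log_cdf_interval(lo: float, hi: float, mu: float, sigma: float) -> float:
    """log[F(hi) - F(lo)] for Normal(mu, sigma), cancellation-safe.

    When both endpoints sit in the same far tail the naive difference of
    CDFs underflows; the complementary (survival) form is used on the upper
    side and log-CDF subtraction on the lower side.
    """
    a = (lo - mu) / sigma
    b = (hi - mu) / sigma
    if not b > a:
        return -math.inf
    if a + b > 0:  # interval in the upper half: survival functions carry precision
        big, small = stats.norm.logsf(a), stats.norm.logsf(b)
    else:
        big, small = stats.norm.logcdf(b), stats.norm.logcdf(a)
    with np.errstate(divide="ignore"):
        out = float(big + np.log1p(-np.exp(small - big)))
    return out if math.isfinite(out) else -math.inf


def _safe_log(x: float) -> float:
    return math.log(x) if x > _LOG_EPS else -math.inf


def loglik_option1(
    params: OccurrenceParams,
    records: list[OccurrenceRecord],
    prev: "PrevalenceSample | None" = None,
) -> float:
    """Censored log-normal likelihood plus optional binomial prevalence.

    Exact records contribute the normal log-density at log c; interval
    records log[F(log LOQ) - F(log LOD)]; non-detects log F(log LOD); a
    prevalence sample contributes the binomial log-pmf of x successes in n
    trials with probability q.
    """
    mu, sigma, q = params.mu, params.sigma, params.q
    if not (sigma > 0) or not math.isfinite(mu):
        return -math.inf
    total = 0.0
    for r in records:
        if r.censor is Censor.EXACT:
            total += float(stats.norm.logpdf(math.log(r.value), mu, sigma))
        elif r.censor is Censor.INTERVAL:
            total += _log_cdf_interval(math.log(r.lod), math.log(r.loq), mu, sigma)
        else:  # BELOW_LOD
            if r.lod <= 0:
                return -math.inf
            total += float(stats.norm.logcdf((math.log(r.lod) - mu) / sigma))
        if total == -math.inf:
            return -math.inf
    if prev is not None:
        if not (0.0 <= q <= 1.0):
            return -math.inf
        total += float(stats.binom.logpmf(prev.n_positive, prev.n_total, q))
    return total if not math.isnan(total) else -math.inf


def loglik_option2(params: OccurrenceParams, records: list[OccurrenceRecord]) -> float:
    """Zero-inflated likelihood: prevalence jointly with (mu, sigma).

    Non-detect: log[1 - q(1 - F(log LOD))] — either a true zero or a
    positive below LOD. Interval: log q + log[F(log LOQ) - F(log LOD)].
    Exact: log q + normal log-density (the truncation normalizer of the
    conditional-on-detection density cancels against the detection
    probability, leaving the plain density times q).
    """
    mu, sigma, q = params.mu, params.sigma, params.q
    if not (sigma > 0) or not (0.0 <= q <= 1.0) or not math.isfinite(mu):
        return -math.inf
    log_q = _safe_log(q)
    total = 0.0
    for r in records:
        if r.censor is Censor.EXACT:
            total += log_q + float(stats.norm.logpdf(math.log(r.value), mu, sigma))
        elif r.censor is Censor.INTERVAL:
            total += log_q + _log_cdf_interval(
                math.log(r.lod), math.log(r.loq), mu, sigma
            )
        else:  # BELOW_LOD: 1 - q * P(detect) with P(detect) = sf(log LOD)
            if r.lod <= 0:
                p_detect = 1.0
            else:
                p_detect = float(stats.norm.sf((math.log(r.lod) - mu) / sigma))
            total += _safe_log(1.0 - q * p_detect)
        if total == -math.inf:
            return -math.inf
    return total if not math.isnan(total) else -math.inf


def sigma_upper_bound(
    log_values: np.ndarray, *, multiple: float = 5.0, min_range: float = 1.0
) -> float:
    """Empirical upper bound U for a Uniform(0, U) prior on sigma.

    The sample sd of the observed log-concentrations is inflated by
    appending two pseudo-extremes, ``min - R`` and ``max + R`` with
    ``R = max(range, min_range)``, then multiplied by ``multiple``. The
    augmentation guarantees a strictly positive bound even for a single
    observation; the bound is shift-invariant.
    """
    x = np.asarray(log_values, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("need at least one observed log-concentration")
    r = max(float(x.max() - x.min()), min_range)
    augmented = np.concatenate([x, [x.min() - r, x.max() + r]])
    return multiple * float(np.std(augmented, ddof=1))


def log_prior_occurrence(params: OccurrenceParams, prior: OccurrencePrior) -> float:
    """Sum of log prior densities; -inf outside the support.

    The gamma-precision option evaluates the Gamma(a, b) density at
    tau = 1/sigma^2 with the |d tau / d sigma| = 2/sigma^3 Jacobian so the
    result is a density in sigma.
    """
    mu, sigma, q = params.mu, params.sigma, params.q
    if not (sigma > 0) or not (0.0 <= q <= 1.0):
        return -math.inf
    total = float(stats.norm.logpdf(mu, prior.mu_loc, prior.mu_scale))
    if prior.sigma_prior == "uniform":
        if sigma >= prior.sigma_upper:
            return -math.inf
        total += -math.log(prior.sigma_upper)
    else:
        tau = sigma ** -2
        total += float(stats.gamma.logpdf(tau, prior.gamma_a, scale=1.0 / prior.gamma_b))
        total += math.log(2.0) - 3.0 * math.log(sigma)  # Jacobian of tau = sigma^-2
    # q ~ Beta(1, 1): log-density 0 on [0, 1]
    return total

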