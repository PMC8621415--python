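"""Log-posterior components for food consumption.

Body weights are log-normal. Positive consumption amounts per body weight
are hierarchical multivariate log-normal: on consumption days the vector of
log amounts of the ``nf`` foods is multivariate normal around a
consumer-specific mean vector (within-consumer covariance ``Cs``), and the
consumer mean vectors are themselves multivariate normal around population
means (between-consumer covariance ``Cmu``). Zero amounts are treated as
missing — a day a food was not eaten says nothing about how much would have
been eaten — so each day contributes the marginal density of its observed
(positive) coordinates only.

Consumption frequency has two options: independent days (Bernoulli
indicators with logit-multivariate-normal consumer frequencies, covariance
``Cp``) or a first-order Markov chain over consecutive diary days with
population-level transition probabilities p01 (0 -> 1) and p11 (1 -> 1),
whose stationary daily consumption probability is p01 / (p01 + p10).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data_io import BodyWeightRecord, DiaryEntry

_CLIP = 1e-12  # clamp for logit/log transforms near 0 and 1


@dataclass(frozen=True)
class BodyWeightParams:
    mu_w: float
    sigma_w: float


@dataclass
class AmountParams:
    """Hierarchical MVN parameters for log amounts per body weight.

    ``mu0``: population mean vector (length nf); ``C_mu``: between-consumer
    covariance of consumer means; ``C_s``: within-consumer day-to-day
    covariance; ``mu_r``: (nr, nf) consumer mean vectors, rows aligned with
    a fixed respondent ordering.
    """

    mu0: np.ndarray
    C_mu: np.ndarray
    C_s: np.ndarray
    mu_r: np.ndarray


@dataclass
class FrequencyParamsIndependent:
    """Logit-MVN consumer frequencies: p0 population, Cp covariance, p_r rows."""

    p0: np.ndarray
    C_p: np.ndarray
    p_r: np.ndarray


@dataclass
class FrequencyParamsMarkov:
    """Population day-to-day transition probabilities per food."""

    p01: np.ndarray
    p11: np.ndarray

    @property
    def p10(self) -> np.ndarray:
        return 1.0 - np.asarray(self.p11, dtype=float)

    @property
    def p00(self) -> np.ndarray:
        return 1.0 - np.asarray(self.p01, dtype=float)


@dataclass(frozen=True)
class TransitionCounts:
    """Observed adjacent-day transition counts for one food.

    ``x01`` of ``n0`` pairs had a non-consumption day followed by
    consumption; ``x11`` of ``n1`` pairs had consumption followed by
    consumption.
    """

    x01: int
    n0: int
    x11: int
    n1: int

    def __post_init__(self) -> None:
        if not (0 <= self.x01 <= self.n0 and 0 <= self.x11 <= self.n1):
            raise ValueError("transition counts must satisfy 0 <= x <= n")


def logit(p: np.ndarray | float) -> np.ndarray | float:
    p = np.clip(p, _CLIP, 1.0 - _CLIP)
    return np.log(p) - np.log1p(-p)


def expit(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def _chol_or_none(C: np.ndarray) -> np.ndarray | None:
    try:
        return np.linalg.cholesky(C)
    except np.linalg.LinAlgError:
        return None


def _mvn_logpdf(x: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> float:
    """MVN log-density returning -inf (not an exception) for non-PD cov."""
    L = _chol_or_none(np.asarray(cov, dtype=float))
    if L is None:
        return -math.inf
    d = np.atleast_1d(np.asarray(x, dtype=float) - np.asarray(mean, dtype=float))
    z = np.linalg.solve(L, d)
    out = -0.5 * float(z @ z) - float(np.log(np.diag(L)).sum()) - 0.5 * d.size * math.log(
        2.0 * math.pi
    )
    return out if math.isfinite(out) else -math.inf


def loglik_bodyweight(params: BodyWeightParams, weights: list[BodyWeightRecord] | np.ndarray) -> float:
    """Sum of normal log-densities of log body weights."""
    if not (params.sigma_w > 0):
        return -math.inf
    w = np.asarray(
        [r.weight for r in weights] if weights and isinstance(weights[0], BodyWeightRecord) else weights,
        dtype=float,
    )
    if np.any(w <= 0):
        return -math.inf
    return float(stats.norm.logpdf(np.log(w), params.mu_w, params.sigma_w).sum())


def amounts_per_bodyweight(
    diaries: list[DiaryEntry], weights: list[BodyWeightRecord]
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """(amounts matrix per bw, weight per entry row, respondent order).

    Rows follow the diary entry order; the respondent order is the sorted
    set of respondent ids (the row ordering used for ``mu_r`` and ``p_r``).
    """
    wmap = {r.respondent_id: r.weight for r in weights}
    amounts = np.array([e.amounts for e in diaries], dtype=float)
    w = np.array([wmap[e.respondent_id] for e in diaries], dtype=float)
    respondents = sorted({e.respondent_id for e in diaries})
    return amounts / w[:, None], w, respondents


def loglik_amounts(
    params: AmountParams,
    diaries: list[DiaryEntry],
    weights: list[BodyWeightRecord],
) -> float:
    """Marginal-MVN likelihood of positive per-body-weight log amounts.

    Each diary day contributes the log-density of its observed (positive)
    coordinates under the marginal MVN obtained by taking the matching
    sub-vector of the consumer mean and sub-block of ``C_s``. Days with no
    positive amount contribute nothing. The hierarchical term adds, per
    consumer, the MVN log-density of the consumer mean row given
    ``(mu0, C_mu)``. Non-positive-definite covariances give -inf.
    """
    if _chol_or_none(params.C_s) is None or _chol_or_none(params.C_mu) is None:
        return -math.inf
    per_bw, _, respondents = amounts_per_bodyweight(diaries, weights)
    ridx = {rid: i for i, rid in enumerate(respondents)}
    total = 0.0
    for row, entry in zip(per_bw, diaries):
        obs = np.flatnonzero(row > 0)
        if obs.size == 0:
            continue
        mean = params.mu_r[ridx[entry.respondent_id], obs]
        cov = params.C_s[np.ix_(obs, obs)]
        total += _mvn_logpdf(np.log(row[obs]), mean, cov)
        if total == -math.inf:
            return -math.inf
    for i in range(len(respondents)):
        total += _mvn_logpdf(params.mu_r[i], params.mu0, params.C_mu)
        if total == -math.inf:
            return -math.inf
    return total


def consumption_indicators(diaries: list[DiaryEntry]) -> tuple[np.ndarray, list[str]]:
    """0/1 consumption indicators per diary row, plus respondent order."""
    u = (np.array([e.amounts for e in diaries], dtype=float) > 0).astype(int)
    respondents = sorted({e.respondent_id for e in diaries})
    return u, respondents


def loglik_frequency_independent(
    params: FrequencyParamsIndependent,
    diaries: list[DiaryEntry],
) -> float:
    """Bernoulli likelihood of daily indicators + logit-MVN hierarchy."""
    if _chol_or_none(params.C_p) is None:
        return -math.inf
    u, respondents = consumption_indicators(diaries)
    ridx = {rid: i for i, rid in enumerate(respondents)}
    total = 0.0
    for row, entry in zip(u, diaries):
        p = params.p_r[ridx[entry.respondent_id]]
        if np.any((p <= 0) & (row == 1)) or np.any((p >= 1) & (row == 0)):
            return -math.inf
        p = np.clip(p, _CLIP, 1.0 - _CLIP)
        total += float(np.where(row == 1, np.log(p), np.log1p(-p)).sum())
    theta0 = logit(params.p0)
    for i in range(len(respondents)):
        total += _mvn_logpdf(logit(params.p_r[i]), theta0, params.C_p)
        if total == -math.inf:
            return -math.inf
    return total if math.isfinite(total) else -math.inf


def count_transitions(day_indicators: np.ndarray) -> TransitionCounts:
    """Adjacent-day transition counts for one respondent and one food.

    ``day_indicators`` is the 0/1 consumption sequence over consecutive
    days, in day order. ``n0 + n1`` equals the number of adjacent pairs.
    """
    u = np.asarray(day_indicators, dtype=int).ravel()
    prev, nxt = u[:-1], u[1:]
    return TransitionCounts(
        x01=int(((prev == 0) & (nxt == 1)).sum()),
        n0=int((prev == 0).sum()),
        x11=int(((prev == 1) & (nxt == 1)).sum()),
        n1=int((prev == 1).sum()),
    )


def count_transitions_all(diaries: list[DiaryEntry]) -> list[TransitionCounts]:
    """Pooled transition counts per food across all respondents.

    Respondents with a single diary day contribute no pairs. Day indices
    must be consecutive per respondent (validated at spec-building time).
    """
    by_resp: dict[str, list[DiaryEntry]] = {}
    for e in diaries:
        by_resp.setdefault(e.respondent_id, []).append(e)
    nf = len(diaries[0].amounts)
    x01 = np.zeros(nf, int)
    n0 = np.zeros(nf, int)
    x11 = np.zeros(nf, int)
    n1 = np.zeros(nf, int)
    for entries in by_resp.values():
        entries = sorted(entries, key=lambda e: e.day_index)
        u = (np.array([e.amounts for e in entries]) > 0).astype(int)
        for j in range(nf):
            c = count_transitions(u[:, j])
            x01[j] += c.x01
            n0[j] += c.n0
            x11[j] += c.x11
            n1[j] += c.n1
    return [
        TransitionCounts(x01=int(x01[j]), n0=int(n0[j]), x11=int(x11[j]), n1=int(n1[j]))
        for j in range(nf)
    ]


def loglik_frequency_markov(
    params: FrequencyParamsMarkov, counts: list[TransitionCounts]
) -> float:
    """Binomial-kernel likelihood of the per-food transition counts.

    Per food: p01^x01 (1-p01)^(n0-x01) * p11^x11 (1-p11)^(n1-x11), with a
    uniform prior on both transition probabilities (so this is also the
    log-posterior kernel).
    """
    p01 = np.atleast_1d(np.asarray(params.p01, dtype=float))
    p11 = np.atleast_1d(np.asarray(params.p11, dtype=float))
    if np.any((p01 < 0) | (p01 > 1) | (p11 < 0) | (p11 > 1)):
        return -math.inf
    total = 0.0
    for j, c in enumerate(counts):
        for p, x, n in ((p01[j], c.x01, c.n0), (p11[j], c.x11, c.n1)):
            if x > 0:
                if p == 0:
                    return -math.inf
                total += x * math.log(p)
            if n - x > 0:
                if p == 1:
                    return -math.inf
                total += (n - x) * math.log1p(-p)
    return total


def markov_stationary(p01: np.ndarray | float, p11: np.ndarray | float) -> np.ndarray | float:
    """Stationary daily consumption probability p01 / (p01 + p10).

    Undefined (raises) when p01 = p10 = 0: both states are absorbing and
    the chain has no unique stationary distribution.
    """
    p01 = np.asarray(p01, dtype=float)
    p10 = 1.0 - np.asarray(p11, dtype=float)
    denom = p01 + p10
    if np.any(denom <= 0):
        raise ValueError("stationary probability undefined when p01 = p10 = 0")
    out = p01 / denom
    return float(out) if out.ndim == 0 else out
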