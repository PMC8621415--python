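"""Joint MCMC sampling of all active model parameters.

The posterior is the product of the active likelihood components and the
priors. Occurrence and consumption share no parameters, so their blocks are
sampled as independent sub-posteriors — the factorization is exact and each
block gets its own deterministic seed stream, which makes the occurrence
draws identical whether or not the consumption block is co-sampled.

Sampling strategy per block:

* prevalence q (separate option) — exact conjugate Beta draws;
* Markov transition probabilities — exact conjugate Beta draws;
* censored / zero-inflated concentration (mu, sigma[, q]) — adaptive
  random-walk Metropolis on the unconstrained scale (mu, log sigma
  [, logit q]), step size tuned during burn-in only;
* body weight — conjugate Normal / Gamma Gibbs;
* amounts hierarchy — Gibbs with data augmentation: missing (zero)
  coordinates of partially observed days are imputed from their
  conditional MVN, after which consumer means, population means and both
  covariances (inverse-Wishart) have closed-form conditionals;
* independent-days frequencies — per-consumer random-walk Metropolis on
  the logit scale (vectorized over consumers), conjugate MVN update for
  the population logit mean and inverse-Wishart for Cp.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .consumption_model import logit
from .data_io import (
    BodyWeightRecord,
    Censor,
    DiaryEntry,
    FrequencyOption,
    ModelSpec,
    OccurrenceOption,
    OccurrenceRecord,
    PrevalenceSample,
)
from .occurrence_model import OccurrencePrior, sigma_upper_bound

_MU_PRIOR_SD = 1000.0  # "flat" but proper normal prior sd for location params
_GIBBS_GAMMA_A = 0.01  # weak Gamma(a, b) prior on log-scale precisions
_GIBBS_GAMMA_B = 0.01


@dataclass
class DataBundle:
    """All input data for one run."""

    occ_records: list[OccurrenceRecord] = field(default_factory=list)
    prev_samples: list[PrevalenceSample] = field(default_factory=list)
    diaries: list[DiaryEntry] = field(default_factory=list)
    weights: list[BodyWeightRecord] = field(default_factory=list)
    foods: tuple[str, ...] = ()


@dataclass
class PosteriorDraws:
    """Retained joint posterior draws, one array per scalar parameter.

    ``params[name]`` has shape (n_chains, n_iter). Naming convention:
    ``occ[hazard|food].mu/.sigma/.q``, ``bw.mu_w/.sigma_w``,
    ``amt.mu0[j]``, ``amt.Cs[j,k]``, ``amt.Cmu[j,k]``, ``freq.p0[j]``,
    ``freq.Cp[j,k]``, ``freq.p01[j]``, ``freq.p11[j]`` with j, k food
    indices in the run's food ordering.
    """

    n_chains: int
    n_iter: int
    params: dict[str, np.ndarray]
    meta: dict

    def __post_init__(self) -> None:
        for name, arr in self.params.items():
            if arr.shape != (self.n_chains, self.n_iter):
                raise ValueError(
                    f"{name}: shape {arr.shape} != ({self.n_chains}, {self.n_iter})"
                )

    @property
    def foods(self) -> tuple[str, ...]:
        return tuple(self.meta.get("foods", ()))

    @property
    def pairs(self) -> tuple[tuple[str, str], ...]:
        return tuple((h, f) for h, f in self.meta.get("pairs", ()))

    def stacked(self, name: str) -> np.ndarray:
        """All chains concatenated: shape (n_chains * n_iter,)."""
        return self.params[name].reshape(-1)

    def matrix(self, prefix: str, nf: int) -> np.ndarray:
        """Per-draw (nf, nf) matrices for e.g. prefix 'amt.Cs'."""
        out = np.empty((self.n_chains * self.n_iter, nf, nf))
        for j in range(nf):
            for k in range(nf):
                out[:, j, k] = self.stacked(f"{prefix}[{j},{k}]")
        return out

    def vector(self, prefix: str, nf: int) -> np.ndarray:
        """Per-draw length-nf vectors for e.g. prefix 'amt.mu0'."""
        out = np.empty((self.n_chains * self.n_iter, nf))
        for j in range(nf):
            out[:, j] = self.stacked(f"{prefix}[{j}]")
        return out

    def to_frame(self) -> pd.DataFrame:
        data = {
            "chain": np.repeat(np.arange(self.n_chains), self.n_iter),
            "draw": np.tile(np.arange(self.n_iter), self.n_chains),
        }
        for name, arr in self.params.items():
            data[name] = arr.reshape(-1)
        return pd.DataFrame(data)

    def save(self, path) -> None:
        """Single columnar Parquet file, run metadata in the schema."""
        import pyarrow as pa
        import pyarrow.parquet as pq

        table = pa.Table.from_pandas(self.to_frame(), preserve_index=False)
        meta = dict(table.schema.metadata or {})
        meta[b"dietexpo"] = json.dumps(self.meta).encode()
        pq.write_table(table.replace_schema_metadata(meta), path)

    @classmethod
    def load(cls, path) -> "PosteriorDraws":
        import pyarrow.parquet as pq

        table = pq.read_table(path)
        meta = json.loads(table.schema.metadata[b"dietexpo"].decode())
        df = table.to_pandas()
        n_chains = int(df["chain"].max()) + 1
        n_iter = int((df["chain"] == 0).sum())
        params = {
            c: df[c].to_numpy().reshape(n_chains, n_iter)
            for c in df.columns
            if c not in ("chain", "draw")
        }
        return cls(n_chains=n_chains, n_iter=n_iter, params=params, meta=meta)


# ---------------------------------------------------------------------------
# vectorized occurrence log-likelihood pieces


class _OccData:
    """Per-pair record arrays for fast likelihood evaluation."""

    def __init__(self, records: list[OccurrenceRecord]):
        self.log_exact = np.array(
            [math.log(r.value) for r in records if r.censor is Censor.EXACT]
        )
        self.iv_lo = np.array(
            [math.log(r.lod) for r in records if r.censor is Censor.INTERVAL]
        )
        self.iv_hi = np.array(
            [math.log(r.loq) for r in records if r.censor is Censor.INTERVAL]
        )
        nd = [r.lod for r in records if r.censor is Censor.BELOW_LOD]
        self.nd_ok = all(l > 0 for l in nd)
        self.nd_lo = np.array([math.log(l) for l in nd if l > 0])
        self.n_detected = self.log_exact.size + self.iv_lo.size


def _log_cdf_diff_vec(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """log(Phi(b) - Phi(a)) elementwise for standard-normal bounds a < b."""
    upper = a + b > 0
    big = np.where(upper, special.log_ndtr(-a), special.log_ndtr(b))
    small = np.where(upper, special.log_ndtr(-b), special.log_ndtr(a))
    with np.errstate(divide="ignore", invalid="ignore"):
        out = big + np.log1p(-np.exp(small - big))
    return out


def _occ_loglik1(d: _OccData, mu: float, sigma: float) -> float:
    total = 0.0
    if d.log_exact.size:
        z = (d.log_exact - mu) / sigma
        total += float(-0.5 * (z ** 2).sum() - d.log_exact.size * (
            math.log(sigma) + 0.5 * math.log(2 * math.pi)))
    if d.iv_lo.size:
        total += float(
            _log_cdf_diff_vec((d.iv_lo - mu) / sigma, (d.iv_hi - mu) / sigma).sum()
        )
    if d.nd_lo.size or not d.nd_ok:
        if not d.nd_ok:
            return -math.inf
        total += float(special.log_ndtr((d.nd_lo - mu) / sigma).sum())
    return total if math.isfinite(total) else -math.inf


def _occ_loglik2(d: _OccData, mu: float, sigma: float, q: float) -> float:
    if not (0.0 <= q <= 1.0):
        return -math.inf
    total = _occ_loglik1(
        _subset_detected(d), mu, sigma
    )  # exact + interval terms without nd
    if total == -math.inf:
        return -math.inf
    if d.n_detected:
        if q <= 0:
            return -math.inf
        total += d.n_detected * math.log(q)
    if d.nd_lo.size:
        p_detect = special.ndtr(-(d.nd_lo - mu) / sigma)  # sf of standardized bound
        with np.errstate(divide="ignore"):
            total += float(np.log1p(-q * p_detect).sum())
    return total if math.isfinite(total) else -math.inf


def _subset_detected(d: _OccData) -> _OccData:
    sub = _OccData.__new__(_OccData)
    sub.log_exact = d.log_exact
    sub.iv_lo = d.iv_lo
    sub.iv_hi = d.iv_hi
    sub.nd_lo = np.empty(0)
    sub.nd_ok = True
    sub.n_detected = d.n_detected
    return sub


def _occ_logpost(
    z: np.ndarray,
    d: _OccData,
    prior: OccurrencePrior,
    zero_inflated: bool,
) -> float:
    """Log posterior on the unconstrained scale with transform Jacobians."""
    mu = z[0]
    log_sigma = z[1]
    sigma = math.exp(log_sigma)
    if prior.sigma_prior == "uniform" and sigma >= prior.sigma_upper:
        return -math.inf
    lp = float(stats.norm.logpdf(mu, prior.mu_loc, _MU_PRIOR_SD))
    if prior.sigma_prior == "uniform":
        lp += -math.log(prior.sigma_upper) + log_sigma  # Jacobian d sigma/d log sigma
    else:
        tau = sigma ** -2
        lp += float(
            stats.gamma.logpdf(tau, prior.gamma_a, scale=1.0 / prior.gamma_b)
        ) + math.log(2.0) - 3.0 * log_sigma + log_sigma
    if zero_inflated:
        q = 1.0 / (1.0 + math.exp(-z[2]))
        lp += math.log(q) + math.log1p(-q)  # Beta(1,1) + logit Jacobian
        ll = _occ_loglik2(d, mu, sigma, q)
    else:
        ll = _occ_loglik1(d, mu, sigma)
    out = lp + ll
    return out if not math.isnan(out) else -math.inf


def _adaptive_rw(
    logpost,
    z0: np.ndarray,
    n_iter: int,
    burnin: int,
    rng: np.random.Generator,
    *,
    target_accept: float = 0.3,
) -> np.ndarray:
    """Adaptive random-walk Metropolis; returns retained draws (n_iter, dim).

    The scalar step size follows a Robbins-Monro recursion toward the
    target acceptance rate during burn-in and is frozen afterwards, which
    keeps the retained chain a valid Markov chain.
    """
    dim = z0.size
    z = z0.astype(float).copy()
    lp = logpost(z)
    if not math.isfinite(lp):
        raise ValueError("non-finite log-posterior at the initialization point")
    log_step = math.log(2.38 / math.sqrt(dim))
    out = np.empty((n_iter, dim))
    for t in range(burnin + n_iter):
        prop = z + math.exp(log_step) * rng.standard_normal(dim)
        lp_prop = logpost(prop)
        accept = math.log(rng.random()) < lp_prop - lp
        if accept:
            z, lp = prop, lp_prop
        if t < burnin:
            log_step += (float(accept) - target_accept) / math.sqrt(t + 1.0)
        else:
            out[t - burnin] = z
    return out


# ---------------------------------------------------------------------------
# initialization


def initialize(spec: ModelSpec, data: DataBundle) -> dict:
    """Moment-based starting point for all active blocks.

    Censored records are substituted at interval midpoints (on the log
    scale) for initialization only; frequencies and prevalences are clamped
    to (0.01, 0.99).
    """
    init: dict = {}
    by_pair: dict[tuple[str, str], list[OccurrenceRecord]] = {}
    for r in data.occ_records:
        by_pair.setdefault((r.hazard_id, r.food_id), []).append(r)
    for pair, recs in by_pair.items():
        logs = []
        for r in recs:
            if r.censor is Censor.EXACT:
                logs.append(math.log(r.value))
            elif r.censor is Censor.INTERVAL:
                logs.append(0.5 * (math.log(r.lod) + math.log(r.loq)))
            elif r.lod > 0:
                logs.append(math.log(r.lod) - 0.5)
        logs = np.array(logs)
        n_det = sum(1 for r in recs if r.censor is not Censor.BELOW_LOD)
        init[pair] = {
            "mu": float(logs.mean()),
            "sigma": float(max(np.std(logs, ddof=1) if logs.size > 1 else 0.5, 0.1)),
            "q": float(np.clip(n_det / len(recs), 0.01, 0.99)),
        }
    prev_by_pair = {(s.hazard_id, s.food_id): s for s in data.prev_samples}
    for pair, s in prev_by_pair.items():
        entry = init.setdefault(pair, {"mu": 0.0, "sigma": 1.0, "q": 0.5})
        entry["q"] = float(np.clip(s.n_positive / max(s.n_total, 1), 0.01, 0.99))
    if data.weights:
        lw = np.log([w.weight for w in data.weights])
        init["bw"] = {
            "mu_w": float(lw.mean()),
            "sigma_w": float(max(lw.std(ddof=1) if lw.size > 1 else 0.2, 0.05)),
        }
    if data.diaries:
        amounts = np.array([e.amounts for e in data.diaries], dtype=float)
        nf = amounts.shape[1]
        wmap = {w.respondent_id: w.weight for w in data.weights}
        w = np.array([wmap.get(e.respondent_id, 1.0) for e in data.diaries])
        per_bw = amounts / w[:, None]
        mu0 = np.zeros(nf)
        pooled_var = np.ones(nf)
        for j in range(nf):
            pos = per_bw[per_bw[:, j] > 0, j]
            if pos.size:
                mu0[j] = np.log(pos).mean()
                pooled_var[j] = max(
                    np.var(np.log(pos), ddof=1) if pos.size > 1 else 0.25, 0.05
                )
        frac = np.clip((amounts > 0).mean(axis=0), 0.01, 0.99)
        init["consumption"] = {
            "mu0": mu0,
            "Cs": np.diag(pooled_var),
            "Cmu": np.diag(pooled_var),
            "p0": frac,
            "Cp": np.eye(nf),
        }
    return init


# ---------------------------------------------------------------------------
# consumption Gibbs machinery


class _ConsumptionGibbs:
    """Gibbs sampler state for the amounts + frequency hierarchy."""

    def __init__(self, spec: ModelSpec, data: DataBundle, init: dict):
        self.spec = spec
        amounts = np.array([e.amounts for e in data.diaries], dtype=float)
        self.nf = amounts.shape[1]
        wmap = {w.respondent_id: w.weight for w in data.weights}
        w = np.array([wmap.get(e.respondent_id, 1.0) for e in data.diaries])
        per_bw = amounts / w[:, None]
        self.respondents = sorted({e.respondent_id for e in data.diaries})
        ridx = {rid: i for i, rid in enumerate(self.respondents)}
        self.nr = len(self.respondents)

        # amount rows: keep only days with >= 1 positive coordinate
        keep = (per_bw > 0).any(axis=1)
        self.obs_mask = per_bw[keep] > 0
        with np.errstate(divide="ignore"):
            self.Y = np.where(self.obs_mask, np.log(np.where(per_bw[keep] > 0, per_bw[keep], 1.0)), 0.0)
        self.row_resp = np.array(
            [ridx[e.respondent_id] for e, k in zip(data.diaries, keep) if k]
        )
        self.n_rows = self.Y.shape[0]
        self.days_per_resp = np.bincount(self.row_resp, minlength=self.nr)

        # frequency sufficient statistics
        u = (amounts > 0).astype(int)
        self.k1 = np.zeros((self.nr, self.nf))
        self.nd = np.zeros((self.nr, 1))
        for e, row in zip(data.diaries, u):
            self.k1[ridx[e.respondent_id]] += row
            self.nd[ridx[e.respondent_id], 0] += 1

        c = init["consumption"]
        self.mu0 = c["mu0"].copy()
        self.Cs = c["Cs"].copy()
        self.Cmu = c["Cmu"].copy()
        self.mu_r = np.tile(self.mu0, (self.nr, 1))
        self.theta0 = np.asarray(logit(c["p0"]), dtype=float)
        self.Cp = c["Cp"].copy()
        self.theta_r = np.tile(self.theta0, (self.nr, 1))
        self.df0 = self.nf + 1  # inverse-Wishart df giving uniform correlations
        self.S0 = np.eye(self.nf)
        self.log_step = math.log(1.0)

        # group rows by missing pattern for vectorized imputation
        self.patterns: list[tuple[np.ndarray, np.ndarray]] = []
        codes = self.obs_mask @ (1 << np.arange(self.nf))
        for code in np.unique(codes):
            rows = np.flatnonzero(codes == code)
            self.patterns.append((rows, self.obs_mask[rows[0]].copy()))

    def _impute(self, rng: np.random.Generator) -> None:
        """Draw missing coordinates from their conditional MVN."""
        for rows, mask in self.patterns:
            mis = ~mask
            if not mis.any():
                continue
            obs = np.flatnonzero(mask)
            misx = np.flatnonzero(mis)
            mu_rows = self.mu_r[self.row_resp[rows]]
            if obs.size == 0:
                cond_mean = mu_rows[:, misx]
                cond_cov = self.Cs[np.ix_(misx, misx)]
            else:
                Soo = self.Cs[np.ix_(obs, obs)]
                Smo = self.Cs[np.ix_(misx, obs)]
                gain = Smo @ np.linalg.inv(Soo)
                resid = self.Y[np.ix_(rows, obs)] - mu_rows[:, obs]
                cond_mean = mu_rows[:, misx] + resid @ gain.T
                cond_cov = self.Cs[np.ix_(misx, misx)] - gain @ Smo.T
            L = np.linalg.cholesky(cond_cov + 1e-12 * np.eye(misx.size))
            draw = cond_mean + rng.standard_normal((rows.size, misx.size)) @ L.T
            self.Y[np.ix_(rows, misx)] = draw

    def _update_mu_r(self, rng: np.random.Generator) -> None:
        Cmu_inv = np.linalg.inv(self.Cmu)
        Cs_inv = np.linalg.inv(self.Cs)
        sums = np.zeros((self.nr, self.nf))
        np.add.at(sums, self.row_resp, self.Y)
        for K in np.unique(self.days_per_resp):
            who = np.flatnonzero(self.days_per_resp == K)
            prec = Cmu_inv + K * Cs_inv
            cov = np.linalg.inv(prec)
            L = np.linalg.cholesky(cov)
            mean = (sums[who] @ Cs_inv + Cmu_inv @ self.mu0) @ cov
            self.mu_r[who] = mean + rng.standard_normal((who.size, self.nf)) @ L.T

    def _update_mu0_Cmu(self, rng: np.random.Generator) -> None:
        Cmu_inv = np.linalg.inv(self.Cmu)
        prec = self.nr * Cmu_inv + np.eye(self.nf) / _MU_PRIOR_SD ** 2
        cov = np.linalg.inv(prec)
        mean = cov @ (Cmu_inv @ self.mu_r.sum(axis=0))
        self.mu0 = rng.multivariate_normal(mean, cov, method="cholesky")
        resid = self.mu_r - self.mu0
        scale = self.S0 + resid.T @ resid
        self.Cmu = stats.invwishart.rvs(
            df=self.df0 + self.nr, scale=scale, random_state=rng
        ).reshape(self.nf, self.nf)

    def _update_Cs(self, rng: np.random.Generator) -> None:
        resid = self.Y - self.mu_r[self.row_resp]
        scale = self.S0 + resid.T @ resid
        self.Cs = stats.invwishart.rvs(
            df=self.df0 + self.n_rows, scale=scale, random_state=rng
        ).reshape(self.nf, self.nf)

    def _freq_loglik(self, theta: np.ndarray) -> np.ndarray:
        """Per-consumer Bernoulli log-likelihood at logits theta (nr, nf)."""
        return (self.k1 * theta - self.nd * np.logaddexp(0.0, theta)).sum(axis=1)

    def _update_theta_r(self, rng: np.random.Generator, adapt: bool, t: int) -> None:
        Cp_inv = np.linalg.inv(self.Cp)
        L = np.linalg.cholesky(self.Cp)
        step = math.exp(self.log_step) / math.sqrt(self.nf)
        prop = self.theta_r + step * rng.standard_normal((self.nr, self.nf)) @ L.T

        def logpost(th: np.ndarray) -> np.ndarray:
            d = th - self.theta0
            prior = -0.5 * np.einsum("ij,jk,ik->i", d, Cp_inv, d)
            return self._freq_loglik(th) + prior

        log_accept = logpost(prop) - logpost(self.theta_r)
        accept = np.log(rng.random(self.nr)) < log_accept
        self.theta_r[accept] = prop[accept]
        if adapt:
            self.log_step += (float(accept.mean()) - 0.3) / math.sqrt(t + 1.0)

    def _update_theta0_Cp(self, rng: np.random.Generator) -> None:
        Cp_inv = np.linalg.inv(self.Cp)
        prec = self.nr * Cp_inv + np.eye(self.nf) / _MU_PRIOR_SD ** 2
        cov = np.linalg.inv(prec)
        mean = cov @ (Cp_inv @ self.theta_r.sum(axis=0))
        self.theta0 = rng.multivariate_normal(mean, cov, method="cholesky")
        resid = self.theta_r - self.theta0
        scale = self.S0 + resid.T @ resid
        self.Cp = stats.invwishart.rvs(
            df=self.df0 + self.nr, scale=scale, random_state=rng
        ).reshape(self.nf, self.nf)

    def step(self, rng: np.random.Generator, adapt: bool, t: int) -> None:
        if "Lr" in self.spec.active_likelihoods and self.n_rows:
            self._impute(rng)
            self._update_mu_r(rng)
            self._update_mu0_Cmu(rng)
            self._update_Cs(rng)
        if "Ljr" in self.spec.active_likelihoods:
            self._update_theta_r(rng, adapt, t)
            self._update_theta0_Cp(rng)


# ---------------------------------------------------------------------------
# top-level sampling


def _pair_key(pair: tuple[str, str]) -> str:
    return f"{pair[0]}|{pair[1]}"


def sample_posterior(
    spec: ModelSpec,
    data: DataBundle,
    *,
    occurrence_priors: dict[tuple[str, str], OccurrencePrior] | None = None,
    store_consumers: bool = False,
) -> PosteriorDraws:
    """Draw the joint posterior sample for every active component.

    Reproducible for a fixed ``spec.seed``: each block (occurrence pair,
    consumption, Markov frequency) consumes its own seed stream derived
    deterministically from the seed, the block identity and the chain
    index, so removing one block does not perturb the draws of another.
    """
    n_iter, burnin, n_chains = spec.iterations, spec.burnin, spec.chains
    params: dict[str, np.ndarray] = {}
    init = initialize(spec, data)

    occ_active = bool(
        {"L1", "L2", "L3", "L4", "L5", "L6", "L7"} & spec.active_likelihoods
    )
    if occ_active:
        by_pair: dict[tuple[str, str], list[OccurrenceRecord]] = {}
        for r in data.occ_records:
            by_pair.setdefault((r.hazard_id, r.food_id), []).append(r)
        prev_by_pair = {(s.hazard_id, s.food_id): s for s in data.prev_samples}
        all_pairs = sorted(set(by_pair) | set(prev_by_pair))
        for p_idx, pair in enumerate(all_pairs):
            key = _pair_key(pair)
            recs = by_pair.get(pair, [])
            prev = prev_by_pair.get(pair)
            mu = np.empty((n_chains, n_iter))
            sg = np.empty((n_chains, n_iter))
            qq = np.empty((n_chains, n_iter))
            for chain in range(n_chains):
                rng = np.random.default_rng(
                    np.random.SeedSequence([spec.seed, 1, p_idx, chain])
                )
                mu_c, sg_c, q_c = _sample_occurrence_pair(
                    spec, recs, prev, init[pair], n_iter, burnin, rng,
                    (occurrence_priors or {}).get(pair),
                )
                mu[chain], sg[chain], qq[chain] = mu_c, sg_c, q_c
            params[f"occ[{key}].mu"] = mu
            params[f"occ[{key}].sigma"] = sg
            params[f"occ[{key}].q"] = qq

    if "Lw" in spec.active_likelihoods and data.weights:
        lw = np.log([w.weight for w in data.weights])
        mu_w = np.empty((n_chains, n_iter))
        sg_w = np.empty((n_chains, n_iter))
        for chain in range(n_chains):
            rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2, chain]))
            mu_w[chain], sg_w[chain] = _sample_bodyweight(lw, n_iter, burnin, rng)
        params["bw.mu_w"] = mu_w
        params["bw.sigma_w"] = sg_w

    nf = len(data.foods) if data.foods else (
        len(data.diaries[0].amounts) if data.diaries else 0
    )
    if {"Lr", "Ljr"} & spec.active_likelihoods and data.diaries:
        names_amt = (
            [f"amt.mu0[{j}]" for j in range(nf)]
            + [f"amt.Cs[{j},{k}]" for j in range(nf) for k in range(nf)]
            + [f"amt.Cmu[{j},{k}]" for j in range(nf) for k in range(nf)]
        )
        names_frq = [f"freq.p0[{j}]" for j in range(nf)] + [
            f"freq.Cp[{j},{k}]" for j in range(nf) for k in range(nf)
        ]
        store_amt = "Lr" in spec.active_likelihoods
        store_frq = "Ljr" in spec.active_likelihoods
        traces = {
            n: np.empty((n_chains, n_iter))
            for n in (names_amt if store_amt else []) + (names_frq if store_frq else [])
        }
        consumer_traces: dict[str, np.ndarray] = {}
        for chain in range(n_chains):
            rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 3, chain]))
            gibbs = _ConsumptionGibbs(spec, data, init)
            for t in range(burnin + n_iter):
                gibbs.step(rng, adapt=t < burnin, t=t)
                if t < burnin:
                    continue
                i = t - burnin
                if store_amt:
                    for j in range(nf):
                        traces[f"amt.mu0[{j}]"][chain, i] = gibbs.mu0[j]
                        for k in range(nf):
                            traces[f"amt.Cs[{j},{k}]"][chain, i] = gibbs.Cs[j, k]
                            traces[f"amt.Cmu[{j},{k}]"][chain, i] = gibbs.Cmu[j, k]
                if store_frq:
                    p0 = 1.0 / (1.0 + np.exp(-gibbs.theta0))
                    for j in range(nf):
                        traces[f"freq.p0[{j}]"][chain, i] = p0[j]
                        for k in range(nf):
                            traces[f"freq.Cp[{j},{k}]"][chain, i] = gibbs.Cp[j, k]
                if store_consumers and store_amt:
                    for j in range(nf):
                        name = f"amt.mu_r_mean[{j}]"
                        consumer_traces.setdefault(
                            name, np.empty((n_chains, n_iter))
                        )[chain, i] = gibbs.mu_r[:, j].mean()
        params.update(traces)
        params.update(consumer_traces)

    if "Lj" in spec.active_likelihoods and data.diaries:
        from .consumption_model import count_transitions_all

        counts = count_transitions_all(data.diaries)
        for j, c in enumerate(counts):
            p01 = np.empty((n_chains, n_iter))
            p11 = np.empty((n_chains, n_iter))
            for chain in range(n_chains):
                rng = np.random.default_rng(
                    np.random.SeedSequence([spec.seed, 4, j, chain])
                )
                p01[chain] = rng.beta(c.x01 + 1, c.n0 - c.x01 + 1, size=n_iter)
                p11[chain] = rng.beta(c.x11 + 1, c.n1 - c.x11 + 1, size=n_iter)
            params[f"freq.p01[{j}]"] = p01
            params[f"freq.p11[{j}]"] = p11

    meta = {
        "seed": spec.seed,
        "foods": list(data.foods),
        "hazards": list(spec.hazards),
        "pairs": [list(p) for p in (all_pairs if occ_active else spec.pairs)],
        "occurrence_option": spec.occurrence_option.value,
        "frequency_option": spec.frequency_option.value,
        "hazard_types": {h: t.value for h, t in spec.hazard_types.items()},
        "active_likelihoods": sorted(spec.active_likelihoods),
    }
    return PosteriorDraws(
        n_chains=n_chains, n_iter=n_iter, params=params, meta=meta
    )


def _sample_occurrence_pair(
    spec: ModelSpec,
    records: list[OccurrenceRecord],
    prev: PrevalenceSample | None,
    init: dict,
    n_iter: int,
    burnin: int,
    rng: np.random.Generator,
    prior: OccurrencePrior | None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    zero_inflated = spec.occurrence_option is OccurrenceOption.ZERO_INFLATED
    if not records:
        # prevalence-only pair: exact conjugate Beta posterior
        if prev is None:
            raise ValueError("pair has neither records nor a prevalence sample")
        q = rng.beta(prev.n_positive + 1, prev.n_total - prev.n_positive + 1, n_iter)
        return np.full(n_iter, np.nan), np.full(n_iter, np.nan), q

    d = _OccData(records)
    if prior is None:
        logs = d.log_exact if d.log_exact.size else np.array([init["mu"]])
        prior = OccurrencePrior(sigma_upper=sigma_upper_bound(logs))
    if zero_inflated:
        z0 = np.array(
            [init["mu"], math.log(init["sigma"]), float(logit(init["q"]))]
        )
        draws = _adaptive_rw(
            lambda z: _occ_logpost(z, d, prior, True), z0, n_iter, burnin, rng
        )
        q = 1.0 / (1.0 + np.exp(-draws[:, 2]))
    else:
        z0 = np.array([init["mu"], math.log(init["sigma"])])
        draws = _adaptive_rw(
            lambda z: _occ_logpost(z, d, prior, False), z0, n_iter, burnin, rng
        )
        if prev is not None:
            q = rng.beta(
                prev.n_positive + 1, prev.n_total - prev.n_positive + 1, n_iter
            )
        else:
            q = np.full(n_iter, np.nan)
    return draws[:, 0], np.exp(draws[:, 1]), q


def _sample_bodyweight(
    log_weights: np.ndarray, n_iter: int, burnin: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Conjugate Normal / Gamma Gibbs for (mu_w, sigma_w)."""
    n = log_weights.size
    s = log_weights.sum()
    mu = float(log_weights.mean())
    tau = 1.0 / max(float(np.var(log_weights, ddof=1)) if n > 1 else 0.04, 1e-6)
    mu_out = np.empty(n_iter)
    sg_out = np.empty(n_iter)
    prior_prec = 1.0 / _MU_PRIOR_SD ** 2
    for t in range(burnin + n_iter):
        prec = prior_prec + n * tau
        mu = rng.normal((tau * s) / prec, 1.0 / math.sqrt(prec))
        ss = float(((log_weights - mu) ** 2).sum())
        tau = rng.gamma(_GIBBS_GAMMA_A + 0.5 * n, 1.0 / (_GIBBS_GAMMA_B + 0.5 * ss))
        if t >= burnin:
            mu_out[t - burnin] = mu
            sg_out[t - burnin] = 1.0 / math.sqrt(tau)
    return mu_out, sg_out


# ---------------------------------------------------------------------------
# diagnostics


def diagnostics(draws: PosteriorDraws) -> dict:
    """Split-Rhat and effective sample size per scalar parameter.

    Returns ``{"params": {name: {"rhat": r, "ess": e}}, "warnings": [...]}``;
    parameters with Rhat > 1.05 are listed as warnings. Diagnostics never
    stop a run — stability should be judged from several runs of different
    lengths.
    """
    import warnings as _warnings

    import arviz as az

    report: dict = {"params": {}, "warnings": []}
    for name, arr in draws.params.items():
        if np.isnan(arr).all():
            continue
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            rhat = float(az.rhat(arr))
            ess = float(az.ess(arr))
        report["params"][name] = {"rhat": rhat, "ess": ess}
        if math.isfinite(rhat) and rhat > 1.05:
            report["warnings"].append(
                f"{name}: split-Rhat {rhat:.3f} > 1.05 — chains disagree; "
                "run longer simulations"
            )
    return report
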