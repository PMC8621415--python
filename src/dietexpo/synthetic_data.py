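"""Synthetic occurrence and consumption data from known ground truth.

The generator inverts the data model exactly: concentrations are drawn
log-normally and censored by thresholding against LOD/LOQ (which matches
both estimation options' data models), prevalence samples are binomial,
body weights log-normal, diary amounts hierarchical multivariate
log-normal with Bernoulli or Markov consumption indicators. Two presets
with documented stand-in parameter magnitudes are shipped:

* ``chemical-like`` — one chemical hazard in two foods, separate
  prevalence samples, heavy censoring, two-day independent diaries;
* ``micro-like`` — one microbiological hazard, zero-inflated occurrence,
  consecutive-day Markov diaries.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .consumption_model import logit, markov_stationary
from .data_io import (
    BodyWeightRecord,
    Censor,
    DiaryEntry,
    FrequencyOption,
    HazardType,
    OccurrenceOption,
    OccurrenceRecord,
    PrevalenceSample,
)
from .posterior_sampler import DataBundle

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PairTruth:
    """True occurrence parameters for one hazard-food pair."""

    hazard_id: str
    food_id: str
    mu: float       # mean log concentration among positives
    sigma: float    # sd of log concentration
    q: float        # contamination prevalence
    lod: float
    loq: float
    unit: str = ""

    def __post_init__(self) -> None:
        if self.sigma <= 0 or not (0.0 <= self.q <= 1.0) or self.lod > self.loq:
            raise ValueError("invalid pair truth")


@dataclass
class GroundTruth:
    """Complete generating parameters for one synthetic study."""

    name: str
    pairs: list[PairTruth]
    hazard_types: dict[str, HazardType]
    foods: tuple[str, ...]
    mu_w: float
    sigma_w: float
    mu0: np.ndarray
    Cs: np.ndarray
    Cmu: np.ndarray
    occurrence_option: OccurrenceOption
    frequency_option: FrequencyOption
    p0: np.ndarray | None = None
    Cp: np.ndarray | None = None
    p01: np.ndarray | None = None
    p11: np.ndarray | None = None
    n_respondents: int = 200
    n_days: int = 2
    n_occurrence: int = 300
    n_prevalence: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        for C in (self.Cs, self.Cmu) + ((self.Cp,) if self.Cp is not None else ()):
            np.linalg.cholesky(C)  # raises if not positive definite
        if self.frequency_option is FrequencyOption.MARKOV:
            if self.p01 is None or self.p11 is None:
                raise ValueError("Markov option requires p01 and p11")
        elif self.p0 is None or self.Cp is None:
            raise ValueError("independent-days option requires p0 and Cp")

    def scalars(self) -> dict[str, float]:
        """Every ground-truth scalar under its posterior trace name."""
        out: dict[str, float] = {"bw.mu_w": self.mu_w, "bw.sigma_w": self.sigma_w}
        for p in self.pairs:
            key = f"{p.hazard_id}|{p.food_id}"
            out[f"occ[{key}].mu"] = p.mu
            out[f"occ[{key}].sigma"] = p.sigma
            out[f"occ[{key}].q"] = p.q
        nf = len(self.foods)
        for j in range(nf):
            out[f"amt.mu0[{j}]"] = float(self.mu0[j])
            for k in range(nf):
                out[f"amt.Cs[{j},{k}]"] = float(self.Cs[j, k])
                out[f"amt.Cmu[{j},{k}]"] = float(self.Cmu[j, k])
        if self.frequency_option is FrequencyOption.MARKOV:
            for j in range(nf):
                out[f"freq.p01[{j}]"] = float(self.p01[j])
                out[f"freq.p11[{j}]"] = float(self.p11[j])
        else:
            for j in range(nf):
                out[f"freq.p0[{j}]"] = float(self.p0[j])
                for k in range(nf):
                    out[f"freq.Cp[{j},{k}]"] = float(self.Cp[j, k])
        return out


def generate_occurrence(
    truth: GroundTruth, rng: np.random.Generator
) -> tuple[list[OccurrenceRecord], list[PrevalenceSample]]:
    """Draw occurrence records and (separate option) prevalence samples.

    SEPARATE: every record is a positive concentration draw, censored by
    thresholding against LOD/LOQ; a Binomial(n, q) prevalence sample is
    drawn per pair. ZERO_INFLATED: a Bernoulli(q) contamination indicator
    decides per record whether a concentration is drawn (then censored) or
    a non-detect is recorded directly; no prevalence sample.
    """
    records: list[OccurrenceRecord] = []
    prev: list[PrevalenceSample] = []
    for p in truth.pairs:
        n = truth.n_occurrence
        if truth.occurrence_option is OccurrenceOption.SEPARATE:
            contaminated = np.ones(n, dtype=bool)
            prev.append(
                PrevalenceSample(
                    hazard_id=p.hazard_id,
                    food_id=p.food_id,
                    n_positive=int(rng.binomial(truth.n_prevalence, p.q)),
                    n_total=truth.n_prevalence,
                )
            )
        else:
            contaminated = rng.random(n) < p.q
        values = np.exp(rng.normal(p.mu, p.sigma, n))
        n_exact = 0
        for contam, value in zip(contaminated, values):
            if not contam or value < p.lod:
                records.append(
                    OccurrenceRecord(
                        hazard_id=p.hazard_id, food_id=p.food_id,
                        censor=Censor.BELOW_LOD, lod=p.lod, loq=p.loq, unit=p.unit,
                    )
                )
            elif value <= p.loq:
                records.append(
                    OccurrenceRecord(
                        hazard_id=p.hazard_id, food_id=p.food_id,
                        censor=Censor.INTERVAL, lod=p.lod, loq=p.loq, unit=p.unit,
                    )
                )
            else:
                n_exact += 1
                records.append(
                    OccurrenceRecord(
                        hazard_id=p.hazard_id, food_id=p.food_id,
                        censor=Censor.EXACT, value=float(value),
                        lod=p.lod, loq=p.loq, unit=p.unit,
                    )
                )
        if n_exact == 0:
            logger.warning(
                "no exact values generated for %s/%s (LOD/LOQ too high?): "
                "data unfit for estimating the concentration distribution",
                p.hazard_id, p.food_id,
            )
    return records, prev


def generate_consumption(
    truth: GroundTruth, rng: np.random.Generator
) -> tuple[list[DiaryEntry], list[BodyWeightRecord]]:
    """Draw the diary and body weights from the consumption model.

    Per respondent: body weight LN(mu_w, sigma_w); consumer mean vector
    MVN(mu0, Cmu); daily consumption indicators from Bernoulli with
    logit-MVN consumer frequencies, or from the Markov chain started at
    its stationary distribution; on consuming coordinates the raw amount
    is exp(MVN(mu_r, Cs)) x body weight, else 0.
    """
    nf = len(truth.foods)
    L_mu = np.linalg.cholesky(truth.Cmu)
    L_s = np.linalg.cholesky(truth.Cs)
    diaries: list[DiaryEntry] = []
    weights: list[BodyWeightRecord] = []
    markov = truth.frequency_option is FrequencyOption.MARKOV
    if markov:
        p_stat = np.asarray(markov_stationary(truth.p01, truth.p11))
    else:
        L_p = np.linalg.cholesky(truth.Cp)
        theta0 = np.asarray(logit(truth.p0), dtype=float)
    for r in range(truth.n_respondents):
        rid = f"r{r:04d}"
        w = float(rng.lognormal(truth.mu_w, truth.sigma_w))
        weights.append(BodyWeightRecord(respondent_id=rid, weight=w))
        mu_r = truth.mu0 + L_mu @ rng.standard_normal(nf)
        if markov:
            u_prev = (rng.random(nf) < p_stat).astype(int)
        else:
            theta = theta0 + L_p @ rng.standard_normal(nf)
            p_r = 1.0 / (1.0 + np.exp(-theta))
        for day in range(1, truth.n_days + 1):
            if markov:
                if day == 1:
                    u = u_prev
                else:
                    p_next = np.where(u_prev == 1, truth.p11, truth.p01)
                    u = (rng.random(nf) < p_next).astype(int)
                u_prev = u
            else:
                u = (rng.random(nf) < p_r).astype(int)
            log_s = mu_r + L_s @ rng.standard_normal(nf)
            amounts = np.where(u == 1, np.exp(log_s) * w, 0.0)
            diaries.append(
                DiaryEntry(respondent_id=rid, day_index=day, amounts=tuple(amounts))
            )
    return diaries, weights


def make_bundle(truth: GroundTruth, seed: int | None = None) -> DataBundle:
    """Generate the full data bundle for a ground truth (bit-reproducible)."""
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    records, prev = generate_occurrence(truth, rng)
    diaries, weights = generate_consumption(truth, rng)
    return DataBundle(
        occ_records=records,
        prev_samples=prev,
        diaries=diaries,
        weights=weights,
        foods=truth.foods,
    )


def default_truth(preset: str, seed: int = 0) -> GroundTruth:
    """Built-in ground-truth presets (documented stand-in magnitudes).

    ``chemical-like``: a chemical contaminant around 0.05 mg/kg (log mean
    -3.0, log sd 0.6) in two foods, 30% prevalence, LOD/LOQ placed so that
    roughly 30% of the records are censored; 200 respondents x 2
    independent diary days; body weight around 75 kg.

    ``micro-like``: a microbiological hazard around 5 CFU/g (log mean 1.6,
    log sd 1.0), 25% contamination, zero-inflated occurrence; 200
    respondents x 2 consecutive diary days with Markov day-to-day
    dependence.
    """
    foods = ("food_a", "food_b")
    mu0 = np.array([0.7, 0.0])  # log of ~2 and ~1 g per kg body weight per day
    Cs = np.array([[0.25, 0.05], [0.05, 0.25]])
    Cmu = np.array([[0.20, 0.04], [0.04, 0.20]])
    common = dict(
        foods=foods, mu_w=math.log(75.0), sigma_w=0.2,
        mu0=mu0, Cs=Cs, Cmu=Cmu,
        n_respondents=200, n_days=2, n_occurrence=300, n_prevalence=100,
        seed=seed,
    )
    if preset == "chemical-like":
        pairs = [
            PairTruth(
                hazard_id="chem1", food_id=f, mu=-3.0, sigma=0.6, q=0.3,
                lod=0.018, loq=0.036, unit="mg/kg",
            )
            for f in foods
        ]
        return GroundTruth(
            name=preset,
            pairs=pairs,
            hazard_types={"chem1": HazardType.CHEMICAL},
            occurrence_option=OccurrenceOption.SEPARATE,
            frequency_option=FrequencyOption.INDEPENDENT_DAYS,
            p0=np.array([0.7, 0.5]),
            Cp=np.array([[0.5, 0.1], [0.1, 0.5]]),
            **common,
        )
    if preset == "micro-like":
        pairs = [
            PairTruth(
                hazard_id="micro1", food_id=f, mu=1.6, sigma=1.0, q=0.25,
                lod=1.0, loq=2.0, unit="CFU/g",
            )
            for f in foods
        ]
        return GroundTruth(
            name=preset,
            pairs=pairs,
            hazard_types={"micro1": HazardType.MICROBIOLOGICAL},
            occurrence_option=OccurrenceOption.ZERO_INFLATED,
            frequency_option=FrequencyOption.MARKOV,
            p01=np.array([0.3, 0.2]),
            p11=np.array([0.6, 0.5]),
            **common,
        )
    raise ValueError(f"unknown preset {preset!r}; use 'chemical-like' or 'micro-like'")


PRESETS = ("chemical-like", "micro-like")
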