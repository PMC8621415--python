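# dietexpo

Bayesian dietary exposure assessment for foodborne microbiological and
chemical hazards.

Food-safety risk assessors need to turn two unrelated data sources — hazard
occurrence measurements (often censored against detection limits) and food
consumption diaries (often just two days per respondent) — into exposure
distributions with honest uncertainty. `dietexpo` fits one joint Bayesian
model to both and composes the posterior into acute (microbiological) and
chronic (chemical) exposure distributions, keeping *variability* (real
differences between consumers, days and servings) separate from
*uncertainty* (imperfect knowledge of the parameters).

## The model

**Occurrence.** Among contaminated units, concentration is log-normal:
log c ~ N(μʰ, σʰ). A measurement is exact (> LOQ), interval-censored
(LOD–LOQ) or a non-detect (< LOD); censored records enter through normal-CDF
likelihood terms. Prevalence q is either estimated from a separate binomial
sample x/n (the *separate* option) or folded into a zero-inflated
concentration likelihood in which a non-detect has probability
1 − q(1 − F(log LOD)) (the *zero-inflated* option).

**Consumption.** Body weights are log-normal. On consumption days the vector
of log amounts per body weight over the nf foods is MVN around a
consumer-specific mean (within-consumer covariance Cs); consumer means are
MVN around population means μ₀ (between-consumer covariance Cμ). Zero
amounts are treated as missing — a day a food was skipped says nothing about
the amount that would have been eaten. Consumption frequency is either a
Bernoulli indicator per day with logit-MVN consumer frequencies (covariance
Cp), or a first-order Markov chain over consecutive days with transition
probabilities p01, p11 and stationary daily frequency p01/(p01 + p10).

**Exposure.** Products of log-normals are log-normal, so single hazard–food
pairs have closed forms: acute positives are
LN(μ₀ⱼ + μʰ + μ_w, Cs_jj + Cμ_jj + (σʰ)² + σ_w²) and chronic positives are
LN(μ₀ⱼ + Cs_jj/2 + log E(c), Cμ_jj) with E(c) = exp(μʰ + (σʰ)²/2). Totals
over several foods are simulated by the conditional sequence (frequencies →
indicators → consumer means → amounts → body weight → concentrations →
contamination indicators), with a final Poisson(dose) step for bacteria.
Evaluating any summary per posterior draw yields its uncertainty
distribution; drawing one consumer per posterior draw yields the posterior
predictive distribution, reported as the 1/5/10/50/90/95/99 % quantile
table. Constant processing (adjustment) factors per hazard–food pair
multiply concentration and prevalence at composition time.

Sampling uses conjugate Gibbs updates wherever the full conditional is
closed-form (prevalence, Markov transitions, body weight, the amount
hierarchy with data augmentation for missing coordinates, inverse-Wishart
covariances) and adaptive random-walk Metropolis for the censored /
zero-inflated occurrence block and per-consumer logit frequencies. See
`docs/methods.md` for assumptions, priors and numerical choices.

## Worked example

Generate the built-in microbiological preset, fit it, and tabulate the
posterior predictive acute dose from both foods:

```bash
dietexpo generate --preset micro-like --out data/ --seed 1
dietexpo fit --data data/ --out draws.parquet --chains 2 --iters 1000 --burnin 500 --seed 1
dietexpo expose --draws draws.parquet --hazard micro1 --foods food_a,food_b \
    --kind acute --out quantiles.csv --seed 1
```

The `fit` step prints the automatically selected likelihood components for
this data set:

```
active likelihood components: ['L5', 'L6', 'L7', 'Lj', 'Lr', 'Lw']
```

i.e. zero-inflated occurrence terms for non-detects, interval-censored and
exact records (L5–L7), Markov day-to-day consumption frequency (Lj), the
hierarchical amounts model (Lr) and body weights (Lw). It also prints
split-Rhat warnings for the zero-inflated occurrence parameters of one pair
— with many non-detects their posterior is weakly identified and chains mix
slowly, so longer runs should be compared (there is deliberately no
automatic stopping). The `expose` step prints the predictive quantile table
(doses in CFU; zeros included in `total`, excluded in `positives_only`):

```
 quantile_pct   total  positives_only
            1    0.00            10.2
            5    0.00            43.0
           10    0.00            83.0
           50    0.00           502.0
           90  482.20          3143.0
           95 1290.15          5161.0
           99 5048.14         10199.0
```

A median of 0 says that on most person-days no contaminated serving of
either food is consumed at all (the simulated zero-dose fraction here is
≈ 0.81); among exposure days the median dose is ≈ 502 CFU.
`dietexpo report` draws the
uncertainty-overlay CDF plots and `dietexpo validate` compares the model
against empirical CDF bounds and bootstrap pseudo-empirical exposures.

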