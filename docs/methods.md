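# Methods

## Model structure

The posterior is a product of independent likelihood contributions, one per
data source, times the priors. Which contributions are active is read off
the data automatically (`data_io.build_model_spec`): exact concentration
values, interval-censored values, non-detects, a binomial prevalence
sample, body weights, positive diary amounts, and daily consumption
indicators each switch on their own term. Occurrence parameters
(μʰ, σʰ, q per hazard–food pair) and consumption parameters share nothing,
so the two blocks are mathematically independent sub-posteriors and are
sampled as such.

### Occurrence

Concentrations among contaminated units are log-normal. Under the
*separate* option all records are treated as true positives: exact values
contribute normal log-densities of log c, interval records
log[F(log LOQ) − F(log LOD)], non-detects log F(log LOD), and prevalence is
estimated from a separate x/n sample through a binomial term. Under the
*zero-inflated* option a non-detect is either a true zero or an undetected
positive, with probability 1 − q(1 − F(log LOD)); detected records carry an
extra factor q (for exact values the truncation normalizer of the
density-given-detection cancels against the detection probability, leaving
q·f(log c)). At least some exact values above LOQ are required or the
concentration distribution is not estimable; the readers enforce this.

Priors: μʰ gets Normal(0, 1000²) on the log scale — flat in practice but
proper, so the posterior is guaranteed proper. q gets Beta(1, 1). σʰ gets
either Uniform(0, U) or a Gamma(0.01, 0.01) prior on the precision 1/σ².
The uniform bound U is derived from the data: the sample sd of the observed
log concentrations after appending two pseudo-extremes min − R and max + R,
with R = max(range, 1), multiplied by 5. The augmentation keeps U strictly
positive even for a single observation and the bound is shift-invariant;
both the multiple and the minimum range are configurable
(`occurrence_model.sigma_upper_bound`).

### Consumption

Body weights w_r are log-normal. Positive daily amounts per body weight are
hierarchical MVN on the log scale: day vectors around consumer means with
within-consumer covariance Cs, consumer means around population means μ₀
with between-consumer covariance Cμ. A zero amount is a missing value, not
a zero on the log scale — each day contributes the marginal density of its
observed coordinates only, and days with no positive amount contribute
nothing. Amounts are read raw and divided by body weight internally, so
users never pre-divide.

Frequency option 1 (independent days): daily indicators are Bernoulli(p_jr)
with consumer logit-frequency vectors MVN around logit(p₀) with covariance
Cp. Option 2 (Markov): consecutive-day transitions with population-level
probabilities p01, p11 (not per-consumer — two diary days cannot identify
personal transition matrices), uniform priors, and stationary daily
frequency p01/(p01 + p10). Amounts on consumption days are independent of
the previous day even under the Markov option. True non-consumers are not
modelled: with few diary days a non-consumer cannot be distinguished from a
rare consumer, so low frequencies simply get low estimates.

Covariance priors: inverse-Wishart with df = nf + 1 and identity scale on
Cs, Cμ and Cp. This df makes the implied prior on every correlation
marginally uniform, which is the intended weakly-informative behaviour; the
prior-predictive uniformity is exercised in the test suite indirectly
through interval coverage. μ₀, logit p₀ and μ_w get Normal(0, 1000²)
priors; the log-scale precisions of body weight get Gamma(0.01, 0.01).

## Sampler

No gradient-based probabilistic-programming backend is used; the sampler is
written directly on the conditional structure of the model:

* exact conjugate Gibbs draws where the full conditional is closed-form —
  prevalence q (Beta), Markov p01/p11 (Beta), μ_w and the body-weight
  precision (Normal/Gamma), consumer means and population means (MVN), Cs,
  Cμ and Cp (inverse-Wishart);
* data augmentation for the missing (zero) coordinates of partially
  observed diary days: they are imputed from their conditional MVN each
  sweep, which restores conjugacy of the covariance updates while leaving
  the marginal posterior identical to the integrated-out likelihood that
  the public `loglik_amounts` computes;
* adaptive random-walk Metropolis on unconstrained scales for the
  non-conjugate blocks: (μʰ, log σʰ) for censored occurrence,
  (μʰ, log σʰ, logit q) jointly for the zero-inflated option, and
  per-consumer logit-frequency vectors (vectorized across consumers, with
  the current Cp as proposal shape). Step sizes follow a Robbins–Monro
  recursion toward ≈ 0.30 acceptance during burn-in and are frozen
  afterwards, so retained draws form a valid Markov chain.

Initialization is moment-based: censored values at interval midpoints (for
the start point only — estimation always integrates censoring), prevalence
and frequencies from observed fractions clamped to (0.01, 0.99),
covariances from diagonal sample variances.

Default run length is 4 chains × 2000 retained after 1000 burn-in; every
block consumes a seed stream derived deterministically from
(seed, block id, chain), so runs are bit-reproducible and removing one
block never perturbs another's draws. Diagnostics (split-Rhat, ESS via
ArviZ) warn above Rhat 1.05 but never stop a run: with heavily censored
zero-inflated data the (q, μ) posterior can be genuinely bimodal and the
right response is comparing runs of different lengths, not auto-stopping.
Parallel tempering for that bimodal regime is a known omission.

## Exposure composition

Single hazard–food pairs are closed-form log-normals (see README). Multi-
food totals are simulated by the conditional sequence per posterior draw;
for microbiological hazards the realized dose adds a Poisson step, which
can produce zero counts even from contaminated servings. Chronic exposure
replaces concentration variability by its mean E(c) = exp(μʰ + σʰ²/2) and
is only produced for chemical hazards; acute exposure only for
microbiological ones. Body weight is assumed independent of consumption.

Uncertainty/variability separation: the uncertainty distribution of any
variability quantile is obtained per posterior draw — closed-form
exp(μ + z_γ σ) for log-normal pairs, empirical over n_V inner simulations
(default 10⁴) for totals — and summarized with 90% bounds. The posterior
predictive table draws one consumer per retained draw (n_U total) and
reports the 1/5/10/50/90/95/99 % quantiles, for totals including zeros and
for positives only. Overlay plots show 20 randomly chosen per-draw
variability CDFs by default.

Adjustment factors are constants per hazard–food pair: the concentration
factor adds log k to μʰ everywhere μʰ appears (closed forms and
simulation); the prevalence factor multiplies q, clipped to [0, 1]. No
uncertainty is attached to them. Under the Markov frequency option the
simulation uses the population stationary probability in the per-consumer
slot, so between-consumer frequency variability vanishes there — a literal
consequence of transition probabilities being population-level parameters.

## Synthetic data and what the tests show

The generator inverts the data model exactly (thresholded censoring of
log-normal draws, binomial prevalence, hierarchical MVN diaries, Bernoulli
or stationary-started Markov indicators), so parameter recovery on its
output tests the estimation machinery, not model misspecification. The two
presets use stand-in magnitudes chosen to be realistic for their domains:
a chemical contaminant near 0.05 mg/kg with log-sd 0.6 and ~30% censoring,
a microbiological hazard near 5 CFU/g with log-sd 1.0 and 25% prevalence,
body weight around 75 kg (log-sd 0.2), daily per-body-weight amounts around
1–2 g/kg with moderate positive between-food correlation, consumption
frequencies 0.4–0.7. Preset sizes (200 respondents × 2 days, 300 occurrence
records, prevalence n = 100) mirror typical small survey data and keep a
full fit at a few seconds, so the 20-replicate coverage check runs at
2 chains × 800 retained after 400 burn-in.

Real data differ from the generator in ways the tests therefore do not
cover: non-log-normal concentration tails, survey weighting and sampling
design, recipe/ingredient decomposition, seasonal consumption patterns, and
measurement error in diaries. Passing recovery tests show calibration under
the model's own assumptions only.

## Numerical choices

* Log-CDF differences use the complementary (survival) form when the
  censoring interval lies in the upper tail, avoiding catastrophic
  cancellation; all likelihoods return −∞ (never NaN, never an exception)
  for impossible parameter/data combinations so samplers can reject.
* logit/log transforms are clamped 1e−12 away from {0, 1}.
* Cholesky factorizations add 1e−12 jitter only in simulation paths where
  posterior-drawn covariance matrices may be numerically semidefinite;
  likelihood evaluation treats non-PD covariance as −∞.
* Empirical-CDF validation substitutes non-detects at LOD/100 for the
  lower bound on log-scale plots (log 0 being undefined); interval records
  at LOD (lower) or LOQ (upper).
* Respondents with one diary day inform amounts and independent-days
  frequency but contribute no transition pairs; foods never consumed leave
  their amount distribution unidentified and are flagged at read time.

## Units

Units are never converted: concentrations, amounts and exposures inherit
the units of the input tables (e.g. CFU/g × g = CFU for acute doses;
mg/kg × g/(kg body weight) for chronic exposure per body weight). Body
weights are kilograms.
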