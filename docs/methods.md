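# Methods

## Outcome model

The outcome is the SDQ total difficulties score (integer 0–40), modelled on
the log scale as `Y_it = log(SDQ_it + 1)`. The score 0 occurs, so a +1
offset is required for the log transform to be defined; the offset makes
the transform a strictly increasing bijection of {0..40}. For person
*i* = 1..N at modelled age *t* ∈ {3, 5, 7, 14, 17} (survey sweeps
2, 3, 4, 6, 7; age 9 months is coded 0.75; the age-11 sweep is excluded
because its score comes from a different informant):

    Y_it ~ Normal(mu_it, sigma^2)
    mu_it = alpha_i + Σ_p beta_p x_itp + Σ_k gamma_tk z_itk (+ interactions)
    alpha_i ~ Normal(mu_alpha, sigma^2_alpha)
    gamma_tk ~ Normal(mu_gamma_k, sigma^2_gamma_k)        [hierarchical pooling]

`mu_alpha` is the global intercept — there is no separate intercept column
in X, which keeps the fixed-effect block identifiable. The Poisson
sensitivity family replaces the first line with
`SDQ_it ~ Poisson(exp(mu_it))` on the raw counts.

Fixed-effect coding (treatment contrasts, see `data/codebook.yaml`):
reference levels are female sex, White ethnicity, normal weight,
couple-parent family, NVQ level 1, non-poverty, rural. The deprivation
exposure enters by default as the binary time-varying contrast
IMD deciles 4–10 vs the most deprived deciles 1–3; a 3-category coding
(4–7, 8–10 vs 1–3) is available through the `imd_4_7` / `imd_8_10`
codebook entries. Pollutants are kept in raw µg/m³ so coefficients read
"per 1 µg/m³"; NDVI and green-space area are standardised to mean 0, SD 1
on the analysed rows (recorded in the design metadata) because their
natural units are not comparable across metrics.

An age-specific exposure contributes one design column per (exposure, age):
the exposure value where the row's age matches, 0 elsewhere. The
cumulative variant replaces the trajectory with the within-person mean
over that person's observed modelled sweeps — one column, one coefficient.
Interaction terms are modifier-dummy × exposure-value columns (a single
coefficient across ages) living in the fixed block.

## Priors

* beta, interactions, mu_alpha, mu_gamma_k: Normal(0, 1000). The 1000 is
  interpreted as a **variance** (the common reading; configurable).
* every precision tau = 1/sigma^2 (residual, intercept, each exposure
  group): Gamma(shape 1, rate 0.01), i.e. inverse-gamma(1, 0.01) on the
  variance. Log-prior densities are evaluated on the precision scale; the
  quadrature oracle in the tests integrates on the same scale.
* `pooling: independent` replaces the hierarchical gamma prior with
  Normal(0, 1000) per coefficient and drops that group's hyperparameters.

## Inference

Gaussian family: blocked conjugate Gibbs.

1. (beta, gamma, interactions) drawn **jointly** from the multivariate
   normal full conditional (one Cholesky solve per iteration) — block
   updates mix far better than scalar sweeps at modest cost;
2. alpha_i: independent normal conditionals (vectorised);
3. mu_alpha, mu_gamma_k: normal conditionals;
4. all precisions: gamma conditionals.

Covariate columns are centred before sampling to remove the
near-nonidentifiability between mu_alpha and the dummy blocks; recorded
draws of mu_alpha (and alpha_i) are shifted back to the raw-covariate
scale, so reported draws always refer to the model as written above.
Chains start overdispersed: coefficients from the prior with variance
shrunk ×0.01 (full Normal(0,1000) draws would overflow the exp link of the
Poisson family), variances from a log-normal. A singular conditional
covariance is ridge-stabilised (1e-8 × mean diagonal) with a warning.
Setting a prior variance to exactly 0 pins those coefficients at the prior
mean (point-mass limit).

Poisson family: random-walk Metropolis within Gibbs. Coefficients are
updated one at a time with per-coefficient proposal scales; the person
intercepts are proposed simultaneously and accepted independently per
person (their conditionals are independent given the coefficients).
Scales adapt every 50 burn-in iterations toward a 0.44 acceptance rate and
are frozen after burn-in (post-burn-in rates are recorded and should sit
in roughly (0.1, 0.6)). Hyperparameter updates remain conjugate.

Defaults follow the study protocol: 2 chains, 10 000 burn-in, 10 000
retained iterations, no thinning. Reproducibility: one seed spawns
independent per-chain streams; identical config + seed gives bit-identical
draws. Individual-intercept draws are stored (they are needed for the
pointwise WAIC likelihood) unless `save_alpha=False`.

## Diagnostics, summaries, model comparison

* Gelman–Rubin: the classic non-split two-chain formulation
  `R = sqrt(((n-1)/n W + B/n) / W)`; a split-chain variant sits behind
  `split=True`. Zero within-chain variance → undefined (NaN). The
  pipeline warns above R-hat 1.1 (error in strict mode).
* Summaries: draws pooled across chains; equal-tailed quantiles
  (`numpy.quantile`, linear interpolation); significance = the 95% CrI
  excludes zero.
* WAIC = −2(lppd − p_waic) with `lppd_i = log mean_s exp(loglik_si)`
  (stable log-sum-exp) and `p_waic_i` the sample variance over draws
  (denominator S−1); the pointwise likelihood conditions on the drawn
  individual intercepts. Compared models are refitted on the
  **intersection** of their complete-case rows, since WAIC values on
  different row sets are not comparable.

## Preprocessing rules

* **Residence inference**: a missing neighbourhood (LSOA) identifier is
  filled when the nearest non-missing LSOA before and after the gap are
  identical (no relocation inferred); multi-sweep gaps fill only if both
  flanks agree; leading/trailing gaps never fill. Idempotent; never
  overwrites observed values. Filled rows recover their LSOA-keyed
  exposure values from the generator's exposure lookup when present.
* **Sweep-7 carry-forward**: income/poverty and IMD were not collected at
  the last sweep; sweep-6 values are assigned uniformly (deterministic on
  synthetic data), and persons who moved between sweeps 6 and 7 — or were
  absent at sweep 6 — are excluded from sweep-7 modelling rows.
* **Sample filters**: England at every observed sweep; first-born only for
  multiple births; complete 7-sweep residence history after inference.
* **Collinearity screen**: VIF_j = 1/(1−R²_j) from OLS of column j on the
  remaining columns plus intercept; flag threshold 10 (conventional);
  exact collinearity reported as infinite, not an error.

## Synthetic cohort generator

The generator emulates the analysis sample of a UK millennium birth cohort
(default n = 3595, seven sweeps): declining pollution trends by sweep
(e.g. PM2.5 mean falling 14.1 → 9.4 µg/m³ with the published per-sweep
SDs), stable NDVI around 0.5, right-skewed green-space area (lognormal
matched to mean/SD), a deprivation mixture drifting from 27.5% → 22.2%
most-deprived and 32.3% → 38.0% least-deprived, covariate prevalences per
sweep, residential relocation (5% per transition), within-person exposure
autocorrelation 0.8 via persistent per-spell anchors (pollutants share one
anchor; greenness, green area and deprivation have their own), and
block-wise missingness: per-sweep outcome missingness matched to the
published per-sweep sample sizes, 3% LSOA missingness per sweep (chosen so
the share of persons with complete pre-inference residence ≈ 0.8),
optional monotone dropout. Slowly-varying binary covariates use a
persistent latent-uniform threshold construction, so prevalence drift
implies few within-person flips.

The outcome is drawn from the model itself: alpha_i ~ N(mu_alpha,
sigma2_alpha), mu_it per the equation, latent log-outcome ~ N(mu_it,
sigma2), then SDQ = clamp(round(exp(latent) − 1), 0, 40). The continuous
latent is retained in `log_sdq_latent` so recovery tests can bypass
discretisation and isolate inference correctness. Default truth: a PM2.5
effect of 0.15 confined to age 3, an IMD contrast growing with age to
−0.72, null green-space effects, mu_alpha = 0.2, sigma2_alpha = 0.16,
sigma2 = 0.2.

What the generator does **not** emulate — and what passing tests therefore
do not establish about real data: no stratified-ward survey design or
oversampling; no real spatial structure (each residence spell is its own
neighbourhood, so exposures are person-anchored rather than shared across
neighbours); exposures are mutually independent given their anchors
(deprivation is not correlated with pollution as it would be in England);
and because the model has no age main effects, the default truth cannot
simultaneously reproduce the observed SDQ-by-age profile — late-adolescent
scores generated under the default truth sit near the bottom of the scale,
where integer rounding is coarse relative to the log scale. That
discretisation visibly attenuates the integer-outcome pipeline estimates
of the larger IMD contrasts (e.g. a generating −0.72 at age 17 is
recovered around −0.4), while latent-scale fits recover all parameters to
within Monte Carlo error. This is a property of the outcome rounding at
near-zero scores, not of the sampler.

## Problem sizes and numerical choices

The shipped tests and the acceptance script run scaled configurations
chosen to exercise every property at desk scale: the conjugate fixture
with 2 × 10 000 retained draws; recovery/coverage with 500 persons,
2 chains × 2 000 retained draws, 50 replicates (20 in the acceptance
script); the model-comparison property with 400–800 persons over 10
replicates; the full-size pipeline fit (3595 persons) with 2 × 1 500
retained draws. The coverage check uses the independent-pooling variant
because its flat coefficient priors make the sparse recovery truth (one
non-zero age window) well specified for interval calibration; under
hierarchical pooling the exchangeable prior mildly shrinks the lone
non-zero coefficient, which is the expected Bayesian behaviour rather
than a sampler defect.

Other numerical choices: pollutant draws are clipped at 0.1 µg/m³ and
NDVI to [0.01, 0.99]; Poisson linear predictors are clipped at 50 before
exponentiation; the Poisson intercept initialises near log(mean(y)+1);
quantiles use linear interpolation; variances in p_waic and the
Gelman–Rubin statistic use ddof = 1.

## Known limitations

* The restricted real-data funnel (18 293 UK children → 3595 analysed) is
  not reproduced; the generator emits analysis-eligible persons directly.
* Exposure misclassification, school/commuting exposure and survey
  weights are out of scope, as in the modelled analysis.
* WAIC is the only fit criterion (no PSIS-LOO).
* The Poisson sampler is adequate for the sensitivity variant but mixes
  more slowly than the Gaussian Gibbs sampler; use longer chains for
  publication-grade Poisson summaries.
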