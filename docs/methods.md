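# Methods

This note documents the models `nightvar` implements, the numerical
choices behind them, what the synthetic-cohort generator does and does
not emulate, and the known limitations.

## Data model and conventions

Nightly sleep metrics are person-night records of sleep duration
(minutes, in [0, 1440]), bedtime and waketime (minutes relative to
midnight; pre-midnight times are negative, so 23:30 is −30 and 01:15 is
+75). `night_index` counts nights since the device was first worn,
0-based, so a person's intercept is their expected level on the first
night (the sampler internally re-bases it to the protocol midpoint; see
below). A night whose sleep episode begins on Friday or Saturday is a
weekend night — these precede non-school days, which is where adolescent
sleep routines shift. Missing values are empty cells on disk and NaN in
memory, never sentinel codes.

Persons with fewer than 3 nights carrying any observed metric have all
sleep metrics set missing (`apply_validity_filter`), but are never
dropped: they stay in every analysis with sleep treated as missing, and
the full-information estimators handle them. Per-person descriptive
statistics use the sample (n−1) standard deviation over available
nights, excluding missing nights pairwise per metric.

## Bifactor S-1 measurement model

Caregiver and youth subscale scores for each of the 8 facets are
z-scored per rater over available cases, averaged over available raters
(a single available rater stands for the facet), and the aggregate is
re-standardized. The model for the 8 indicators y is

    y = μ + Λη + ε,   Cov(η) = Φ,   Cov(ε) = Θ,   Cov(η, ε) = K′

with orthogonal unit-variance general, specific-internalizing and
specific-externalizing factors; emotion dysregulation loads only on the
general factor. Free covariance parameters beyond the 15 loadings and 8
residual variances: Θ(HYP,AT), Θ(WD,HYP), and K(ext, AD) — the last
estimated freely, sign unconstrained. Model df = 36 − 26 = 10.

**Estimation.** Casewise (full-information) Gaussian likelihood over
missingness patterns, maximized with L-BFGS-B on an unconstrained
parameterization (residual variances are not bounded away from zero;
a negative residual variance at the solution is reported as a Heywood
warning, never silently). With complete data the means profile out and
the objective reduces to the covariance-only likelihood, which is the
fast path. Multiple random starts are supported and seeded. Factor signs
follow the positive-dominant-loading convention.

**Fit statistics.** The saturated log-likelihood comes from an EM
algorithm for the unstructured multivariate-normal mean/covariance under
missingness (closed form when complete); the independence baseline
(free means and variances, zero covariances) factorizes per variable and
is closed-form over available cases. Then χ² = 2(llₛₐₜ − llₘ), plain ML
without a robustness correction: the robust scaling factor would alter
standard errors and the χ² scale but none of the quantities this
pipeline consumes downstream (loadings and factor scores). CFI uses the
independence baseline; RMSEA uses n (not n−1) in the denominator, fixed
for determinism; SRMR is the root mean square of correlation-metric
residuals over all unique elements including the diagonal.

**Factor scores** are regression-method (posterior mean) scores,
η̂ = Cov(η, y_obs) Σ_obs⁻¹ (y_obs − μ_obs), computed per missingness
pattern; persons with no observed indicators keep their row with missing
scores. Regression scores are the conventional choice when scores enter
a downstream regression as predictors; with orthogonal factors their
joint use as predictors gives asymptotically unbiased slopes.

The correlated-factors supplement replaces the bifactor with three
correlated factors (internalizing: AD/WD/SOM; externalizing:
ODD/CD/HYP/AT; dysregulation: ERI as a single indicator with loading
fixed at 1 and residual variance fixed at 5% of the indicator variance,
factor variance free — a standard single-indicator identification).

## Mixed-effects location-scale model

For person i, outcome s ∈ {duration, bedtime, waketime}, observed night
t:

    y_sit = α_si + γ_s,night · night_it + γ_s,weekend · weekend_it + ε_sit
    ε_sit ~ N(0, exp(ω_si))
    (α_i, ω_i) ~ MVN(B x_i, Ψ),   x_i = [1, ĝ, ŝ_int, ŝ_ext, age_z, sex, medu_z, inr_z]

so within-person variability is the person-specific residual variance on
the log scale, net of the linear night trend and the weekend shift. The
within-level slopes are fixed (non-random) per outcome; within-level
residuals are independent across outcomes given (α, ω) — cross-outcome
dependence lives in Ψ at the between level (a documented
simplification). Bedtime variability uses the same log-variance
transform as the others; its sign convention only shifts α. Factor
scores enter as fixed, known predictors (two-step estimation; score
uncertainty is not propagated). Age, maternal education and
income-to-needs are z-scored over the sample; sex stays binary. Missing
person-level covariates are mean-imputed with a logged count; missing
nights are simply absent rows, and age — which drives wear-night
missingness — is always in the between-level design, making the
missingness ignorable under MAR.

**Priors.** N(0, 10⁶) on every regression coefficient and within-level
slope; inverse-Wishart(dim + 1, I) on Ψ. These are diffuse relative to
the data scales.

**Sampler.** Two MCMC chains from dispersed starts (chain 0 starts at
data-derived values, later chains jitter them), each a Gibbs scan:

- α_i: exact blocked draw from its multivariate-normal full conditional
  (prior conditional on ω_i combined with the nightly likelihood),
  vectorized over persons;
- ω_si: random-walk Metropolis per outcome, vectorized over persons,
  with Robbins–Monro step adaptation toward 0.44 acceptance during
  burn-in (adaptation stops at burn-in end, preserving the stationary
  distribution);
- γ_s: conjugate weighted-least-squares draw;
- B: conjugate matrix-normal draw given Ψ;
- **interweaving (ASIS) updates of B**: after the centered draw, the
  α-block rows of B are redrawn exactly in the non-centered
  parameterization (person residuals u = α − B_α x held fixed, where the
  data likelihood is again Gaussian in B_α), and the ω-block rows are
  redrawn by scalar Metropolis steps in the same ancillary
  parameterization. Without these, the one-at-a-time scan shows strong
  autocorrelation between person effects, B and Ψ, especially for the
  low-ICC duration outcome;
- Ψ: conjugate inverse-Wishart draw.

The within-level predictors (night index, weekend) are centered at
their pooled observed means inside the sampler — a pure
reparameterization that re-bases the person intercepts to the protocol
midpoint and average weekend share while leaving every slope, Ψ and γ
unchanged; it removes the intercept–slope posterior correlation that
otherwise cripples mixing. Persons with no observed nights contribute
only through the between-level model (their α, ω are imputed from the
conditional prior each sweep, which leaves the posterior of the shared
parameters exactly as if they were absent — they are retained so no
person is ever dropped).

The first half of each chain is discarded as burn-in. Convergence is
monitored by the Gelman–Rubin potential scale reduction
PSR = sqrt(((L−1)/L·W + B/L)/W) for every stored model-level parameter
(B, γ, Ψ; person effects are nuisance). The convergence protocol
(`converge_and_double`) doubles iterations until max PSR < 1.05 ("nears
1.0" made concrete), then doubles once more and reports both PSR
vectors; the final posterior comes from the doubled run. In practice the
regression coefficients and γ sit at PSR ≈ 1.00 within ~1000 iterations;
the slowest parameters are between-person variance components of
low-ICC outcomes (the α-duration variance), the classic hard case for
variance-component Gibbs samplers — the per-parameter PSR column in
every summary exposes this honestly.

95% credibility intervals are equal-tailed linear-interpolation
quantiles of the pooled post-burn-in draws; an interval excluding zero
is flagged significant. Standardized coefficients are computed within
each draw as β = b · SD(x)/SD(y), with SD(y) the model-implied total
between-level SD at that draw (regression-explained variance from the
sample predictor covariance plus the Ψ diagonal); draws with
non-positive implied variance are dropped with a reported count. The
unconditional ICC uses a homogeneous-variance random-intercept model
estimated by ML (statsmodels MixedLM).

The moderation model z-scores the general-factor score and the four
demographics and adds the four products (products of z-scores, not
z-scores of products) to every between-level equation simultaneously.
The correlated-factors supplement runs two separate location-scale
models — duration only, and bedtime + waketime — with the same
demographic covariates as the primary model.

## Synthetic cohort generator

The generator is the package's stand-in for the study sample and the
engine for all recovery experiments. Its defaults encode the reference
study conditions:

- **Cohort**: 238 adolescents, 14 requested nights.
- **Latents**: orthogonal standard-normal g, s_int, s_ext per person.
- **Indicators**: each facet's signal carries the configured
  standardized loadings; caregiver and youth scores are the common
  signal plus independent rater noise scaled so the two raters correlate
  at `rater_reliability` (default 0.8). The signal loadings are
  internally disattenuated by sqrt((1+r)/(2r)) so that the *aggregated*
  indicators carry exactly the configured loadings; 0.8 is the smallest
  round reliability for which the strongest facets stay admissible
  (communality < 1). Real caregiver–youth agreement is typically lower;
  the generator trades that realism for exact loading calibration.
- **Demographics**: age uniform on [14, 18]; sex Bernoulli(0.534);
  maternal education categorical on {10, 12, 14, 16} years with the
  reference marginals; income-to-needs lognormal matched to mean 2.53,
  SD 1.84. Covariate effects apply to the z-scored (population-scale)
  covariates.
- **Between level**: the 6×7 coefficient matrix defaults to the
  reference estimates (e.g. 0.121 for the general-factor effect on
  duration log-variance); α intercepts put cohort means at 389.54, −3.83
  and 463.07 minutes; ω intercepts make exp(ω/2) match mean nightly SDs
  of 79.10, 74.22 and 91.92 minutes; Ψ diagonals are solved so total
  between-person variance reproduces intraclass correlations of 0.17,
  0.42 and 0.29 given the mean within-night variance, with fixed modest
  residual correlations (bedtime–waketime 0.5, duration–bedtime −0.35,
  variability pairs 0.3). Ψ is validated positive definite before any
  sampling.
- **Within level**: night trend (−0.8, +1.0, +0.5 min/night) and weekend
  shifts (+15, +45, +60 min) — typical adolescent weekend delays; the
  three metrics are drawn independently given (α, ω).
- **Missingness**: per-night wear probability 1 − logistic(−1.87 −
  0.30·age_z), calibrated to ~12.1 observed of 14 nights among valid
  wearers and giving older adolescents fewer missing nights; 34/238 of
  persons (age-weighted toward younger) are "invalid" with only 0–2
  worn nights, so the validity filter leaves them with no usable sleep.
  Both mechanisms depend on age only, hence MAR given the model's
  covariates.

What the generator does **not** emulate: item-level questionnaire
responses; epoch-level actigraphy (it emits nightly metrics directly);
the mechanical dependence duration ≈ waketime − bedtime (metrics are
conditionally independent given the person's latent level and scale, so
tests passing here say nothing about that constraint in real data);
non-Gaussian nightly residuals; informative (MNAR) missingness. Passing
recovery tests demonstrate the estimators are correct for the assumed
data-generating process, not that the process matches any particular
real cohort.

## Degenerate inputs and tie-breaks

Reading a cohort validates referential integrity (every night row's
person exists) and numeric fields (errors carry row numbers). The
validity filter is idempotent and count-preserving. `model_df` rejects
over-parameterized specifications. The FIML objective guards
non-positive-definite implied covariances with a smooth eigenvalue
penalty. PSR of identical constant chains is defined as 1. The MELSM
requires at least 2 persons with at least 2 observed nights. Replicate
seeds for recovery experiments derive deterministically from a master
seed and stay below 2³¹.

## Problem sizes used in the checks

The test suite calibrates fit indices over 100 replicates of 500
persons; recovers loadings at n = 2000; runs interval-coverage and null
calibration experiments with 20 replicates of 200 persons × 14 nights at
1200 MCMC iterations per chain (a deliberately reduced chain length —
the convergence protocol is available when publication-grade convergence
of every variance component is needed); and checks ICC recovery at
500 × 14. The acceptance script runs the full pipeline on a 238-person
cohort at 10000 iterations plus a 20-replicate coverage experiment at
1200 iterations.

## Known limitations

- Two-step estimation: factor-score uncertainty is not propagated into
  the location-scale model's posteriors.
- Within-level residuals are cross-outcome independent given (α, ω).
- Between-person variance components of low-ICC outcomes mix slowly
  (PSR can linger near 1.1–1.2 at moderate chain lengths even when all
  regression coefficients have converged); rely on the doubling
  protocol and the reported per-parameter PSR.
- Plain ML χ² (no robustness correction) for the measurement model.
- The single-indicator dysregulation factor in the supplement uses a
  fixed 5% residual-variance identification; conclusions about that
  factor are conditional on the chosen reliability.
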