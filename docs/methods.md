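# Methods

## The model

`pedisrisk` fits a Bayesian logistic regression for the six-month amputation
risk of diabetic foot ulcer (DFU) patients from their baseline PEDIS
classification. For patient *i* with predictor row
x_i = (1, perfusion_i, extent_i, depth_i, infection_i, sensation_i, age_z_i, gender_i),

    y_i ~ Bernoulli(logit⁻¹(βᵀ x_i)),        β_j ~ Cauchy(loc_j, scale_j),

with two binary outcomes fit separately: *any* lower-extremity amputation and
*major* (above-ankle) amputation, the latter nested in the former.

Predictor coding, fixed throughout the package (the fitting, the prediction
and the synthetic data-generating process use the same coding):

* the five PEDIS grades enter as numeric integers — one coefficient per
  factor, so the coefficient is a per-grade log-odds increment;
* age is z-scored (by the fitting cohort's own mean/SD at fit time, by the
  configured mean/SD inside the generator) so its coefficient is on a scale
  comparable to the grade coefficients;
* gender is coded male = 1, female = 0.

Weakly-informative priors are zero-centred Cauchy with scale 1 on every slope
and Cauchy(0, 10) on the intercept.

## Prior elicitation from published odds ratios

Informative priors for the five risk factors are built from previously
published odds ratios with confidence intervals:

1. **SE recovery.** From a single source CI, SE_OR = (hi − lo)/(2 z); because
   the conservative adjustment below subtracts the SE from the OR directly,
   the symmetric-width convention on the OR scale is the default
   (`se_from_ci`), with the log-scale convention available (`se_from_ci_log`).
2. **Pooling.** Multiple effects for the same coefficient are pooled by
   inverse-variance fixed-effect weighting on the log-OR scale; the pooled SE
   is brought back to the OR scale by the delta method. A single effect passes
   through unchanged. Random-effects pooling is out of scope.
3. **Conservative adjustment.** adjusted = max(OR_pooled − 2·SE, 0.05): the
   prior location is pulled toward the null from above; the 0.05 floor keeps
   the subsequent log defined.
4. **Prior construction.** location = ln(adjusted OR). The prior **scale** is
   elicited from the source's own precision: 2 × pooled SE on the log-OR
   scale, floored at 0.1 and capped at the weakly-informative 1. The
   doubling mirrors step 3 — the prior admits twice the dispersion the source
   reports, a deliberate humility about between-study heterogeneity. We do
   not reuse the weakly-informative scale of 1 for elicited priors: a
   location-shifted Cauchy at the *same* scale as the default prior changes
   posterior dispersion only through second-order curvature differences
   (a few percent at best, sign-indefinite for weakly identified
   coefficients), so it cannot express the variance reduction that is the
   entire point of informing a model from external evidence. An explicit
   `scale=` argument overrides the rule.

The intercept, age and gender always keep weakly-informative priors;
external evidence is elicited only for the risk factors.

`example_published_effects()` is a **synthetic** fixture — one constructed
OR/CI per factor, chosen so the chain lands at conservative locations of
0.37–0.80 on the log-odds scale, the magnitude reported for informed DFU
amputation models. It is not a transcription of any study.

## Sampling

The posterior is explored by Metropolis–Hastings, self-contained and exactly
reproducible from a seed (per-chain generators spawned from one
`SeedSequence`). Two samplers are provided:

* **Independence MH (default).** A damped-Newton ascent finds the posterior
  mode and Laplace covariance (the Cauchy prior is not log-concave, so the
  negative Hessian is ridge-regularised when needed). Proposals are drawn
  independently from a multivariate Student-t (df = 8, a heavier envelope
  than the Gaussian Laplace approximation) centred at the mode. On well-posed
  problems the acceptance rate is ≈ 0.75–0.95 and retained draws are nearly
  independent, which is what makes effective sample sizes above 10,000 out of
  32,000 retained draws attainable; a random-walk chain of the same length
  could not reach that (its ESS/N is roughly 0.3/d at dimension d). Proposal
  log-densities for all steps are precomputed in a vectorised batch, so a
  full default fit takes a few seconds on one CPU.
* **Adaptive random-walk Metropolis (`sampler="rwm"`).** A multivariate
  normal proposal whose global scale is tuned by Robbins–Monro toward the
  canonical 0.234 acceptance rate and whose shape is taken from the running
  draw covariance, both frozen after the adaptation window. Kept as a
  robustness cross-check: it makes no Gaussian-like assumption about where
  the mass is.

Both samplers are validated against deterministic 1-D quadrature of the same
posterior (mean within 3 Monte-Carlo SEs; Kolmogorov–Smirnov distance of the
32,000 retained draws below 0.02) and, in the flat-prior large-n limit,
against an independent IRLS maximum-likelihood fit.

Defaults: 4 chains × 8,500 steps, burn-in 500, retaining all
4 × 8,000 = 32,000 post-burn-in draws. A `retain` option subsamples evenly if
a smaller draw count is wanted. Chains start at the Laplace mode plus a small
seeded jitter (random-walk variant) or from the first proposal (independence
variant); burn-in absorbs initialisation bias.

## Diagnostics

* **Split R-hat**: each chain halved; R̂ = sqrt(((n−1)/n·W + B/n)/W) over the
  2·chains half-sequences. Zero-variance draws return exactly 1. Threshold
  1.01.
* **ESS**: chain-averaged autocovariances (FFT), combined with the
  between-chain variance, truncated by Geyer's initial monotone positive-pair
  rule. ESS may legitimately exceed the draw count for antithetic chains and
  is reported as N for degenerate (zero-variance) coefficients. Threshold
  10,000 at the default 32,000 draws, scaled proportionally for shorter runs.
* **Autocorrelation**: biased autocovariance normalised by lag 0.
* **Collinearity**: pairwise Pearson correlations of the numeric predictor
  columns; |r| ≥ 0.8 flags a pair; zero-variance columns are reported as
  undefined. (Rank-normalised R-hat variants and divergence diagnostics are
  out of scope.)

Diagnostic failures attach warnings to the fit and to the pipeline manifest;
they never abort a run.

## Posterior inference

* **HDI**: sorted-window search — window length m = ceil(mass·n), narrowest
  window wins, ties to the smallest index. Assumes unimodality (adequate for
  regression coefficients and the AUC). Verified exactly against exhaustive
  window enumeration.
* **Coefficient summaries**: posterior median β, 95% HDI, OR = exp(median),
  OR interval by endpoint exponentiation of the β HDI. HDIs are not
  transform-invariant, so the endpoint-exponentiated interval is a convention
  — it matches how published DFU risk tables relate their β and OR columns.
  A factor is "associated" when the β HDI excludes 0 (a boundary exactly at
  0 counts as covered).
* **AUC**: rank-based Mann–Whitney with tied pairs counted 1/2, computed per
  posterior draw on in-sample (apparent) predictions — no cross-validation,
  matching how such models are typically reported at this cohort size. The
  per-draw score enters only through ranks, so any strictly increasing
  transform of the predicted probabilities leaves the AUC unchanged.
* **Model comparison**: ΔAUC = difference of posterior AUC medians; Cohen's d
  = (mean_b − mean_a)/sqrt((sd_a² + sd_b²)/2).
* **Risk prediction**: per-draw inverse-logit of the linear predictor for an
  explicit covariate profile. Age and gender must be stated — there are no
  silent defaults, because the published worked examples omit them and a
  hidden default would make predictions irreproducible.

## Synthetic cohort generator

The generator emulates the published reference cohort (237 patients, German
single-centre wound-care study):

* per-factor marginal stage probabilities from the published descriptive
  table (perfusion 48.1/32.5/19.4%, …); **factors are sampled independently
  by default** because only marginals were published — no joint distribution
  is recoverable. An optional Gaussian-copula hook
  (`GeneratorConfig.factor_corr`) imposes exchangeable correlation between
  the latent severity scores while preserving the marginals exactly, for
  sensitivity studies of correlated grades;
* age ~ Normal(65.9, 12.3²) truncated at 18; 83.5% male;
* outcomes from the logistic process above with true coefficients defaulting
  to the published informed any-amputation medians (0.703, 1.283, 0.656,
  −0.021, 0.516) plus age_z = 0.25 (amputees are ~4 years older in the
  published table) and gender = 0;
* the intercept is calibrated by Brent root-finding on a fixed 200,000-row
  Monte-Carlo predictor sample (internal fixed seed) so the simulated
  prevalence hits 31.6% within 0.002;
* major amputations use their own coefficient set (the published informed
  major medians) simulated *among the any-amputation cases*, with the
  conditional intercept calibrated so the overall major prevalence hits
  12.2%. Simulating the two processes independently would violate the
  nesting invariant major ⇒ any for ~3% of patients; conditioning keeps the
  nesting exact and both prevalences on target;
* 16/254 ≈ 6.3% of records are flagged lost-to-follow-up (outcomes blanked,
  excluded from fitting, retained in files).

What passing tests on these cohorts do **not** show: behaviour under
correlated risk factors (real PEDIS grades correlate), non-logistic outcome
mechanisms, informative loss to follow-up, or any misclassification of
grades/outcomes. The generator is a test harness for the statistical
machinery, not a reconstruction of the source population.

## Validation-study problem sizes

The repeated-fit studies use deliberately bounded sizes: parameter recovery
runs 20 replicates at n = 2,000 with 2 × 3,000-step chains (the
mean-over-replicates posterior median is the bias check, since a single
replicate's sampling SE for the sensation coefficient is ≈ 0.2 — its marginal
is 7%/93% — which no estimator can beat at n = 2,000); the informative-prior
study runs 20 replicates at n = 100 with ~12% prevalence and full-length
default chains (posterior-SD differences of a few percent need low
Monte-Carlo noise); sampler correctness and diagnostics checks use the full
default 4 × 8,500 configuration.

## Numerical choices

* logistic link via `logaddexp`; probabilities underflow gracefully at
  |η| ≈ 700 rather than erroring;
* Newton steps use Cholesky solves with step-halving line search and ridge
  escalation for indefinite Hessians;
* HDI/median tie-breaks: first (smallest-index) window; `numpy` median
  conventions;
* degenerate inputs are errors where they invalidate the estimand (empty
  cohorts, single-class outcomes, single samples for an HDI) and defined
  values where a convention is standard (R-hat of constant chains = 1,
  ESS of constant chains = N).

## Known limitations

* Independence-MH efficiency degrades if the posterior is far from unimodal
  Gaussian-like; the `rwm` sampler and the attached diagnostics are the
  safety net, not a gradient-based sampler.
* The sample-window HDI is biased slightly narrow at small draw counts and
  assumes unimodality.
* Endpoint-exponentiated OR intervals are not the HDI of the OR.
* Apparent (in-sample) AUC overstates out-of-sample discrimination; no
  cross-validation or calibration analysis is provided.
* The published coefficient table cannot be reproduced numerically — the
  underlying patient-level data were never released; it is used only for
  generator magnitudes and internal-consistency checks.
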