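# pedisrisk

Bayesian six-month amputation-risk modelling for diabetic foot ulcer (DFU)
patients from PEDIS-classified cohorts.

Diabetic foot ulcers are closely linked to lower-extremity amputation, and the
IWGDF's PEDIS classification (Perfusion, Extent, Depth, Infection, Sensation —
ordinal grades summing to a 5–15 score) is a standardised way to describe an
ulcer at baseline. This package is for biostatisticians and clinical
researchers who want to turn such cohorts into transparent risk models: it
fits Bayesian logistic regressions for two nested outcomes (any amputation;
major, above-ankle amputation), reports full posterior distributions instead
of point estimates, and lets external evidence from earlier studies enter as
informative priors — a "chain of knowledge" across studies that never
requires sharing patient-level data.

## The model

For patient *i* with covariates
x_i = (1, perfusion, extent, depth, infection, sensation, age_z, gender):

    y_i ~ Bernoulli(logit⁻¹(βᵀ x_i)),      β_j ~ Cauchy(loc_j, scale_j)

* **Uninformed models**: zero-centred Cauchy(0, 1) priors on every slope
  (Cauchy(0, 10) on the intercept).
* **Informed models**: prior locations elicited from published odds ratios —
  pool (inverse-variance, log-OR scale), subtract twice the standard error
  (conservative adjustment), log-transform; prior scales elicited from the
  pooled SE. See `docs/methods.md`.
* **Sampling**: a self-contained Metropolis–Hastings sampler (independence
  proposals from a Laplace approximation; adaptive random-walk as an option),
  4 chains × 8,500 steps with 500 burn-in by default, validated against
  deterministic quadrature.
* **Inference**: 95% highest-density intervals (HDI) with null-exclusion
  decisions, odds ratios as exponentiated posterior medians, posterior AUC
  distributions (one Mann–Whitney AUC per draw), informed-vs-uninformed
  comparison (ΔAUC, Cohen's d), and per-patient posterior risk predictions.
* **Synthetic cohorts**: a generator emulating the published reference
  cohort's marginals (48.1/32.5/19.4% perfusion stages, 31.6% / 12.2%
  outcome prevalences, age ~ N(65.9, 12.3²) truncated at 18, 83.5% male),
  so every stage of the pipeline is testable without patient data.

## Worked example

Simulate a 237-patient cohort, fit the twofold strategy (uninformed and
informed priors) for the any-amputation outcome, and predict two ulcer
profiles:

```bash
pedisrisk simulate --n 237 --seed 42 --out cohort.csv
pedisrisk elicit --effects effects.json --out priors.json   # published ORs -> priors
pedisrisk run --cohort cohort.csv --outcomes any --prior-mode both \
    --effects effects.json --thin 4 --seed 42 --out run/
```

prints

```
any/uninformed: AUC 0.723, converged=True
any/informed: AUC 0.725, converged=True
any: delta AUC +0.002, Cohen's d 0.229
```

— the posterior-median apparent AUC of each model with its convergence
verdict, and the informed-vs-uninformed comparison (at this cohort size and
event count the informative priors barely move the AUC; their main effect is
tighter coefficient posteriors). Then:

```bash
pedisrisk predict --draws run/any/informed/draws.csv --cohort cohort.csv \
  --profile '{"perfusion":2,"extent":2,"depth":1,"infection":1,"sensation":1,"age":66,"gender":"male"}'
# {"median": 0.0319, "hdi_low": 0.0017, "hdi_high": 0.1065, "n_draws": 32000}

pedisrisk predict --draws run/any/informed/draws.csv --cohort cohort.csv \
  --profile '{"perfusion":3,"extent":3,"depth":3,"infection":1,"sensation":1,"age":66,"gender":"male"}'
# {"median": 0.4749, "hdi_low": 0.1986, "hdi_high": 0.7724, "n_draws": 32000}
```

A moderate ulcer (PAD without critical ischaemia, 1–5 cm², superficial) gets
a median posterior amputation risk of ~3% with a narrow credible interval; a
severe ulcer (critical ischaemia, > 5 cm², reaching bone) ~47% with a wide
one — the model separates the two profiles with non-overlapping 95% HDIs,
and the interval widths express how confident it is in each prediction.

The same steps are available as library calls (`generate_cohort`,
`elicit_priors`, `fit`, `posterior_auc`, `predict_risk`, `run_pipeline`);
see the module docstrings.

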