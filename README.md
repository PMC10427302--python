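# harshpref

Bayesian multilevel analysis of how experimentally primed environmental
harshness — perceived **pathogen prevalence (PP)** and **resource
scarcity (RS)** — shifts heterosexual women's forced choices between
masculinised and feminised versions of male faces, together with the
ordinal rating and mediation submodels that explain *why*.

The package is for researchers in evolutionary psychology / human
behavioural ecology who want a tested, reproducible implementation of
this analysis family: a 12-trial two-alternative forced choice modelled
with a logistic link, three cumulative-logit ordinal rating models with
shared cut-points, a mediation submodel for the perceived-harshness
scales, cross-classified varying intercepts, and a synthetic-data
generator that reproduces the whole design for parameter-recovery and
calibration experiments.

## The model in brief

Choice of the masculinised face is Bernoulli with

```
logit P = α_c + β^A_c ΔA + β^F_c ΔF + β^H_c ΔH
        + β_PP z_PP + β_RS z_RS + β_side s + u_target + v_rater
```

(condition-specific intercepts and rating-difference slopes, standardised
perceived-score slopes, a ±0.5 screen-side contrast, and
normally-distributed target and rater intercepts with hyper-SDs σ_t,
σ_r). Each rating dimension is a cumulative-logit model: six ordered
cut-points shared by both morph versions, version-specific condition
intercepts and perceived-score slopes, and target / rater / target×rater
varying intercepts shared between versions. Perceived scores are
themselves regressed on condition (the mediation paths). Everything is
sampled jointly with a gradient-based HMC backend written for this
posterior (analytic gradients, dense mass block over the correlated
directions); summaries use posterior means with 89% compatibility
intervals. See `docs/methods.md` for the full account.

## Worked example

```python
import harshpref as hp

# a complete synthetic study at the original design:
# 102/101/86 raters (control/PP/RS), 12 targets, generating values at the
# published posterior means
cfg = hp.default_sim_config(seed=11)
data = hp.simulate_study(cfg)

clean, report, _ = hp.preprocess(data)
print(report.n_retained_raters, report.n_retained_datapoints)

samples = hp.fit(clean,
                 sampler_config=hp.SamplerConfig(n_draws=2000,
                                                 n_warmup=800, n_chains=2),
                 seed=5)
print(samples.diagnostics["rhat"].max())

d = hp.contrast(samples, "choice.alpha[control]", "choice.alpha[PP]")
print(hp.summarise_draws(d, "control - PP"))
```

Output from this exact run:

```
289 3350
1.0279414849483615
name     control - PP
mean         0.284074
lower        0.131063
upper        0.433878
dtype: object
```

289 raters are retained and 3350 of 3468 choice records survive the
recognition screen (the recognition rate is part of the generator). Every
split-R̂ across the ~11,000 parameters is below the 1.05 gate. The
control − PP condition contrast is the analysis' headline quantity: the
log-odds advantage of choosing the masculinised face in the control
condition over the PP condition, here estimated from data generated with
a true contrast of 0.17 and covered by the 89% interval. Expected
masc − fem rating differences per condition come from
`hp.rating_difference_posterior(samples, clean, "formidability")`, and
`hp.headline_estimates(samples, clean)` collects the full report table.

A thin CLI mirrors the stages: `harshpref simulate`, `harshpref
preprocess`, `harshpref fit`, `harshpref report` (see `--help`).

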