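# Methods

## The scientific setting

`harshpref` implements a Bayesian multilevel analysis of a priming
experiment on women's facial masculinity preferences. Heterosexual women
are randomly assigned to one of three conditions — a video heightening
perceived **pathogen prevalence (PP)**, one heightening perceived
**resource scarcity (RS)**, or a neutral control — and then complete:

* a 12-trial **two-alternative forced choice (2AFC)** between a
  masculinised and a feminised morph of the same male face (choice of a
  long-term partner);
* Likert (1–7) **ratings** of all 24 face versions on attractiveness,
  healthiness and formidability;
* self-report **perceived PP / RS scales**, an attention check about the
  video, and a face-recognition screen.

The analysis asks whether the priming shifts the probability of choosing
the masculinised face, whether perceived-harshness scores carry an
independent association, and whether the condition effects are mediated by
changes in how the faces are rated.

## Model

All blocks are fit jointly; they share observed covariates but no
parameters, so the joint posterior factorises exactly across blocks and
can be sampled block by block.

**Choice block.** For rater $r$ in condition $c(r)$, target $t$:

$$
\mathrm{logit}\, P(\text{masc chosen}) =
\alpha_{c} + \beta^{A}_{c} \Delta A_{rt} + \beta^{F}_{c} \Delta F_{rt}
+ \beta^{H}_{c} \Delta H_{rt}
+ \beta_{PP} z^{PP}_r + \beta_{RS} z^{RS}_r
+ \beta_{side}\, s_r + u_t + v_r,
$$

where $\Delta A, \Delta F, \Delta H$ are the observed masculinised −
feminised rating differences of that rater–target pair (per rating unit;
positive slope = higher-rated masculinised faces chosen more), $z^{PP},
z^{RS}$ are the standardised perceived scores, $s_r = \pm 0.5$ codes the
screen side of the masculinised photo (−0.5 left, +0.5 right),
$u_t \sim N(0, \sigma_t)$ and $v_r \sim N(0, \sigma_r)$. There is no
global intercept: each condition has its own $\alpha_c$ and its own slope
triple.

**Rating blocks** (one per dimension). Cumulative-logit ordinal
regression with six ordered cut-points $c_1 < \dots < c_6$ shared by both
morph versions of the dimension: $P(Y > k) =
\mathrm{logit}^{-1}(\phi - c_k)$, with

$$
\phi_{\text{mas}} = a^{mas}_{c} + g^{mas}_{PP} z^{PP} + g^{mas}_{RS} z^{RS}
 + w_t + x_r + z_{tr},
\qquad
\phi_{\text{fem}} = a^{fem}_{c} + g^{fem}_{PP} z^{PP} + g^{fem}_{RS} z^{RS}
 + w_t + x_r + z_{tr},
$$

so the masculinised and feminised predictors have independent condition
intercepts and perceived-score slopes but share the three varying
intercepts: target $w_t \sim N(0, \sigma_T)$, rater
$x_r \sim N(0, \sigma_R)$, and target × rater cell
$z_{tr} \sim N(0, \sigma_{TR})$ (a rater may find a particular face
appealing regardless of morphing).

**Mediation (scales) block.** The standardised perceived scores are also
outcomes: $z^{s}_r \sim N(\mu_{s, c(r)}, \tau_s)$ with one mean per
scale × condition and one estimated residual SD per scale. This closes
the indirect paths: condition → perceived score → choice/ratings.

**Priors.** Weakly regularising: Normal(0, 1.5) on condition intercepts,
Normal(0, 5) on cut-points, Normal(0, 1) on slopes, Exponential(1) on all
hyper-SDs and residual SDs; overridable via `Priors`. The cut-point scale
is deliberately wider than the intercept scale: the latent location of a
rating block spreads with $\sqrt{\sigma_T^2 + \sigma_R^2 +
\sigma_{TR}^2}$ (about 6 latent units for attractiveness at realistic
hyper-SD values), so thresholds must be free to sit several units out.
Because a common shift of (cut-points, condition intercepts) leaves the
ordinal likelihood unchanged, that direction is identified only by the
priors; a tight cut-point prior would silently pin it. The prior scales
are stand-ins in the published analysis's spirit ("unbiased, weakly
regularised"), stated here explicitly so they can be criticised and
overridden.

## Exclusion cascade

Filters run in a fixed order, each switchable for sensitivity variants:
(1) a manual drop list; (2) non-heterosexual raters; (3) raters answering
*both* attention-check questions wrong (`attention_correct == 0`; one
correct answer retains); (4) raters recognising more than four target
faces (all their data); (5) individual choice *and* rating records of a
recognised face (the rating reflects the same contaminated knowledge).
Scale scores are item means; Cronbach's α uses the standard variance
decomposition. Standardisation (sample SD, n−1) runs on the retained
sample, after the cascade, so the model's z-scores are centred in the
analysed population.

## Synthetic-data generator

`simulate_study` is the generative reading of the fitted model: raters are
assigned to conditions (default retained-design sizes 102/101/86, 12
targets) with exactly counterbalanced masculinised-photo sides within
condition; perceived scores are drawn from the mediation block; ratings
from the cumulative-logit blocks; choices Bernoulli from the logistic
block using the *realised* simulated rating differences (mirroring the
analysis, which uses observed differences as predictors); recognition and
attention-check flags are independent noise.

Default generating values are the published posterior means (condition
contrasts 0.17 / 0.04 in log-odds, perceived-PP slope −0.06 per SD, side
slope 0.08, $\sigma_t = 0.72$, $\sigma_r = 0.12$, the nine expected
rating differences, and the nine rating hyper-SDs). Quantities the source
reports on the *outcome* scale are mapped back to the latent scale
numerically: the masc − fem intercept gap of each dimension × condition
is solved (Gauss–Hermite integration + Brent root-finding) so that the
implied population-expected rating difference equals the reported value.
Cut-points are not published; the defaults are evenly spaced and chosen
once so the marginal rating distributions sit where the raw data sit
(attractiveness rated low on average, the other dimensions mid-scale).
The mediation means are small condition effects consistent with the
reported direction (perceived PP highest under PP priming; perceived RS
highest in control), residual SD 1.

What the generator does *not* emulate: item-level scale structure beyond
an equal-loading model (optional, used only to exercise Cronbach's α),
demographic covariate effects, reaction times, and any dependence between
recognition and the other exclusion flags (flags are independent). A pass
on synthetic data therefore demonstrates that the pipeline recovers the
parameters of *this* generative structure at realistic sizes and values —
not that the substantive conclusions hold in new empirical data.

Batch replication derives per-replicate seeds from a documented splittable
counter scheme (`SeedSequence([master_seed, replicate])`), so a replicate
set is a pure function of the master seed.

## Inference

The sampler is Hamiltonian Monte Carlo with analytic gradients on the
unconstrained parameterisation: log hyper-SDs, an ordered (first value +
log-increments) transform for cut-points, and non-centred varying
intercepts. Step size is tuned by dual averaging to a 0.8 target
acceptance rate; the number of leapfrog steps is jittered uniformly up to
`max_leapfrog` (default 32) to avoid resonance; warm-up contains two mass
re-estimation windows.

Two geometric features of the model defeat a purely diagonal mass matrix
and are handled structurally:

* the prior-identified cut-point/intercept ridge of each ordinal block,
  and the posterior trade-off between population slopes on rater-level
  covariates and the rater intercepts, produce strong correlations
  involving a *small* set of directions;
* therefore the mass matrix is dense over the top-level parameters plus
  all target intercepts plus the five covariate-spanned rater-intercept
  directions. The latter are exposed by rotating the iid-normal raw rater
  intercepts with an orthogonal basis whose leading columns span the
  condition indicators and $z^{PP}, z^{RS}$ — a rotation of an isotropic
  prior, so the model is untouched.

At the full design (289 raters, ~11,000 parameters) this yields maximum
split-R̂ ≈ 1.02 across all parameters with 2 × 1000 retained draws in
about six minutes on one CPU. `fit` computes split-R̂ and bulk ESS (via
`arviz`) for every parameter and raises by default when any R̂ exceeds
1.05.

Derived quantities are pure functions of the draws: 89% central
percentile ("compatibility") intervals, posterior contrasts, expected
rating differences (per draw, per observed rater–target pair, under the
pair's own varying intercepts, averaged within condition), and
counterfactual choice probabilities (inverse-logit over a covariate grid
with varying intercepts at zero, rating differences and side contrast at
zero unless overridden).

## Numerical choices

* Ordinal category log-probabilities are computed in log space
  (`-softplus` forms plus `log(-expm1(·))` for interior categories), so
  extreme latent locations stay finite; collapsed cut-point proposals get
  a finite, very low density rather than NaN and are rejected on density.
* The cut-point transform clamps log-increments at 80 before
  exponentiation for the same reason.
* Cut-points are initialised at the empirical marginal logit quantiles of
  the observed scores; other coordinates start at 0.1-scale jitter.
* Reproducibility: every chain's RNG derives from
  `SeedSequence([seed, block, chain])`; identical seeds give identical
  draws.

## Scaling of the shipped experiments

The test suite and the acceptance script run the full design (289 raters,
12 targets) with 2000 retained draws for the joint fit, and use
choice-block-only fits (the exact marginal posterior, since the blocks
factorise) for replicate experiments: interval coverage across 20
replicates of 60 raters, and null calibration across 20 replicates of 100
raters with all condition effects at zero. The 10,000-draw default of
`SamplerConfig` reproduces the original reporting convention when more
precision is wanted.

## Known limitations

* Static HMC with jittered path length, not a dynamic (NUTS-style)
  integrator; the dense-block metric compensates for this model family,
  but strongly different models may need `max_leapfrog` raised.
* The scales block models standardised scores with an estimated residual
  SD; after standardisation the marginal SD is 1 by construction, so the
  residual SD and condition means are gently coupled — harmless for the
  contrasts of interest.
* Choice records whose rating differences cannot be formed (possible
  under exclusion variants that drop rating records) are dropped from the
  choice likelihood with a logged count.
* The recruitment arithmetic of the original participant flow contains an
  unresolvable overlap ambiguity upstream of the data this pipeline
  consumes; the exclusion report tallies only what it computes from its
  input.
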