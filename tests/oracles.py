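"""Independent scalar-loop reimplementations used as numerical oracles.

Everything here is deliberately written record-by-record with plain
``math`` calls and no shared code with the package's vectorised
implementations.
"""

from __future__ import annotations

import math

import numpy as np

CONDS = ("control", "pathogen_prevalence", "resource_scarcity")


def inv_logit(x: float) -> float:
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


def normal_logpdf(x: float, mu: float, sd: float) -> float:
    return (-0.5 * ((x - mu) / sd) ** 2 - math.log(sd)
            - 0.5 * math.log(2 * math.pi))


def ordinal_prob(cutpoints, phi: float, score: int) -> float:
    """P(Y = score) by direct difference of cumulative inverse logits."""
    upper = 1.0 if score == 1 else inv_logit(phi - cutpoints[score - 2])
    lower = 0.0 if score == 7 else inv_logit(phi - cutpoints[score - 1])
    return upper - lower


def naive_joint_logdensity(params, priors, data) -> float:
    """Row-by-row evaluation of the joint posterior density.

    ``params`` is a :class:`harshpref.model.JointParams` with every varying
    intercept supplied; ``data`` is a preprocessed StudyDataset.
    """
    raters = data.raters.set_index("rater_id")
    cond_idx = {rid: CONDS.index(raters.loc[rid, "condition"])
                for rid in raters.index}
    target_ids = sorted(set(data.choices["target_id"])
                        | set(data.ratings["target_id"]))
    t_idx = {tid: i for i, tid in enumerate(target_ids)}
    r_idx = {rid: i for i, rid in enumerate(raters.index)}

    # rating lookup for choice-model difference predictors
    score = {}
    for row in data.ratings.itertuples():
        score[(row.rater_id, row.target_id, row.version,
               row.dimension)] = row.score

    total = 0.0
    ch = params.choice
    for row in data.choices.itertuples():
        key = (row.rater_id, row.target_id)
        try:
            dd = {dim: (score[key + ("masculinised", dim)]
                        - score[key + ("feminised", dim)])
                  for dim in ("attractiveness", "formidability",
                              "healthiness")}
        except KeyError:
            continue      # incomplete rating pair: dropped from the choice block
        c = cond_idx[row.rater_id]
        eta = (ch.alpha[c]
               + ch.beta_attr[c] * dd["attractiveness"]
               + ch.beta_form[c] * dd["formidability"]
               + ch.beta_heal[c] * dd["healthiness"]
               + ch.beta_pp * raters.loc[row.rater_id, "z_pp"]
               + ch.beta_rs * raters.loc[row.rater_id, "z_rs"]
               + ch.beta_side * row.side_contrast
               + ch.u_target[t_idx[row.target_id]]
               + ch.v_rater[r_idx[row.rater_id]])
        p = inv_logit(eta)
        total += math.log(p if row.chose_masculinised else 1.0 - p)

    for row in data.ratings.itertuples():
        p = params.ratings[row.dimension]
        c = cond_idx[row.rater_id]
        mas = row.version == "masculinised"
        phi = ((p.a_mas[c] if mas else p.a_fem[c])
               + (p.g_mas_pp if mas else p.g_fem_pp)
               * raters.loc[row.rater_id, "z_pp"]
               + (p.g_mas_rs if mas else p.g_fem_rs)
               * raters.loc[row.rater_id, "z_rs"]
               + p.w_target[t_idx[row.target_id]]
               + p.x_rater[r_idx[row.rater_id]]
               + np.asarray(p.z_cell)[t_idx[row.target_id],
                                      r_idx[row.rater_id]])
        total += math.log(ordinal_prob(p.cutpoints, phi, row.score))

    sc = params.scales
    for rid in raters.index:
        c = cond_idx[rid]
        total += normal_logpdf(raters.loc[rid, "z_pp"], sc.mu[0][c],
                               sc.resid_sd[0])
        total += normal_logpdf(raters.loc[rid, "z_rs"], sc.mu[1][c],
                               sc.resid_sd[1])

    # varying-intercept densities
    for i in range(len(target_ids)):
        total += normal_logpdf(ch.u_target[i], 0.0, ch.sigma_target)
    for i in range(len(raters.index)):
        total += normal_logpdf(ch.v_rater[i], 0.0, ch.sigma_rater)
    for dim in ("attractiveness", "healthiness", "formidability"):
        p = params.ratings[dim]
        for i in range(len(target_ids)):
            total += normal_logpdf(p.w_target[i], 0.0, p.sigma_target)
        for i in range(len(raters.index)):
            total += normal_logpdf(p.x_rater[i], 0.0, p.sigma_rater)
        for v in np.asarray(p.z_cell).ravel():
            total += normal_logpdf(float(v), 0.0, p.sigma_cell)

    # priors
    for c in range(3):
        total += normal_logpdf(ch.alpha[c], 0.0, priors.intercept_scale)
        for b in (ch.beta_attr[c], ch.beta_form[c], ch.beta_heal[c]):
            total += normal_logpdf(b, 0.0, priors.slope_scale)
    for b in (ch.beta_pp, ch.beta_rs, ch.beta_side):
        total += normal_logpdf(b, 0.0, priors.slope_scale)
    for s in (ch.sigma_target, ch.sigma_rater):
        total += math.log(priors.sd_rate) - priors.sd_rate * s
    for dim in ("attractiveness", "healthiness", "formidability"):
        p = params.ratings[dim]
        for j in range(6):
            total += normal_logpdf(p.cutpoints[j], 0.0,
                                   priors.cutpoint_scale)
        for c in range(3):
            total += normal_logpdf(p.a_mas[c], 0.0, priors.intercept_scale)
            total += normal_logpdf(p.a_fem[c], 0.0, priors.intercept_scale)
        for g in (p.g_mas_pp, p.g_mas_rs, p.g_fem_pp, p.g_fem_rs):
            total += normal_logpdf(g, 0.0, priors.slope_scale)
        for s in (p.sigma_target, p.sigma_rater, p.sigma_cell):
            total += math.log(priors.sd_rate) - priors.sd_rate * s
    for i in range(2):
        for c in range(3):
            total += normal_logpdf(sc.mu[i][c], 0.0, priors.intercept_scale)
        total += math.log(priors.sd_rate) - priors.sd_rate * sc.resid_sd[i]
    return total


def random_joint_params(rng: np.random.Generator, n_targets: int,
                        n_raters: int):
    """Draw a random, moderately scaled JointParams with all intercepts."""
    from harshpref.model import (ChoiceParams, JointParams, RatingParams,
                                 ScaleParams)

    def cuts():
        c = np.sort(rng.normal(0, 2.0, 6))
        return c + 0.05 * np.arange(6)          # enforce strict ordering

    choice = ChoiceParams(
        alpha=rng.normal(0, 1, 3), beta_attr=rng.normal(0, 0.5, 3),
        beta_form=rng.normal(0, 0.5, 3), beta_heal=rng.normal(0, 0.5, 3),
        beta_pp=rng.normal(0, 0.5), beta_rs=rng.normal(0, 0.5),
        beta_side=rng.normal(0, 0.5),
        sigma_target=rng.uniform(0.2, 1.5), sigma_rater=rng.uniform(0.2, 1.5),
        u_target=rng.normal(0, 0.5, n_targets),
        v_rater=rng.normal(0, 0.5, n_raters))
    ratings = {}
    for dim in ("attractiveness", "healthiness", "formidability"):
        ratings[dim] = RatingParams(
            cutpoints=cuts(), a_mas=rng.normal(0, 1, 3),
            a_fem=rng.normal(0, 1, 3),
            g_mas_pp=rng.normal(0, 0.5), g_mas_rs=rng.normal(0, 0.5),
            g_fem_pp=rng.normal(0, 0.5), g_fem_rs=rng.normal(0, 0.5),
            sigma_target=rng.uniform(0.3, 2.0),
            sigma_rater=rng.uniform(0.3, 2.0),
            sigma_cell=rng.uniform(0.3, 2.0),
            w_target=rng.normal(0, 0.8, n_targets),
            x_rater=rng.normal(0, 0.8, n_raters),
            z_cell=rng.normal(0, 0.8, (n_targets, n_raters)))
    scales = ScaleParams(mu=rng.normal(0, 0.6, (2, 3)),
                         resid_sd=rng.uniform(0.5, 1.5, 2))
    return JointParams(choice=choice, ratings=ratings, scales=scales)
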