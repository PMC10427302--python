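"""Synthetic study generator: the generative reading of the fitted model.

:func:`simulate_study` produces a complete study-shaped dataset — raters
with condition assignment, counterbalanced screen sides, perceived-score
draws from the mediation submodel, Likert ratings from the cumulative-logit
submodels, forced choices from the logistic submodel driven by the
*realised* rating differences, and independent recognition / attention-check
noise.  Defaults reproduce the retained design of the original study:
102 / 101 / 86 raters in the control / pathogen-prevalence /
resource-scarcity conditions, 12 target faces, and generating parameter
values equal to the published posterior means, so that the default regime
is the realistic one for parameter-recovery experiments.

Because the published results report expected masculinised − feminised
rating *differences* rather than latent intercepts, the generating
intercept gaps are solved numerically so that the implied expected rating
difference (integrating over the varying-intercept distribution) equals the
reported value for each condition and dimension.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import roots_hermitenorm

from .datamodel import CONDITIONS, DIMENSIONS, StudyDataset
from .model import (ChoiceParams, RatingParams, ScaleParams, ordinal_mean,
                    sigmoid)


class SimulationError(ValueError):
    pass


@dataclasses.dataclass
class SimConfig:
    """Everything the generator needs, including the generating parameters."""

    choice_params: ChoiceParams
    rating_params: dict[str, RatingParams]
    scale_params: ScaleParams
    n_raters_per_condition: tuple[int, int, int] = (102, 101, 86)
    n_targets: int = 12
    recognition_rate: float = 110 / 3468     # per rater x target
    attention_fail_rate: float = 0.0         # both check questions wrong
    nonheterosexual_rate: float = 0.0
    backfill_items: bool = False             # raw Likert items for alpha
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.recognition_rate, self.attention_fail_rate,
                  self.nonheterosexual_rate):
            if not 0.0 <= p <= 1.0:
                raise SimulationError("rates must be probabilities")
        if self.n_targets < 2:
            raise SimulationError("need at least two targets")
        if len(self.n_raters_per_condition) != 3:
            raise SimulationError("need one sample size per condition")
        for dim, rp in self.rating_params.items():
            if not np.all(np.diff(rp.cutpoints) > 0):
                raise SimulationError(f"{dim}: cut-points not ordered")


# ---------------------------------------------------------------------------
# Reference generating values (published posterior means)
# ---------------------------------------------------------------------------

#: Choice-model posterior means: condition intercepts chosen so the pairwise
#: contrasts are control−PP = 0.17, control−RS = 0.04 (hence RS−PP = 0.13)
#: around a near-even baseline (50.2% masculinised choices overall);
#: attractiveness slopes 0.10/0.09/0.06, healthiness slope 0.07 in RS,
#: perceived-PP slope −0.06 per SD, side contrast 0.08 (right-side choice
#: probability 0.51), hyper-SDs 0.72 (targets) and 0.12 (raters).
REFERENCE_CHOICE = dict(
    alpha=(0.07, -0.10, 0.03),
    beta_attr=(0.10, 0.09, 0.06),
    beta_form=(0.0, 0.0, 0.0),
    beta_heal=(0.0, 0.0, 0.07),
    beta_pp=-0.06, beta_rs=0.0, beta_side=0.08,
    sigma_target=0.72, sigma_rater=0.12,
)

#: Per-dimension reference values.  Hyper-SDs are the published posterior
#: means; expected masc − fem rating differences per condition are the
#: published estimates and determine the intercept gaps (solved in
#: :func:`intercept_gap_for_rating_difference`).  Cut-points are not
#: published; the defaults below are evenly spaced and chosen so the
#: marginal rating distributions sit where the raw data sit (attractiveness
#: rated low on average, healthiness and formidability mid-scale).
REFERENCE_RATING = {
    "attractiveness": dict(
        sigma_target=5.97, sigma_rater=3.00, sigma_cell=2.48,
        rating_diff=(0.06, 0.02, 0.04),
        cutpoints=(-4.0, -1.0, 2.0, 5.0, 8.0, 11.0),
        g_mas_pp=-0.8, g_mas_rs=0.0, g_fem_pp=-0.8, g_fem_rs=0.0),
    "formidability": dict(
        sigma_target=1.43, sigma_rater=2.07, sigma_cell=1.90,
        rating_diff=(0.44, 0.47, 0.42),
        cutpoints=(-4.0, -2.4, -0.8, 0.8, 2.4, 4.0),
        g_mas_pp=-0.4, g_mas_rs=0.0, g_fem_pp=-0.4, g_fem_rs=0.0),
    "healthiness": dict(
        sigma_target=1.88, sigma_rater=1.89, sigma_cell=2.02,
        rating_diff=(0.05, 0.11, 0.14),
        cutpoints=(-4.2, -2.5, -0.9, 0.7, 2.3, 4.0),
        g_mas_pp=0.0, g_mas_rs=0.0, g_fem_pp=0.0, g_fem_rs=0.0),
}

#: Mediation submodel: small condition effects on the standardised perceived
#: scores — PP score highest under PP priming; RS score highest in control —
#: with unit residual SD.
REFERENCE_SCALES = dict(
    mu=((-0.10, 0.25, -0.10),      # perceived PP by condition
        (0.15, -0.10, -0.05)),     # perceived RS by condition
    resid_sd=(1.0, 1.0),
)


def expected_rating_difference(cutpoints: Sequence[float], gap: float,
                               latent_sd: float, n_nodes: int = 80) -> float:
    """Population-expected masc − fem rating difference for intercept gap.

    Integrates ``E[Y | phi]`` over ``phi ~ Normal(0, latent_sd)`` with
    Gauss–Hermite quadrature; the masculinised version sits at ``phi + gap``.
    """
    nodes, weights = roots_hermitenorm(n_nodes)
    weights = weights / weights.sum()
    phi = nodes * latent_sd
    c = np.asarray(cutpoints, dtype=float)
    return float(weights @ (ordinal_mean(c, phi + gap) - ordinal_mean(c, phi)))


def intercept_gap_for_rating_difference(cutpoints: Sequence[float],
                                        target_diff: float,
                                        latent_sd: float) -> float:
    """Solve the phi gap whose expected rating difference equals the target."""
    if target_diff == 0.0:
        return 0.0
    f = lambda gap: expected_rating_difference(cutpoints, gap,
                                               latent_sd) - target_diff
    sign, hi = np.sign(target_diff), 0.1
    while sign * f(sign * hi) < 0:    # f increases in gap; expand the bracket
        hi *= 2
        if hi > 50:
            raise SimulationError("rating difference unreachable")
    a, b = sorted((0.0, sign * hi))
    return float(brentq(f, a, b))


def reference_rating_params(dim: str) -> RatingParams:
    """RatingParams at the published posterior means for one dimension."""
    ref = REFERENCE_RATING[dim]
    latent_sd = float(np.sqrt(ref["sigma_target"] ** 2
                              + ref["sigma_rater"] ** 2
                              + ref["sigma_cell"] ** 2))
    gaps = [intercept_gap_for_rating_difference(ref["cutpoints"], d,
                                                latent_sd)
            for d in ref["rating_diff"]]
    return RatingParams(
        cutpoints=np.asarray(ref["cutpoints"], dtype=float),
        a_mas=np.asarray(gaps), a_fem=np.zeros(3),
        g_mas_pp=ref["g_mas_pp"], g_mas_rs=ref["g_mas_rs"],
        g_fem_pp=ref["g_fem_pp"], g_fem_rs=ref["g_fem_rs"],
        sigma_target=ref["sigma_target"], sigma_rater=ref["sigma_rater"],
        sigma_cell=ref["sigma_cell"])


def default_sim_config(seed: int = 0, **overrides) -> SimConfig:
    """SimConfig at the reference (published posterior mean) regime."""
    cfg = SimConfig(
        choice_params=ChoiceParams(**REFERENCE_CHOICE),
        rating_params={d: reference_rating_params(d) for d in DIMENSIONS},
        scale_params=ScaleParams(**REFERENCE_SCALES),
        seed=seed)
    return dataclasses.replace(cfg, **overrides) if overrides else cfg


def null_sim_config(seed: int = 0, **overrides) -> SimConfig:
    """Reference regime with all condition effects set to zero.

    Choice intercepts, rating intercept gaps and mediation means are
    equalised across conditions; used for null-calibration experiments.
    """
    cfg = default_sim_config(seed, **overrides)
    cfg.choice_params.alpha = np.zeros(3)
    for rp in cfg.rating_params.values():
        rp.a_mas = np.zeros(3)
        rp.a_fem = np.zeros(3)
    cfg.scale_params.mu = np.zeros((2, 3))
    return cfg


# ---------------------------------------------------------------------------
# Generator
# ---------------------------------------------------------------------------

_PP_ITEM_NOISE = 1.155   # equal-loading item noise SD giving alpha ~ 0.84 (k=7)
_RS_ITEM_NOISE = 1.691   # giving alpha ~ 0.71 (k=7)
_N_ITEMS = 7


def _draw_or_given(given: np.ndarray | None, sd: float, size,
                   rng: np.random.Generator) -> np.ndarray:
    if given is not None:
        return np.asarray(given, dtype=float)
    return rng.normal(0.0, sd, size=size)


def _ordinal_draw(cutpoints: np.ndarray, phi: np.ndarray,
                  rng: np.random.Generator) -> np.ndarray:
    """Draw Likert scores: Y = 1 + #{thresholds the latent draw exceeds}.

    One shared uniform per record against the decreasing exceedance
    probabilities P(Y > k) = sigmoid(phi - c_k) yields the categorical
    distribution of the cumulative-logit model.
    """
    u = rng.random(phi.shape)
    exceed = u[..., None] < sigmoid(phi[..., None] - cutpoints)
    return 1 + exceed.sum(axis=-1)


def simulate_study(config: SimConfig,
                   seed: int | np.random.SeedSequence | None = None,
                   ) -> StudyDataset:
    """Generate one complete study-shaped dataset.

    Fully reproducible from ``config.seed`` (or an explicit ``seed``
    override).  Varying intercepts left as ``None`` in the generating
    parameters are drawn from their hyper-SDs; supplied arrays are used
    as given.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    T = config.n_targets
    ns = [int(n) for n in config.n_raters_per_condition]
    R = sum(ns)
    target_ids = np.arange(1, T + 1)

    # --- raters --------------------------------------------------------
    cond = np.repeat(np.arange(3), ns)
    masc_side = np.empty(R, dtype=object)
    for c in range(3):            # counterbalanced within condition
        idx = np.flatnonzero(cond == c)
        half = len(idx) // 2
        sides = np.array(["left"] * half + ["right"] * (len(idx) - half),
                         dtype=object)
        masc_side[idx] = rng.permutation(sides)
    rater_ids = np.array([f"R{i + 1:04d}" for i in range(R)])

    heterosexual = rng.random(R) >= config.nonheterosexual_rate
    fails = rng.random(R) < config.attention_fail_rate
    attention = np.where(fails, 0, rng.choice([1, 2], size=R, p=[0.2, 0.8]))

    sc = config.scale_params
    pp_score = rng.normal(sc.mu[0, cond], sc.resid_sd[0])
    rs_score = rng.normal(sc.mu[1, cond], sc.resid_sd[1])

    raters = pd.DataFrame({
        "rater_id": rater_ids,
        "condition": np.array(CONDITIONS, dtype=object)[cond],
        "heterosexual": heterosexual.astype(int),
        "attention_correct": attention,
        "masc_side": masc_side,
        "age": np.clip(np.round(rng.normal(21.03, 2.98, R)), 18, 40
                       ).astype(int),
        "relationship_status": (rng.random(R) < 109 / 289).astype(int),
        "mate_value_face": np.clip(np.round(rng.normal(4.58, 1.16, R)),
                                   1, 7).astype(int),
        "mate_value_body": np.clip(np.round(rng.normal(4.55, 1.32, R)),
                                   1, 7).astype(int),
        "pp_score": pp_score,
        "rs_score": rs_score,
    })
    if config.backfill_items:
        for scale, score, noise in (("pp", pp_score, _PP_ITEM_NOISE),
                                    ("rs", rs_score, _RS_ITEM_NOISE)):
            items = score[:, None] + rng.normal(0, noise, (R, _N_ITEMS))
            items = np.clip(np.round(4.0 + items), 1, 7).astype(int)
            for j in range(_N_ITEMS):
                raters[f"{scale}_item_{j + 1}"] = items[:, j]

    # --- ratings -------------------------------------------------------
    rating_frames = []
    # realised masc - fem differences per rater x target x dimension
    diffs = {}
    t_grid, r_grid = np.meshgrid(np.arange(T), np.arange(R), indexing="ij")
    t_flat, r_flat = t_grid.ravel(), r_grid.ravel()
    for dim in DIMENSIONS:
        p = config.rating_params[dim]
        w = _draw_or_given(p.w_target, p.sigma_target, T, rng)
        x = _draw_or_given(p.x_rater, p.sigma_rater, R, rng)
        z = _draw_or_given(p.z_cell, p.sigma_cell, (T, R), rng)
        base = (w[t_flat] + x[r_flat] + z[t_flat, r_flat])
        scores = {}
        for version, a, g_pp, g_rs in (
                ("masculinised", p.a_mas, p.g_mas_pp, p.g_mas_rs),
                ("feminised", p.a_fem, p.g_fem_pp, p.g_fem_rs)):
            phi = (a[cond[r_flat]] + g_pp * pp_score[r_flat]
                   + g_rs * rs_score[r_flat] + base)
            scores[version] = _ordinal_draw(p.cutpoints, phi, rng)
            rating_frames.append(pd.DataFrame({
                "rater_id": rater_ids[r_flat],
                "target_id": target_ids[t_flat],
                "version": version,
                "dimension": dim,
                "score": scores[version],
            }))
        diffs[dim] = (scores["masculinised"].astype(float)
                      - scores["feminised"].astype(float))
    ratings = pd.concat(rating_frames, ignore_index=True)

    # --- choices (driven by realised rating differences) ---------------
    cp = config.choice_params
    u = _draw_or_given(cp.u_target, cp.sigma_target, T, rng)
    v = _draw_or_given(cp.v_rater, cp.sigma_rater, R, rng)
    side = np.where(masc_side[r_flat] == "left", -0.5, 0.5)
    ccond = cond[r_flat]
    eta = (cp.alpha[ccond]
           + cp.beta_attr[ccond] * diffs["attractiveness"]
           + cp.beta_form[ccond] * diffs["formidability"]
           + cp.beta_heal[ccond] * diffs["healthiness"]
           + cp.beta_pp * pp_score[r_flat] + cp.beta_rs * rs_score[r_flat]
           + cp.beta_side * side + u[t_flat] + v[r_flat])
    chose = (rng.random(eta.shape) < sigmoid(eta)).astype(int)
    recognised = (rng.random(eta.shape) < config.recognition_rate).astype(int)

    choices = pd.DataFrame({
        "rater_id": rater_ids[r_flat],
        "target_id": target_ids[t_flat],
        "chose_masculinised": chose,
        "recognised": recognised,
        "side_contrast": side,
    })
    return StudyDataset(raters=raters, choices=choices,
                        ratings=ratings).validate()


def generating_values(config: SimConfig) -> dict[str, float]:
    """Flat map of generating top-level parameter values by posterior name.

    Used in parameter-recovery experiments: keys match the component names
    of :class:`harshpref.inference.PosteriorSamples`.  The mediation-model
    means and residual SDs are re-expressed on the standardised scale the
    fitted model sees (preprocessing standardises the perceived scores over
    the retained sample), using the population mean and SD implied by the
    generating mixture over conditions.
    """
    short = ("control", "PP", "RS")
    out: dict[str, float] = {}
    cp = config.choice_params
    for key, arr in (("alpha", cp.alpha), ("beta_attr", cp.beta_attr),
                     ("beta_form", cp.beta_form), ("beta_heal", cp.beta_heal)):
        for lab, v in zip(short, arr):
            out[f"choice.{key}[{lab}]"] = float(v)
    out["choice.beta_pp"] = cp.beta_pp
    out["choice.beta_rs"] = cp.beta_rs
    out["choice.beta_side"] = cp.beta_side
    out["choice.sigma_target"] = cp.sigma_target
    out["choice.sigma_rater"] = cp.sigma_rater
    for dim, p in config.rating_params.items():
        for j in range(6):
            out[f"{dim}.cut[{j + 1}]"] = float(p.cutpoints[j])
        for lab, vm, vf in zip(short, p.a_mas, p.a_fem):
            out[f"{dim}.a_mas[{lab}]"] = float(vm)
            out[f"{dim}.a_fem[{lab}]"] = float(vf)
        for key in ("g_mas_pp", "g_mas_rs", "g_fem_pp", "g_fem_rs"):
            out[f"{dim}.{key}"] = float(getattr(p, key))
        out[f"{dim}.sigma_target"] = p.sigma_target
        out[f"{dim}.sigma_rater"] = p.sigma_rater
        out[f"{dim}.sigma_cell"] = p.sigma_cell
    sc = config.scale_params
    weights = np.asarray(config.n_raters_per_condition, dtype=float)
    weights = weights / weights.sum()
    for i, scale in enumerate(("pp", "rs")):
        m = float(weights @ sc.mu[i])
        sd = float(np.sqrt(sc.resid_sd[i] ** 2
                           + weights @ (sc.mu[i] - m) ** 2))
        for lab, v in zip(short, sc.mu[i]):
            out[f"scales.mu[{scale},{lab}]"] = (float(v) - m) / sd
        out[f"scales.resid_sd[{scale}]"] = float(sc.resid_sd[i]) / sd
    return out


def batch_seed(master_seed: int, replicate: int) -> int:
    """Deterministic per-replicate seed from (master seed, counter)."""
    ss = np.random.SeedSequence([int(master_seed), int(replicate)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def simulate_batch(config: SimConfig, n_replicates: int,
                   ) -> list[StudyDataset]:
    """Independent, reproducible replicate datasets.

    Replicate ``r`` uses the seed ``batch_seed(config.seed, r)``, a
    splittable counter scheme: the set of replicates is a pure function of
    the master seed.
    """
    if n_replicates < 1:
        raise SimulationError("n_replicates must be >= 1")
    return [simulate_study(config, seed=batch_seed(config.seed, r))
            for r in range(n_replicates)]
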