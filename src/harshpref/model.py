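"""Joint model: choice, rating and mediation blocks as pure log-densities.

The structural model has three kinds of blocks, which share observed
covariates but no parameters:

* **Choice block** — the 12-trial forced choice is Bernoulli with a logit
  link.  The linear predictor has one intercept per priming condition, one
  slope per condition for each observed rating difference
  (masculinised − feminised attractiveness / formidability / healthiness),
  population slopes for the standardised perceived pathogen-prevalence and
  resource-scarcity scores, a ±0.5 contrast for the screen side of the
  masculinised photo, and varying intercepts per target face and per rater
  with hyper-SDs ``sigma_target`` and ``sigma_rater``.

* **Rating blocks** (one per dimension) — cumulative-logit ordinal
  regressions on the 1–7 Likert scores.  Six ordered cut-points are shared
  by both morph versions of a dimension; the latent location ``phi`` has
  separate condition intercepts and perceived-score slopes for the
  masculinised and feminised version, and varying intercepts per target,
  per rater and per target × rater cell, shared between versions.

* **Scales block** — the mediation submodel: the standardised perceived
  scores are normal outcomes with one mean per scale × condition.

Every log-density here is a pure function of parameters and data.  The
module also provides the unconstrained parameterisation (log hyper-SDs,
ordered cut-point transform, non-centred varying intercepts) with analytic
gradients, which the HMC sampler in :mod:`harshpref.inference` consumes.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datamodel import CONDITIONS, DIMENSIONS, StudyDataset

logger = logging.getLogger(__name__)

COND_INDEX = {c: i for i, c in enumerate(CONDITIONS)}
N_CUTPOINTS = 6
N_CATEGORIES = 7

_LOG_2PI = float(np.log(2.0 * np.pi))


# ---------------------------------------------------------------------------
# Parameter containers (constrained / interpretable scale)
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class ChoiceParams:
    """Parameters of the forced-choice logistic submodel.

    Condition-indexed arrays follow the order ``(control, PP, RS)``.
    ``u_target`` / ``v_rater`` may be ``None`` when only the top-level
    parameters are of interest (e.g. when specifying generating values —
    the simulator then draws them from their hyper-SDs).
    """

    alpha: np.ndarray                      # (3,) condition intercepts, log-odds
    beta_attr: np.ndarray                  # (3,) per rating-unit difference
    beta_form: np.ndarray                  # (3,)
    beta_heal: np.ndarray                  # (3,)
    beta_pp: float                         # per SD of perceived PP
    beta_rs: float                         # per SD of perceived RS
    beta_side: float                       # on the ±0.5 side contrast
    sigma_target: float                    # hyper-SD of target intercepts
    sigma_rater: float                     # hyper-SD of rater intercepts
    u_target: np.ndarray | None = None     # (T,)
    v_rater: np.ndarray | None = None      # (R,)

    def __post_init__(self) -> None:
        for name in ("alpha", "beta_attr", "beta_form", "beta_heal"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
            if getattr(self, name).shape != (3,):
                raise ValueError(f"{name} must have one entry per condition")
        if self.sigma_target <= 0 or self.sigma_rater <= 0:
            raise ValueError("hyper-SDs must be positive")


@dataclasses.dataclass
class RatingParams:
    """Parameters of one cumulative-logit rating submodel (one dimension)."""

    cutpoints: np.ndarray                  # (6,) strictly increasing
    a_mas: np.ndarray                      # (3,) condition intercepts, phi_mas
    a_fem: np.ndarray                      # (3,) condition intercepts, phi_fem
    g_mas_pp: float
    g_mas_rs: float
    g_fem_pp: float
    g_fem_rs: float
    sigma_target: float                    # SD of target intercepts
    sigma_rater: float                     # SD of rater intercepts
    sigma_cell: float                      # SD of target x rater intercepts
    w_target: np.ndarray | None = None     # (T,)
    x_rater: np.ndarray | None = None      # (R,)
    z_cell: np.ndarray | None = None       # (T, R) or flat observed cells

    def __post_init__(self) -> None:
        self.cutpoints = np.asarray(self.cutpoints, dtype=float)
        if self.cutpoints.shape != (N_CUTPOINTS,):
            raise ValueError("exactly six cut-points are required")
        if not np.all(np.diff(self.cutpoints) > 0):
            raise ValueError("cut-points must be strictly increasing")
        self.a_mas = np.asarray(self.a_mas, dtype=float)
        self.a_fem = np.asarray(self.a_fem, dtype=float)
        if self.a_mas.shape != (3,) or self.a_fem.shape != (3,):
            raise ValueError("a_mas/a_fem must have one entry per condition")
        if min(self.sigma_target, self.sigma_rater, self.sigma_cell) <= 0:
            raise ValueError("hyper-SDs must be positive")


@dataclasses.dataclass
class ScaleParams:
    """Mediation submodel: perceived scores regressed on condition.

    ``mu`` is indexed ``[scale, condition]`` with scales ordered
    ``(pp, rs)`` and conditions ``(control, PP, RS)``.
    """

    mu: np.ndarray                         # (2, 3)
    resid_sd: np.ndarray                   # (2,)

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.resid_sd = np.asarray(self.resid_sd, dtype=float)
        if self.mu.shape != (2, 3):
            raise ValueError("mu must be 2 scales x 3 conditions")
        if self.resid_sd.shape != (2,) or np.any(self.resid_sd <= 0):
            raise ValueError("resid_sd must be two positive values")


@dataclasses.dataclass
class JointParams:
    """All parameters of the structural model."""

    choice: ChoiceParams
    ratings: Mapping[str, RatingParams]    # keyed by dimension
    scales: ScaleParams


@dataclasses.dataclass
class Priors:
    """Weakly regularising prior scales, overridable from configuration.

    Normal(0, ``intercept_scale``) on condition intercepts, Normal(0,
    ``cutpoint_scale``) on the ordered cut-points, Normal(0,
    ``slope_scale``) on slopes, Exponential(``sd_rate``) on every hyper-SD
    and residual SD.  The cut-point scale is wider than the intercept
    scale because the latent locations of the rating blocks spread with
    the varying-intercept hyper-SDs (posterior means up to ~6 latent
    units): thresholds must be free to span that range, otherwise the
    prior — not the data — pins the location of the prior-identified
    cut-point/intercept ridge.
    """

    intercept_scale: float = 1.5
    cutpoint_scale: float = 5.0
    slope_scale: float = 1.0
    sd_rate: float = 1.0

    def __post_init__(self) -> None:
        if min(self.intercept_scale, self.cutpoint_scale,
               self.slope_scale, self.sd_rate) <= 0:
            raise ValueError("all prior scales must be positive")


# ---------------------------------------------------------------------------
# Link-scale primitives
# ---------------------------------------------------------------------------


def sigmoid(x: np.ndarray | float) -> np.ndarray:
    """Numerically stable inverse logit."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softplus(x: np.ndarray | float) -> np.ndarray:
    """log(1 + exp(x)) without overflow."""
    x = np.asarray(x, dtype=float)
    return np.maximum(x, 0.0) + np.log1p(np.exp(-np.abs(x)))


def ordinal_category_logprobs(cutpoints: np.ndarray,
                              phi: np.ndarray | float) -> np.ndarray:
    """Log probabilities of the 7 Likert categories under a cumulative logit.

    ``P(Y > k) = sigmoid(phi - c_k)`` for the six ordered thresholds; the
    category probabilities are successive differences.  Evaluated in log
    space so extreme latent locations stay finite.

    Returns an array of shape ``phi.shape + (7,)``.
    """
    c = np.asarray(cutpoints, dtype=float)
    if c.shape != (N_CUTPOINTS,) or not np.all(np.diff(c) > 0):
        raise ValueError("cut-points must be six strictly increasing values")
    phi = np.asarray(phi, dtype=float)
    a = phi[..., None] - c                  # (..., 6)
    out = np.empty(phi.shape + (N_CATEGORIES,), dtype=float)
    # P(Y=1) = 1 - sigmoid(phi - c_1);  P(Y=7) = sigmoid(phi - c_6)
    out[..., 0] = -softplus(a[..., 0])
    out[..., 6] = -softplus(-a[..., 5])
    # interior: log(sigmoid(aL) - sigmoid(aU)) with aL > aU
    aL, aU = a[..., :-1], a[..., 1:]
    out[..., 1:6] = (-softplus(-aL) - softplus(aU)
                     + np.log1p(-np.exp(aU - aL)))
    return out


def ordinal_category_probs(cutpoints: np.ndarray,
                           phi: np.ndarray | float) -> np.ndarray:
    """Category probabilities (shape ``phi.shape + (7,)``); they sum to 1."""
    return np.exp(ordinal_category_logprobs(cutpoints, phi))


def ordinal_mean(cutpoints: np.ndarray, phi: np.ndarray | float) -> np.ndarray:
    """Expected Likert score ``E[Y] = 1 + sum_k P(Y > c_k)``."""
    phi = np.asarray(phi, dtype=float)
    return 1.0 + sigmoid(phi[..., None]
                         - np.asarray(cutpoints, dtype=float)).sum(axis=-1)


def _normal_logpdf(x: np.ndarray, mu: np.ndarray | float,
                   sd: np.ndarray | float) -> np.ndarray:
    z = (np.asarray(x, dtype=float) - mu) / sd
    return -0.5 * z * z - np.log(sd) - 0.5 * _LOG_2PI


# ---------------------------------------------------------------------------
# Data preparation (tables -> index arrays)
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class RatingBlockData:
    """Index arrays for one dimension's rating records."""

    score: np.ndarray        # (M,) int, 1..7
    t: np.ndarray            # (M,) target index 0..T-1
    r: np.ndarray            # (M,) rater index 0..R-1
    cell: np.ndarray         # (M,) observed target x rater cell index
    cond: np.ndarray         # (M,) condition index of the rater
    mas: np.ndarray          # (M,) bool, True for the masculinised version
    n_cells: int
    cell_t: np.ndarray       # (n_cells,) target index of each cell
    cell_r: np.ndarray       # (n_cells,) rater index of each cell


@dataclasses.dataclass
class PreparedData:
    """Model-ready index arrays derived from a preprocessed StudyDataset."""

    n_raters: int
    n_targets: int
    rater_ids: np.ndarray
    target_ids: np.ndarray
    rater_cond: np.ndarray   # (R,) condition index
    z_pp: np.ndarray         # (R,)
    z_rs: np.ndarray         # (R,)
    # choice block
    choice_y: np.ndarray
    choice_t: np.ndarray
    choice_r: np.ndarray
    choice_side: np.ndarray
    choice_diffs: np.ndarray  # (N, 3) attr, form, heal masc - fem
    n_choice_dropped: int
    # rating blocks
    rating_blocks: dict[str, RatingBlockData]


def prepare(data: StudyDataset) -> PreparedData:
    """Turn a preprocessed dataset into the index arrays the model consumes.

    Requires ``z_pp``/``z_rs`` on the rater table and ``side_contrast`` on
    the choice table (see :mod:`harshpref.preprocess`).  Choice records
    whose masc − fem rating differences cannot be formed (a version's rating
    was removed by an exclusion variant) are dropped from the choice block
    with a logged count.
    """
    raters, choices, ratings = data.raters, data.choices, data.ratings
    for col in ("z_pp", "z_rs"):
        if col not in raters.columns:
            raise ValueError(f"rater table lacks {col!r}; run preprocessing "
                             "(standardise_scales) first")
    if "side_contrast" not in choices.columns:
        raise ValueError("choice table lacks 'side_contrast'; run "
                         "preprocessing (code_side_contrast) first")

    rater_ids = np.asarray(raters["rater_id"])
    rater_index = {rid: i for i, rid in enumerate(rater_ids)}
    target_ids = np.unique(np.concatenate([
        choices["target_id"].to_numpy(),
        ratings["target_id"].to_numpy()]))
    target_index = {tid: i for i, tid in enumerate(target_ids)}
    R, T = len(rater_ids), len(target_ids)

    rater_cond = raters["condition"].map(COND_INDEX).to_numpy(dtype=np.int64)
    z_pp = raters["z_pp"].to_numpy(dtype=float)
    z_rs = raters["z_rs"].to_numpy(dtype=float)
    if np.isnan(z_pp).any() or np.isnan(z_rs).any():
        raise ValueError("NaN standardised perceived scores")

    # masc - fem rating difference per rater x target x dimension
    wide = ratings.pivot_table(index=["rater_id", "target_id", "dimension"],
                               columns="version", values="score",
                               aggfunc="first")
    diffs = (wide.get("masculinised") - wide.get("feminised")).unstack(
        "dimension")

    ch = choices.merge(
        diffs.reset_index(), on=["rater_id", "target_id"], how="left")
    diff_cols = ["attractiveness", "formidability", "healthiness"]
    for col in diff_cols:
        if col not in ch.columns:
            ch[col] = np.nan
    ok = ch[diff_cols].notna().all(axis=1)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("dropping %d choice records lacking complete rating "
                    "differences", n_dropped)
    ch = ch[ok]

    choice_r = ch["rater_id"].map(rater_index).to_numpy(dtype=np.int64)
    choice_t = ch["target_id"].map(target_index).to_numpy(dtype=np.int64)
    choice_side = ch["side_contrast"].to_numpy(dtype=float)
    choice_y = ch["chose_masculinised"].to_numpy(dtype=float)
    choice_diffs = ch[diff_cols].to_numpy(dtype=float)

    blocks: dict[str, RatingBlockData] = {}
    for dim in DIMENSIONS:
        sub = ratings[ratings["dimension"] == dim]
        r = sub["rater_id"].map(rater_index).to_numpy(dtype=np.int64)
        t = sub["target_id"].map(target_index).to_numpy(dtype=np.int64)
        flat = t * R + r
        uniq, cell = np.unique(flat, return_inverse=True)
        blocks[dim] = RatingBlockData(
            score=sub["score"].to_numpy(dtype=np.int64),
            t=t, r=r, cell=cell.astype(np.int64),
            cond=rater_cond[r],
            mas=(sub["version"] == "masculinised").to_numpy(),
            n_cells=len(uniq),
            cell_t=(uniq // R).astype(np.int64),
            cell_r=(uniq % R).astype(np.int64),
        )

    return PreparedData(
        n_raters=R, n_targets=T, rater_ids=rater_ids, target_ids=target_ids,
        rater_cond=rater_cond, z_pp=z_pp, z_rs=z_rs,
        choice_y=choice_y, choice_t=choice_t, choice_r=choice_r,
        choice_side=choice_side, choice_diffs=choice_diffs,
        n_choice_dropped=n_dropped, rating_blocks=blocks)


# ---------------------------------------------------------------------------
# Public log-likelihoods (constrained scale)
# ---------------------------------------------------------------------------


def choice_linear_predictor(params: ChoiceParams, condition: str,
                            rating_diffs: Sequence[float], z_pp: float,
                            z_rs: float, side_contrast: float,
                            u_target: float = 0.0,
                            v_rater: float = 0.0) -> float:
    """Log-odds of choosing the masculinised face for one trial.

    ``rating_diffs`` is the (attractiveness, formidability, healthiness)
    triple of masculinised − feminised ratings for this rater–target pair.
    """
    c = COND_INDEX[condition]
    d_attr, d_form, d_heal = (float(v) for v in rating_diffs)
    return float(params.alpha[c]
                 + params.beta_attr[c] * d_attr
                 + params.beta_form[c] * d_form
                 + params.beta_heal[c] * d_heal
                 + params.beta_pp * z_pp + params.beta_rs * z_rs
                 + params.beta_side * side_contrast
                 + u_target + v_rater)


def _choice_eta(params: ChoiceParams, prep: PreparedData) -> np.ndarray:
    c = prep.rater_cond[prep.choice_r]
    u = params.u_target if params.u_target is not None else np.zeros(
        prep.n_targets)
    v = params.v_rater if params.v_rater is not None else np.zeros(
        prep.n_raters)
    return (params.alpha[c]
            + params.beta_attr[c] * prep.choice_diffs[:, 0]
            + params.beta_form[c] * prep.choice_diffs[:, 1]
            + params.beta_heal[c] * prep.choice_diffs[:, 2]
            + params.beta_pp * prep.z_pp[prep.choice_r]
            + params.beta_rs * prep.z_rs[prep.choice_r]
            + params.beta_side * prep.choice_side
            + np.asarray(u)[prep.choice_t]
            + np.asarray(v)[prep.choice_r])


def choice_loglik(params: ChoiceParams,
                  data: StudyDataset | PreparedData) -> float:
    """Bernoulli log-likelihood of all forced-choice records."""
    prep = data if isinstance(data, PreparedData) else prepare(data)
    eta = _choice_eta(params, prep)
    if np.isnan(eta).any():
        raise ValueError("NaN in choice linear predictor")
    return float(np.sum(prep.choice_y * eta - softplus(eta)))


def _rating_phi(p: RatingParams, blk: RatingBlockData, prep: PreparedData,
                ) -> np.ndarray:
    mas = blk.mas
    a = np.where(mas, p.a_mas[blk.cond], p.a_fem[blk.cond])
    g_pp = np.where(mas, p.g_mas_pp, p.g_fem_pp)
    g_rs = np.where(mas, p.g_mas_rs, p.g_fem_rs)
    w = p.w_target if p.w_target is not None else np.zeros(prep.n_targets)
    x = p.x_rater if p.x_rater is not None else np.zeros(prep.n_raters)
    phi = (a + g_pp * prep.z_pp[blk.r] + g_rs * prep.z_rs[blk.r]
           + np.asarray(w)[blk.t] + np.asarray(x)[blk.r])
    if p.z_cell is not None:
        z = np.asarray(p.z_cell)
        if z.ndim == 2:          # full (T, R) grid
            phi = phi + z[blk.t, blk.r]
        else:                    # flat, observed cells only
            phi = phi + z[blk.cell]
    return phi


def rating_loglik(params: Mapping[str, RatingParams],
                  data: StudyDataset | PreparedData,
                  dimensions: Sequence[str] = DIMENSIONS) -> float:
    """Cumulative-logit log-likelihood summed over the given dimensions."""
    prep = data if isinstance(data, PreparedData) else prepare(data)
    total = 0.0
    for dim in dimensions:
        blk = prep.rating_blocks[dim]
        if np.any((blk.score < 1) | (blk.score > 7)):
            raise ValueError(f"{dim}: rating score outside 1..7")
        p = params[dim]
        phi = _rating_phi(p, blk, prep)
        lp = ordinal_category_logprobs(p.cutpoints, phi)
        total += float(lp[np.arange(len(phi)), blk.score - 1].sum())
    return total


def scales_loglik(params: ScaleParams,
                  data: StudyDataset | PreparedData) -> float:
    """Gaussian log-likelihood of the standardised perceived scores."""
    prep = data if isinstance(data, PreparedData) else prepare(data)
    c = prep.rater_cond
    lp = (_normal_logpdf(prep.z_pp, params.mu[0, c], params.resid_sd[0])
          + _normal_logpdf(prep.z_rs, params.mu[1, c], params.resid_sd[1]))
    return float(lp.sum())


def joint_logdensity(params: JointParams, priors: Priors,
                     data: StudyDataset | PreparedData) -> float:
    """Unnormalised joint log posterior density on the constrained scale.

    Likelihood of every block plus the varying-intercept normal densities
    plus the prior densities.  Varying intercepts absent from ``params``
    (``None``) contribute neither likelihood shift nor density.
    """
    prep = data if isinstance(data, PreparedData) else prepare(data)
    total = (choice_loglik(params.choice, prep)
             + rating_loglik(params.ratings, prep)
             + scales_loglik(params.scales, prep))

    ch = params.choice
    if ch.u_target is not None:
        total += float(_normal_logpdf(ch.u_target, 0.0,
                                      ch.sigma_target).sum())
    if ch.v_rater is not None:
        total += float(_normal_logpdf(ch.v_rater, 0.0, ch.sigma_rater).sum())
    for dim in DIMENSIONS:
        p = params.ratings[dim]
        if p.w_target is not None:
            total += float(_normal_logpdf(p.w_target, 0.0,
                                          p.sigma_target).sum())
        if p.x_rater is not None:
            total += float(_normal_logpdf(p.x_rater, 0.0,
                                          p.sigma_rater).sum())
        if p.z_cell is not None:
            total += float(_normal_logpdf(np.asarray(p.z_cell).ravel(), 0.0,
                                          p.sigma_cell).sum())
    total += prior_logdensity(params, priors)
    return total


def prior_logdensity(params: JointParams, priors: Priors) -> float:
    """Log density of the weakly regularising priors (top level only)."""
    pr = priors
    ch = params.choice
    total = float(_normal_logpdf(ch.alpha, 0.0, pr.intercept_scale).sum())
    for b in (ch.beta_attr, ch.beta_form, ch.beta_heal):
        total += float(_normal_logpdf(b, 0.0, pr.slope_scale).sum())
    for b in (ch.beta_pp, ch.beta_rs, ch.beta_side):
        total += float(_normal_logpdf(b, 0.0, pr.slope_scale))
    for s in (ch.sigma_target, ch.sigma_rater):
        total += float(-pr.sd_rate * s + np.log(pr.sd_rate))
    for dim in DIMENSIONS:
        p = params.ratings[dim]
        total += float(_normal_logpdf(p.cutpoints, 0.0,
                                      pr.cutpoint_scale).sum())
        total += float(_normal_logpdf(p.a_mas, 0.0, pr.intercept_scale).sum())
        total += float(_normal_logpdf(p.a_fem, 0.0, pr.intercept_scale).sum())
        for g in (p.g_mas_pp, p.g_mas_rs, p.g_fem_pp, p.g_fem_rs):
            total += float(_normal_logpdf(g, 0.0, pr.slope_scale))
        for s in (p.sigma_target, p.sigma_rater, p.sigma_cell):
            total += float(-pr.sd_rate * s + np.log(pr.sd_rate))
    sc = params.scales
    total += float(_normal_logpdf(sc.mu, 0.0, pr.intercept_scale).sum())
    total += float((-pr.sd_rate * sc.resid_sd
                    + np.log(pr.sd_rate)).sum())
    return total


# ---------------------------------------------------------------------------
# Unconstrained parameterisation with analytic gradients (sampler backend)
# ---------------------------------------------------------------------------
#
# Transforms: hyper-SDs are exp(log_sd); cut-points are
# c_0 = raw_0, c_m = c_{m-1} + exp(raw_m); varying intercepts are
# non-centred (raw ~ N(0, 1), effect = sd * raw).  Each block's
# ``logp_and_grad`` returns the log posterior density on the unconstrained
# scale (including Jacobians) and its gradient.


@dataclasses.dataclass
class BlockLayout:
    """Flat-vector layout of one sampling block.

    ``n_dense`` marks how many leading coordinates benefit from a dense
    mass matrix during sampling (the top-level parameters, the target
    intercepts and the covariate-spanned rater-intercept directions, which
    are mutually correlated in the posterior).  ``rotations`` holds the
    orthogonal matrix applied to the rater-intercept coordinates; an
    orthogonal rotation of an iid standard-normal vector leaves the model
    unchanged but moves the weakly identified covariate directions into
    the dense block.
    """

    name: str
    entries: list[tuple[str, int]]
    n_dense: int = 0
    rotations: dict = dataclasses.field(default_factory=dict)

    @property
    def ndim(self) -> int:
        return sum(n for _, n in self.entries)

    def slices(self) -> dict[str, slice]:
        out, start = {}, 0
        for key, n in self.entries:
            out[key] = slice(start, start + n)
            start += n
        return out

    def unpack(self, theta: np.ndarray) -> dict[str, np.ndarray]:
        return {k: theta[s] for k, s in self.slices().items()}


def cutpoints_from_raw(raw: np.ndarray) -> np.ndarray:
    c = np.empty_like(raw)
    c[0] = raw[0]
    # clamp the log-increments so a wild proposal stays finite (and gets
    # rejected on density, not on NaN)
    c[1:] = raw[0] + np.cumsum(np.exp(np.minimum(raw[1:], 80.0)))
    return c


def raw_from_cutpoints(c: np.ndarray) -> np.ndarray:
    c = np.asarray(c, dtype=float)
    raw = np.empty_like(c)
    raw[0] = c[0]
    raw[1:] = np.log(np.diff(c))
    return raw


#: number of rater-level covariate directions (3 condition indicators,
#: z_pp, z_rs) that are weakly identified against the population-level
#: intercepts and slopes and therefore join the dense mass block
N_RATER_SOFT = 5


def rater_rotation(prep: PreparedData) -> np.ndarray:
    """Orthogonal basis of rater space; the leading columns span the
    rater-level covariates (condition indicators, z_pp, z_rs).

    Rotating the iid-normal raw rater intercepts by an orthogonal matrix
    leaves the prior (and hence the model) unchanged, but concentrates the
    posterior correlations with the population-level parameters into the
    first :data:`N_RATER_SOFT` coordinates, where the sampler's dense mass
    block can absorb them.
    """
    A = np.column_stack(
        [(prep.rater_cond == c).astype(float) for c in range(3)]
        + [prep.z_pp, prep.z_rs])
    q, _ = np.linalg.qr(A, mode="complete")
    return q


def choice_layout(T: int, R: int, rotation: np.ndarray | None = None,
                  ) -> BlockLayout:
    return BlockLayout("choice", [
        ("alpha", 3), ("beta_attr", 3), ("beta_form", 3), ("beta_heal", 3),
        ("beta_pp", 1), ("beta_rs", 1), ("beta_side", 1),
        ("log_sigma_target", 1), ("log_sigma_rater", 1),
        ("u_raw", T), ("v_rot", R)],
        n_dense=17 + T + min(N_RATER_SOFT, R),
        rotations={} if rotation is None else {"v_rot": rotation})


def rating_layout(dim: str, T: int, R: int, n_cells: int,
                  rotation: np.ndarray | None = None) -> BlockLayout:
    return BlockLayout(dim, [
        ("cut_raw", N_CUTPOINTS), ("a_mas", 3), ("a_fem", 3),
        ("g_mas_pp", 1), ("g_mas_rs", 1), ("g_fem_pp", 1), ("g_fem_rs", 1),
        ("log_sigma_target", 1), ("log_sigma_rater", 1),
        ("log_sigma_cell", 1),
        ("w_raw", T), ("x_rot", R), ("z_raw", n_cells)],
        n_dense=19 + T + min(N_RATER_SOFT, R),
        rotations={} if rotation is None else {"x_rot": rotation})


def scales_layout(fix_resid_sd: float | None = None) -> BlockLayout:
    entries = [("mu", 6)]
    if fix_resid_sd is None:
        entries.append(("log_resid_sd", 2))
    layout = BlockLayout("scales", entries)
    layout.n_dense = layout.ndim
    return layout


def choice_logp_and_grad(prep: PreparedData, priors: Priors):
    """Return ``(layout, f)`` with ``f(theta) -> (logp, grad)``."""
    U = rater_rotation(prep)
    layout = choice_layout(prep.n_targets, prep.n_raters, rotation=U)
    sl = layout.slices()
    cond = prep.rater_cond[prep.choice_r]
    zpp = prep.z_pp[prep.choice_r]
    zrs = prep.z_rs[prep.choice_r]
    y, t, r = prep.choice_y, prep.choice_t, prep.choice_r
    da, df, dh = (prep.choice_diffs[:, i] for i in range(3))
    side = prep.choice_side
    T, R = prep.n_targets, prep.n_raters
    s_int2 = priors.intercept_scale ** 2
    s_slp2 = priors.slope_scale ** 2
    rate = priors.sd_rate

    def f(theta: np.ndarray) -> tuple[float, np.ndarray]:
        p = layout.unpack(theta)
        st = np.exp(p["log_sigma_target"][0])
        sr = np.exp(p["log_sigma_rater"][0])
        u_raw, v_rot = p["u_raw"], p["v_rot"]
        v_raw = U @ v_rot
        eta = (p["alpha"][cond] + p["beta_attr"][cond] * da
               + p["beta_form"][cond] * df + p["beta_heal"][cond] * dh
               + p["beta_pp"][0] * zpp + p["beta_rs"][0] * zrs
               + p["beta_side"][0] * side
               + st * u_raw[t] + sr * v_raw[r])
        logp = float(np.sum(y * eta - softplus(eta)))
        # priors (unconstrained scale, incl. Jacobian of log-sd transform)
        logp += float(-0.5 * np.sum(p["alpha"] ** 2) / s_int2)
        for key in ("beta_attr", "beta_form", "beta_heal",
                    "beta_pp", "beta_rs", "beta_side"):
            logp += float(-0.5 * np.sum(p[key] ** 2) / s_slp2)
        logp += float(-0.5 * np.sum(u_raw ** 2) - 0.5 * np.sum(v_rot ** 2))
        logp += (-rate * st + p["log_sigma_target"][0]
                 - rate * sr + p["log_sigma_rater"][0])

        e = y - sigmoid(eta)
        grad = np.zeros(layout.ndim)
        grad[sl["alpha"]] = np.bincount(cond, e, 3) - p["alpha"] / s_int2
        grad[sl["beta_attr"]] = (np.bincount(cond, e * da, 3)
                                 - p["beta_attr"] / s_slp2)
        grad[sl["beta_form"]] = (np.bincount(cond, e * df, 3)
                                 - p["beta_form"] / s_slp2)
        grad[sl["beta_heal"]] = (np.bincount(cond, e * dh, 3)
                                 - p["beta_heal"] / s_slp2)
        grad[sl["beta_pp"]] = e @ zpp - p["beta_pp"][0] / s_slp2
        grad[sl["beta_rs"]] = e @ zrs - p["beta_rs"][0] / s_slp2
        grad[sl["beta_side"]] = e @ side - p["beta_side"][0] / s_slp2
        grad[sl["u_raw"]] = st * np.bincount(t, e, T) - u_raw
        grad[sl["v_rot"]] = sr * (U.T @ np.bincount(r, e, R)) - v_rot
        grad[sl["log_sigma_target"]] = st * (e @ u_raw[t]) - rate * st + 1.0
        grad[sl["log_sigma_rater"]] = sr * (e @ v_raw[r]) - rate * sr + 1.0
        return logp, grad

    return layout, f


def _ordinal_obs_logp_grad(c: np.ndarray, phi: np.ndarray, score: np.ndarray,
                           ) -> tuple[float, np.ndarray, np.ndarray]:
    """Log-likelihood, d/dphi per record, and d/dc (summed) for one block."""
    k = score - 1                                   # 0..6
    lo = k - 1                                      # threshold below, -1 if none
    hi = k                                          # threshold above, 6 if none
    has_lo, has_hi = lo >= 0, hi <= 5
    aL = np.where(has_lo, phi - c[np.clip(lo, 0, 5)], np.inf)
    aU = np.where(has_hi, phi - c[np.clip(hi, 0, 5)], -np.inf)

    # logp = -softplus(aU) - softplus(-aL) + log1p(-exp(aU - aL))
    sp_aU = np.where(has_hi, softplus(np.where(has_hi, aU, 0.0)), 0.0)
    sp_mL = np.where(has_lo, softplus(np.where(has_lo, -aL, 0.0)), 0.0)
    both = has_lo & has_hi
    # gap = -(c_hi - c_lo) < 0; clamp so a collapsed pair of cut-points
    # yields a very low (finite) density instead of NaN warnings
    gap = np.where(both, np.minimum(aU - aL, -1e-12), -np.inf)
    log_gap = np.where(both, np.log(-np.expm1(np.where(both, gap, -1.0))),
                       0.0)
    logp = float(np.sum(-sp_aU - sp_mL + log_gap))

    sig_aU = np.where(has_hi, sigmoid(np.where(has_hi, aU, 0.0)), 0.0)
    sig_mL = np.where(has_lo, sigmoid(np.where(has_lo, -aL, 0.0)), 0.0)
    g_phi = sig_mL - sig_aU
    g_phi[~has_lo] = -sig_aU[~has_lo]               # score = 1
    g_phi[~has_hi] = sig_mL[~has_hi]                # score = 7

    # q = exp(gap) / (1 - exp(gap)) couples the two thresholds
    q = np.where(both,
                 np.exp(gap) / -np.expm1(np.where(both, gap, -1.0)), 0.0)
    g_c = (np.bincount(np.clip(lo, 0, 5), np.where(has_lo, -(sig_mL + q), 0.0),
                       minlength=6)
           + np.bincount(np.clip(hi, 0, 5), np.where(has_hi, sig_aU + q, 0.0),
                         minlength=6))
    return logp, g_phi, g_c


def rating_logp_and_grad(dim: str, prep: PreparedData, priors: Priors):
    """Return ``(layout, f)`` for one rating dimension."""
    blk = prep.rating_blocks[dim]
    U = rater_rotation(prep)
    layout = rating_layout(dim, prep.n_targets, prep.n_raters, blk.n_cells,
                           rotation=U)
    sl = layout.slices()
    T, R, C = prep.n_targets, prep.n_raters, blk.n_cells
    mas = blk.mas.astype(float)
    fem = 1.0 - mas
    zpp, zrs = prep.z_pp[blk.r], prep.z_rs[blk.r]
    s_int2 = priors.intercept_scale ** 2
    s_cut2 = priors.cutpoint_scale ** 2
    s_slp2 = priors.slope_scale ** 2
    rate = priors.sd_rate
    cond_mas = np.where(blk.mas, blk.cond, 3 + blk.cond)  # 6-level version x cond

    def f(theta: np.ndarray) -> tuple[float, np.ndarray]:
        p = layout.unpack(theta)
        c = cutpoints_from_raw(p["cut_raw"])
        sT = np.exp(p["log_sigma_target"][0])
        sR = np.exp(p["log_sigma_rater"][0])
        sC = np.exp(p["log_sigma_cell"][0])
        w_raw, x_rot, z_raw = p["w_raw"], p["x_rot"], p["z_raw"]
        x_raw = U @ x_rot
        a = np.concatenate([p["a_mas"], p["a_fem"]])[cond_mas]
        g_pp = mas * p["g_mas_pp"][0] + fem * p["g_fem_pp"][0]
        g_rs = mas * p["g_mas_rs"][0] + fem * p["g_fem_rs"][0]
        phi = (a + g_pp * zpp + g_rs * zrs
               + sT * w_raw[blk.t] + sR * x_raw[blk.r] + sC * z_raw[blk.cell])

        logp, g_phi, g_c = _ordinal_obs_logp_grad(c, phi, blk.score)

        # priors
        logp += float(-0.5 * np.sum(c ** 2) / s_cut2
                      + np.sum(p["cut_raw"][1:]))          # Jacobian
        logp += float(-0.5 * (np.sum(p["a_mas"] ** 2)
                              + np.sum(p["a_fem"] ** 2)) / s_int2)
        for key in ("g_mas_pp", "g_mas_rs", "g_fem_pp", "g_fem_rs"):
            logp += float(-0.5 * p[key][0] ** 2 / s_slp2)
        logp += float(-0.5 * (np.sum(w_raw ** 2) + np.sum(x_rot ** 2)
                              + np.sum(z_raw ** 2)))
        logp += (-rate * sT + p["log_sigma_target"][0]
                 - rate * sR + p["log_sigma_rater"][0]
                 - rate * sC + p["log_sigma_cell"][0])

        grad = np.zeros(layout.ndim)
        g_c_total = g_c - c / s_cut2
        # chain rule through the ordered transform
        rev = np.cumsum(g_c_total[::-1])[::-1]
        g_raw = np.empty(N_CUTPOINTS)
        g_raw[0] = rev[0]
        g_raw[1:] = np.exp(p["cut_raw"][1:]) * rev[1:] + 1.0
        grad[sl["cut_raw"]] = g_raw

        g_a = np.bincount(cond_mas, g_phi, 6)
        grad[sl["a_mas"]] = g_a[:3] - p["a_mas"] / s_int2
        grad[sl["a_fem"]] = g_a[3:] - p["a_fem"] / s_int2
        grad[sl["g_mas_pp"]] = (g_phi * mas) @ zpp - p["g_mas_pp"][0] / s_slp2
        grad[sl["g_mas_rs"]] = (g_phi * mas) @ zrs - p["g_mas_rs"][0] / s_slp2
        grad[sl["g_fem_pp"]] = (g_phi * fem) @ zpp - p["g_fem_pp"][0] / s_slp2
        grad[sl["g_fem_rs"]] = (g_phi * fem) @ zrs - p["g_fem_rs"][0] / s_slp2
        grad[sl["w_raw"]] = sT * np.bincount(blk.t, g_phi, T) - w_raw
        grad[sl["x_rot"]] = (sR * (U.T @ np.bincount(blk.r, g_phi, R))
                             - x_rot)
        grad[sl["z_raw"]] = sC * np.bincount(blk.cell, g_phi, C) - z_raw
        grad[sl["log_sigma_target"]] = (sT * (g_phi @ w_raw[blk.t])
                                        - rate * sT + 1.0)
        grad[sl["log_sigma_rater"]] = (sR * (g_phi @ x_raw[blk.r])
                                       - rate * sR + 1.0)
        grad[sl["log_sigma_cell"]] = (sC * (g_phi @ z_raw[blk.cell])
                                      - rate * sC + 1.0)
        return logp, grad

    return layout, f


def scales_logp_and_grad(prep: PreparedData, priors: Priors,
                         fix_resid_sd: float | None = None):
    """Return ``(layout, f)`` for the mediation (scales) block.

    ``fix_resid_sd`` freezes both residual SDs at a known value, reducing
    the block to a conjugate normal–normal model (used as an analytic
    cross-check of the sampler).
    """
    layout = scales_layout(fix_resid_sd)
    sl = layout.slices()
    cond = prep.rater_cond
    z = np.stack([prep.z_pp, prep.z_rs])            # (2, R)
    n_c = np.bincount(cond, minlength=3).astype(float)
    s_int2 = priors.intercept_scale ** 2
    rate = priors.sd_rate
    R = prep.n_raters

    def f(theta: np.ndarray) -> tuple[float, np.ndarray]:
        p = layout.unpack(theta)
        mu = p["mu"].reshape(2, 3)
        if fix_resid_sd is None:
            sd = np.exp(p["log_resid_sd"])
        else:
            sd = np.array([fix_resid_sd, fix_resid_sd])
        resid = z - mu[:, cond]                     # (2, R)
        logp = float(np.sum(-0.5 * (resid / sd[:, None]) ** 2)
                     - R * np.sum(np.log(sd)) - R * _LOG_2PI
                     - 0.5 * np.sum(mu ** 2) / s_int2)
        grad = np.zeros(layout.ndim)
        g_mu = np.stack([np.bincount(cond, resid[0], 3),
                         np.bincount(cond, resid[1], 3)]) / sd[:, None] ** 2
        grad[sl["mu"]] = (g_mu - mu / s_int2).ravel()
        if fix_resid_sd is None:
            logp += float(np.sum(-rate * sd + p["log_resid_sd"]))
            g_sd = (np.sum(resid ** 2, axis=1) / sd ** 2 - R) - rate * sd + 1.0
            grad[sl["log_resid_sd"]] = g_sd
        return logp, grad

    return layout, f
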