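"""Posterior sampling, summaries, contrasts and derived quantities.

The joint posterior factorises exactly over the model's blocks — the
choice submodel, the three rating submodels and the mediation (scales)
submodel share observed covariates but no parameters — so :func:`fit`
samples each block independently and concatenates the draws; the result is
identical to sampling the joint density at a fraction of the cost.

The sampler is Hamiltonian Monte Carlo on the unconstrained
parameterisation of :mod:`harshpref.model` (analytic gradients): dual
averaging of the step size toward a target acceptance rate, diagonal mass
matrix estimated during warm-up, and a jittered number of leapfrog steps
per iteration to avoid resonance.  Convergence is checked with split-R̂ and
bulk effective sample size (via ``arviz``) on every retained parameter.

All derived quantities — 89% compatibility intervals, posterior contrasts,
expected rating differences — are computed from the draws after sampling,
never inside the sampler.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Sequence

import arviz as az
import numpy as np
import pandas as pd

from .datamodel import CONDITIONS, CONDITION_SHORT, DIMENSIONS, StudyDataset
from .model import (BlockLayout, PreparedData, Priors, choice_logp_and_grad,
                    cutpoints_from_raw, ordinal_mean, prepare,
                    rating_logp_and_grad, scales_logp_and_grad)

COND_SHORT = [CONDITION_SHORT[c] for c in CONDITIONS]     # control, PP, RS
DEFAULT_INTERVAL = 0.89

BLOCK_NAMES = ("choice",) + DIMENSIONS + ("scales",)


class ConvergenceError(RuntimeError):
    """Sampling did not converge; carries the per-parameter diagnostics."""

    def __init__(self, message: str, diagnostics: pd.DataFrame):
        super().__init__(message)
        self.diagnostics = diagnostics


@dataclasses.dataclass
class SamplerConfig:
    """Knobs of the HMC backend.

    ``n_draws`` is the total number of retained posterior samples across
    chains (default 10,000, the reporting convention of the analysis).
    """

    n_draws: int = 10_000
    n_warmup: int = 1000
    n_chains: int = 2
    max_leapfrog: int = 32
    target_accept: float = 0.8
    rhat_threshold: float = 1.05

    def __post_init__(self) -> None:
        if self.n_draws < self.n_chains:
            raise ValueError("need at least one draw per chain")
        if not 0 < self.target_accept < 1:
            raise ValueError("target_accept must be in (0, 1)")


# ---------------------------------------------------------------------------
# Hamiltonian Monte Carlo
# ---------------------------------------------------------------------------


class _Metric:
    """Kinetic-energy metric: diagonal overall, optionally dense on a
    leading block of coordinates (the top-level parameters), so that the
    prior-identified ridge directions of the rating blocks are
    preconditioned away while the varying intercepts stay cheap."""

    def __init__(self, ndim: int, n_dense: int = 0):
        self.diag = np.ones(ndim)            # posterior variance estimate
        self.n_dense = 0
        self.cov = None
        self.chol = None
        self._set_dense_target(n_dense)

    def _set_dense_target(self, n_dense: int) -> None:
        self._dense_target = n_dense

    def update(self, window: np.ndarray) -> None:
        var = np.var(window, axis=0)
        self.diag = np.clip(var, 1e-8, None)
        k = self._dense_target
        if k and len(window) > k + 5:
            cov = np.cov(window[:, :k], rowvar=False)
            cov = np.atleast_2d(cov)
            # regularise toward its diagonal for stability
            cov = 0.95 * cov + 0.05 * np.diag(np.diag(cov))
            cov += 1e-8 * np.eye(k)
            try:
                self.chol = np.linalg.cholesky(cov)
                self.cov = cov
                self.n_dense = k
            except np.linalg.LinAlgError:
                self.cov = self.chol = None
                self.n_dense = 0

    def sample_momentum(self, rng: np.random.Generator) -> np.ndarray:
        xi = rng.standard_normal(len(self.diag))
        p = xi / np.sqrt(self.diag)
        if self.n_dense:
            # p_dense ~ N(0, cov^{-1}):  p = L^{-T} xi  with cov = L L^T
            k = self.n_dense
            p[:k] = np.linalg.solve(self.chol.T, xi[:k])
        return p

    def velocity(self, p: np.ndarray) -> np.ndarray:
        v = self.diag * p
        if self.n_dense:
            k = self.n_dense
            v[:k] = self.cov @ p[:k]
        return v

    def kinetic(self, p: np.ndarray) -> float:
        if self.n_dense:
            k = self.n_dense
            return float(0.5 * (p[:k] @ (self.cov @ p[:k])
                                + np.sum(p[k:] ** 2 * self.diag[k:])))
        return float(0.5 * np.sum(p * p * self.diag))


def _find_reasonable_epsilon(f: Callable, theta: np.ndarray,
                             metric: "_Metric",
                             rng: np.random.Generator) -> float:
    """Double/halve the step size until one leapfrog step is ~50% acceptable."""
    eps = 0.1 / max(1.0, len(theta)) ** 0.25
    logp0, grad0 = f(theta)
    p = metric.sample_momentum(rng)
    h0 = logp0 - metric.kinetic(p)

    def one_step(eps: float) -> float:
        p1 = p + 0.5 * eps * grad0
        th1 = theta + eps * metric.velocity(p1)
        logp1, grad1 = f(th1)
        p1 = p1 + 0.5 * eps * grad1
        return logp1 - metric.kinetic(p1) - h0

    dh = one_step(eps)
    if not np.isfinite(dh):
        dh = -np.inf
    direction = 1.0 if dh > np.log(0.5) else -1.0
    for _ in range(50):
        eps *= 2.0 ** direction
        dh = one_step(eps)
        if not np.isfinite(dh):
            dh = -np.inf
        if (dh > np.log(0.5)) != (direction > 0):
            break
    return eps


def hmc_chain(f: Callable, init: np.ndarray, n_warmup: int, n_draws: int,
              rng: np.random.Generator, max_leapfrog: int = 32,
              target_accept: float = 0.8, n_dense: int = 0,
              ) -> tuple[np.ndarray, dict]:
    """Run one HMC chain; returns retained draws and sampler statistics.

    ``n_dense`` marks how many leading coordinates get a dense mass-matrix
    block (estimated during warm-up); the rest use a diagonal metric.
    """
    ndim = len(init)
    theta = init.astype(float).copy()
    logp, grad = f(theta)
    if not np.isfinite(logp):
        raise ValueError("initial point has non-finite log density")
    metric = _Metric(ndim, n_dense=min(n_dense, ndim))

    # dual-averaging state (re-initialised when the mass matrix updates)
    def fresh_da(eps: float) -> dict:
        return dict(mu=np.log(10.0 * eps), log_eps=np.log(eps),
                    log_eps_bar=0.0, h_bar=0.0, count=0)

    eps = _find_reasonable_epsilon(f, theta, metric, rng)
    da = fresh_da(eps)
    gamma, t0, kappa = 0.05, 10.0, 0.75

    # two mass-adaptation windows within warm-up
    boundaries = [int(n_warmup * 0.15), int(n_warmup * 0.45),
                  int(n_warmup * 0.85)]
    window: list[np.ndarray] = []

    draws = np.empty((n_draws, ndim))
    accum: list[float] = []

    total = n_warmup + n_draws
    errstate = np.errstate(over="ignore", invalid="ignore",
                           divide="ignore", under="ignore")
    errstate.__enter__()
    for it in range(total):
        warming = it < n_warmup
        p0 = metric.sample_momentum(rng)
        h0 = logp - metric.kinetic(p0)
        # jitter the path length over the upper half of the budget:
        # breaks resonance without wasting gradient calls on tiny paths
        L = int(rng.integers(max(1, max_leapfrog // 2), max_leapfrog + 1))
        th, p, g = theta.copy(), p0.copy(), grad
        lp = logp
        diverged = False
        p = p + 0.5 * eps * g
        for step in range(L):
            th = th + eps * metric.velocity(p)
            lp, g = f(th)
            if not np.isfinite(lp):
                diverged = True
                break
            p = p + (eps if step < L - 1 else 0.5 * eps) * g
        if diverged:
            alpha = 0.0
        else:
            h1 = lp - metric.kinetic(p)
            alpha = float(min(1.0, np.exp(min(0.0, h1 - h0))))
            if np.log(rng.random()) < h1 - h0:
                theta, logp, grad = th, lp, g
        if warming:
            da["count"] += 1
            m = da["count"]
            da["h_bar"] = ((1 - 1 / (m + t0)) * da["h_bar"]
                           + (target_accept - alpha) / (m + t0))
            da["log_eps"] = da["mu"] - np.sqrt(m) / gamma * da["h_bar"]
            w = m ** (-kappa)
            da["log_eps_bar"] = (w * da["log_eps"]
                                 + (1 - w) * da["log_eps_bar"])
            eps = float(np.exp(da["log_eps"]))
            if it >= boundaries[0]:
                window.append(theta.copy())
            if it + 1 in boundaries[1:] and len(window) >= 10:
                metric.update(np.asarray(window))
                window.clear()
                eps = _find_reasonable_epsilon(f, theta, metric, rng)
                da = fresh_da(eps)
            if it == n_warmup - 1:
                eps = float(np.exp(da["log_eps_bar"]))
        else:
            draws[it - n_warmup] = theta
            accum.append(alpha)
    errstate.__exit__(None, None, None)

    stats = dict(step_size=eps, accept_rate=float(np.mean(accum))
                 if accum else float("nan"))
    return draws, stats


# ---------------------------------------------------------------------------
# Posterior container
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class PosteriorSamples:
    """Named posterior draws on the constrained (interpretable) scale.

    ``columns`` maps a parameter name (e.g. ``"choice.alpha"``) to an array
    of shape ``(n_samples,)`` or ``(n_samples, k)``; ``labels`` carries the
    component labels of vector parameters, so ``get("choice.alpha[PP]")``
    resolves a single component.
    """

    columns: dict[str, np.ndarray]
    labels: dict[str, list[str]]
    n_chains: int
    diagnostics: pd.DataFrame
    metadata: dict = dataclasses.field(default_factory=dict)
    top_level: list[str] = dataclasses.field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.columns.values())))

    def names(self, top_level_only: bool = False) -> list[str]:
        """Flat component names (vector parameters expanded)."""
        out = []
        for name, arr in self.columns.items():
            if top_level_only and name not in self.top_level:
                continue
            if arr.ndim == 1:
                out.append(name)
            else:
                out.extend(f"{name}[{lab}]" for lab in self.labels[name])
        return out

    def get(self, name: str) -> np.ndarray:
        """Draws for a parameter or a single ``name[label]`` component."""
        if name in self.columns:
            return self.columns[name]
        if name.endswith("]") and "[" in name:
            base, lab = name[:-1].split("[", 1)
            if base in self.columns:
                try:
                    idx = self.labels[base].index(lab)
                except ValueError:
                    raise KeyError(f"unknown component {name!r}") from None
                return self.columns[base][:, idx]
        raise KeyError(f"unknown parameter {name!r}")

    def per_chain(self, name: str) -> np.ndarray:
        """Draws reshaped to (chain, draw, ...) for diagnostics."""
        arr = self.get(name)
        return arr.reshape(self.n_chains, -1, *arr.shape[1:])


def summarise_draws(draws: np.ndarray, name: str = "quantity",
                    prob: float = DEFAULT_INTERVAL) -> pd.Series:
    """Posterior mean and central ``prob`` compatibility interval."""
    draws = np.asarray(draws, dtype=float)
    if draws.size == 0:
        raise ValueError("empty draw set")
    lo, hi = np.percentile(draws, [50 * (1 - prob), 50 * (1 + prob)])
    return pd.Series({"name": name, "mean": float(draws.mean()),
                      "lower": float(lo), "upper": float(hi)})


def summarise(samples: PosteriorSamples, prob: float = DEFAULT_INTERVAL,
              names: Sequence[str] | None = None,
              top_level_only: bool = True) -> pd.DataFrame:
    """Summary table: mean and central compatibility interval per parameter."""
    if names is None:
        names = samples.names(top_level_only=top_level_only)
    rows = [summarise_draws(samples.get(n), n, prob) for n in names]
    table = pd.DataFrame(rows).reset_index(drop=True)
    diag = samples.diagnostics.set_index("name")
    table["rhat"] = [diag["rhat"].get(n, np.nan) for n in table["name"]]
    table["ess_bulk"] = [diag["ess_bulk"].get(n, np.nan)
                         for n in table["name"]]
    return table


def contrast(samples: PosteriorSamples, quantity_a: str,
             quantity_b: str) -> np.ndarray:
    """Per-draw posterior of ``a − b``."""
    return samples.get(quantity_a) - samples.get(quantity_b)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


def _initial_point(block: str, layout: BlockLayout, prep: PreparedData,
                   rng: np.random.Generator) -> np.ndarray:
    """Jittered start; rating blocks start their cut-points at the
    empirical marginal logit quantiles of the observed scores."""
    init = 0.1 * rng.standard_normal(layout.ndim)
    if block in DIMENSIONS:
        from .model import raw_from_cutpoints
        score = prep.rating_blocks[block].score
        cum = np.cumsum(np.bincount(score, minlength=8)[1:7]) / len(score)
        cum = np.clip(cum, 1e-3, 1 - 1e-3)
        cuts = np.log(cum / (1 - cum))
        cuts = np.maximum.accumulate(cuts + 1e-3 * np.arange(6))
        cuts += np.arange(6) * 1e-3     # ensure strictly increasing
        sl = layout.slices()
        init[sl["cut_raw"]] = raw_from_cutpoints(cuts)
    return init


def _block_builder(block: str, prep: PreparedData, priors: Priors,
                   fix_resid_sd: float | None):
    if block == "choice":
        return choice_logp_and_grad(prep, priors)
    if block in DIMENSIONS:
        return rating_logp_and_grad(block, prep, priors)
    if block == "scales":
        return scales_logp_and_grad(prep, priors, fix_resid_sd)
    raise ValueError(f"unknown block {block!r}")


def _constrain_block(block: str, layout: BlockLayout, draws: np.ndarray,
                     prep: PreparedData, fix_resid_sd: float | None,
                     ) -> tuple[dict[str, np.ndarray], dict[str, list[str]],
                                list[str]]:
    """Map unconstrained draws to named constrained columns."""
    sl = layout.slices()
    cols: dict[str, np.ndarray] = {}
    labels: dict[str, list[str]] = {}
    top: list[str] = []
    t_labs = [str(t) for t in prep.target_ids]
    r_labs = [str(r) for r in prep.rater_ids]

    def add(name: str, arr: np.ndarray, labs: list[str] | None = None,
            top_level: bool = True) -> None:
        cols[name] = arr
        if labs is not None:
            labels[name] = labs
        if top_level:
            top.append(name)

    if block == "choice":
        add("choice.alpha", draws[:, sl["alpha"]], COND_SHORT)
        add("choice.beta_attr", draws[:, sl["beta_attr"]], COND_SHORT)
        add("choice.beta_form", draws[:, sl["beta_form"]], COND_SHORT)
        add("choice.beta_heal", draws[:, sl["beta_heal"]], COND_SHORT)
        add("choice.beta_pp", draws[:, sl["beta_pp"]].ravel())
        add("choice.beta_rs", draws[:, sl["beta_rs"]].ravel())
        add("choice.beta_side", draws[:, sl["beta_side"]].ravel())
        st = np.exp(draws[:, sl["log_sigma_target"]].ravel())
        sr = np.exp(draws[:, sl["log_sigma_rater"]].ravel())
        add("choice.sigma_target", st)
        add("choice.sigma_rater", sr)
        add("choice.u_target", st[:, None] * draws[:, sl["u_raw"]],
            t_labs, top_level=False)
        v_raw = draws[:, sl["v_rot"]] @ layout.rotations["v_rot"].T
        add("choice.v_rater", sr[:, None] * v_raw, r_labs, top_level=False)
    elif block in DIMENSIONS:
        blk = prep.rating_blocks[block]
        cuts = np.apply_along_axis(cutpoints_from_raw, 1,
                                   draws[:, sl["cut_raw"]])
        add(f"{block}.cut", cuts, [str(i + 1) for i in range(6)])
        add(f"{block}.a_mas", draws[:, sl["a_mas"]], COND_SHORT)
        add(f"{block}.a_fem", draws[:, sl["a_fem"]], COND_SHORT)
        for key in ("g_mas_pp", "g_mas_rs", "g_fem_pp", "g_fem_rs"):
            add(f"{block}.{key}", draws[:, sl[key]].ravel())
        sT = np.exp(draws[:, sl["log_sigma_target"]].ravel())
        sR = np.exp(draws[:, sl["log_sigma_rater"]].ravel())
        sC = np.exp(draws[:, sl["log_sigma_cell"]].ravel())
        add(f"{block}.sigma_target", sT)
        add(f"{block}.sigma_rater", sR)
        add(f"{block}.sigma_cell", sC)
        add(f"{block}.w_target", sT[:, None] * draws[:, sl["w_raw"]],
            t_labs, top_level=False)
        x_raw = draws[:, sl["x_rot"]] @ layout.rotations["x_rot"].T
        add(f"{block}.x_rater", sR[:, None] * x_raw, r_labs,
            top_level=False)
        cell_labs = [f"{prep.target_ids[t]}:{prep.rater_ids[r]}"
                     for t, r in zip(blk.cell_t, blk.cell_r)]
        add(f"{block}.z_cell", sC[:, None] * draws[:, sl["z_raw"]],
            cell_labs, top_level=False)
    elif block == "scales":
        mu = draws[:, sl["mu"]]
        labs = [f"{s},{c}" for s in ("pp", "rs") for c in COND_SHORT]
        add("scales.mu", mu, labs)
        if fix_resid_sd is None:
            add("scales.resid_sd", np.exp(draws[:, sl["log_resid_sd"]]),
                ["pp", "rs"])
    return cols, labels, top


def fit(data: StudyDataset | PreparedData,
        priors: Priors | None = None,
        sampler_config: SamplerConfig | None = None,
        seed: int = 0,
        blocks: Sequence[str] | None = None,
        fix_resid_sd: float | None = None,
        check_convergence: bool = True) -> PosteriorSamples:
    """Sample the joint posterior (block by block) and attach diagnostics.

    Parameters
    ----------
    data
        A preprocessed dataset (or its prepared index arrays).
    blocks
        Subset of ``("choice", "attractiveness", "healthiness",
        "formidability", "scales")``; defaults to all.  Because the joint
        posterior factorises over blocks, fitting a subset yields the exact
        marginal posterior of that subset's parameters.
    fix_resid_sd
        Freeze the mediation submodel's residual SDs (conjugate reduction).
    check_convergence
        Raise :class:`ConvergenceError` when any split-R̂ exceeds the
        configured threshold.
    """
    prep = data if isinstance(data, PreparedData) else prepare(data)
    priors = priors or Priors()
    cfg = sampler_config or SamplerConfig()
    blocks = list(blocks) if blocks is not None else list(BLOCK_NAMES)
    n_per_chain = cfg.n_draws // cfg.n_chains

    columns: dict[str, np.ndarray] = {}
    labels: dict[str, list[str]] = {}
    top_level: list[str] = []
    diag_frames = []
    stats: dict[str, list[dict]] = {}

    for b_idx, block in enumerate(blocks):
        layout, f = _block_builder(block, prep, priors, fix_resid_sd)
        chain_draws, chain_stats = [], []
        for chain in range(cfg.n_chains):
            ss = np.random.SeedSequence([int(seed), b_idx, chain])
            rng = np.random.default_rng(ss)
            init = _initial_point(block, layout, prep, rng)
            d, st = hmc_chain(f, init, cfg.n_warmup, n_per_chain, rng,
                              cfg.max_leapfrog, cfg.target_accept,
                              n_dense=layout.n_dense)
            chain_draws.append(d)
            chain_stats.append(st)
        draws = np.concatenate(chain_draws, axis=0)
        stats[block] = chain_stats
        cols, labs, top = _constrain_block(block, layout, draws, prep,
                                           fix_resid_sd)
        columns.update(cols)
        labels.update(labs)
        top_level.extend(top)

        diag_rows = []
        for name, arr in cols.items():
            chains = arr.reshape(cfg.n_chains, -1, *arr.shape[1:])
            ds = az.convert_to_dataset(
                chains if chains.ndim == 3 else chains[..., None])
            rhat = np.atleast_1d(az.rhat(ds)["x"].to_numpy())
            ess = np.atleast_1d(az.ess(ds)["x"].to_numpy())
            if arr.ndim == 1:
                diag_rows.append((name, float(rhat[0]), float(ess[0])))
            else:
                for j, lab in enumerate(labels[name]):
                    diag_rows.append((f"{name}[{lab}]", float(rhat[j]),
                                      float(ess[j])))
        diag_frames.append(pd.DataFrame(
            diag_rows, columns=["name", "rhat", "ess_bulk"]))

    diagnostics = pd.concat(diag_frames, ignore_index=True)
    samples = PosteriorSamples(
        columns=columns, labels=labels, n_chains=cfg.n_chains,
        diagnostics=diagnostics,
        metadata=dict(seed=seed, sampler=dataclasses.asdict(cfg),
                      blocks=blocks, stats=stats,
                      n_choice_dropped=prep.n_choice_dropped),
        top_level=top_level)

    if check_convergence:
        bad = diagnostics[diagnostics["rhat"] > cfg.rhat_threshold]
        if len(bad):
            worst = bad.sort_values("rhat", ascending=False).head(10)
            raise ConvergenceError(
                f"{len(bad)} parameter(s) with split-R̂ > "
                f"{cfg.rhat_threshold}:\n{worst.to_string(index=False)}",
                diagnostics)
    return samples


# ---------------------------------------------------------------------------
# Derived quantities
# ---------------------------------------------------------------------------


def rating_difference_posterior(samples: PosteriorSamples,
                                data: StudyDataset | PreparedData,
                                dimension: str,
                                chunk: int = 200,
                                ) -> dict[str, np.ndarray]:
    """Posterior of the expected masc − fem rating difference per condition.

    For every draw and every observed rater–target pair, the expected
    Likert score is evaluated under the pair's own varying intercepts for
    the masculinised and the feminised latent locations; the differences
    are averaged over pairs within each priming condition.
    """
    if f"{dimension}.cut" not in samples.columns:
        raise KeyError(f"dimension {dimension!r} was not fitted")
    prep = data if isinstance(data, PreparedData) else prepare(data)
    blk = prep.rating_blocks[dimension]
    # one entry per observed target x rater cell
    ct, cr = blk.cell_t, blk.cell_r
    cond = prep.rater_cond[cr]
    zpp, zrs = prep.z_pp[cr], prep.z_rs[cr]

    cuts = samples.get(f"{dimension}.cut")
    a_mas = samples.get(f"{dimension}.a_mas")
    a_fem = samples.get(f"{dimension}.a_fem")
    g = {k: samples.get(f"{dimension}.{k}")
         for k in ("g_mas_pp", "g_mas_rs", "g_fem_pp", "g_fem_rs")}
    w = samples.get(f"{dimension}.w_target")
    x = samples.get(f"{dimension}.x_rater")
    z = samples.get(f"{dimension}.z_cell")

    n = samples.n_samples
    out = {c: np.empty(n) for c in COND_SHORT}
    cond_masks = [cond == i for i in range(3)]
    for start in range(0, n, chunk):
        end = min(start + chunk, n)
        s = slice(start, end)
        base = (w[s][:, ct] + x[s][:, cr] + z[s])          # (chunk, P)
        phi_mas = (a_mas[s][:, cond] + g["g_mas_pp"][s, None] * zpp
                   + g["g_mas_rs"][s, None] * zrs + base)
        phi_fem = (a_fem[s][:, cond] + g["g_fem_pp"][s, None] * zpp
                   + g["g_fem_rs"][s, None] * zrs + base)
        for d in range(end - start):
            c6 = cuts[start + d]
            diff = (ordinal_mean(c6, phi_mas[d])
                    - ordinal_mean(c6, phi_fem[d]))
            for i, lab in enumerate(COND_SHORT):
                out[lab][start + d] = diff[cond_masks[i]].mean()
    return out
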