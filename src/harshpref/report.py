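"""Counterfactual predictions, headline estimates and raw descriptives.

Posterior log-odds are translated into choice probabilities over covariate
grids with varying intercepts set to zero (a population-typical rater and
target); rating differences and the ±0.5 side contrast are fixed at zero
unless the grid overrides them, isolating the priming-condition and
perceived-score effects.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .datamodel import (CONDITION_SHORT, CONDITIONS, DIMENSIONS, StudyDataset,
                        VERSIONS)
from .inference import (COND_SHORT, DEFAULT_INTERVAL, PosteriorSamples,
                        contrast, rating_difference_posterior,
                        summarise_draws)
from .model import PreparedData, prepare, sigmoid

__all__ = ["CovariateGrid", "predict_choice_prob", "headline_estimates",
           "raw_descriptives"]


@dataclasses.dataclass
class CovariateGrid:
    """Covariate settings for counterfactual choice-probability curves."""

    condition: str = "control"            # short or long condition label
    z_pp: Sequence[float] = (0.0,)
    z_rs: Sequence[float] = (0.0,)
    side_contrast: float = 0.0
    rating_diffs: Sequence[float] = (0.0, 0.0, 0.0)   # attr, form, heal

    def condition_label(self) -> str:
        if self.condition in COND_SHORT:
            return self.condition
        if self.condition in CONDITIONS:
            return CONDITION_SHORT[self.condition]
        raise KeyError(f"unknown condition {self.condition!r}")


def predict_choice_prob(samples: PosteriorSamples, grid: CovariateGrid,
                        prob: float = DEFAULT_INTERVAL) -> pd.DataFrame:
    """Posterior masculinised-choice probability at every grid point.

    Per draw, the inverse logit of the choice linear predictor with varying
    intercepts set to zero; summarised with the posterior mean and the
    central compatibility interval.
    """
    lab = grid.condition_label()
    alpha = samples.get(f"choice.alpha[{lab}]")
    slopes = np.stack([samples.get(f"choice.beta_attr[{lab}]"),
                       samples.get(f"choice.beta_form[{lab}]"),
                       samples.get(f"choice.beta_heal[{lab}]")])
    diffs = np.asarray(grid.rating_diffs, dtype=float)
    base = (alpha + diffs @ slopes
            + samples.get("choice.beta_side") * grid.side_contrast)
    rows = []
    for zpp in grid.z_pp:
        for zrs in grid.z_rs:
            eta = (base + samples.get("choice.beta_pp") * zpp
                   + samples.get("choice.beta_rs") * zrs)
            p = sigmoid(eta)
            s = summarise_draws(p, name=f"p(masc|{lab},z_pp={zpp},"
                                        f"z_rs={zrs})", prob=prob)
            rows.append({"condition": lab, "z_pp": zpp, "z_rs": zrs,
                         "mean": s["mean"], "lower": s["lower"],
                         "upper": s["upper"]})
    return pd.DataFrame(rows)


def headline_estimates(samples: PosteriorSamples,
                       data: StudyDataset | PreparedData,
                       prob: float = DEFAULT_INTERVAL) -> pd.DataFrame:
    """The analysis' headline quantities with compatibility intervals.

    Rows: the three pairwise condition-intercept contrasts of the choice
    model; the perceived-score slopes; the side contrast translated to
    left/right selection probabilities; the per-condition rating-difference
    slopes; per-condition expected masc − fem rating differences for every
    dimension; and all hyper-SDs.
    """
    prep = data if isinstance(data, PreparedData) else prepare(data)
    rows: list[pd.Series] = []

    def add(draws: np.ndarray, name: str) -> None:
        rows.append(summarise_draws(draws, name, prob))

    for a, b in (("control", "PP"), ("control", "RS"), ("RS", "PP")):
        add(contrast(samples, f"choice.alpha[{a}]", f"choice.alpha[{b}]"),
            f"choice.contrast[{a}-{b}]")
    add(samples.get("choice.beta_pp"), "choice.beta_pp")
    add(samples.get("choice.beta_rs"), "choice.beta_rs")
    beta_side = samples.get("choice.beta_side")
    add(sigmoid(0.5 * beta_side), "choice.p_select[right]")
    add(sigmoid(-0.5 * beta_side), "choice.p_select[left]")
    for name in ("beta_attr", "beta_form", "beta_heal"):
        for lab in COND_SHORT:
            add(samples.get(f"choice.{name}[{lab}]"),
                f"choice.{name}[{lab}]")
    add(samples.get("choice.sigma_target"), "choice.sigma_target")
    add(samples.get("choice.sigma_rater"), "choice.sigma_rater")
    for dim in DIMENSIONS:
        if f"{dim}.cut" not in samples.columns:
            continue
        diffs = rating_difference_posterior(samples, prep, dim)
        for lab in COND_SHORT:
            add(diffs[lab], f"{dim}.rating_diff[{lab}]")
        for comp in ("sigma_target", "sigma_rater", "sigma_cell"):
            add(samples.get(f"{dim}.{comp}"), f"{dim}.{comp}")
    if "scales.mu" in samples.columns:
        for lab in samples.labels["scales.mu"]:
            add(samples.get(f"scales.mu[{lab}]"), f"scales.mu[{lab}]")
    return pd.DataFrame(rows).reset_index(drop=True)


def raw_descriptives(data: StudyDataset) -> pd.DataFrame:
    """Observed masculinised-choice proportions, mean ratings and tallies."""
    if len(data.choices) == 0:
        raise ValueError("no choice records")
    rows = []
    merged = data.choices.merge(data.raters[["rater_id", "condition"]],
                                on="rater_id")
    rows.append(("choice.prop_masculinised[all]",
                 merged["chose_masculinised"].mean(), len(merged)))
    for cond in CONDITIONS:
        sub = merged[merged["condition"] == cond]
        rows.append((f"choice.prop_masculinised[{CONDITION_SHORT[cond]}]",
                     sub["chose_masculinised"].mean(), len(sub)))
    for dim in DIMENSIONS:
        for version in VERSIONS:
            sub = data.ratings[(data.ratings["dimension"] == dim)
                               & (data.ratings["version"] == version)]
            if len(sub):
                rows.append((f"{dim}.mean_rating[{version}]",
                             sub["score"].mean(), len(sub)))
    rows.append(("n_raters", float(data.n_raters), data.n_raters))
    rows.append(("n_choice_records", float(len(data.choices)),
                 len(data.choices)))
    return pd.DataFrame(rows, columns=["name", "value", "n"])
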