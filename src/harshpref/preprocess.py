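"""Exclusion cascade, scale scoring, standardisation and contrast coding.

The participant filter runs in a fixed order:

1. a manual drop list (participants removed for idiosyncratic reasons),
2. non-heterosexual raters,
3. raters who answered **both** attention-check questions wrong
   (``attention_correct == 0``; one correct answer retains),
4. raters who recognised more than four target faces (all their data),
5. individual choice and rating records whose target face was recognised.

Steps 2, 3 and 5 can be switched off individually via
:class:`ExclusionVariant` to reproduce the alternative inclusion criteria.
Perceived-scale scoring (item means + Cronbach's alpha), standardisation of
the scale scores on the retained sample, and the ±0.5 side-contrast coding
live here too, so that a raw dataset goes in and a model-ready dataset
comes out of :func:`preprocess`.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .datamodel import CONDITIONS, StudyDataset

#: Raters recognising more than this many targets are removed entirely.
MAX_RECOGNISED_FACES = 4


class PreprocessError(ValueError):
    pass


@dataclasses.dataclass
class ExclusionVariant:
    """Switchable inclusion criteria; all-False is the primary analysis."""

    keep_recognised_points: bool = False
    keep_attention_failures: bool = False
    keep_nonheterosexual: bool = False

    #: named variants matching the alternative-criteria analyses
    @classmethod
    def named(cls, name: str) -> "ExclusionVariant":
        variants = {
            "main": cls(),
            "keep_recognised": cls(keep_recognised_points=True),
            "keep_attention": cls(keep_attention_failures=True),
            "keep_nonheterosexual": cls(keep_nonheterosexual=True),
        }
        try:
            return variants[name]
        except KeyError:
            raise ValueError(f"unknown exclusion variant {name!r}; "
                             f"one of {sorted(variants)}") from None


@dataclasses.dataclass
class ExclusionReport:
    """Tally of every stage of the exclusion cascade."""

    n_recruited: int = 0
    n_removed_idiosyncratic: int = 0
    n_removed_nonheterosexual: int = 0
    n_removed_attention: int = 0
    n_raters_removed_recognition: int = 0
    n_datapoints_removed_recognition: int = 0
    n_retained_raters: int = 0
    n_retained_datapoints: int = 0
    per_condition_retained: dict = dataclasses.field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def apply_exclusions(data: StudyDataset,
                     variant: ExclusionVariant | None = None,
                     drop_raters: Sequence = (),
                     ) -> tuple[StudyDataset, ExclusionReport]:
    """Run the exclusion cascade; return the filtered data and the tally.

    ``drop_raters`` is the manual pre-pipeline drop list (idiosyncratic
    removals); it is applied before any rule-based filter.
    """
    variant = variant or ExclusionVariant()
    raters = data.raters.copy()
    choices = data.choices.copy()
    ratings = data.ratings.copy()
    rep = ExclusionReport(n_recruited=len(raters))

    for col in ("heterosexual", "attention_correct"):
        if col not in raters.columns or raters[col].isna().any():
            raise PreprocessError(f"rater table lacks complete {col!r}")
    if "recognised" not in choices.columns or choices["recognised"].isna().any():
        raise PreprocessError("choice table lacks complete recognition flags")
    att = pd.to_numeric(raters["attention_correct"])
    if ((att < 0) | (att > 2)).any():
        raise PreprocessError("attention_correct outside 0..2")

    def keep_raters(mask: pd.Series) -> int:
        nonlocal raters
        removed = int((~mask).sum())
        raters = raters[mask]
        return removed

    # 1. manual drop list
    rep.n_removed_idiosyncratic = keep_raters(
        ~raters["rater_id"].isin(set(drop_raters)))

    # 2. orientation
    if not variant.keep_nonheterosexual:
        rep.n_removed_nonheterosexual = keep_raters(
            raters["heterosexual"].astype(bool))

    # 3. attention check: removed only if both questions were wrong
    if not variant.keep_attention_failures:
        rep.n_removed_attention = keep_raters(
            pd.to_numeric(raters["attention_correct"]) >= 1)

    # 4. raters recognising too many faces
    n_recognised = (choices[choices["recognised"].astype(bool)]
                    .groupby("rater_id").size())
    over = set(n_recognised[n_recognised > MAX_RECOGNISED_FACES].index)
    before = len(raters)
    raters = raters[~raters["rater_id"].isin(over)]
    rep.n_raters_removed_recognition = before - len(raters)

    kept_ids = set(raters["rater_id"])
    choices = choices[choices["rater_id"].isin(kept_ids)]
    ratings = ratings[ratings["rater_id"].isin(kept_ids)]

    # 5. recognised data points
    if not variant.keep_recognised_points:
        rec = choices[choices["recognised"].astype(bool)]
        rep.n_datapoints_removed_recognition = len(rec)
        rec_pairs = set(zip(rec["rater_id"], rec["target_id"]))
        choices = choices[~choices["recognised"].astype(bool)]
        if rec_pairs and len(ratings):
            pair = list(zip(ratings["rater_id"], ratings["target_id"]))
            ratings = ratings[[p not in rec_pairs for p in pair]]

    rep.n_retained_raters = len(raters)
    rep.n_retained_datapoints = len(choices)
    rep.per_condition_retained = {
        c: int((raters["condition"] == c).sum()) for c in CONDITIONS}
    out = StudyDataset(raters=raters, choices=choices, ratings=ratings)
    return out, rep


# ---------------------------------------------------------------------------
# Scale scoring
# ---------------------------------------------------------------------------


def cronbach_alpha(items: np.ndarray) -> float:
    """Cronbach's alpha of an items matrix (rows = raters, cols = items).

    ``alpha = k/(k-1) * (1 - sum var(item) / var(total))`` with sample
    (n−1) variances.
    """
    items = np.asarray(items, dtype=float)
    if items.ndim != 2 or items.shape[1] < 2:
        raise PreprocessError("alpha needs at least two items")
    if items.shape[0] < 2:
        raise PreprocessError("alpha undefined for fewer than two raters")
    k = items.shape[1]
    total_var = items.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise PreprocessError("alpha undefined: zero total-score variance")
    return float(k / (k - 1) * (1.0 - items.var(axis=0, ddof=1).sum()
                                / total_var))


def score_scales(raters: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Compute per-rater scale means and Cronbach's alpha for each scale.

    Looks for item columns named ``pp_item_*`` / ``rs_item_*``.  Scales with
    item columns get a fresh ``pp_score`` / ``rs_score``; a scale without
    item columns must already carry its score column (e.g. simulated data),
    and its alpha is reported as ``None``.
    """
    raters = raters.copy()
    alphas: dict[str, float | None] = {}
    for scale in ("pp", "rs"):
        item_cols = sorted(c for c in raters.columns
                           if c.startswith(f"{scale}_item_"))
        if item_cols:
            items = raters[item_cols].to_numpy(dtype=float)
            alphas[scale] = cronbach_alpha(items)
            raters[f"{scale}_score"] = items.mean(axis=1)
        elif f"{scale}_score" in raters.columns:
            alphas[scale] = None
        else:
            raise PreprocessError(
                f"no {scale}_item_* columns and no {scale}_score column")
    return raters, alphas


def standardise_scales(raters: pd.DataFrame) -> pd.DataFrame:
    """Add ``z_pp``/``z_rs``: scale scores standardised over these raters.

    Standardisation uses the sample SD (n−1) of the retained sample, so it
    must run after the exclusion cascade.
    """
    raters = raters.copy()
    for scale in ("pp", "rs"):
        col = f"{scale}_score"
        if col not in raters.columns:
            raise PreprocessError(f"missing {col}; run score_scales first")
        x = raters[col].to_numpy(dtype=float)
        if len(x) < 2:
            raise PreprocessError("cannot standardise fewer than two raters")
        sd = x.std(ddof=1)
        if sd == 0:
            raise PreprocessError(f"zero variance in {col}")
        raters[f"z_{scale}"] = (x - x.mean()) / sd
    return raters


def code_side_contrast(choices: pd.DataFrame,
                       raters: pd.DataFrame) -> pd.DataFrame:
    """Attach the ±0.5 side contrast to every choice record.

    −0.5 when the rater saw masculinised faces on the left of the screen,
    +0.5 on the right.  The side is constant within a rater by design; an
    existing inconsistent ``side_contrast`` column raises.
    """
    mapping = {"left": -0.5, "right": 0.5}
    side = raters.set_index("rater_id")["masc_side"]
    bad = ~side.isin(mapping)
    if bad.any():
        raise PreprocessError(
            f"unknown masc_side {side[bad].iloc[0]!r} "
            f"for rater {side[bad].index[0]!r}")
    choices = choices.copy()
    coded = choices["rater_id"].map(side).map(mapping)
    if "side_contrast" in choices.columns:
        if not np.allclose(choices["side_contrast"].to_numpy(dtype=float),
                           coded.to_numpy(dtype=float)):
            raise PreprocessError(
                "side_contrast inconsistent with the rater's masc_side")
    choices["side_contrast"] = coded
    return choices


def preprocess(data: StudyDataset,
               variant: ExclusionVariant | None = None,
               drop_raters: Sequence = (),
               ) -> tuple[StudyDataset, ExclusionReport, dict]:
    """Exclusions → scale scoring → standardisation → contrast coding.

    Returns the model-ready dataset, the exclusion report, and the
    Cronbach's alpha per scale (``None`` where raw items were absent).
    """
    filtered, report = apply_exclusions(data, variant, drop_raters)
    raters, alphas = score_scales(filtered.raters)
    raters = standardise_scales(raters)
    choices = code_side_contrast(filtered.choices, raters)
    out = StudyDataset(raters=raters, choices=choices,
                       ratings=filtered.ratings)
    return out, report, alphas
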