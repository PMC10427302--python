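"""Study data model and long-format CSV I/O.

The study design: heterosexual women are primed with one of three videos
(pathogen prevalence, resource scarcity, or a neutral control), then complete
a 12-trial two-alternative forced choice between a masculinised and a
feminised version of the same male face, rate all 24 face versions on three
dimensions (attractiveness, healthiness, formidability, Likert 1-7), answer
two attention-check questions about the video, report perceived
pathogen-prevalence / resource-scarcity scale items, and flag faces they
recognise.

Everything downstream consumes a :class:`StudyDataset` — three tidy tables:

``raters``
    one row per participant: condition, orientation, attention check,
    scale scores, side assignment, demographics.
``choices``
    one row per participant x target: the binary forced choice plus the
    recognition flag for that target.
``ratings``
    one row per participant x target x version x dimension: the Likert score.
"""

from __future__ import annotations

import dataclasses
import io
import os
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

# ---------------------------------------------------------------------------
# Constants: factor levels
# ---------------------------------------------------------------------------

#: The three priming conditions, in canonical order.
CONDITIONS = ("control", "pathogen_prevalence", "resource_scarcity")

#: Short labels used in parameter names and report tables.
CONDITION_SHORT = {"control": "control", "pathogen_prevalence": "PP",
                   "resource_scarcity": "RS"}

#: The two morph versions shown in every trial.
VERSIONS = ("masculinised", "feminised")

#: The three rating dimensions (blocks of the rating task).
DIMENSIONS = ("attractiveness", "healthiness", "formidability")

SIDES = ("left", "right")

LIKERT_MIN, LIKERT_MAX = 1, 7

RATER_COLUMNS = [
    "rater_id", "condition", "heterosexual", "attention_correct",
    "masc_side", "age", "relationship_status",
    "mate_value_face", "mate_value_body",
]
# optional rater columns: pp_score, rs_score, z_pp, z_rs, pp_item_*, rs_item_*
CHOICE_COLUMNS = ["rater_id", "target_id", "chose_masculinised", "recognised"]
# optional choice column: side_contrast
RATING_COLUMNS = ["rater_id", "target_id", "version", "dimension", "score"]


class SchemaError(ValueError):
    """A table violates the documented column schema (named row and field)."""


class IntegrityError(ValueError):
    """Cross-table referential integrity is broken."""


# ---------------------------------------------------------------------------
# Container
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class StudyDataset:
    """The three study tables plus light referential validation.

    Parameters
    ----------
    raters, choices, ratings
        Tidy tables following the column schemas documented in this module.
    """

    raters: pd.DataFrame
    choices: pd.DataFrame
    ratings: pd.DataFrame

    # -- construction helpers ------------------------------------------------

    def __post_init__(self) -> None:
        self.raters = self.raters.reset_index(drop=True)
        self.choices = self.choices.reset_index(drop=True)
        self.ratings = self.ratings.reset_index(drop=True)

    def copy(self) -> "StudyDataset":
        return StudyDataset(self.raters.copy(), self.choices.copy(),
                            self.ratings.copy())

    @property
    def n_raters(self) -> int:
        return len(self.raters)

    @property
    def n_targets(self) -> int:
        if len(self.choices) == 0:
            return 0
        return self.choices["target_id"].nunique()

    def rater_ids(self) -> np.ndarray:
        return self.raters["rater_id"].to_numpy()

    # -- validation ----------------------------------------------------------

    def validate(self) -> "StudyDataset":
        """Check schemas, value ranges and referential integrity.

        Raises
        ------
        SchemaError
            for a malformed cell, naming the table, row and field.
        IntegrityError
            for a choice/rating that references an unknown rater or for a
            duplicated observation unit.
        """
        _require_columns("raters", self.raters, RATER_COLUMNS)
        _require_columns("choices", self.choices, CHOICE_COLUMNS)
        _require_columns("ratings", self.ratings, RATING_COLUMNS)

        _check_levels("raters", self.raters, "condition", CONDITIONS)
        _check_levels("raters", self.raters, "masc_side", SIDES)
        _check_int_range("raters", self.raters, "attention_correct", 0, 2)
        _check_levels("ratings", self.ratings, "version", VERSIONS)
        _check_levels("ratings", self.ratings, "dimension", DIMENSIONS)
        _check_int_range("ratings", self.ratings, "score",
                         LIKERT_MIN, LIKERT_MAX)
        _check_int_range("choices", self.choices, "chose_masculinised", 0, 1)

        if self.raters["rater_id"].duplicated().any():
            row = int(self.raters.index[self.raters["rater_id"].duplicated()][0])
            raise IntegrityError(f"raters row {row}: duplicated rater_id "
                                 f"{self.raters['rater_id'].iloc[row]!r}")

        known = set(self.raters["rater_id"])
        for name, table in (("choices", self.choices),
                            ("ratings", self.ratings)):
            if len(table) == 0:
                continue
            bad = ~table["rater_id"].isin(known)
            if bad.any():
                row = int(table.index[bad][0])
                raise IntegrityError(
                    f"{name} row {row}: unknown rater_id "
                    f"{table['rater_id'].iloc[row]!r}")

        dup = self.choices.duplicated(subset=["rater_id", "target_id"])
        if dup.any():
            raise IntegrityError(
                f"choices row {int(self.choices.index[dup][0])}: duplicate "
                "rater_id x target_id")
        dup = self.ratings.duplicated(
            subset=["rater_id", "target_id", "version", "dimension"])
        if dup.any():
            raise IntegrityError(
                f"ratings row {int(self.ratings.index[dup][0])}: duplicate "
                "rater_id x target_id x version x dimension")
        return self

    # -- comparison (row order insensitive) ----------------------------------

    def equals(self, other: "StudyDataset") -> bool:
        """Equality up to row order and column order of optional columns."""
        def canon(df: pd.DataFrame, keys: list[str]) -> pd.DataFrame:
            cols = sorted(df.columns)
            out = df[cols].sort_values(by=[k for k in keys if k in cols])
            return out.reset_index(drop=True)

        for a, b, keys in (
            (self.raters, other.raters, ["rater_id"]),
            (self.choices, other.choices, ["rater_id", "target_id"]),
            (self.ratings, other.ratings,
             ["rater_id", "target_id", "version", "dimension"]),
        ):
            ca, cb = canon(a, keys), canon(b, keys)
            if list(ca.columns) != list(cb.columns) or ca.shape != cb.shape:
                return False
            for col in ca.columns:
                va, vb = ca[col].to_numpy(), cb[col].to_numpy()
                if va.dtype.kind == "f" or vb.dtype.kind == "f":
                    if not np.allclose(va.astype(float), vb.astype(float),
                                       equal_nan=True):
                        return False
                elif not (va == vb).all():
                    return False
        return True


# ---------------------------------------------------------------------------
# Validation helpers
# ---------------------------------------------------------------------------


def _require_columns(name: str, df: pd.DataFrame, cols: Iterable[str]) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{name}: missing column(s) {missing}")


def _check_levels(name: str, df: pd.DataFrame, col: str,
                  levels: tuple[str, ...]) -> None:
    if len(df) == 0:
        return
    bad = ~df[col].isin(levels)
    if bad.any():
        row = int(df.index[bad][0])
        raise SchemaError(f"{name} row {row}, field {col!r}: "
                          f"{df[col].iloc[row]!r} not in {levels}")


def _check_int_range(name: str, df: pd.DataFrame, col: str,
                     lo: int, hi: int) -> None:
    if len(df) == 0:
        return
    vals = pd.to_numeric(df[col], errors="coerce")
    bad = vals.isna() | (vals < lo) | (vals > hi) | (vals % 1 != 0)
    if bad.any():
        row = int(df.index[bad][0])
        raise SchemaError(f"{name} row {row}, field {col!r}: "
                          f"{df[col].iloc[row]!r} outside {lo}..{hi}")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_FILENAMES = {"raters": "raters.csv", "choices": "choices.csv",
              "ratings": "ratings.csv"}


def _resolve_paths(paths: str | os.PathLike | Mapping[str, str | os.PathLike],
                   ) -> dict[str, Path]:
    if isinstance(paths, (str, os.PathLike)):
        base = Path(paths)
        return {k: base / v for k, v in _FILENAMES.items()}
    return {k: Path(paths[k]) for k in _FILENAMES}


def read_study(paths: str | os.PathLike | Mapping[str, str | os.PathLike],
               validate: bool = True) -> StudyDataset:
    """Read the three study tables.

    Parameters
    ----------
    paths
        Either a directory containing ``raters.csv``, ``choices.csv`` and
        ``ratings.csv``, or a mapping with those three keys to file paths.
    validate
        Run :meth:`StudyDataset.validate` after reading (default).
    """
    p = _resolve_paths(paths)
    for key, path in p.items():
        if not path.exists():
            raise FileNotFoundError(f"{key} table not found at {path}")
    ds = StudyDataset(
        raters=pd.read_csv(p["raters"]),
        choices=pd.read_csv(p["choices"]),
        ratings=pd.read_csv(p["ratings"]),
    )
    return ds.validate() if validate else ds


def write_study(data: StudyDataset,
                paths: str | os.PathLike | Mapping[str, str | os.PathLike],
                ) -> None:
    """Write the three tables as UTF-8 comma-separated files with headers.

    Round-trips: ``read_study(write_study(d)) == d`` up to row order.
    """
    p = _resolve_paths(paths)
    for path in p.values():
        path.parent.mkdir(parents=True, exist_ok=True)
    data.raters.to_csv(p["raters"], index=False)
    data.choices.to_csv(p["choices"], index=False)
    data.ratings.to_csv(p["ratings"], index=False)
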