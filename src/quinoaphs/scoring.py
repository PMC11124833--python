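"""Six-level ordinal panicle-sprouting scale and raw score-table handling.

Preharvest sprouting (PHS) on a misted quinoa panicle is scored visually on
an odd-number ordinal scale ``{0, 1, 3, 5, 7, 9}``.  Each level stands for a
band of the relative percentage of sprouted seeds on the panicle:

====== =====================
level  percent sprouted
====== =====================
0      exactly 0
1      (0, 20)
3      [20, 40)
5      [40, 60)
7      [60, 80)
9      [80, 100]
====== =====================

The printed scale uses integer ranges (1-19, 20-39, ...); intervals here are
half-open at the upper bound so that any *real* percentage (e.g. from seed
counts in an image) maps to exactly one level.  A positive percentage below
20 maps to level 1 (radicle emergence is present); 0 maps only to exact 0.

A raw score table is long-format: one row per panicle per day, with design
labels (genotype, planting date, batch, replicate).  Missing observations
are absent rows, never zeros — zero means "observed, no sprouting".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError

#: Ordered ordinal levels of the sprouting scale.
SCORE_LEVELS = (0, 1, 3, 5, 7, 9)

#: Required columns of a long-format panicle score table.
SCORE_COLUMNS = ("genotype_id", "planting_date", "batch", "replicate", "day", "score")

#: Valid planting-date labels.
PLANTING_DATES = ("PD1", "PD2")

#: Days of the misting test.
DAYS = tuple(range(1, 8))

# Upper edges of the percent bands for the positive levels 1,3,5,7,9.
_UPPER_EDGES = np.array([20.0, 40.0, 60.0, 80.0])
_POSITIVE_LEVELS = np.array([1, 3, 5, 7, 9])


def percent_to_score(pct):
    """Map a sprouting percentage to its ordinal scale level.

    Parameters
    ----------
    pct : float or array-like
        Percentage of sprouted seeds, in ``[0, 100]``.

    Returns
    -------
    int or ndarray of int
        The unique scale level whose band contains ``pct``.

    Raises
    ------
    DataError
        If any value lies outside ``[0, 100]`` or is NaN.
    """
    arr = np.asarray(pct, dtype=float)
    if arr.size and (np.any(~np.isfinite(arr)) or arr.min() < 0 or arr.max() > 100):
        raise DataError("sprouting percentage must lie in [0, 100]")
    idx = np.searchsorted(_UPPER_EDGES, arr, side="right")
    level = _POSITIVE_LEVELS[idx]
    level = np.where(arr == 0, 0, level)
    if np.isscalar(pct) or np.ndim(pct) == 0:
        return int(level)
    return level.astype(int)


def score_intervals() -> dict:
    """Return the percent band for each level as ``{level: (low, high, closed)}``.

    ``closed`` describes which endpoints belong to the band: level 0 is the
    point {0}, level 1 is open on both sides, 3/5/7 are closed-left, and 9 is
    closed on both sides.
    """
    return {
        0: (0.0, 0.0, "both"),
        1: (0.0, 20.0, "neither"),
        3: (20.0, 40.0, "left"),
        5: (40.0, 60.0, "left"),
        7: (60.0, 80.0, "left"),
        9: (80.0, 100.0, "both"),
    }


@dataclass
class ScoreValidationReport:
    """Structural findings on a raw score table; empty frames mean clean."""

    n_rows: int = 0
    duplicate_keys: pd.DataFrame = field(default_factory=pd.DataFrame)
    out_of_scale: pd.DataFrame = field(default_factory=pd.DataFrame)
    bad_days: pd.DataFrame = field(default_factory=pd.DataFrame)
    under_replicated: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def ok(self) -> bool:
        return (
            self.duplicate_keys.empty
            and self.out_of_scale.empty
            and self.bad_days.empty
            and self.under_replicated.empty
        )

    def summary(self) -> str:
        return (
            f"{self.n_rows} rows; {len(self.duplicate_keys)} duplicate keys; "
            f"{len(self.out_of_scale)} out-of-scale scores; "
            f"{len(self.bad_days)} invalid days; "
            f"{len(self.under_replicated)} under-replicated genotypes"
        )


def _require_columns(table: pd.DataFrame) -> None:
    missing = [c for c in SCORE_COLUMNS if c not in table.columns]
    if missing:
        raise DataError(f"score table is missing columns: {missing}")


def validate_scores(table: pd.DataFrame, min_replicates: int = 3) -> ScoreValidationReport:
    """Check structural rules of a panicle score table.

    Flags duplicated (genotype, planting date, batch, replicate, day) keys,
    scores outside the ordinal scale, days outside 1..7, and genotypes with
    fewer than ``min_replicates`` panicle replicates in total (default 3,
    the experimental minimum).  Biological exclusions (molded panicles, poor
    seed set) are the caller's decision and are not inferred here.
    """
    _require_columns(table)
    key_cols = ["genotype_id", "planting_date", "batch", "replicate", "day"]
    dup_mask = table.duplicated(subset=key_cols, keep=False)
    duplicates = table.loc[dup_mask, key_cols].drop_duplicates()

    scale = set(SCORE_LEVELS)
    out_of_scale = table.loc[~table["score"].isin(scale)]
    bad_days = table.loc[~table["day"].isin(DAYS)]

    reps = (
        table.groupby("genotype_id")[["planting_date", "batch", "replicate"]]
        .apply(lambda g: len(g.drop_duplicates()))
        .rename("n_replicates")
        .reset_index()
    )
    under = reps.loc[reps["n_replicates"] < min_replicates]

    return ScoreValidationReport(
        n_rows=len(table),
        duplicate_keys=duplicates.reset_index(drop=True),
        out_of_scale=out_of_scale.reset_index(drop=True),
        bad_days=bad_days.reset_index(drop=True),
        under_replicated=under.reset_index(drop=True),
    )


def daily_genotype_means(
    table: pd.DataFrame,
    by_planting_date: bool = True,
    weighted: bool = False,
) -> pd.DataFrame:
    """Average replicate scores per genotype per day into a trajectory table.

    Parameters
    ----------
    table : DataFrame
        Long-format score table (see :data:`SCORE_COLUMNS`).
    by_planting_date : bool
        If True, average within each planting date (one trajectory per
        genotype x PD); otherwise pool replicates across planting dates.
    weighted : bool
        If True, multiply the means by 10 so values reflect the median of
        each level's percent band (display convention for distribution
        plots); the unweighted table is the analysis input.

    Returns
    -------
    DataFrame
        Columns ``genotype_id`` (+ ``planting_date``), ``day1`` .. ``day7``.
        A day with no observation for a genotype is NaN, never 0.
    """
    _require_columns(table)
    keys = ["genotype_id", "planting_date"] if by_planting_date else ["genotype_id"]
    wide = table.pivot_table(index=keys, columns="day", values="score", aggfunc="mean")
    wide = wide.reindex(columns=list(DAYS))
    wide.columns = [f"day{d}" for d in DAYS]
    if weighted:
        wide = wide * 10.0
    return wide.reset_index()


def read_score_table(path) -> pd.DataFrame:
    """Read the phenotype CSV dialect (UTF-8, header required)."""
    table = pd.read_csv(path)
    _require_columns(table)
    return table


def write_score_table(table: pd.DataFrame, path) -> None:
    """Write a score table as CSV (UTF-8, with header)."""
    _require_columns(table)
    table.to_csv(path, index=False)
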