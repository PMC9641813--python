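"""Response-matrix container, scoring conventions, and CSV I/O.

The universal input of every analysis stage is a persons x items table of
ordinal Likert responses coded 1..n_categories (default 5, "extraordinary"
to "none at all").  Totals are standardized linearly to the 0-100 range,
with higher scores indicating milder symptoms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ResponseMatrix",
    "ScaleDefinition",
    "ValidationError",
    "read_responses",
    "write_responses",
    "raw_total",
    "standardize_score",
    "score_distribution",
]


class ValidationError(ValueError):
    """Raised when an input violates the response-matrix contract."""


@dataclass(frozen=True)
class ScaleDefinition:
    """An (ordered) subset of an instrument's items forming a scale.

    Parameters
    ----------
    item_ids : sequence of str
        Item labels, non-empty, no duplicates.
    n_categories : int
        Number of ordered response categories (default 5).
    min_category : int
        Code of the lowest category (default 1).
    """

    item_ids: tuple[str, ...]
    n_categories: int = 5
    min_category: int = 1

    def __init__(self, item_ids: Sequence[str], n_categories: int = 5, min_category: int = 1):
        ids = tuple(str(i) for i in item_ids)
        if not ids:
            raise ValidationError("scale must contain at least one item")
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate item ids in scale definition")
        object.__setattr__(self, "item_ids", ids)
        object.__setattr__(self, "n_categories", int(n_categories))
        object.__setattr__(self, "min_category", int(min_category))

    def __len__(self) -> int:
        return len(self.item_ids)

    def __iter__(self):
        return iter(self.item_ids)

    @property
    def max_category(self) -> int:
        return self.min_category + self.n_categories - 1


class ResponseMatrix:
    """Validated persons x items matrix of integer category codes.

    Every cell must lie in ``[min_category, min_category + n_categories - 1]``;
    missing values are rejected.  Backed by a pandas DataFrame with item ids
    as columns and person ids as the index.
    """

    def __init__(
        self,
        values,
        item_ids: Sequence[str] | None = None,
        person_ids: Sequence | None = None,
        n_categories: int = 5,
        min_category: int = 1,
    ):
        if isinstance(values, pd.DataFrame):
            df = values.copy()
            if item_ids is not None:
                df.columns = list(item_ids)
            if person_ids is not None:
                df.index = list(person_ids)
        else:
            arr = np.asarray(values)
            if arr.ndim != 2:
                raise ValidationError("response values must be two-dimensional")
            if item_ids is None:
                item_ids = [f"item{j + 1}" for j in range(arr.shape[1])]
            if person_ids is None:
                person_ids = list(range(1, arr.shape[0] + 1))
            df = pd.DataFrame(arr, columns=list(item_ids), index=list(person_ids))

        self.n_categories = int(n_categories)
        self.min_category = int(min_category)
        self._validate(df)
        self._df = df.astype(np.int64)

    def _validate(self, df: pd.DataFrame) -> None:
        if df.shape[0] < 2 or df.shape[1] < 2:
            raise ValidationError(
                f"need at least 2 persons and 2 items, got {df.shape[0]} x {df.shape[1]}"
            )
        if len(set(df.columns)) != df.shape[1]:
            dupes = df.columns[df.columns.duplicated()].tolist()
            raise ValidationError(f"duplicate item ids: {dupes}")
        if len(set(df.index)) != df.shape[0]:
            raise ValidationError("duplicate person ids")
        lo, hi = self.min_category, self.min_category + self.n_categories - 1
        for col in df.columns:
            s = df[col]
            if s.isna().any():
                row = s.index[s.isna()][0]
                raise ValidationError(f"missing value at person {row!r}, item {col!r}")
            vals = s.to_numpy()
            if not np.all(vals == np.floor(vals)):
                row = s.index[vals != np.floor(vals)][0]
                raise ValidationError(f"non-integer response at person {row!r}, item {col!r}")
            bad = (vals < lo) | (vals > hi)
            if bad.any():
                row = s.index[bad][0]
                raise ValidationError(
                    f"response {s.loc[row]} out of range [{lo}, {hi}] "
                    f"at person {row!r}, item {col!r}"
                )

    # -- accessors -----------------------------------------------------
    @property
    def values(self) -> np.ndarray:
        return self._df.to_numpy()

    @property
    def item_ids(self) -> list[str]:
        return [str(c) for c in self._df.columns]

    @property
    def person_ids(self) -> list:
        return list(self._df.index)

    @property
    def n_persons(self) -> int:
        return self._df.shape[0]

    @property
    def n_items(self) -> int:
        return self._df.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self._df.shape

    def to_frame(self) -> pd.DataFrame:
        return self._df.copy()

    def full_scale(self) -> ScaleDefinition:
        """The scale consisting of all items in instrument order."""
        return ScaleDefinition(self.item_ids, self.n_categories, self.min_category)

    def subset_values(self, subset: ScaleDefinition) -> np.ndarray:
        """Columns for the subset's items, in subset order."""
        missing = [i for i in subset.item_ids if i not in self._df.columns]
        if missing:
            raise ValidationError(f"unknown item ids: {missing}")
        return self._df.loc[:, list(subset.item_ids)].to_numpy()

    def __eq__(self, other) -> bool:
        return isinstance(other, ResponseMatrix) and self._df.equals(other._df)


def read_responses(path: str | Path, n_categories: int = 5, min_category: int = 1) -> ResponseMatrix:
    """Read a response matrix from CSV (header = item ids, one row per person)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValidationError(f"empty response file: {path}") from None
    if df.shape[0] == 0:
        raise ValidationError(f"no response rows in {path}")
    return ResponseMatrix(df.reset_index(drop=True), n_categories=n_categories,
                          min_category=min_category)


def write_responses(m: ResponseMatrix, path: str | Path) -> None:
    """Write a response matrix to CSV (item-id header, no person index)."""
    m.to_frame().to_csv(path, index=False)


def raw_total(m: ResponseMatrix, subset: ScaleDefinition | None = None) -> np.ndarray:
    """Per-person raw sum of category codes over the subset's items."""
    if subset is None:
        subset = m.full_scale()
    return m.subset_values(subset).sum(axis=1)


def standardize_score(raw, k: int, min_cat: int = 1, max_cat: int = 5):
    """Linearly map a raw total on k items to the 0-100 range.

    score = 100 * (raw - k*min_cat) / (k * (max_cat - min_cat)), so the
    floor (all responses at the minimum category) maps to 0 and the
    ceiling to 100.
    """
    raw_arr = np.asarray(raw, dtype=float)
    lo, hi = k * min_cat, k * max_cat
    if np.any(raw_arr < lo) or np.any(raw_arr > hi):
        raise ValidationError(f"raw total outside attainable range [{lo}, {hi}]")
    out = 100.0 * (raw_arr - lo) / (hi - lo)
    return float(out) if np.isscalar(raw) or out.ndim == 0 else out


def standardized_scores(m: ResponseMatrix, subset: ScaleDefinition | None = None) -> np.ndarray:
    """Per-person standardized (0-100) totals over the subset."""
    if subset is None:
        subset = m.full_scale()
    return standardize_score(
        raw_total(m, subset), len(subset), subset.min_category, subset.max_category
    )


@dataclass(frozen=True)
class ScoreSummary:
    minimum: float
    maximum: float
    median: float
    q1: float
    q3: float
    mean: float


def score_distribution(scores, quantile_method: str = "linear") -> ScoreSummary:
    """Summary statistics of a score sample: min, max, median, Q1, Q3, mean.

    Quartiles use linear interpolation between closest ranks by default;
    the method is configurable through numpy's quantile conventions.
    """
    arr = np.asarray(list(scores), dtype=float)
    if arr.size == 0:
        raise ValidationError("cannot summarize an empty score list")
    q1, med, q3 = np.quantile(arr, [0.25, 0.5, 0.75], method=quantile_method)
    return ScoreSummary(
        minimum=float(arr.min()),
        maximum=float(arr.max()),
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        mean=float(arr.mean()),
    )
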