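"""Seven-criterion CTT/IRT item screen and count-based selection.

Each item is profiled with classical statistics (item-total correlation,
alpha-if-deleted, corrected item-total correlation), its one-factor CFA
loading, and its GPCM parameters and average information.  The screen
counts how many of seven quality criteria the item satisfies:

  1. item-total correlation >= 0.4
  2. deleting the item reduces Cronbach alpha (alpha_if_deleted < full alpha)
  3. corrected item-total correlation >= 0.4
  4. factor loading >= 0.4
  5. discrimination alpha > 0.5
  6. every threshold beta strictly inside (-4, 4)
  7. average item information >= 0.5

Selection keeps the k items with the highest counts, breaking ties by the
higher average information and finally by instrument position, which makes
the procedure deterministic.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .data import ScaleDefinition, ValidationError

__all__ = [
    "ItemCriteriaProfile",
    "CriteriaThresholds",
    "CriteriaResult",
    "evaluate_criteria",
    "select_items",
    "criteria_table",
    "load_spd10_profiles",
]


@dataclass(frozen=True)
class ItemCriteriaProfile:
    """All per-item statistics entering the seven-criterion screen."""

    item_id: str
    item_total_r: float
    alpha_if_deleted: float
    citc: float
    loading: float
    alpha_irt: float
    betas: tuple[float, ...]
    avg_info: float

    def __post_init__(self):
        vals = [self.item_total_r, self.alpha_if_deleted, self.citc, self.loading,
                self.alpha_irt, self.avg_info, *self.betas]
        if not all(np.isfinite(v) for v in vals):
            raise ValidationError(f"non-finite statistic in profile for {self.item_id!r}")


@dataclass(frozen=True)
class CriteriaThresholds:
    """Cutoffs of the screen; defaults are the conventional values."""

    item_total_r_min: float = 0.4
    citc_min: float = 0.4
    loading_min: float = 0.4
    alpha_irt_min: float = 0.5        # strict: alpha > this
    beta_range: tuple[float, float] = (-4.0, 4.0)  # open interval
    avg_info_min: float = 0.5


@dataclass(frozen=True)
class CriteriaResult:
    item_id: str
    flags: tuple[bool, bool, bool, bool, bool, bool, bool]
    count: int


def evaluate_criteria(
    p: ItemCriteriaProfile,
    full_alpha: float,
    thresholds: CriteriaThresholds = CriteriaThresholds(),
) -> CriteriaResult:
    """Apply the seven criteria to one item's profile."""
    if not np.isfinite(full_alpha):
        raise ValidationError("full-scale alpha must be finite")
    lo, hi = thresholds.beta_range
    flags = (
        p.item_total_r >= thresholds.item_total_r_min,
        p.alpha_if_deleted < full_alpha,
        p.citc >= thresholds.citc_min,
        p.loading >= thresholds.loading_min,
        p.alpha_irt > thresholds.alpha_irt_min,
        all(lo < b < hi for b in p.betas),
        p.avg_info >= thresholds.avg_info_min,
    )
    return CriteriaResult(p.item_id, flags, sum(flags))


def select_items(
    profiles: Sequence[ItemCriteriaProfile],
    k: int,
    full_alpha: float,
    thresholds: CriteriaThresholds = CriteriaThresholds(),
) -> ScaleDefinition:
    """Keep the k items satisfying the most criteria.

    Ties on the criteria count are broken by the higher average item
    information, then by original instrument position.  The returned scale
    lists items in instrument order.
    """
    if k > len(profiles):
        raise ValidationError(f"cannot select {k} items from {len(profiles)}")
    results = [evaluate_criteria(p, full_alpha, thresholds) for p in profiles]
    order = sorted(
        range(len(profiles)),
        key=lambda i: (-results[i].count, -profiles[i].avg_info, i),
    )
    chosen = sorted(order[:k])
    return ScaleDefinition([profiles[i].item_id for i in chosen])


def criteria_table(
    profiles: Sequence[ItemCriteriaProfile],
    full_alpha: float,
    thresholds: CriteriaThresholds = CriteriaThresholds(),
) -> pd.DataFrame:
    """Tidy per-item table: statistics, the seven flags, and the count."""
    rows = []
    for p in profiles:
        res = evaluate_criteria(p, full_alpha, thresholds)
        row = {
            "item_id": p.item_id,
            "item_total_r": p.item_total_r,
            "alpha_if_deleted": p.alpha_if_deleted,
            "citc": p.citc,
            "loading": p.loading,
            "alpha_irt": p.alpha_irt,
        }
        row.update({f"beta{v + 1}": b for v, b in enumerate(p.betas)})
        row["avg_info"] = p.avg_info
        row.update({f"criterion_{i + 1}": bool(f) for i, f in enumerate(res.flags)})
        row["n_criteria"] = res.count
        rows.append(row)
    return pd.DataFrame(rows)


def _profiles_from_rows(rows: list[dict]) -> list[ItemCriteriaProfile]:
    out = []
    for row in rows:
        betas = tuple(
            float(row[key]) for key in sorted(row) if key.startswith("beta")
        )
        out.append(
            ItemCriteriaProfile(
                item_id=str(row["item_id"]),
                item_total_r=float(row["item_total_r"]),
                alpha_if_deleted=float(row["alpha_if_deleted"]),
                citc=float(row["citc"]),
                loading=float(row["loading"]),
                alpha_irt=float(row["alpha"]),
                betas=betas,
                avg_info=float(row["avg_info"]),
            )
        )
    return out


def read_profiles(path: str | Path) -> list[ItemCriteriaProfile]:
    """Read item profiles from a CSV with columns item_id, item_total_r,
    alpha_if_deleted, citc, loading, alpha, beta1..betam, avg_info."""
    with open(path, newline="") as fh:
        return _profiles_from_rows(list(csv.DictReader(fh)))


def load_spd10_profiles() -> list[ItemCriteriaProfile]:
    """The published CTT/CFA/GPCM item statistics of the ten SPD-10 items."""
    ref = resources.files("scaleshort").joinpath("calibration/spd10_item_stats.csv")
    with resources.as_file(ref) as path:
        return read_profiles(path)
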