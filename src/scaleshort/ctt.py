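"""Classical test theory statistics: Cronbach alpha, item-total correlations,
alpha-if-item-deleted, and split-half reliability.

All variances are sample variances (denominator n-1), the convention SPSS
uses; alpha depends on variances only through ratios, so the choice matters
only for consistency with the split-half and item-level statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import ResponseMatrix, ScaleDefinition, ValidationError

__all__ = [
    "CTTItemStats",
    "ReliabilityReport",
    "cronbach_alpha",
    "item_stats",
    "split_half",
]


@dataclass(frozen=True)
class CTTItemStats:
    """Item-level CTT statistics for the screening criteria.

    item_total_r includes the item in the total; citc (corrected item-total
    correlation) excludes it; alpha_if_deleted is Cronbach alpha of the
    remaining items.
    """

    item_id: str
    item_total_r: float
    citc: float
    alpha_if_deleted: float


@dataclass(frozen=True)
class ReliabilityReport:
    cronbach_alpha: float
    split_half: float


def _subset_values(m: ResponseMatrix, subset: ScaleDefinition | None) -> np.ndarray:
    if subset is None:
        subset = m.full_scale()
    return m.subset_values(subset).astype(float)


def _alpha_from_values(x: np.ndarray) -> float:
    k = x.shape[1]
    if k < 2:
        raise ValidationError("Cronbach alpha needs at least 2 items")
    if x.shape[0] < 3:
        raise ValidationError("Cronbach alpha needs at least 3 persons")
    item_var = x.var(axis=0, ddof=1)
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise ValidationError("degenerate scale: total score has zero variance")
    return float(k / (k - 1) * (1.0 - item_var.sum() / total_var))


def cronbach_alpha(m: ResponseMatrix, subset: ScaleDefinition | None = None) -> float:
    """Cronbach alpha:  k/(k-1) * (1 - sum(item variances)/variance(total))."""
    return _alpha_from_values(_subset_values(m, subset))


def item_stats(m: ResponseMatrix, subset: ScaleDefinition | None = None) -> list[CTTItemStats]:
    """Per-item item-total correlation, CITC, and alpha-if-deleted."""
    if subset is None:
        subset = m.full_scale()
    x = _subset_values(m, subset)
    k = x.shape[1]
    if k < 3:
        raise ValidationError("item statistics need at least 3 items (alpha-if-deleted)")
    for j, item in enumerate(subset.item_ids):
        if x[:, j].var(ddof=1) == 0:
            raise ValidationError(f"item {item!r} has zero variance")
    total = x.sum(axis=1)
    out = []
    for j, item in enumerate(subset.item_ids):
        rest = total - x[:, j]
        r_with = np.corrcoef(x[:, j], total)[0, 1]
        r_rest = np.corrcoef(x[:, j], rest)[0, 1]
        alpha_del = _alpha_from_values(np.delete(x, j, axis=1))
        out.append(CTTItemStats(item, float(r_with), float(r_rest), float(alpha_del)))
    return out


def split_half(
    m: ResponseMatrix,
    subset: ScaleDefinition | None = None,
    scheme: str = "odd-even",
    seed: int | None = None,
) -> float:
    """Spearman-Brown corrected split-half reliability, 2r/(1+r).

    The split is by item position within the subset: ``odd-even`` (default),
    ``first-last``, or ``random`` (seeded permutation).  The correction is
    capped at 1.
    """
    if subset is None:
        subset = m.full_scale()
    x = _subset_values(m, subset)
    k = x.shape[1]
    if k < 2:
        raise ValidationError("split-half needs at least 2 items")
    idx = np.arange(k)
    if scheme == "odd-even":
        first, second = idx[::2], idx[1::2]
    elif scheme == "first-last":
        first, second = idx[: k // 2], idx[k // 2:]
    elif scheme == "random":
        perm = np.random.default_rng(seed).permutation(idx)
        first, second = perm[: k // 2], perm[k // 2:]
    else:
        raise ValueError(f"unknown split scheme {scheme!r}")
    a, b = x[:, first].sum(axis=1), x[:, second].sum(axis=1)
    if a.var(ddof=1) == 0 or b.var(ddof=1) == 0:
        raise ValidationError("a half-scale total is constant; split-half undefined")
    r = float(np.corrcoef(a, b)[0, 1])
    return min(2 * r / (1 + r), 1.0)


def reliability_report(
    m: ResponseMatrix,
    subset: ScaleDefinition | None = None,
    scheme: str = "odd-even",
    seed: int | None = None,
) -> ReliabilityReport:
    return ReliabilityReport(
        cronbach_alpha=cronbach_alpha(m, subset),
        split_half=split_half(m, subset, scheme=scheme, seed=seed),
    )
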