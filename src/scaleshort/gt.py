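"""Generalizability theory for the single-facet persons x items design.

The G-study decomposes item-level score variance into person (sigma2_p),
item (sigma2_i), and person-by-item interaction/residual (sigma2_pi)
components by equating observed ANOVA mean squares to their expectations:

    sigma2_pi = MS_pi
    sigma2_p  = (MS_p - MS_pi) / n_i
    sigma2_i  = (MS_i - MS_pi) / n_p

Negative estimates are truncated at zero, the standard GT practice.

The D-study projects, for a hypothetical form of n' items, the relative and
absolute error variances on the per-item mean-score metric and the
corresponding generalizability (G) and dependability (phi) coefficients:

    rel_err = sigma2_pi / n'                 (sigma^2_delta)
    abs_err = (sigma2_i + sigma2_pi) / n'    (sigma^2_Delta)
    G       = sigma2_p / (sigma2_p + rel_err)
    phi     = sigma2_p / (sigma2_p + abs_err)

At n' equal to the observed number of items, G coincides with Cronbach
alpha (Hoyt's identity).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .data import ResponseMatrix, ValidationError

__all__ = [
    "VarianceComponents",
    "DStudyIndices",
    "g_study",
    "d_study",
    "d_study_table",
    "min_items",
]


@dataclass(frozen=True)
class VarianceComponents:
    """Estimated variance components, in squared category-score units."""

    sigma2_p: float
    sigma2_i: float
    sigma2_pi: float

    def __post_init__(self):
        for name in ("sigma2_p", "sigma2_i", "sigma2_pi"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValidationError(f"{name} must be finite and >= 0, got {v}")


@dataclass(frozen=True)
class DStudyIndices:
    """Projected decision-study indices for a form of n_items items."""

    n_items: int
    G: float
    phi: float
    rel_err: float
    abs_err: float


def g_study(m: ResponseMatrix | np.ndarray) -> VarianceComponents:
    """Estimate p x i variance components by ANOVA.

    Accepts a ResponseMatrix or any persons x items real-valued array (the
    decomposition itself does not require integer category codes).
    """
    x = m.values.astype(float) if isinstance(m, ResponseMatrix) else np.asarray(m, dtype=float)
    n_p, n_i = x.shape
    if n_p < 3 or n_i < 2:
        raise ValidationError("G-study needs at least 3 persons and 2 items")
    grand = x.mean()
    person_means = x.mean(axis=1)
    item_means = x.mean(axis=0)
    ss_p = n_i * ((person_means - grand) ** 2).sum()
    ss_i = n_p * ((item_means - grand) ** 2).sum()
    resid = x - person_means[:, None] - item_means[None, :] + grand
    ss_pi = (resid ** 2).sum()
    ms_p = ss_p / (n_p - 1)
    ms_i = ss_i / (n_i - 1)
    ms_pi = ss_pi / ((n_p - 1) * (n_i - 1))
    return VarianceComponents(
        sigma2_p=max((ms_p - ms_pi) / n_i, 0.0),
        sigma2_i=max((ms_i - ms_pi) / n_p, 0.0),
        sigma2_pi=max(ms_pi, 0.0),
    )


def d_study(vc: VarianceComponents, n_prime: int) -> DStudyIndices:
    """Project G, phi, and error variances for a form of n_prime items."""
    if n_prime < 1:
        raise ValidationError("n_prime must be >= 1")
    if vc.sigma2_p == 0 and vc.sigma2_pi == 0:
        raise ValidationError("indices undefined: no person or interaction variance")
    rel = vc.sigma2_pi / n_prime
    ab = (vc.sigma2_i + vc.sigma2_pi) / n_prime
    return DStudyIndices(
        n_items=int(n_prime),
        G=vc.sigma2_p / (vc.sigma2_p + rel),
        phi=vc.sigma2_p / (vc.sigma2_p + ab),
        rel_err=rel,
        abs_err=ab,
    )


def d_study_table(vc: VarianceComponents, n_range: Iterable[int] = range(3, 11)) -> pd.DataFrame:
    """D-study indices for each candidate form length, as a tidy table."""
    rows = [d_study(vc, n) for n in n_range]
    return pd.DataFrame(
        {
            "n_items": [r.n_items for r in rows],
            "G": [r.G for r in rows],
            "phi": [r.phi for r in rows],
            "rel_err": [r.rel_err for r in rows],
            "abs_err": [r.abs_err for r in rows],
        }
    )


def min_items(
    vc: VarianceComponents,
    n_range: Iterable[int] = range(3, 11),
    g_min: float = 0.70,
    phi_min: float = 0.70,
    err_max: float = 0.20,
) -> int | None:
    """Smallest form length whose projected indices clear every threshold.

    Requires strictly G > g_min, phi > phi_min, and both error variances
    strictly below err_max; returns None when no candidate qualifies.
    """
    candidates = sorted(set(int(n) for n in n_range))
    if not candidates:
        raise ValidationError("empty candidate range")
    for n in candidates:
        d = d_study(vc, n)
        if d.G > g_min and d.phi > phi_min and d.rel_err < err_max and d.abs_err < err_max:
            return n
    return None
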