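"""Synthetic Likert-response generation under a generalized partial credit model.

A unidimensional latent quality-of-life trait theta ~ N(0, 1) drives every
item through a GPCM with per-item discrimination alpha and step thresholds
beta_1..beta_m.  Category probabilities follow

    P(X = c | theta) = exp(sum_{v<=c} alpha (theta - beta_v)) / normalizer,

with categories indexed 0..m internally and stored as codes 1..m+1 to match
the instrument's coding.  The packaged default bank is the published GPCM
calibration of the ten SPD-10 items, so instrument-like data is one call away.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np

from .data import ResponseMatrix, ValidationError

__all__ = [
    "GPCMItemParams",
    "ItemBank",
    "load_spd10_bank",
    "gpcm_category_probs",
    "simulate_thetas",
    "simulate_responses",
]


@dataclass(frozen=True)
class GPCMItemParams:
    """GPCM parameters for one polytomous item.

    alpha is the discrimination (slope, >= 0); betas are the m step
    thresholds on the latent-trait scale for an item with m+1 categories.
    Thresholds need not be ordered: reversals simply mean some category is
    never the single most likely one.
    """

    item_id: str
    alpha: float
    betas: tuple[float, ...]

    def __post_init__(self):
        object.__setattr__(self, "alpha", float(self.alpha))
        object.__setattr__(self, "betas", tuple(float(b) for b in self.betas))
        if not np.isfinite(self.alpha) or self.alpha < 0:
            raise ValidationError(f"{self.item_id}: discrimination must be finite and >= 0")
        if len(self.betas) == 0 or not all(np.isfinite(b) for b in self.betas):
            raise ValidationError(f"{self.item_id}: thresholds must be finite and non-empty")

    @property
    def n_categories(self) -> int:
        return len(self.betas) + 1


@dataclass(frozen=True)
class ItemBank:
    """An ordered collection of GPCM items sharing one latent trait.

    The latent-trait distribution is standard normal, the conventional
    identification of the GPCM scale.
    """

    items: tuple[GPCMItemParams, ...]

    def __init__(self, items: Sequence[GPCMItemParams]):
        items = tuple(items)
        if not items:
            raise ValidationError("item bank is empty")
        ids = [it.item_id for it in items]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate item ids in bank")
        object.__setattr__(self, "items", items)

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self):
        return iter(self.items)

    def __getitem__(self, item_id: str) -> GPCMItemParams:
        for it in self.items:
            if it.item_id == item_id:
                return it
        raise KeyError(item_id)

    @property
    def item_ids(self) -> list[str]:
        return [it.item_id for it in self.items]

    def subset(self, item_ids: Sequence[str]) -> "ItemBank":
        return ItemBank([self[i] for i in item_ids])

    # -- serialization -------------------------------------------------
    @classmethod
    def from_json(cls, path: str | Path) -> "ItemBank":
        with open(path) as fh:
            payload = json.load(fh)
        return cls._from_payload(payload)

    @classmethod
    def _from_payload(cls, payload: dict) -> "ItemBank":
        return cls(
            [
                GPCMItemParams(d["item_id"], d["alpha"], d["betas"])
                for d in payload["items"]
            ]
        )

    def to_json(self, path: str | Path, **meta) -> None:
        payload = dict(meta)
        payload["items"] = [
            {"item_id": it.item_id, "alpha": it.alpha, "betas": list(it.betas)}
            for it in self.items
        ]
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def load_spd10_bank() -> ItemBank:
    """The published GPCM calibration of the ten SPD-10 items."""
    ref = resources.files("scaleshort").joinpath("calibration/spd10_gpcm.json")
    return ItemBank._from_payload(json.loads(ref.read_text()))


def gpcm_category_probs(p: GPCMItemParams, theta) -> np.ndarray:
    """GPCM category probabilities at the given trait value(s).

    Returns an array of m+1 probabilities (categories 0..m) for scalar
    theta, or shape (len(theta), m+1) for a vector.
    """
    th = np.asarray(theta, dtype=float)
    if not np.all(np.isfinite(th)):
        raise ValidationError("theta must be finite")
    scalar = th.ndim == 0
    th = np.atleast_1d(th)
    steps = p.alpha * (th[:, None] - np.asarray(p.betas)[None, :])  # (n, m)
    cum = np.concatenate([np.zeros((th.size, 1)), np.cumsum(steps, axis=1)], axis=1)
    cum -= cum.max(axis=1, keepdims=True)
    e = np.exp(cum)
    probs = e / e.sum(axis=1, keepdims=True)
    return probs[0] if scalar else probs


def simulate_thetas(n: int, seed: int | np.random.Generator) -> np.ndarray:
    """Draw n latent traits from the standard normal, reproducibly."""
    if n < 1:
        raise ValidationError("need at least one person")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.standard_normal(n)


def simulate_responses(
    bank: ItemBank,
    thetas: np.ndarray,
    seed: int | np.random.Generator,
    person_ids: Sequence | None = None,
) -> ResponseMatrix:
    """Draw a response matrix: one GPCM draw per person-item, coded 1..m+1."""
    thetas = np.asarray(thetas, dtype=float)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = thetas.size
    cols = {}
    for it in bank:
        probs = gpcm_category_probs(it, thetas)  # (n, m+1)
        u = rng.random((n, 1))
        cats = (probs.cumsum(axis=1) < u).sum(axis=1)  # inverse-CDF draw, 0..m
        cols[it.item_id] = cats + 1
    n_cat = max(it.n_categories for it in bank)
    values = np.column_stack([cols[i] for i in bank.item_ids])
    return ResponseMatrix(values, item_ids=bank.item_ids, person_ids=person_ids,
                          n_categories=n_cat)
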