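"""Optimal test assembly: anchored-information subset search and short-form
evaluation.

Stage one fixes the form length k and finds the item subset maximizing the
test information function evaluated at a small set of trait anchors
(default -3, -1, 0, 1, 3; objective = sum over anchors, with a maximin
alternative).  The search is an exact branch-and-bound over include/exclude
decisions; under the default separable objective with a single cardinality
constraint the optimum provably equals the top-k items by anchor-summed
item information, which serves as an internal cross-check.

Stage two evaluates each candidate length against reliability and
concurrent-validity criteria -- Cronbach alpha at least a fixed fraction
(default 95%) of the full form's, and correlations of at least 0.95 between
short- and full-form total scores and factor (EAP) scores -- and keeps the
shortest passing form.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .ctt import cronbach_alpha
from .data import ResponseMatrix, ScaleDefinition, ValidationError, standardized_scores
from .gpcm import eap_scores, item_information
from .simulate import ItemBank

__all__ = [
    "AssemblyProblem",
    "ShortFormEvaluation",
    "assemble",
    "evaluate_short_form",
    "select_optimal_length",
    "first_passing",
    "passes_criteria",
]

DEFAULT_ANCHORS = (-3.0, -1.0, 0.0, 1.0, 3.0)


@dataclass(frozen=True)
class AssemblyProblem:
    """A fixed-length assembly task over an item bank."""

    bank: ItemBank
    k: int
    anchors: tuple[float, ...] = DEFAULT_ANCHORS
    objective: str = "sum"  # "sum" | "maximin"

    def __post_init__(self):
        if not (3 <= self.k <= len(self.bank)):
            raise ValidationError(
                f"form length {self.k} outside [3, {len(self.bank)}]"
            )
        if not self.anchors:
            raise ValidationError("need at least one anchor")
        if self.objective not in ("sum", "maximin"):
            raise ValidationError(f"unknown objective {self.objective!r}")


def _anchor_info(bank: ItemBank, anchors: Sequence[float]) -> np.ndarray:
    """Item information at each anchor; shape (n_items, n_anchors)."""
    return np.array(
        [[item_information(it, a) for a in anchors] for it in bank]
    )


def _objective(info_rows: np.ndarray, objective: str) -> float:
    tif = info_rows.sum(axis=0)
    return float(tif.sum()) if objective == "sum" else float(tif.min())


def assemble(prob: AssemblyProblem) -> ScaleDefinition:
    """Exact branch-and-bound search for the information-optimal subset.

    Depth-first include/exclude search with an additive upper bound (current
    information plus the best still-selectable items); ties on the objective
    resolve to the lexicographically smallest item-index set, so the result
    is deterministic.
    """
    info = _anchor_info(prob.bank, prob.anchors)  # (J, A)
    J, k = len(prob.bank), prob.k

    # per-item scalar used for bounding; exact for the separable sum objective
    scores = info.sum(axis=1)
    # suffix_best[i][r] = sum of the r largest scores among items i..J-1
    best_state = {"obj": -np.inf, "set": None}

    def bound(i: int, chosen: list[int], current: np.ndarray) -> float:
        need = k - len(chosen)
        remaining = sorted(scores[i:], reverse=True)[:need]
        if prob.objective == "sum":
            return float(current.sum()) + float(np.sum(remaining))
        # maximin: optimistic bound adds the best remaining rows everywhere
        return float(current.min()) + float(np.sum(remaining))

    def dfs(i: int, chosen: list[int], current: np.ndarray):
        if len(chosen) == k:
            obj = _objective(info[chosen], prob.objective)
            if obj > best_state["obj"] + 1e-12 or (
                abs(obj - best_state["obj"]) <= 1e-12
                and (best_state["set"] is None or chosen < best_state["set"])
            ):
                best_state["obj"] = obj
                best_state["set"] = list(chosen)
            return
        if i == J or J - i < k - len(chosen):
            return
        if bound(i, chosen, current) < best_state["obj"] - 1e-12:
            return
        # include item i first (items come pre-sorted by promise below)
        chosen.append(i)
        dfs(i + 1, chosen, current + info[i])
        chosen.pop()
        dfs(i + 1, chosen, current)

    dfs(0, [], np.zeros(info.shape[1]))
    idx = sorted(best_state["set"])
    return ScaleDefinition([prob.bank.item_ids[i] for i in idx])


def top_k_by_anchor_info(bank: ItemBank, k: int,
                         anchors: Sequence[float] = DEFAULT_ANCHORS) -> ScaleDefinition:
    """Top-k items by anchor-summed information (the separable-case optimum)."""
    scores = _anchor_info(bank, anchors).sum(axis=1)
    order = sorted(range(len(bank)), key=lambda i: (-scores[i], i))
    return ScaleDefinition([bank.item_ids[i] for i in sorted(order[:k])])


@dataclass(frozen=True)
class ShortFormEvaluation:
    """Reliability and concurrent validity of a candidate short form."""

    k: int
    items: tuple[str, ...]
    cronbach_alpha: float
    corr_total: float
    corr_factor: float
    full_alpha: float
    passes: bool


def passes_criteria(alpha: float, full_alpha: float, corr_total: float, corr_factor: float,
                    alpha_ratio_min: float = 0.95, corr_min: float = 0.95) -> bool:
    """The stage-two acceptance rule for a candidate short form."""
    return (
        alpha >= alpha_ratio_min * full_alpha
        and corr_total >= corr_min
        and corr_factor >= corr_min
    )


def evaluate_short_form(
    m: ResponseMatrix,
    subset: ScaleDefinition,
    full: ScaleDefinition,
    bank: ItemBank,
    alpha_ratio_min: float = 0.95,
    corr_min: float = 0.95,
) -> ShortFormEvaluation:
    """Compare a short form against the full form on the same respondents.

    Computes the short form's Cronbach alpha and the Pearson correlations
    of its standardized total scores and EAP factor scores with the full
    form's.
    """
    unknown = [i for i in subset.item_ids if i not in full.item_ids]
    if unknown:
        raise ValidationError(f"short-form items not in the full form: {unknown}")
    alpha = cronbach_alpha(m, subset)
    full_alpha = cronbach_alpha(m, full)
    tot_s = standardized_scores(m, subset)
    tot_f = standardized_scores(m, full)
    corr_total = float(np.corrcoef(tot_s, tot_f)[0, 1])
    eap_s = eap_scores(bank, m, subset)
    eap_f = eap_scores(bank, m, full)
    corr_factor = float(np.corrcoef(eap_s, eap_f)[0, 1])
    return ShortFormEvaluation(
        k=len(subset),
        items=tuple(subset.item_ids),
        cronbach_alpha=alpha,
        corr_total=corr_total,
        corr_factor=corr_factor,
        full_alpha=full_alpha,
        passes=passes_criteria(alpha, full_alpha, corr_total, corr_factor,
                               alpha_ratio_min, corr_min),
    )


def first_passing(evaluations: Sequence[ShortFormEvaluation]) -> ShortFormEvaluation:
    """Shortest passing candidate; if none passes, the best by corr_total."""
    if not evaluations:
        raise ValidationError("no candidate evaluations")
    for ev in sorted(evaluations, key=lambda e: e.k):
        if ev.passes:
            return ev
    return max(evaluations, key=lambda e: e.corr_total)


def select_optimal_length(
    m: ResponseMatrix,
    bank: ItemBank,
    k_range: Sequence[int] = range(3, 11),
    anchors: Sequence[float] = DEFAULT_ANCHORS,
    objective: str = "sum",
    alpha_ratio_min: float = 0.95,
    corr_min: float = 0.95,
) -> tuple[ShortFormEvaluation, list[ShortFormEvaluation]]:
    """Assemble and evaluate every candidate length; keep the shortest passer.

    Returns (chosen, all candidate evaluations in ascending k).  When no
    candidate passes, the one with the highest total-score correlation is
    returned flagged as non-passing.
    """
    full = ScaleDefinition(bank.item_ids, m.n_categories, m.min_category)
    evals = []
    for k in sorted(set(int(k) for k in k_range)):
        subset = assemble(AssemblyProblem(bank, k, tuple(anchors), objective))
        evals.append(
            evaluate_short_form(m, subset, full, bank,
                                alpha_ratio_min=alpha_ratio_min, corr_min=corr_min)
        )
    return first_passing(evals), evals


def candidate_table(evaluations: Sequence[ShortFormEvaluation]) -> pd.DataFrame:
    """Candidate short forms as a tidy table (one row per length)."""
    return pd.DataFrame(
        {
            "k": [e.k for e in evaluations],
            "items": [" ".join(e.items) for e in evaluations],
            "cronbach_alpha": [e.cronbach_alpha for e in evaluations],
            "corr_factor": [e.corr_factor for e in evaluations],
            "corr_total": [e.corr_total for e in evaluations],
            "passes": [e.passes for e in evaluations],
        }
    )
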