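from itertools import combinations

import numpy as np
import pytest

import scaleshort as ss
from scaleshort.data import ValidationError
from scaleshort.gpcm import item_information
from scaleshort.ota import (
    DEFAULT_ANCHORS,
    AssemblyProblem,
    ShortFormEvaluation,
    assemble,
    evaluate_short_form,
    first_passing,
    passes_criteria,
    select_optimal_length,
    top_k_by_anchor_info,
)
from scaleshort.simulate import GPCMItemParams, ItemBank

SPD7 = ("CRF1", "CRF2", "CRF3", "CRF4", "CRF6", "CRF8", "CRF9")


def exhaustive_best(bank, k, anchors, objective="sum"):
    """Oracle: enumerate every size-k subset and keep the best objective."""
    info = np.array([[item_information(it, a) for a in anchors] for it in bank])
    best, best_set = -np.inf, None
    for combo in combinations(range(len(bank)), k):
        tif = info[list(combo)].sum(axis=0)
        obj = tif.sum() if objective == "sum" else tif.min()
        if obj > best + 1e-12:
            best, best_set = obj, combo
    return best, set(bank.item_ids[i] for i in best_set)


class TestAssemble:
    def test_full_bank_trivial(self, spd10_bank):
        sel = assemble(AssemblyProblem(spd10_bank, 10))
        assert tuple(sel.item_ids) == tuple(spd10_bank.item_ids)

    @pytest.mark.parametrize("k", range(3, 11))
    def test_matches_exhaustive_enumeration(self, spd10_bank, k):
        prob = AssemblyProblem(spd10_bank, k)
        sel = assemble(prob)
        info = np.array(
            [[item_information(spd10_bank[i], a) for a in DEFAULT_ANCHORS]
             for i in sel.item_ids]
        )
        best, _ = exhaustive_best(spd10_bank, k, DEFAULT_ANCHORS)
        assert info.sum() == pytest.approx(best, rel=1e-12)

    @pytest.mark.parametrize("k", range(3, 11))
    def test_reduces_to_top_k_under_sum_objective(self, spd10_bank, k):
        sel = assemble(AssemblyProblem(spd10_bank, k))
        top = top_k_by_anchor_info(spd10_bank, k)
        assert sel.item_ids == top.item_ids

    def test_seven_item_optimum_is_short_form(self, spd10_bank):
        sel = assemble(AssemblyProblem(spd10_bank, 7))
        assert tuple(sel.item_ids) == SPD7

    def test_objective_strictly_increasing_in_k(self, spd10_bank):
        values = []
        for k in range(3, 11):
            sel = assemble(AssemblyProblem(spd10_bank, k))
            tif = sum(
                item_information(spd10_bank[i], a)
                for i in sel.item_ids for a in DEFAULT_ANCHORS
            )
            values.append(tif)
        assert np.all(np.diff(values) > 0)

    def test_maximin_optimum_need_not_be_nested(self):
        # two items informative low, two high, one balanced in the middle:
        # the balanced item enters the maximin optimum at k=3 but leaves at k=4
        bank = ItemBank(
            [
                GPCMItemParams("L1", 2.0, (-2.0, -2.0, -2.0, -2.0)),
                GPCMItemParams("L2", 1.8, (-2.0, -2.0, -2.0, -2.0)),
                GPCMItemParams("R1", 2.0, (2.0, 2.0, 2.0, 2.0)),
                GPCMItemParams("R2", 1.8, (2.0, 2.0, 2.0, 2.0)),
                GPCMItemParams("M", 1.2, (0.0, 0.0, 0.0, 0.0)),
            ]
        )
        anchors = (-2.0, 2.0)
        _, best3 = exhaustive_best(bank, 3, anchors, "maximin")
        _, best4 = exhaustive_best(bank, 4, anchors, "maximin")
        assert not best3 <= best4  # the oracle itself shows non-nesting
        sel3 = assemble(AssemblyProblem(bank, 3, anchors, "maximin"))
        sel4 = assemble(AssemblyProblem(bank, 4, anchors, "maximin"))
        assert set(sel3.item_ids) == best3
        assert set(sel4.item_ids) == best4

    def test_invalid_k_rejected(self, spd10_bank):
        with pytest.raises(ValidationError):
            AssemblyProblem(spd10_bank, 2)
        with pytest.raises(ValidationError):
            AssemblyProblem(spd10_bank, 11)


class TestEvaluateShortForm:
    def test_subset_equal_full_is_perfect(self, spd10_bank, sim164):
        full = sim164.full_scale()
        ev = evaluate_short_form(sim164, full, full, spd10_bank)
        assert ev.corr_total == pytest.approx(1.0)
        assert ev.corr_factor == pytest.approx(1.0)
        assert ev.cronbach_alpha == pytest.approx(ev.full_alpha)
        assert ev.passes

    def test_noise_only_subset_fails(self):
        strong = [GPCMItemParams(f"s{j}", 1.5, (-1.0, -0.5, 0.5, 1.0)) for j in range(5)]
        noise = [GPCMItemParams(f"n{j}", 0.01, (-1.0, -0.5, 0.5, 1.0)) for j in range(3)]
        bank = ItemBank(strong + noise)
        th = ss.simulate_thetas(400, 41)
        m = ss.simulate_responses(bank, th, 42)
        ev = evaluate_short_form(
            m, ss.ScaleDefinition([i.item_id for i in noise]), m.full_scale(), bank
        )
        assert ev.corr_total < 0.5
        assert not ev.passes

    def test_short_form_beats_all_triplets(self, spd10_bank):
        # total-score agreement grows with form length: the 7-item form should
        # outperform every 3-item subset on most instrument-sized samples
        wins = 0
        for seed in range(50):
            th = ss.simulate_thetas(164, 3000 + seed)
            m = ss.simulate_responses(spd10_bank, th, 4000 + seed)
            full_tot = ss.standardized_scores(m)
            spd7_tot = ss.standardized_scores(m, ss.ScaleDefinition(SPD7))
            r7 = np.corrcoef(spd7_tot, full_tot)[0, 1]
            best3 = max(
                np.corrcoef(
                    ss.standardized_scores(m, ss.ScaleDefinition(trip)), full_tot
                )[0, 1]
                for trip in combinations(spd10_bank.item_ids, 3)
            )
            if r7 > best3:
                wins += 1
        assert wins >= 26

    def test_unknown_subset_item_rejected(self, spd10_bank, sim164):
        with pytest.raises(ValidationError):
            evaluate_short_form(
                sim164,
                ss.ScaleDefinition(["CRF1", "CRF99", "CRF3"]),
                ss.ScaleDefinition(["CRF1", "CRF3"]),
                spd10_bank,
            )


def _published_candidates():
    """Candidate evaluations built from the published per-length statistics."""
    stats = {
        3: (0.648, 0.892, 0.851), 4: (0.721, 0.923, 0.886), 5: (0.733, 0.952, 0.929),
        6: (0.758, 0.962, 0.938), 7: (0.778, 0.980, 0.957), 8: (0.797, 0.990, 0.971),
        9: (0.808, 0.999, 0.987), 10: (0.795, 1.000, 1.000),
    }
    full_alpha = 0.795
    out = []
    for k, (alpha, r_factor, r_total) in stats.items():
        out.append(
            ShortFormEvaluation(
                k=k, items=tuple(f"item{j}" for j in range(k)),
                cronbach_alpha=alpha, corr_total=r_total, corr_factor=r_factor,
                full_alpha=full_alpha,
                passes=passes_criteria(alpha, full_alpha, r_total, r_factor),
            )
        )
    return out


class TestLengthSelection:
    def test_published_statistics_select_seven(self):
        chosen = first_passing(_published_candidates())
        assert chosen.k == 7

    def test_zero_thresholds_select_smallest(self, spd10_bank, sim164):
        chosen, _ = select_optimal_length(
            sim164, spd10_bank, alpha_ratio_min=0.0, corr_min=0.0
        )
        assert chosen.k == 3

    def test_impossible_criteria_flagged(self, spd10_bank, sim164):
        chosen, evals = select_optimal_length(
            sim164, spd10_bank, corr_min=1.01
        )
        assert not chosen.passes
        assert chosen.corr_total == max(e.corr_total for e in evals)
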