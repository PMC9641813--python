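import numpy as np
import pytest

import scaleshort as ss
from scaleshort.data import ValidationError
from scaleshort.gpcm import (
    GPCM,
    average_item_information,
    eap_scores,
    item_information,
    test_information as tif,
)
from scaleshort.simulate import GPCMItemParams, gpcm_category_probs

SPD7 = ["CRF1", "CRF2", "CRF3", "CRF4", "CRF6", "CRF8", "CRF9"]


class TestItemInformation:
    def test_zero_discrimination(self):
        p = GPCMItemParams("x", 0.0, (-1, 0, 1, 2))
        for theta in (-3, 0, 2.5):
            assert item_information(p, theta) == 0.0

    def test_matches_finite_difference_oracle(self, spd10_bank):
        # -d^2 log P_c / d theta^2 is category-free for the GPCM and equals
        # the Fisher information; check against central differences
        h = 1e-4
        for item in spd10_bank:
            for theta in (-2.0, 0.0, 1.5):
                for c in range(5):
                    lp = [
                        np.log(gpcm_category_probs(item, t)[c])
                        for t in (theta - h, theta, theta + h)
                    ]
                    fd = -(lp[0] - 2 * lp[1] + lp[2]) / h**2
                    assert item_information(item, theta) == pytest.approx(fd, abs=1e-5)

    def test_flat_item_dominated_everywhere(self, spd10_bank):
        grid = np.linspace(-3, 3, 61)
        weak = item_information(spd10_bank["CRF7"], grid)
        strong = item_information(spd10_bank["CRF6"], grid)
        assert np.all(weak < strong)


class TestAverageInformation:
    def test_zero_discrimination(self):
        assert average_item_information(GPCMItemParams("x", 0.0, (0, 0, 0, 0))) == 0.0

    def test_flat_item_reference_value(self, spd10_bank):
        assert average_item_information(spd10_bank["CRF7"]) == pytest.approx(0.05, abs=0.02)

    def test_quadrature_matches_monte_carlo(self, spd10_bank):
        item = spd10_bank["CRF3"]
        rng = np.random.default_rng(17)
        draws = item_information(item, rng.standard_normal(1_000_000))
        mc, se = draws.mean(), draws.std() / 1000.0
        assert average_item_information(item) == pytest.approx(mc, abs=3 * se)

    def test_grid_must_cover_working_range(self, spd10_bank):
        with pytest.raises(ValidationError):
            average_item_information(spd10_bank["CRF1"], grid=np.linspace(-2, 2, 100))


class TestTestInformation:
    def test_additivity(self, spd10_bank):
        grid = np.linspace(-3, 3, 25)
        full = tif(spd10_bank, None, grid)
        sub = tif(spd10_bank, SPD7, grid)
        comp = tif(
            spd10_bank, [i for i in spd10_bank.item_ids if i not in SPD7], grid
        )
        np.testing.assert_allclose(full, sub + comp, rtol=1e-12)

    def test_single_item_subset(self, spd10_bank):
        assert tif(spd10_bank, ["CRF4"], 0.7) == pytest.approx(
            item_information(spd10_bank["CRF4"], 0.7)
        )

    def test_short_form_value_matches_hand_sum(self, spd10_bank):
        total = sum(item_information(spd10_bank[i], 0.0) for i in SPD7)
        assert tif(spd10_bank, SPD7, 0.0) == pytest.approx(total, rel=1e-12)

    def test_unknown_item_rejected(self, spd10_bank):
        with pytest.raises(KeyError):
            tif(spd10_bank, ["CRF99"], 0.0)


class TestEAP:
    def test_extreme_patterns_ordered(self, spd10_bank):
        m = ss.ResponseMatrix(
            np.vstack([np.ones(10, dtype=int), np.full(10, 5)]),
            item_ids=spd10_bank.item_ids,
        )
        lo, hi = eap_scores(spd10_bank, m)
        assert lo < hi

    def test_item_order_invariance(self, spd10_bank, sim164):
        a = eap_scores(spd10_bank, sim164, SPD7)
        b = eap_scores(spd10_bank, sim164, list(reversed(SPD7)))
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_recovers_latent_trait(self, spd10_bank):
        thetas = ss.simulate_thetas(5000, 23)
        m = ss.simulate_responses(spd10_bank, thetas, 24)
        est = eap_scores(spd10_bank, m)
        assert np.corrcoef(est, thetas)[0, 1] > 0.75


class TestFit:
    def test_loglik_nondecreasing_and_converges(self, sim164):
        res = GPCM(sim164).fit()
        assert res.converged
        assert np.all(np.diff(res.loglik_history) > -1e-8)

    def test_row_permutation_invariance(self, sim164):
        perm = np.random.default_rng(2).permutation(sim164.n_persons)
        shuffled = ss.ResponseMatrix(sim164.values[perm], item_ids=sim164.item_ids)
        a = GPCM(sim164).fit()
        b = GPCM(shuffled).fit()
        for ia, ib in zip(a.bank, b.bank):
            assert ia.alpha == pytest.approx(ib.alpha, abs=1e-6)
            np.testing.assert_allclose(ia.betas, ib.betas, atol=1e-5)

    def test_parameter_recovery_moderate_sample(self, spd10_bank):
        ests = {i: [] for i in spd10_bank.item_ids}
        for seed in range(3):
            th = ss.simulate_thetas(2000, 300 + seed)
            m = ss.simulate_responses(spd10_bank, th, 400 + seed)
            res = GPCM(m).fit()
            for it in res.bank:
                ests[it.item_id].append(it.alpha)
        for item in spd10_bank:
            if item.alpha >= 0.4:
                assert np.mean(ests[item.item_id]) == pytest.approx(item.alpha, abs=0.2)

    def test_rmse_decreases_with_sample_size(self, spd10_bank):
        truth = np.array([it.alpha for it in spd10_bank])
        rmse = []
        for n, base in ((300, 50), (2000, 60), (8000, 70)):
            errs = []
            for seed in range(3):
                th = ss.simulate_thetas(n, base + seed)
                m = ss.simulate_responses(spd10_bank, th, base + 10 + seed)
                est = np.array([it.alpha for it in GPCM(m).fit().bank])
                errs.append((est - truth) ** 2)
            rmse.append(np.sqrt(np.mean(errs)))
        assert rmse[0] > rmse[1] > rmse[2]

    def test_unobserved_category_collapsed(self, spd10_bank):
        th = ss.simulate_thetas(200, 5)
        m = ss.simulate_responses(spd10_bank, th, 6)
        vals = m.values.copy()
        # force category 5 of the first item to never occur
        vals[:, 0] = np.minimum(vals[:, 0], 4)
        m2 = ss.ResponseMatrix(vals, item_ids=m.item_ids)
        res = GPCM(m2).fit()
        assert res.collapsed_categories == {"CRF1": [4]}
        assert res.bank["CRF1"].n_categories == 4
        assert res.converged

    def test_constant_item_rejected(self):
        vals = np.column_stack([np.full(50, 3), np.random.default_rng(0).integers(1, 6, 50),
                                np.random.default_rng(1).integers(1, 6, 50)])
        with pytest.raises(ValidationError, match="constant"):
            GPCM(ss.ResponseMatrix(vals)).fit()


class TestReliabilityLink:
    def test_marginal_reliability_close_to_alpha(self, spd10_bank, sim_large):
        # 1 - 1/(1 + average TIF) versus Cronbach alpha on a large sample
        tif_bar = sum(average_item_information(it) for it in spd10_bank)
        rho = 1 - 1 / (1 + tif_bar)
        assert abs(rho - ss.cronbach_alpha(sim_large)) < 0.05
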