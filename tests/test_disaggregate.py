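"""Claim/non-claim disaggregation: shares, splits, conservation."""

import math

import numpy as np
import pytest

import hrcimpact as h
from hrcimpact.config import ConfigError, Estimate, GroupHRCParams
from hrcimpact.disaggregate import hrc_sales_share, split_group
from hrcimpact.nutrients import NUTRIENTS, FoodGroup, NutrientVector


def simulate_share(q, or_choice, n_choices, seed, shelf_size=2000):
    """Discrete-choice oracle: multinomial purchases from a synthetic shelf.

    Claim items get choice weight ``or_choice``, non-claim items weight 1;
    returns the claim share among simulated purchases and the realised
    shelf prevalence.
    """
    rng = np.random.default_rng(seed)
    flags = rng.random(shelf_size) < q
    k = flags.sum()
    if k in (0, shelf_size):
        return float(k > 0), k / shelf_size
    w = np.where(flags, or_choice, 1.0)
    chosen = rng.choice(shelf_size, size=n_choices, p=w / w.sum())
    return float(flags[chosen].mean()), k / shelf_size


class TestSalesShare:
    @pytest.mark.parametrize("q", [0.0, 0.1, 0.31, 0.5, 0.9, 1.0])
    def test_unit_or_gives_share_equal_prevalence(self, q):
        assert hrc_sales_share(q, 1.0) == pytest.approx(q)

    def test_boundaries(self):
        assert hrc_sales_share(0.0, 2.5) == 0.0
        assert hrc_sales_share(1.0, 2.5) == 1.0

    def test_fruit_veg_worked_value(self):
        s = hrc_sales_share(0.31, 1.92)
        assert s == pytest.approx(0.31 * 1.92 / (0.31 * 1.92 + 0.69), abs=1e-12)
        assert s == pytest.approx(0.4631, abs=5e-4)

    def test_strictly_increasing_in_q_and_or(self):
        assert hrc_sales_share(0.32, 1.92) > hrc_sales_share(0.31, 1.92)
        assert hrc_sales_share(0.31, 2.0) > hrc_sales_share(0.31, 1.92)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            hrc_sales_share(1.2, 1.0)
        with pytest.raises(ValueError):
            hrc_sales_share(0.5, 0.0)

    def test_matches_choice_simulation_fruit_veg(self):
        """10^6 simulated shelf choices reproduce the closed-form share."""
        sim, q_shelf = simulate_share(0.31, 1.92, 1_000_000, seed=0)
        expected = hrc_sales_share(q_shelf, 1.92)
        se = math.sqrt(expected * (1 - expected) / 1_000_000)
        assert abs(sim - expected) <= 3 * se

    def test_matches_choice_simulation_random_pairs(self):
        rng = np.random.default_rng(123)
        for i in range(20):
            q = rng.uniform(0.05, 0.9)
            orc = rng.uniform(0.3, 4.0)
            sim, q_shelf = simulate_share(q, orc, 100_000, seed=1000 + i)
            expected = hrc_sales_share(q_shelf, orc)
            se = math.sqrt(max(expected * (1 - expected), 1e-9) / 100_000)
            assert abs(sim - expected) <= 3 * se + 1e-9


class TestSplitGroup:
    def test_homogeneous_group(self):
        """NQR=1 everywhere: both streams share one concentration."""
        sp = split_group(FoodGroup.DAIRY, 400.0,
                         NutrientVector(energy_kcal=600), 0.3, 1.5, {})
        assert sp.conc_hrc["energy_kcal"] == pytest.approx(150.0)
        assert sp.conc_non["energy_kcal"] == pytest.approx(150.0)

    def test_zero_prevalence_all_nonclaim(self):
        sp = split_group(FoodGroup.DAIRY, 400.0,
                         NutrientVector(energy_kcal=600), 0.0, 1.5, {})
        assert sp.intake_hrc["energy_kcal"] == 0.0
        assert sp.intake_non["energy_kcal"] == pytest.approx(600.0)

    def test_toy_algebraic_solution(self):
        """500 g, 800 kcal, q=0.5, OR=1, NQR(energy)=0.5:
        s=0.5; conc_non solves 800 = 2.5*(0.5*c) + 2.5*c -> c = 213.33."""
        sp = split_group(FoodGroup.STARCHY, 500.0,
                         NutrientVector(energy_kcal=800), 0.5, 1.0,
                         {"energy_kcal": 0.5})
        assert sp.s_hrc == pytest.approx(0.5)
        assert sp.conc_non["energy_kcal"] == pytest.approx(213.3333, abs=1e-3)
        assert sp.conc_hrc["energy_kcal"] == pytest.approx(106.6667, abs=1e-3)
        total = sp.intake_hrc["energy_kcal"] + sp.intake_non["energy_kcal"]
        assert total == pytest.approx(800.0, rel=1e-12)

    def test_nqr_relation_holds_for_every_nutrient(self):
        nqr = {n: 0.6 + 0.05 * i for i, n in enumerate(NUTRIENTS)}
        intake = NutrientVector.from_mapping(
            {n: 10.0 + i for i, n in enumerate(NUTRIENTS)})
        sp = split_group(FoodGroup.HFSS, 250.0, intake, 0.4, 1.3, nqr)
        for n in NUTRIENTS:
            assert sp.conc_hrc[n] == pytest.approx(nqr[n] * sp.conc_non[n])

    def test_zero_sales_with_intake_is_error(self):
        with pytest.raises(ConfigError):
            split_group(FoodGroup.MISC, 0.0, NutrientVector(energy_kcal=5),
                        0.2, 1.0, {})

    def test_zero_sales_zero_intake_is_empty_split(self):
        sp = split_group(FoodGroup.MISC, 0.0, NutrientVector(), 0.2, 1.0, {})
        assert sp.sales_total_g == 0.0


def _random_config(rng):
    params, sales, nqr = {}, h.SalesTable(), h.NQRTable()
    for g in FoodGroup:
        q = rng.uniform(0.02, 0.95)
        orc = 1.0 if g is FoodGroup.MISC else rng.uniform(0.3, 4.0)
        params[g] = GroupHRCParams(g, Estimate.exact(orc), Estimate.exact(q),
                                   Estimate.exact(q / 2), Estimate.exact(q / 2))
        intake = NutrientVector.from_mapping(
            {n: rng.uniform(0.1, 500.0) for n in NUTRIENTS})
        sales.records[g] = h.SalesRecord(g, rng.uniform(5.0, 600.0), intake)
        for n in NUTRIENTS:
            nqr.set(g, "baseline", n, rng.uniform(0.2, 3.0))
    return params, sales, nqr


class TestBaselineDisaggregation:
    def test_conservation_over_random_configs(self):
        """100 random configurations reconstruct sales and every nutrient
        total to 1e-9 relative."""
        rng = np.random.default_rng(2024)
        for _ in range(100):
            params, sales, nqr = _random_config(rng)
            state = h.baseline_disaggregate(sales, params, nqr)
            assert state.total_sales() == pytest.approx(
                sales.total_sales(), rel=1e-9)
            want = sales.total_intake()
            got = state.total_intake()
            for n in NUTRIENTS:
                assert got[n] == pytest.approx(want[n], rel=1e-9)

    def test_zero_prevalence_gives_zero_hrc_share(self):
        rng = np.random.default_rng(7)
        params, sales, nqr = _random_config(rng)
        params = {
            g: GroupHRCParams(g, p.or_choice, Estimate.exact(0.0),
                              Estimate.exact(0.0), Estimate.exact(0.0))
            for g, p in params.items()
        }
        state = h.baseline_disaggregate(sales, params, nqr)
        assert state.hrc_sales() == 0.0

    def test_or_increase_moves_intake_between_streams(self):
        rng = np.random.default_rng(8)
        params, sales, nqr = _random_config(rng)
        state = h.baseline_disaggregate(sales, params, nqr)
        g = FoodGroup.DAIRY
        boosted = dict(params)
        p = params[g]
        boosted[g] = GroupHRCParams(g, Estimate.exact(p.or_choice.point * 1.5),
                                    p.q_baseline, p.q_pass_fsanz, p.q_pass_eu)
        state2 = h.baseline_disaggregate(sales, boosted, nqr)
        assert state2.groups[g].intake_hrc["energy_kcal"] > \
            state.groups[g].intake_hrc["energy_kcal"]
        assert state2.groups[g].intake_non["energy_kcal"] < \
            state.groups[g].intake_non["energy_kcal"]
        assert state2.groups[g].intake_total()["energy_kcal"] == pytest.approx(
            state.groups[g].intake_total()["energy_kcal"], rel=1e-12)

    def test_single_group_matches_split_group(self):
        sales = h.SalesTable()
        sales.records[FoodGroup.STARCHY] = h.SalesRecord(
            FoodGroup.STARCHY, 500.0, NutrientVector(energy_kcal=800))
        params = {FoodGroup.STARCHY: GroupHRCParams(
            FoodGroup.STARCHY, Estimate.exact(1.0), Estimate.exact(0.5),
            Estimate.exact(0.25), Estimate.exact(0.25))}
        nqr = h.NQRTable()
        nqr.set(FoodGroup.STARCHY, "baseline", "energy_kcal", 0.5)
        state = h.baseline_disaggregate(sales, params, nqr)
        direct = split_group(FoodGroup.STARCHY, 500.0,
                             NutrientVector(energy_kcal=800), 0.5, 1.0,
                             nqr.ratios(FoodGroup.STARCHY, "baseline"))
        assert state.groups[FoodGroup.STARCHY] == direct

    def test_calibrated_baseline_reproduces_study_shares(self, baseline_state):
        """Claim foods ~37% of purchase grams and ~29% of energy."""
        assert 100 * baseline_state.hrc_purchase_share() == pytest.approx(37, abs=2)
        assert 100 * baseline_state.hrc_energy_share() == pytest.approx(29, abs=2)
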