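"""Counterfactual scenario builders and diet deltas."""

import numpy as np
import pytest

import hrcimpact as h
from hrcimpact.config import ConfigError, Estimate, GroupHRCParams
from hrcimpact.disaggregate import split_group
from hrcimpact.nutrients import NUTRIENTS, FoodGroup, NutrientVector


def _toy_baseline(q=0.5, orc=1.0, nqr_energy=0.5, sales=500.0, kcal=800.0):
    state = h.DietState()
    state.groups[FoodGroup.STARCHY] = split_group(
        FoodGroup.STARCHY, sales, NutrientVector(energy_kcal=kcal), q, orc,
        {"energy_kcal": nqr_energy},
    )
    return state


def _toy_params(q=0.5, orc=1.0):
    return {FoodGroup.STARCHY: GroupHRCParams(
        FoodGroup.STARCHY, Estimate.exact(orc), Estimate.exact(q),
        Estimate.exact(q / 2), Estimate.exact(q / 2))}


def _toy_nqr(variant_value, variant="pass_fsanz", baseline_value=0.5):
    t = h.NQRTable()
    t.set(FoodGroup.STARCHY, "baseline", "energy_kcal", baseline_value)
    t.set(FoodGroup.STARCHY, variant, "energy_kcal", variant_value)
    return t


class TestNullIdentities:
    def test_restricted_null_is_exact(self, cfg_calibrated, baseline_state):
        q_base = {g: p.q_baseline.point
                  for g, p in cfg_calibrated.hrc_params.items()}
        null = h.build_restricted(
            baseline_state, q_base, cfg_calibrated.nqr, "baseline",
            cfg_calibrated.hrc_params)
        delta = h.diet_delta(null, baseline_state)
        assert all(v == 0.0 for v in delta.values.values())

    def test_reformulated_null_is_exact(self, cfg_calibrated, baseline_state):
        null = h.build_reformulated(baseline_state, cfg_calibrated.nqr, "baseline")
        delta = h.diet_delta(null, baseline_state)
        assert all(v == 0.0 for v in delta.values.values())

    def test_null_deaths_are_exactly_zero(self, cfg_calibrated, baseline_state):
        null = h.build_reformulated(baseline_state, cfg_calibrated.nqr, "baseline")
        res = h.deaths_averted(h.diet_delta(null, baseline_state), cfg_calibrated)
        assert res.total == 0.0 and res.total_with_energy == 0.0
        assert all(v == 0.0 for v in res.by_cell.values())
        assert all(v == 0.0 for v in res.by_risk_factor.values())


class TestRestricted:
    def test_zero_pass_prevalence_removes_claim_stream(self):
        base = _toy_baseline()
        out = h.build_restricted(base, {FoodGroup.STARCHY: 0.0},
                                 _toy_nqr(0.4), "pass_fsanz", _toy_params())
        sp = out.groups[FoodGroup.STARCHY]
        assert sp.intake_hrc["energy_kcal"] == 0.0
        assert sp.intake_non["energy_kcal"] == pytest.approx(
            sp.sales_total_g * sp.conc_non["energy_kcal"] / 100)

    def test_toy_pinned_value(self):
        """q=0.5,OR=1,NQR=0.5 baseline (conc_non=213.33); restrict to
        q'=0.25, NQR'=0.4: intake = 5*(0.25*0.4 + 0.75)*213.33 = 906.67."""
        base = _toy_baseline()
        out = h.build_restricted(base, {FoodGroup.STARCHY: 0.25},
                                 _toy_nqr(0.4), "pass_fsanz", _toy_params())
        e = out.total_intake()["energy_kcal"]
        conc_non = 800 * 100 / (250 * 0.5 + 250)
        assert e == pytest.approx(5 * (0.25 * 0.4 + 0.75) * conc_non, rel=1e-12)
        assert e == pytest.approx(906.6667, abs=1e-3)

    def test_group_sales_totals_unchanged(self, cfg_calibrated, baseline_state):
        out = h.run_scenario(cfg_calibrated, "1a", baseline=baseline_state)
        for g, sp in out.groups.items():
            assert sp.sales_total_g == pytest.approx(
                baseline_state.groups[g].sales_total_g, rel=1e-12)

    def test_nonclaim_concentration_held_at_baseline(self, cfg_calibrated,
                                                     baseline_state):
        out = h.run_scenario(cfg_calibrated, "1a", baseline=baseline_state)
        for g, sp in out.groups.items():
            assert sp.conc_non == baseline_state.groups[g].conc_non

    def test_prevalence_increase_rejected_without_override(self):
        base = _toy_baseline()
        with pytest.raises(ConfigError, match="exceeds baseline"):
            h.build_restricted(base, {FoodGroup.STARCHY: 0.8},
                               _toy_nqr(0.4), "pass_fsanz", _toy_params(q=0.5))

    def test_missing_pass_prevalence_is_config_error(self):
        base = _toy_baseline()
        with pytest.raises(ConfigError):
            h.build_restricted(base, {}, _toy_nqr(0.4), "pass_fsanz",
                               _toy_params())

    def test_energy_rises_when_healthier_claim_foods_lose_boost(
            self, cfg_calibrated, baseline_state):
        """Restriction with claim foods healthier than non-claim
        (NQR_energy < 1) and reduced prevalence raises energy intake —
        the central counterintuitive mechanism."""
        q_pass = {g: p.q_pass_fsanz.point
                  for g, p in cfg_calibrated.hrc_params.items()}
        out = h.build_restricted(baseline_state, q_pass, cfg_calibrated.nqr,
                                 "baseline", cfg_calibrated.hrc_params)
        delta = h.diet_delta(out, baseline_state)
        assert delta["energy_kcal"] > 0


class TestReformulated:
    def test_null_nqr_reproduces_baseline(self):
        base = _toy_baseline()
        out = h.build_reformulated(base, _toy_nqr(0.5), "pass_fsanz")
        assert out.groups == base.groups

    def test_energy_strictly_decreases_with_lower_pass_nqr(self):
        base = _toy_baseline(nqr_energy=0.8)
        out = h.build_reformulated(
            base, _toy_nqr(0.5, baseline_value=0.8), "pass_fsanz")
        assert out.total_intake()["energy_kcal"] < \
            base.total_intake()["energy_kcal"]

    def test_toy_pinned_value(self):
        """Baseline NQR 0.8 (conc_non=177.78, s=0.5); reformulate to
        NQR 0.5: intake = 5*(0.5*0.5+0.5)*177.78 = 666.67."""
        base = _toy_baseline(nqr_energy=0.8)
        out = h.build_reformulated(
            base, _toy_nqr(0.5, baseline_value=0.8), "pass_fsanz")
        assert out.total_intake()["energy_kcal"] == pytest.approx(
            666.6667, abs=1e-3)

    def test_sales_split_stays_at_baseline(self, cfg_calibrated, baseline_state):
        out = h.run_scenario(cfg_calibrated, "1b", baseline=baseline_state)
        for g, sp in out.groups.items():
            assert sp.s_hrc == baseline_state.groups[g].s_hrc

    def test_dominates_restriction_on_energy(self, cfg_calibrated,
                                             baseline_state):
        """With pass NQR(energy) <= 1, reformulation (model b) never ends
        with more energy than restriction (model a)."""
        a = h.run_scenario(cfg_calibrated, "1a", baseline=baseline_state)
        b = h.run_scenario(cfg_calibrated, "1b", baseline=baseline_state)
        assert b.total_intake()["energy_kcal"] <= a.total_intake()["energy_kcal"]


class TestUniformBoost:
    def test_zero_boost_equals_unit_or(self, cfg_calibrated):
        state = h.uniform_boost_variant(cfg_calibrated, 0.0)
        for g, sp in state.groups.items():
            q = cfg_calibrated.hrc_params[g].q_baseline.point
            assert sp.s_hrc == pytest.approx(q, abs=1e-12)

    def test_sixteen_percent_boost_per_group(self, cfg_calibrated):
        state = h.uniform_boost_variant(cfg_calibrated, 0.16)
        for g, sp in state.groups.items():
            q = cfg_calibrated.hrc_params[g].q_baseline.point
            assert sp.s_hrc == pytest.approx(1.16 * q, rel=1e-12)

    def test_larger_boost_favours_claim_foods(self, cfg_calibrated):
        lo = h.uniform_boost_variant(cfg_calibrated, 0.16)
        hi = h.uniform_boost_variant(cfg_calibrated, 0.75)
        assert hi.hrc_sales() > lo.hrc_sales()

    def test_invalid_boost(self):
        with pytest.raises(ValueError):
            h.or_from_uniform_boost(0.5, -1.2)
        with pytest.raises(ValueError):
            h.or_from_uniform_boost(0.9, 0.2)  # implied share >= 1

    def test_sensitivity_pair_directions(self, cfg_calibrated):
        base, restricted = h.boost_sensitivity(cfg_calibrated, 0.16)
        delta = h.diet_delta(restricted, base)
        assert delta["energy_kcal"] > 0  # same mechanism as the OR-based run


class TestDietDelta:
    def test_identical_states_give_zeros(self, baseline_state):
        delta = h.diet_delta(baseline_state, baseline_state)
        assert all(v == 0.0 for v in delta.values.values())

    def test_mismatched_groups_rejected(self, baseline_state):
        partial = h.DietState(
            groups={FoodGroup.DAIRY: baseline_state.groups[FoodGroup.DAIRY]})
        with pytest.raises(ConfigError):
            h.diet_delta(partial, baseline_state)

    def test_single_nutrient_perturbation_isolated(self):
        base = _toy_baseline()
        out = h.build_reformulated(base, _toy_nqr(0.4, baseline_value=0.5),
                                   "pass_fsanz")
        delta = h.diet_delta(out, base)
        moved = [n for n in NUTRIENTS if delta[n] != 0.0]
        assert moved == ["energy_kcal"]

    def test_report_units_convert_sodium_to_grams(self, cfg_calibrated,
                                                  baseline_state):
        out = h.run_scenario(cfg_calibrated, "1b", baseline=baseline_state)
        delta = h.diet_delta(out, baseline_state)
        rep = delta.to_report_units()
        assert rep["sodium_g"] == pytest.approx(delta["sodium_mg"] / 1000)

    def test_calibrated_1b_energy_delta_near_reported(self, cfg_calibrated,
                                                      baseline_state):
        """Model 1b energy reduction lands near the reported -90 kcal/day."""
        out = h.run_scenario(cfg_calibrated, "1b", baseline=baseline_state)
        delta = h.diet_delta(out, baseline_state)
        assert delta["energy_kcal"] == pytest.approx(-90.1, abs=10)
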