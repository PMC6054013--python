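"""Household and company agents: demography, expectations, decisions."""

import math

import numpy as np
import pytest

from luces.agents import (
    Action,
    Company,
    DEFAULT_OPTIONS,
    Household,
    OPTIONS_BY_NAME,
    choice_probabilities,
    company_decide,
    expected_income,
    household_decide,
    instantaneous_income,
    update_demography,
    update_expectation,
)
from luces.landscape import LandCover, Soil
from luces.policy import (
    CommodityEconomics,
    DEFAULT_PRICES,
    PriceTable,
    apply_scenario_prices,
    scenario_preset,
)

from conftest import make_grid


def settlement_grid(n=10):
    cover = np.full((n, n), int(LandCover.MINERAL_FOREST))
    cover[0, 0] = int(LandCover.SETTLEMENT)
    return make_grid(cover)


class TestDemography:
    def test_high_growth_district_rate(self, rng):
        hh = [Household(id=i, home=(0, 0)) for i in range(100)]
        out = update_demography(hh, 0.042, settlement_grid(), rng)
        assert len(out) == 104

    def test_low_growth_district_rate(self, rng):
        hh = [Household(id=i, home=(0, 0)) for i in range(100)]
        out = update_demography(hh, 0.007, settlement_grid(), rng)
        assert len(out) == 100  # floor of 100.7

    def test_zero_growth_identity(self, rng):
        hh = [Household(id=i, home=(0, 0)) for i in range(7)]
        assert update_demography(hh, 0.0, settlement_grid(), rng) is hh

    def test_new_households_settle_on_settlement_cells(self, rng):
        grid = settlement_grid()
        hh = [Household(id=1, home=(0, 0), preferences={"paddy": 2.0})]
        out = update_demography(hh, 1.0, grid, rng)
        assert len(out) == 2
        newcomer = out[-1]
        assert grid.cover[newcomer.home] == int(LandCover.SETTLEMENT)
        assert newcomer.preferences == {"paddy": 2.0}  # inherits defaults
        assert newcomer.id != out[0].id

    def test_growth_without_settlements_errors(self, rng):
        grid = make_grid(np.full((4, 4), int(LandCover.AGRICULTURE)))
        households = [Household(id=1, home=(0, 0)), Household(id=2, home=(0, 0))]
        with pytest.raises(ValueError, match="settlement"):
            update_demography(households, 0.5, grid, rng)


class TestExpectations:
    def test_net_income_arithmetic(self):
        prices = PriceTable({"rubber": CommodityEconomics(50.0, 30.0, 2.0)})
        hh = Household(id=1, home=(0, 0), labor=2.0)
        opt = OPTIONS_BY_NAME["rubber_agroforest"]
        # net 2*50-30 = 70 per ha over labor/labor_cost = 1 ha
        assert instantaneous_income(opt, prices, hh) == pytest.approx(70.0)

    def test_alpha_limits(self):
        assert update_expectation(10.0, 50.0, 1.0) == 50.0
        assert update_expectation(10.0, 50.0, 0.0) == 10.0

    @pytest.mark.parametrize("alpha", [0.1, 0.5, 0.9])
    def test_convergence_matches_closed_form(self, alpha):
        """E_t = r + (1-alpha)^t (E_0 - r) under constant realized income."""
        r, e0 = 80.0, 5.0
        e = e0
        for t in range(1, 30):
            e = update_expectation(e, r, alpha)
            assert e == pytest.approx(r + (1 - alpha) ** t * (e0 - r), abs=1e-9)

    def test_expected_income_updates_household_state(self):
        prices = PriceTable({"rattan": CommodityEconomics(100.0, 10.0, 0.5)})
        hh = Household(id=1, home=(0, 0), labor=2.0, expectations={"collect_rattan": 0.0})
        opt = OPTIONS_BY_NAME["collect_rattan"]
        got = expected_income(opt, prices, hh, alpha=0.5)
        assert got == pytest.approx(0.5 * instantaneous_income(opt, prices, hh))
        assert hh.expectations["collect_rattan"] == got


class TestChoiceModel:
    def test_probabilities_match_hand_enumeration(self):
        names = ["a", "b", "c", "d"]
        exp = {"a": 120.0, "b": 80.0, "c": 0.0, "d": -30.0}
        pref = {"a": 1.0, "b": 2.0, "c": 0.5, "d": 1.0}
        beta, scale = 1.5, 100.0
        got = choice_probabilities(names, exp, pref, beta, scale)
        weights = [pref[n] * math.exp(beta * max(exp[n], 0.0) / scale) for n in names]
        total = sum(weights)
        for g, w in zip(got, weights):
            assert g == pytest.approx(w / total, abs=1e-12)
        assert sum(got) == pytest.approx(1.0, abs=1e-12)

    def test_sharp_beta_approaches_argmax(self):
        names = ["low", "high"]
        exp = {"low": 50.0, "high": 60.0}
        probs = choice_probabilities(names, exp, {}, beta=1000.0, scale=1.0)
        assert probs[names.index("high")] > 1 - 1e-12

    def test_zero_beta_is_preference_weighted(self):
        probs = choice_probabilities(["a", "b"], {"a": 1e6, "b": 0.0}, {"a": 1.0, "b": 3.0}, 0.0)
        assert probs == pytest.approx([0.25, 0.75])

    def test_collect_price_rise_weakly_reduces_conversion_mass(self):
        """Better NTFP markets pull choice mass away from land conversion."""
        hh = Household(id=1, home=(0, 0), labor=2.0)
        convert_opts = {"rubber_agroforest", "paddy", "oil_palm_smallholding"}
        names = [o.name for o in DEFAULT_OPTIONS]

        def conversion_mass(rattan_price):
            prices = PriceTable(DEFAULT_PRICES)
            base = prices["rattan"]
            prices["rattan"] = CommodityEconomics(
                rattan_price, base.production_cost, base.yield_per_ha
            )
            exp = {
                o.name: instantaneous_income(o, prices, hh) for o in DEFAULT_OPTIONS
            }
            probs = choice_probabilities(names, exp, {}, beta=2.0, scale=100.0)
            return sum(p for n, p in zip(names, probs) if n in convert_opts)

        masses = [conversion_mass(p) for p in (1000.0, 1800.0, 2600.0, 4000.0)]
        assert all(a >= b for a, b in zip(masses, masses[1:]))
        assert masses[0] > masses[-1]


class TestHouseholdDecide:
    def setup_method(self):
        cover = np.full((9, 9), int(LandCover.MINERAL_FOREST))
        cover[4, 4] = int(LandCover.SETTLEMENT)
        self.grid = make_grid(cover)
        self.hh = Household(id=1, home=(4, 4), labor=2.0, search_radius=3)
        self.prices = apply_scenario_prices(DEFAULT_PRICES, scenario_preset("BAU"))
        for o in DEFAULT_OPTIONS:
            self.hh.expectations[o.name] = instantaneous_income(o, self.prices, self.hh)

    def test_zero_labor_yields_no_actions(self, rng):
        self.hh.labor = 0.0
        assert (
            household_decide(self.hh, self.grid, self.prices, scenario_preset("BAU"), 2.0, rng)
            == []
        )

    def test_actions_have_valid_structure(self, rng):
        actions = household_decide(
            self.hh, self.grid, self.prices, scenario_preset("BAU"), 2.0, rng
        )
        assert len(actions) >= 1
        for a in actions:
            assert a.actor_kind == "household"
            assert a.kind in ("convert", "collect", "harvest")
            if a.kind == "convert":
                assert a.target is not None

    def test_at_most_one_conversion_per_year(self, rng):
        for _ in range(30):
            actions = household_decide(
                self.hh, self.grid, self.prices, scenario_preset("BAU"), 2.0, rng
            )
            assert sum(a.kind == "convert" for a in actions) <= 1

    def test_dominant_option_always_chosen_at_sharp_beta(self, rng):
        self.hh.expectations = {o.name: 0.0 for o in DEFAULT_OPTIONS}
        self.hh.expectations["paddy"] = 500.0
        for _ in range(10):
            actions = household_decide(
                self.hh, self.grid, self.prices, scenario_preset("BAU"), 1e6, rng, scale=1.0
            )
            assert actions and actions[0].target == LandCover.AGRICULTURE

    def test_mpl_logging_excluded_from_feasible_set(self, rng):
        self.hh.expectations = {o.name: 0.0 for o in DEFAULT_OPTIONS}
        self.hh.expectations["community_timber"] = 1e6
        mpl_prices = apply_scenario_prices(DEFAULT_PRICES, scenario_preset("MPL"))
        for _ in range(10):
            actions = household_decide(
                self.hh, self.grid, mpl_prices, scenario_preset("MPL"), 1e6, rng, scale=1.0
            )
            assert all(a.kind != "harvest" for a in actions)

    def test_no_forest_disables_collection(self, rng):
        grid = make_grid(np.full((9, 9), int(LandCover.DEGRADED_LAND)))
        hh = Household(id=1, home=(4, 4), labor=2.0, search_radius=3)
        hh.expectations = {o.name: 1.0 for o in DEFAULT_OPTIONS}
        for _ in range(10):
            for a in household_decide(hh, grid, self.prices, scenario_preset("BAU"), 1.0, rng):
                assert a.kind == "convert"

    def test_conversion_targets_best_suitability_cell(self, rng):
        suit = np.zeros((9, 9))
        suit[2, 3] = 0.9
        self.grid.suitability["rice"] = suit
        self.hh.expectations = {o.name: 0.0 for o in DEFAULT_OPTIONS}
        self.hh.expectations["paddy"] = 500.0
        actions = household_decide(
            self.hh, self.grid, self.prices, scenario_preset("BAU"), 1e6, rng, scale=1.0
        )
        assert (actions[0].row, actions[0].col) == (2, 3)


class TestCompanyDecide:
    def make_company(self, sector="oil_palm", quota_ha=2.0, margin=300.0):
        return Company(id=1, sector=sector, permit_zone=1, annual_quota_ha=quota_ha, profit_margin=margin)

    def zone_grid(self, soil=None):
        cover = np.full((10, 10), int(LandCover.DEGRADED_LAND))
        grid = make_grid(cover, soil=soil)
        grid.zone[:5, :] = 1
        return grid

    def test_no_candidates_returns_empty(self, rng):
        cover = np.full((5, 5), int(LandCover.SETTLEMENT))
        grid = make_grid(cover)
        grid.zone[:] = 1
        assert company_decide(self.make_company(), grid, DEFAULT_PRICES, scenario_preset("BAU"), 2012, rng) == []

    def test_nonpositive_margin_returns_empty(self, rng):
        grid = self.zone_grid()
        co = self.make_company(margin=0.0)
        assert company_decide(co, grid, DEFAULT_PRICES, scenario_preset("BAU"), 2012, rng) == []

    def test_quota_respected_exactly(self, rng):
        grid = self.zone_grid()
        co = self.make_company(quota_ha=3.0)
        actions = company_decide(co, grid, DEFAULT_PRICES, scenario_preset("BAU"), 2012, rng)
        assert len(actions) * grid.cell_area_ha <= co.annual_quota_ha
        assert len(actions) == 6  # 3 ha / 0.5 ha per cell

    def test_selection_matches_brute_force_sort(self, rng):
        grid = self.zone_grid()
        suit = np.random.default_rng(3).random((10, 10))
        grid.suitability["oil_palm"] = suit
        co = self.make_company(quota_ha=4.0)
        actions = company_decide(co, grid, DEFAULT_PRICES, scenario_preset("BAU"), 2012, rng)
        # brute force: every permitted cell, sorted by score desc then (row, col)
        candidates = []
        for r in range(10):
            for c in range(10):
                if grid.zone[r, c] == 1 and grid.cover[r, c] != int(LandCover.SETTLEMENT):
                    candidates.append((-suit[r, c] * co.profit_margin, r, c))
        candidates.sort()
        expected = [(r, c) for _, r, c in candidates[: len(actions)]]
        assert [(a.row, a.col) for a in actions] == expected

    def test_tie_break_is_reading_order(self, rng):
        grid = self.zone_grid()  # uniform suitability: all scores tie
        co = self.make_company(quota_ha=1.5)
        actions = company_decide(co, grid, DEFAULT_PRICES, scenario_preset("BAU"), 2012, rng)
        assert [(a.row, a.col) for a in actions] == [(0, 0), (0, 1), (0, 2)]

    def test_em_selects_only_mineral_soil(self, rng):
        soil = np.zeros((10, 10), dtype=int)
        soil[:, :5] = int(Soil.PEAT)
        grid = self.zone_grid(soil=soil)
        co = self.make_company(quota_ha=10.0)
        actions = company_decide(co, grid, DEFAULT_PRICES, scenario_preset("EM"), 2020, rng)
        assert actions
        for a in actions:
            assert grid.soil[a.row, a.col] == int(Soil.MINERAL)

    def test_moratorium_excludes_peat_forest_cells(self, rng):
        cover = np.full((10, 10), int(LandCover.PEAT_FOREST))
        soil = np.full((10, 10), int(Soil.PEAT))
        grid = make_grid(cover, soil=soil)
        grid.zone[:] = 1
        co = self.make_company(quota_ha=10.0)
        assert company_decide(co, grid, DEFAULT_PRICES, scenario_preset("BAU"), 2012, rng) == []
        # outside the window the same zone is convertible
        assert company_decide(co, grid, DEFAULT_PRICES, scenario_preset("BAU"), 2020, rng)
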