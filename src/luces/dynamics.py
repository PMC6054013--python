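"""The annual production cycle and multi-year simulation driver.

Each simulated year executes a fixed 12-step schedule:

1.  scenario price adjustment (premium / subsidy on the base price table);
2.  market-expectation update (households adapt expectations to current
    effective prices);
3.  demography update (household population grows at the district rate);
4.  company decisions (planned change) and
5.  their conversions applied;
6.  household decisions (unplanned change) and
7.  their conversions applied;
8.  NTFP collection and timber harvests logged;
9.  income realisation and expectation update for the chosen options;
10. cell ageing, plantation maturation and peat oxidation;
11. settlement redistribution driven by local land demand;
12. ecosystem-service accounting appended to the ledger; the year advances.

Companies act before households (planned before unplanned change).  Prices
are held constant over the horizon; only the scenario's premium/subsidy
modifies them.  The run is a pure function of (config, seed): every random
draw goes through one seeded generator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import agents as ag
from .agents import Action, Company, Household
from .ecosystem_services import (
    ESAccount,
    ESCoefficients,
    annual_emissions,
    ledger_frame,
    make_account,
)
from .landscape import (
    DistrictProfile,
    LandCover,
    LandscapeGrid,
    Soil,
    TRANSITION_TARGETS,
    area_summary,
    district_preset,
    generate_synthetic_district,
)
from .policy import (
    DEFAULT_PRICES,
    PriceTable,
    Scenario,
    allowed_conversion,
    apply_scenario_prices,
    scenario_preset,
)


@dataclass
class SimulationConfig:
    """Everything a run needs; a pure function of this + seed reproduces it."""

    scenario: Scenario | str = "BAU"
    district: DistrictProfile | str = "west_kotawaringin"
    start_year: int = 2010
    n_years: int = 15
    seed: int = 0
    height: int = 100
    width: int = 100
    initial_grid: LandscapeGrid | None = None
    prices: PriceTable = field(default_factory=lambda: PriceTable(DEFAULT_PRICES))
    coefficients: ESCoefficients = field(default_factory=ESCoefficients)
    n_households: int | None = None  # None -> district preset
    population_growth_rate: float | None = None  # None -> district preset
    # household decision parameters
    alpha: float = 0.5
    beta: float = 2.0
    choice_scale: float = 100.0
    search_radius: int = 8
    max_conversions_per_year: int = 1
    household_labor: float = 2.0
    # company parameters
    company_quota_fraction: float = 0.02  # of permit-zone area per year
    company_profit_margins: dict[str, float] = field(
        default_factory=lambda: {"oil_palm": 300.0, "timber": 150.0}
    )
    # settlement growth
    settlement_threshold: int = 5
    settlement_radius: int = 5
    max_new_settlements_per_year: int = 1
    store_annual_grids: bool = False

    def __post_init__(self) -> None:
        if self.n_years < 0:
            raise ValueError("n_years must be >= 0")

    def resolved_scenario(self) -> Scenario:
        return self.scenario if isinstance(self.scenario, Scenario) else scenario_preset(self.scenario)

    def resolved_profile(self) -> DistrictProfile:
        if isinstance(self.district, DistrictProfile):
            return self.district
        return district_preset(self.district)


@dataclass
class SimulationState:
    grid: LandscapeGrid
    households: list[Household]
    companies: list[Company]
    prices: PriceTable
    scenario: Scenario
    year: int
    rng: np.random.Generator
    config: SimulationConfig
    growth_rate: float = 0.0
    ledger: list[ESAccount] = field(default_factory=list)
    action_log: list[Action] = field(default_factory=list)


@dataclass
class SimulationResult:
    config: SimulationConfig
    final_grid: LandscapeGrid
    areas: pd.DataFrame  # year x class-fraction table
    ledger: list[ESAccount]
    action_log: list[Action]
    annual_grids: list[LandscapeGrid] = field(default_factory=list)

    @property
    def ledger_frame(self) -> pd.DataFrame:
        return ledger_frame(self.ledger)

    def actions_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "year": a.year,
                    "actor_kind": a.actor_kind,
                    "actor_id": a.actor_id,
                    "kind": a.kind,
                    "row": a.row,
                    "col": a.col,
                    "source": a.source.label if a.source is not None else "",
                    "target": a.target.label if a.target is not None else "",
                    "commodity": a.commodity or "",
                    "reason": a.reason,
                }
                for a in self.action_log
            ],
            columns=[
                "year",
                "actor_kind",
                "actor_id",
                "kind",
                "row",
                "col",
                "source",
                "target",
                "commodity",
                "reason",
            ],
        )


# ---------------------------------------------------------------------------
# State initialisation
# ---------------------------------------------------------------------------


def init_state(config: SimulationConfig) -> SimulationState:
    scenario = config.resolved_scenario()
    profile = config.resolved_profile()
    rng = np.random.default_rng(config.seed)
    if config.initial_grid is not None:
        grid = config.initial_grid.copy()
    else:
        grid = generate_synthetic_district(
            replace(profile, seed=config.seed), config.height, config.width
        )
    grid.year = config.start_year

    n_households = config.n_households
    if n_households is None:
        n_households = profile.n_households
    growth = config.population_growth_rate
    if growth is None:
        growth = profile.population_growth_rate

    settlement = np.argwhere(grid.cover == int(LandCover.SETTLEMENT))
    households: list[Household] = []
    effective = apply_scenario_prices(config.prices, scenario)
    for i in range(n_households):
        if settlement.size:
            r, c = settlement[int(rng.integers(len(settlement)))]
            home = (int(r), int(c))
        else:
            home = (int(rng.integers(grid.height)), int(rng.integers(grid.width)))
        hh = Household(
            id=i + 1,
            home=home,
            labor=config.household_labor,
            search_radius=config.search_radius,
            preferences={o.name: 1.0 for o in ag.DEFAULT_OPTIONS},
        )
        # expectations start at the instantaneous incomes under current prices
        for opt in ag.DEFAULT_OPTIONS:
            hh.expectations[opt.name] = ag.instantaneous_income(opt, effective, hh)
        households.append(hh)

    companies: list[Company] = []
    zone_ids = sorted(int(z) for z in np.unique(grid.zone) if z > 0)
    sectors = ("oil_palm", "timber")
    for i, zone_id in enumerate(zone_ids):
        zone_area_ha = float((grid.zone == zone_id).sum()) * grid.cell_area_ha
        sector = sectors[i % len(sectors)]
        companies.append(
            Company(
                id=i + 1,
                sector=sector,
                permit_zone=zone_id,
                annual_quota_ha=config.company_quota_fraction * zone_area_ha,
                profit_margin=config.company_profit_margins.get(sector, 0.0),
            )
        )

    state = SimulationState(
        grid=grid,
        households=households,
        companies=companies,
        prices=PriceTable(config.prices),
        scenario=scenario,
        year=config.start_year,
        rng=rng,
        config=config,
        growth_rate=growth,
    )
    # initial ledger entry (year 0, no flux yet)
    state.ledger.append(make_account(grid, config.coefficients))
    return state


# ---------------------------------------------------------------------------
# Applying actions
# ---------------------------------------------------------------------------


def apply_action(grid: LandscapeGrid, action: Action) -> LandscapeGrid:
    """Apply one action to the grid in place (and return the grid).

    Convert actions set cover, owner and reset age; collect and harvest
    actions never change the grid.  Conversion targets are restricted to
    the transition table (agroforest, agriculture, oil palm and timber
    plantations, settlement); settlement is a sink and can never be a
    source.
    """
    if action.kind in ("collect", "harvest"):
        return grid
    if action.kind != "convert":
        raise ValueError(f"unknown action kind {action.kind!r}")
    source = LandCover(int(grid.cover[action.row, action.col]))
    target = action.target
    if target not in TRANSITION_TARGETS:
        raise ValueError(f"disallowed transition {source.label} -> {target.label}")
    if source == LandCover.SETTLEMENT:
        raise ValueError(f"disallowed transition {source.label} -> {target.label}: settlement is a sink")
    grid.cover[action.row, action.col] = int(target)
    owner = action.actor_id if action.actor_kind == "household" else -action.actor_id
    grid.owner[action.row, action.col] = owner
    grid.age[action.row, action.col] = 0
    return grid


# ---------------------------------------------------------------------------
# Settlement redistribution
# ---------------------------------------------------------------------------


def update_settlements(
    grid: LandscapeGrid,
    conversions: Sequence[tuple[int, int]],
    threshold: int = 5,
    radius: int = 5,
    max_new: int = 1,
) -> list[tuple[int, int]]:
    """Let settlements follow land demand.

    If at least ``threshold`` of this year's conversions fall within a
    Chebyshev window of ``radius`` around some conversion cell, the cell at
    the (rounded) centroid of that cluster becomes settlement.  At most
    ``max_new`` new settlement cells appear per year.  Returns the new
    settlement cells.
    """
    if len(conversions) < threshold or max_new <= 0:
        return []
    pts = np.asarray(conversions, dtype=np.int64)
    # densest window centred on a conversion cell
    cheb = np.maximum(
        np.abs(pts[:, 0][:, None] - pts[:, 0][None, :]),
        np.abs(pts[:, 1][:, None] - pts[:, 1][None, :]),
    )
    in_window = cheb <= radius
    counts = in_window.sum(axis=1)
    best = int(np.argmax(counts))  # first max: deterministic
    if counts[best] < threshold:
        return []
    members = pts[in_window[best]]
    cr = int(math.floor(members[:, 0].mean() + 0.5))
    cc = int(math.floor(members[:, 1].mean() + 0.5))
    cr = min(max(cr, 0), grid.height - 1)
    cc = min(max(cc, 0), grid.width - 1)
    if grid.cover[cr, cc] == int(LandCover.SETTLEMENT):
        return []
    grid.cover[cr, cc] = int(LandCover.SETTLEMENT)
    grid.owner[cr, cc] = 0
    grid.age[cr, cc] = 0
    return [(cr, cc)]


# ---------------------------------------------------------------------------
# The annual cycle
# ---------------------------------------------------------------------------


def annual_cycle(state: SimulationState) -> SimulationState:
    """Advance the simulation by one year (in place; returns the state)."""
    grid = state.grid
    cfg = state.config
    coeffs = cfg.coefficients
    year = state.year
    prev_cover = grid.cover.copy()
    prev_depleted = grid.peat_depleted.copy()
    prev_grid_view = LandscapeGrid(
        cover=prev_cover,
        soil=grid.soil,
        peat_depleted=prev_depleted,
        cell_area_ha=grid.cell_area_ha,
        year=year,
    )
    soil_before = grid.soil.copy()

    # (1) scenario price adjustment
    effective_prices = apply_scenario_prices(state.prices, state.scenario)

    # (2) market-expectation update for every option
    for hh in state.households:
        for opt in ag.DEFAULT_OPTIONS:
            ag.expected_income(opt, effective_prices, hh, cfg.alpha)

    # (3) demography
    state.households = ag.update_demography(
        state.households, state.growth_rate, grid, state.rng
    )

    # (4)-(5) company decisions, applied
    year_actions: list[Action] = []
    conversions: list[tuple[int, int]] = []
    for company in state.companies:
        for action in ag.company_decide(
            company, grid, effective_prices, state.scenario, year, state.rng
        ):
            _checked_apply(grid, action, state.scenario)
            year_actions.append(action)
            conversions.append((action.row, action.col))

    # (6)-(8) household decisions: conversions applied, collection logged
    collection: list[Action] = []
    for hh in state.households:
        actions = ag.household_decide(
            hh,
            grid,
            effective_prices,
            state.scenario,
            cfg.beta,
            state.rng,
            year=year,
            scale=cfg.choice_scale,
            max_conversions_per_year=cfg.max_conversions_per_year,
        )
        for action in actions:
            if action.kind == "convert":
                _checked_apply(grid, action, state.scenario)
                hh.holdings.add(action.row * grid.width + action.col)
                conversions.append((action.row, action.col))
            else:
                collection.append(action)
            year_actions.append(action)

    # (9) income realisation and expectation update for chosen options
    chosen_by_hh: dict[int, str] = {}
    for action in year_actions:
        if action.actor_kind == "household" and action.commodity:
            opt = _option_for_commodity(action)
            if opt is not None:
                chosen_by_hh[action.actor_id] = opt.name
    hh_by_id = {hh.id: hh for hh in state.households}
    for hh_id, opt_name in chosen_by_hh.items():
        hh = hh_by_id.get(hh_id)
        if hh is None:
            continue
        realized = ag.instantaneous_income(
            ag.OPTIONS_BY_NAME[opt_name], effective_prices, hh
        )
        hh.expectations[opt_name] = ag.update_expectation(
            hh.expectations.get(opt_name, realized), realized, cfg.alpha
        )

    # (10) ageing and peat oxidation
    converted_mask = grid.cover != prev_cover
    grid.age[~converted_mask] += 1
    oxidising = (grid.soil == int(Soil.PEAT)) & ~np.isin(
        grid.cover, [int(LandCover.PEAT_FOREST), int(LandCover.MINERAL_FOREST)]
    )
    remaining = np.maximum(coeffs.peat_stock_density - grid.peat_depleted, 0.0)
    grid.peat_depleted[oxidising] += np.minimum(
        coeffs.peat_oxidation_rate, remaining[oxidising]
    )

    # (11) settlement redistribution
    update_settlements(
        grid,
        conversions,
        threshold=cfg.settlement_threshold,
        radius=cfg.settlement_radius,
        max_new=cfg.max_new_settlements_per_year,
    )

    # (12) accounting; the year advances
    grid.year = year + 1
    state.year = year + 1
    emission, sequestration = annual_emissions(prev_grid_view, grid, coeffs)
    state.ledger.append(
        make_account(grid, coeffs, collection, emission=emission, sequestration=sequestration)
    )
    state.action_log.extend(year_actions)

    if not np.array_equal(soil_before, grid.soil):  # pragma: no cover
        raise AssertionError("soil class changed during a cycle; soil is immutable")
    return state


def _option_for_commodity(action: Action) -> ag.LivelihoodOption | None:
    for opt in ag.DEFAULT_OPTIONS:
        if opt.commodity == action.commodity:
            return opt
    return None


def _checked_apply(grid: LandscapeGrid, action: Action, scenario: Scenario) -> None:
    decision = allowed_conversion(
        grid.cell(action.row, action.col), action.actor_kind, action.target, action.year, scenario
    )
    if not decision:  # pragma: no cover - decisions pre-check permissions
        raise RuntimeError(
            f"invariant violation: {action.actor_kind} conversion at "
            f"({action.row}, {action.col}) denied by rule {decision.reason!r}"
        )
    apply_action(grid, action)


# ---------------------------------------------------------------------------
# Driver
# ---------------------------------------------------------------------------


def run_simulation(config: SimulationConfig) -> SimulationResult:
    """Run the full multi-year simulation described by ``config``.

    Returns annual class-fraction trajectories, the ecosystem-service
    ledger, the action log, and the final grid.  Bit-reproducible from
    (config, seed).
    """
    state = init_state(config)
    rows = [_area_row(state.grid)]
    annual_grids = [state.grid.copy()] if config.store_annual_grids else []
    n_cells = state.grid.n_cells
    for _ in range(config.n_years):
        annual_cycle(state)
        if state.grid.n_cells != n_cells:  # pragma: no cover
            raise AssertionError("cell count changed during simulation")
        rows.append(_area_row(state.grid))
        if config.store_annual_grids:
            annual_grids.append(state.grid.copy())
    areas = pd.DataFrame(rows).set_index("year")
    return SimulationResult(
        config=config,
        final_grid=state.grid,
        areas=areas,
        ledger=state.ledger,
        action_log=state.action_log,
        annual_grids=annual_grids,
    )


def _area_row(grid: LandscapeGrid) -> dict:
    row: dict = {"year": grid.year}
    row.update({c.label: f for c, f in area_summary(grid).items()})
    return row
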