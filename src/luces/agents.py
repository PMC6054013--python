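"""Household and company agents: state, demography, expectations, decisions.

Two agent kinds drive land-cover change. Permit-holding **companies** drive
planned change: each year a company ranks the cells of its concession zone by
``suitability x profit margin`` and converts the best ones up to an annual
quota, subject to the scenario's permission rules. **Households** drive
unplanned change: each household holds adaptive income expectations over a
set of livelihood options (NTFP collection, rubber agroforest, paddy,
smallholder oil palm, community timber) and each year draws one option from
a preference-weighted logit over the options that are feasible near its
home. Options that convert land emit a conversion action; NTFP collection
and timber harvesting never change land cover.

The choice model is deliberately simple and fully config-exposed: choice
probability is proportional to ``preference * exp(beta * E / scale)`` where
``E`` is the (clamped non-negative) expected net income of the option,
``beta`` the choice sharpness and ``scale`` a normalising income.  Income
expectations follow the standard adaptive rule
``E_t = (1 - alpha) * E_{t-1} + alpha * realized_t``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .landscape import (
    FOREST_CLASSES,
    LandCover,
    LandscapeGrid,
    Soil,
)
from .policy import (
    CommodityEconomics,
    PLANTATION_CLASSES,
    PriceTable,
    Scenario,
    allowed_conversion,
)


@dataclass(frozen=True)
class LivelihoodOption:
    """One livelihood an agent can pursue.

    ``converts_to`` is the land-cover class the option establishes, or
    ``None`` for collection/harvest options that leave cover untouched.
    ``labor_cost`` is in labour-units per hectare-year and bounds the area a
    household can work.  ``implies_logging`` marks timber extraction from
    standing natural forest.
    """

    name: str
    commodity: str
    converts_to: LandCover | None
    labor_cost: float
    implies_logging: bool = False

    def __post_init__(self) -> None:
        if self.labor_cost <= 0:
            raise ValueError("labor_cost must be positive")


DEFAULT_OPTIONS: tuple[LivelihoodOption, ...] = (
    LivelihoodOption("collect_rattan", "rattan", None, labor_cost=2.0),
    LivelihoodOption("collect_jelutong", "jelutong", None, labor_cost=2.0),
    LivelihoodOption("rubber_agroforest", "rubber", LandCover.AGROFOREST, labor_cost=2.0),
    LivelihoodOption("paddy", "rice", LandCover.AGRICULTURE, labor_cost=2.0),
    LivelihoodOption(
        "oil_palm_smallholding", "oil_palm", LandCover.OIL_PALM_PLANTATION, labor_cost=2.0
    ),
    LivelihoodOption(
        "community_timber", "community_timber", None, labor_cost=2.0, implies_logging=True
    ),
)

OPTIONS_BY_NAME = {o.name: o for o in DEFAULT_OPTIONS}


@dataclass
class Household:
    id: int
    home: tuple[int, int]
    labor: float = 2.0
    holdings: set[int] = field(default_factory=set)  # flat cell indices
    expectations: dict[str, float] = field(default_factory=dict)
    preferences: dict[str, float] = field(default_factory=dict)
    search_radius: int = 8


@dataclass
class Company:
    id: int  # positive; stored negated in the owner raster
    sector: str  # "oil_palm" or "timber"
    permit_zone: int
    annual_quota_ha: float
    profit_margin: float  # currency/ha/yr for the sector's target class

    @property
    def target_class(self) -> LandCover:
        return (
            LandCover.OIL_PALM_PLANTATION
            if self.sector == "oil_palm"
            else LandCover.TIMBER_PLANTATION
        )


@dataclass(frozen=True)
class Action:
    """One logged agent action; ``kind`` is convert, collect or harvest."""

    actor_id: int
    actor_kind: str
    kind: str
    row: int
    col: int
    target: LandCover | None = None
    commodity: str | None = None
    source: LandCover | None = None
    reason: str = ""
    year: int = 0


# ---------------------------------------------------------------------------
# Expectations
# ---------------------------------------------------------------------------


def instantaneous_income(
    option: LivelihoodOption,
    prices: Mapping[str, CommodityEconomics],
    household: Household,
) -> float:
    """Net income (currency/yr) the option yields this year at current prices.

    Per-hectare net income (``yield * price - cost``) times the area the
    household's labour can work.  May be negative; negativity is only
    clamped inside the choice weights so unattractive options stay ranked.
    """
    econ = prices[option.commodity]
    workable_ha = household.labor / option.labor_cost
    return econ.net_income_per_ha * workable_ha


def update_expectation(previous: float, realized: float, alpha: float) -> float:
    """Adaptive expectation: ``E_t = (1 - alpha) E_{t-1} + alpha realized``."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    return (1.0 - alpha) * previous + alpha * realized


def expected_income(
    option: LivelihoodOption,
    prices: Mapping[str, CommodityEconomics],
    household: Household,
    alpha: float,
) -> float:
    """Update and return the household's expectation for this option."""
    realized = instantaneous_income(option, prices, household)
    prev = household.expectations.get(option.name, realized)
    new = update_expectation(prev, realized, alpha)
    household.expectations[option.name] = new
    return new


# ---------------------------------------------------------------------------
# Choice model
# ---------------------------------------------------------------------------


def choice_probabilities(
    option_names: Sequence[str],
    expectations: Mapping[str, float],
    preferences: Mapping[str, float],
    beta: float,
    scale: float = 100.0,
) -> list[float]:
    """Preference-weighted logit choice probabilities over feasible options.

    ``P(i) proportional to pref_i * exp(beta * max(E_i, 0) / scale)``.
    Weights are computed in plain Python floats so they can be checked
    against hand-normalised enumeration exactly.
    """
    if beta < 0:
        raise ValueError("beta must be non-negative")
    if scale <= 0:
        raise ValueError("scale must be positive")
    # subtract the max exponent for overflow safety; cancels in normalisation
    exponents = [beta * max(expectations.get(n, 0.0), 0.0) / scale for n in option_names]
    m = max(exponents) if exponents else 0.0
    weights = [preferences.get(n, 1.0) * math.exp(e - m) for n, e in zip(option_names, exponents)]
    total = sum(weights)
    if total <= 0:
        # all preferences zero: uniform fallback
        return [1.0 / len(weights)] * len(weights) if weights else []
    return [w / total for w in weights]


# ---------------------------------------------------------------------------
# Demography
# ---------------------------------------------------------------------------


def update_demography(
    households: list[Household],
    growth_rate: float,
    grid: LandscapeGrid,
    rng: np.random.Generator,
    default_household: Household | None = None,
) -> list[Household]:
    """Grow (or shrink) the household population at an annual rate.

    The new population size is ``floor(n * (1 + growth_rate))`` — floor
    rounding keeps small-n runs deterministic.  New households are placed on
    settlement cells drawn uniformly and inherit the preferences, labour and
    search radius of ``default_household`` (or of the first household).
    """
    if growth_rate < -1.0:
        raise ValueError("growth_rate must be >= -1")
    n = len(households)
    target = math.floor(n * (1.0 + growth_rate))
    if target == n:
        return households
    if target < n:
        keep = rng.permutation(n)[:target]
        return [households[i] for i in sorted(keep)]
    settlement = np.argwhere(grid.cover == int(LandCover.SETTLEMENT))
    if settlement.size == 0:
        raise ValueError("cannot add households: the grid has no settlement cells")
    template = default_household or (households[0] if households else None)
    next_id = max((h.id for h in households), default=0) + 1
    out = list(households)
    for i in range(target - n):
        r, c = settlement[int(rng.integers(len(settlement)))]
        out.append(
            Household(
                id=next_id + i,
                home=(int(r), int(c)),
                labor=template.labor if template else 2.0,
                expectations=dict(template.expectations) if template else {},
                preferences=dict(template.preferences) if template else {},
                search_radius=template.search_radius if template else 8,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Household decisions
# ---------------------------------------------------------------------------


def _window(grid: LandscapeGrid, home: tuple[int, int], radius: int):
    r, c = home
    r0, r1 = max(0, r - radius), min(grid.height, r + radius + 1)
    c0, c1 = max(0, c - radius), min(grid.width, c + radius + 1)
    return r0, r1, c0, c1


def _household_candidate_mask(
    grid: LandscapeGrid,
    sl,
    target: LandCover,
    year: int,
    scenario: Scenario,
) -> np.ndarray:
    """Vectorised mirror of allowed_conversion for household convert actions."""
    r0, r1, c0, c1 = sl
    cover = grid.cover[r0:r1, c0:c1]
    owner = grid.owner[r0:r1, c0:c1]
    mask = (cover != int(LandCover.SETTLEMENT)) & (cover != int(target)) & (owner == 0)
    if (
        "household" in scenario.moratorium_actor_scope
        and scenario.moratorium_start <= year <= scenario.moratorium_end
    ):
        for cls in scenario.protected_covers:
            mask &= cover != int(cls)
    return mask


def household_decide(
    household: Household,
    grid: LandscapeGrid,
    prices: Mapping[str, CommodityEconomics],
    scenario: Scenario,
    beta: float,
    rng: np.random.Generator,
    *,
    year: int | None = None,
    options: Sequence[LivelihoodOption] = DEFAULT_OPTIONS,
    scale: float = 100.0,
    max_conversions_per_year: int = 1,
) -> list[Action]:
    """Draw this year's livelihood action for one household.

    Feasibility: a convert option needs an unowned, non-settlement candidate
    cell of a different class within the search radius that passes
    :func:`allowed_conversion`; a collect/harvest option needs standing
    forest in the radius (and, for logging, enforcement that allows it).
    The chosen convert option is applied to the candidate cell with the
    highest suitability for its commodity (ties broken in row-major order).
    ``prices`` must already be scenario-adjusted.
    """
    if household.labor <= 0:
        return []
    yr = grid.year if year is None else year
    sl = _window(grid, household.home, household.search_radius)
    r0, r1, c0, c1 = sl
    cover_w = grid.cover[r0:r1, c0:c1]
    forest_here = np.isin(cover_w, [int(f) for f in FOREST_CLASSES])

    feasible: list[LivelihoodOption] = []
    masks: dict[str, np.ndarray] = {}
    for opt in options:
        if opt.converts_to is None:
            if not forest_here.any():
                continue
            if opt.implies_logging and not scenario.community_logging_allowed:
                continue
            feasible.append(opt)
        else:
            mask = _household_candidate_mask(grid, sl, opt.converts_to, yr, scenario)
            if mask.any():
                feasible.append(opt)
                masks[opt.name] = mask
    if not feasible:
        return []

    names = [o.name for o in feasible]
    probs = choice_probabilities(names, household.expectations, household.preferences, beta, scale)
    choice = feasible[int(rng.choice(len(feasible), p=probs))]

    actions: list[Action] = []
    if choice.converts_to is None:
        # collection/harvest on the nearest-in-reading-order forest cell
        flat = int(np.argmax(forest_here))
        rr, cc = divmod(flat, cover_w.shape[1])
        row, col = r0 + rr, c0 + cc
        kind = "harvest" if choice.implies_logging else "collect"
        decision = allowed_conversion(
            grid.cell(row, col),
            "household",
            LandCover.AGROFOREST,  # dummy convertible target; rule (c) is what matters
            yr,
            scenario,
            implies_logging=choice.implies_logging,
        )
        if not decision:
            return []
        actions.append(
            Action(
                actor_id=household.id,
                actor_kind="household",
                kind=kind,
                row=row,
                col=col,
                commodity=choice.commodity,
                source=LandCover(int(grid.cover[row, col])),
                reason=decision.reason,
                year=yr,
            )
        )
    else:
        mask = masks[choice.name]
        suit = grid.suitability_for(choice.commodity)[r0:r1, c0:c1]
        score = np.where(mask, suit, -np.inf)
        for _ in range(max_conversions_per_year):
            flat = int(np.argmax(score))  # first max in row-major order
            if not np.isfinite(score.ravel()[flat]):
                break
            rr, cc = divmod(flat, score.shape[1])
            row, col = r0 + rr, c0 + cc
            decision = allowed_conversion(
                grid.cell(row, col), "household", choice.converts_to, yr, scenario
            )
            if not decision:
                score[rr, cc] = -np.inf
                continue
            actions.append(
                Action(
                    actor_id=household.id,
                    actor_kind="household",
                    kind="convert",
                    row=row,
                    col=col,
                    target=choice.converts_to,
                    commodity=choice.commodity,
                    source=LandCover(int(grid.cover[row, col])),
                    reason=decision.reason,
                    year=yr,
                )
            )
            score[rr, cc] = -np.inf
    return actions


# ---------------------------------------------------------------------------
# Company decisions
# ---------------------------------------------------------------------------


def company_candidate_cells(
    company: Company,
    grid: LandscapeGrid,
    scenario: Scenario,
    year: int,
) -> np.ndarray:
    """Flat indices of zone cells the company may convert this year."""
    target = company.target_class
    mask = (
        (grid.zone == company.permit_zone)
        & (grid.cover != int(LandCover.SETTLEMENT))
        & (grid.cover != int(target))
        & (grid.owner == 0)
    )
    if (
        "company" in scenario.moratorium_actor_scope
        and scenario.moratorium_start <= year <= scenario.moratorium_end
    ):
        for cls in scenario.protected_covers:
            mask &= grid.cover != int(cls)
    if target in PLANTATION_CLASSES:
        allowed_soils = [int(s) for s in scenario.company_plantation_soils]
        mask &= np.isin(grid.soil, allowed_soils)
    return np.flatnonzero(mask.ravel())


def company_decide(
    company: Company,
    grid: LandscapeGrid,
    prices: Mapping[str, CommodityEconomics],
    scenario: Scenario,
    year: int,
    rng: np.random.Generator,
) -> list[Action]:
    """Select this year's company conversions.

    Candidates are the permitted cells of the concession; they are ranked by
    ``suitability * profit_margin`` (descending), ties broken by (row, col)
    reading order, and converted until the annual hectare quota is reached.
    A non-positive profit margin means the company does not expand.
    """
    if company.profit_margin <= 0:
        return []
    candidates = company_candidate_cells(company, grid, scenario, year)
    if candidates.size == 0:
        return []
    suit = grid.suitability_for(company.sector).ravel()[candidates]
    scores = suit * company.profit_margin
    order = np.lexsort((candidates, -scores))
    k = int(company.annual_quota_ha / grid.cell_area_ha)
    chosen = candidates[order[:k]]
    target = company.target_class
    actions = []
    for flat in chosen:
        row, col = divmod(int(flat), grid.width)
        decision = allowed_conversion(grid.cell(row, col), "company", target, year, scenario)
        if not decision:  # pragma: no cover - mask mirrors the rules
            continue
        actions.append(
            Action(
                actor_id=company.id,
                actor_kind="company",
                kind="convert",
                row=row,
                col=col,
                target=target,
                commodity=company.sector,
                source=LandCover(int(grid.cover[row, col])),
                reason=decision.reason,
                year=year,
            )
        )
    return actions
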