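"""Forest-moratorium scenario definitions and the rules they imply.

Three scenarios are shipped as presets:

* **BAU** (business as usual): peat forest is protected from conversion by
  permit-holding companies during a 2011-2014 moratorium window; household
  ("community-scale") conversion of peat forest remains possible.
* **EM** (extended moratorium): the company-scale window runs 2011-2036 and
  new company plantations may only be established on mineral soil.
* **MPL** (moratorium plus livelihoods): EM plus a livelihoods programme —
  farm-gate prices of NTFPs, agroforest rubber and community timber rise by
  15 %, production costs fall by a 5 % subsidy, local timber demand is
  restricted to community plantations, and community logging of natural
  forest is stopped by stricter enforcement.

The conversion-permission predicate :func:`allowed_conversion` is pure and
returns a reason code naming whichever rule fired, so simulation logs can be
audited rule by rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

from .landscape import CONVERTIBLE_TARGETS, CellView, LandCover, Soil

PLANTATION_CLASSES = frozenset({LandCover.OIL_PALM_PLANTATION, LandCover.TIMBER_PLANTATION})

#: commodities known to the economics table
COMMODITIES = ("rattan", "jelutong", "timber", "community_timber", "rubber", "rice", "oil_palm")


@dataclass(frozen=True)
class Scenario:
    """Machine-readable policy scenario."""

    name: str
    moratorium_start: int = 2011
    moratorium_end: int = 2014
    moratorium_actor_scope: frozenset[str] = frozenset({"company"})
    protected_covers: frozenset[LandCover] = frozenset({LandCover.PEAT_FOREST})
    company_plantation_soils: frozenset[Soil] = frozenset({Soil.PEAT, Soil.MINERAL})
    premium_commodities: frozenset[str] = frozenset()
    price_premium_frac: float = 0.0
    cost_subsidy_frac: float = 0.0
    community_logging_allowed: bool = True
    timber_demand_community_only: bool = False

    def __post_init__(self) -> None:
        if self.moratorium_start > self.moratorium_end:
            raise ValueError("moratorium_start must be <= moratorium_end")
        if not 0.0 <= self.price_premium_frac <= 1.0:
            raise ValueError("price_premium_frac must be in [0, 1]")
        if not 0.0 <= self.cost_subsidy_frac <= 1.0:
            raise ValueError("cost_subsidy_frac must be in [0, 1]")


BAU = Scenario(name="BAU")
EM = replace(
    BAU,
    name="EM",
    moratorium_end=2036,
    company_plantation_soils=frozenset({Soil.MINERAL}),
)
MPL = replace(
    EM,
    name="MPL",
    premium_commodities=frozenset({"rattan", "jelutong", "rubber", "community_timber"}),
    price_premium_frac=0.15,
    cost_subsidy_frac=0.05,
    community_logging_allowed=False,
    timber_demand_community_only=True,
)

_PRESETS = {"BAU": BAU, "EM": EM, "MPL": MPL}


def scenario_preset(name: str) -> Scenario:
    """Return one of the shipped scenarios by name (BAU, EM or MPL)."""
    try:
        return _PRESETS[name.upper()]
    except KeyError:
        raise ValueError(f"unknown scenario {name!r}; available: {sorted(_PRESETS)}") from None


@dataclass(frozen=True)
class Decision:
    """Outcome of a permission check: boolean plus the rule that fired."""

    allowed: bool
    reason: str

    def __bool__(self) -> bool:
        return self.allowed


def allowed_conversion(
    cell: CellView,
    actor_kind: str,
    target: LandCover,
    year: int,
    scenario: Scenario,
    *,
    implies_logging: bool = False,
) -> Decision:
    """Whether an actor may convert (or log) a cell this year.

    Denial reasons, in evaluation order:

    * ``"moratorium"`` — the actor kind is within the moratorium's scope,
      the cell's cover is protected, and the year falls inside the window;
    * ``"company_soil_restriction"`` — a company plantation target on a soil
      class the scenario excludes;
    * ``"community_logging_banned"`` — a household action that implies
      logging natural forest while enforcement forbids it.

    ``implies_logging`` marks timber harvesting from standing forest
    (community logging); plain conversion does not imply it.
    """
    if actor_kind not in ("household", "company"):
        raise ValueError(f"unknown actor kind {actor_kind!r}")
    if target not in CONVERTIBLE_TARGETS:
        raise ValueError(f"{LandCover(target).label} is not a convertible target class")
    if (
        actor_kind in scenario.moratorium_actor_scope
        and cell.cover in scenario.protected_covers
        and scenario.moratorium_start <= year <= scenario.moratorium_end
    ):
        return Decision(False, "moratorium")
    if (
        actor_kind == "company"
        and target in PLANTATION_CLASSES
        and cell.soil not in scenario.company_plantation_soils
    ):
        return Decision(False, "company_soil_restriction")
    if actor_kind == "household" and implies_logging and not scenario.community_logging_allowed:
        return Decision(False, "community_logging_banned")
    return Decision(True, "allowed")


@dataclass(frozen=True)
class CommodityEconomics:
    """Farm-gate economics of one commodity.

    ``yield_per_ha`` is in tonnes (or m3 for timber) per hectare per year
    on a mature plot; prices and costs are in currency units per tonne and
    per hectare-year respectively.
    """

    farm_gate_price: float
    production_cost: float
    yield_per_ha: float

    def __post_init__(self) -> None:
        if min(self.farm_gate_price, self.production_cost, self.yield_per_ha) < 0:
            raise ValueError("prices, costs and yields must be non-negative")

    @property
    def net_income_per_ha(self) -> float:
        return self.yield_per_ha * self.farm_gate_price - self.production_cost


class PriceTable(dict):
    """Mapping commodity name -> :class:`CommodityEconomics`."""

    def copy(self) -> "PriceTable":
        return PriceTable(self)


# Default farm-gate economics (currency/yr). These are uncalibrated
# order-of-magnitude placeholders, editable via CSV; they are chosen so that
# smallholder NTFP and agroforest incomes sit just below oil palm, which is
# the configuration under which a ~15 % premium makes forest-friendly options
# competitive with oil palm.
DEFAULT_PRICES = PriceTable(
    {
        "rattan": CommodityEconomics(1800.0, 30.0, 0.30),
        "jelutong": CommodityEconomics(2600.0, 30.0, 0.20),
        "timber": CommodityEconomics(260.0, 60.0, 2.0),
        "community_timber": CommodityEconomics(260.0, 60.0, 2.0),
        "rubber": CommodityEconomics(900.0, 40.0, 0.60),
        "rice": CommodityEconomics(250.0, 220.0, 2.5),
        "oil_palm": CommodityEconomics(100.0, 620.0, 12.0),
    }
)


def apply_scenario_prices(prices: Mapping[str, CommodityEconomics], scenario: Scenario) -> PriceTable:
    """Apply a scenario's price premium and cost subsidy to a price table.

    For commodities in ``scenario.premium_commodities`` the farm-gate price
    is multiplied by ``1 + price_premium_frac`` and the production cost by
    ``1 - cost_subsidy_frac``; all other commodities are untouched.  The
    input table is never mutated.
    """
    out = PriceTable()
    for name, econ in prices.items():
        if name in scenario.premium_commodities:
            econ = CommodityEconomics(
                farm_gate_price=econ.farm_gate_price * (1.0 + scenario.price_premium_frac),
                production_cost=econ.production_cost * (1.0 - scenario.cost_subsidy_frac),
                yield_per_ha=econ.yield_per_ha,
            )
        out[name] = econ
    return out


def load_price_table(path) -> PriceTable:
    """Load a price table from CSV (commodity,farm_gate_price,production_cost,yield_per_ha)."""
    import pandas as pd

    df = pd.read_csv(path)
    required = {"commodity", "farm_gate_price", "production_cost", "yield_per_ha"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"price table {path} is missing column(s) {sorted(missing)}")
    return PriceTable(
        {
            str(row.commodity): CommodityEconomics(
                float(row.farm_gate_price), float(row.production_cost), float(row.yield_per_ha)
            )
            for row in df.itertuples()
        }
    )


def save_price_table(prices: Mapping[str, CommodityEconomics], path) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            {
                "commodity": name,
                "farm_gate_price": e.farm_gate_price,
                "production_cost": e.production_cost,
                "yield_per_ha": e.yield_per_ha,
            }
            for name, e in prices.items()
        ]
    ).to_csv(path, index=False)
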