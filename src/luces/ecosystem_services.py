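"""Annual accounting of provisioning services and carbon stocks/emissions.

Six provisioning services are tracked: timber, rattan, jelutong, rubber,
rice and oil palm.  Cultivated services (rubber from agroforest, rice from
agriculture, oil palm and timber from plantations) are summed over the cells
of the producing class, with a maturity lag after conversion.  NTFPs (rattan
and jelutong) are tied to collection actions: only forest cells actually
visited by a collector this year contribute, so better NTFP markets raise
both supply and the incentive to keep forest standing.  Timber harvested by
community logging of natural forest is added to timber supply.

Carbon is split into above-ground biomass (per land-cover class) and a peat
stock carried by peat-soil cells.  Converted (non-forest) peat cells oxidise
at a fixed annual rate until their stock is exhausted.  Annual emissions use
a gross convention: the sum of positive per-cell stock decreases (conversion
losses plus peat oxidation); sequestration gains are reported separately and
never netted.  Default coefficients are order-of-magnitude placeholders
shipped as an editable CSV — they are not a calibration to any district.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .agents import Action
from .landscape import FOREST_CLASSES, LandCover, LandscapeGrid, Soil

SERVICES = ("timber", "rattan", "jelutong", "rubber", "rice", "oil_palm")

#: which cultivated commodity each producing class yields
_CULTIVATED_BY_CLASS = {
    LandCover.AGROFOREST: "rubber",
    LandCover.AGRICULTURE: "rice",
    LandCover.OIL_PALM_PLANTATION: "oil_palm",
    LandCover.TIMBER_PLANTATION: "timber",
}


@dataclass(frozen=True)
class ESCoefficients:
    """Per-class service yields and carbon densities.

    ``yields`` maps a producing class to (commodity, units/ha/yr);
    ``maturity`` is the plot age (years since conversion) at which the
    cultivated yield switches on.  ``ntfp_yields`` are the per-visited-cell
    NTFP off-takes.  ``agb_density`` is above-ground biomass in t CO2e/ha;
    ``peat_stock_density`` the drainable peat carbon under peat soil and
    ``peat_oxidation_rate`` its annual release from converted peat cells,
    both in t CO2e/ha.
    """

    yields: Mapping[LandCover, float] = field(
        default_factory=lambda: {
            LandCover.AGROFOREST: 0.60,  # rubber t/ha/yr
            LandCover.AGRICULTURE: 2.5,  # rice t/ha/yr
            LandCover.OIL_PALM_PLANTATION: 12.0,  # FFB t/ha/yr
            LandCover.TIMBER_PLANTATION: 3.0,  # m3/ha/yr
        }
    )
    maturity: Mapping[LandCover, int] = field(
        default_factory=lambda: {
            LandCover.AGROFOREST: 2,
            LandCover.AGRICULTURE: 1,
            LandCover.OIL_PALM_PLANTATION: 3,
            LandCover.TIMBER_PLANTATION: 5,
        }
    )
    ntfp_yields: Mapping[str, float] = field(
        default_factory=lambda: {"rattan": 0.30, "jelutong": 0.20}
    )
    logging_yield: float = 2.0  # m3 timber per logged forest cell-visit, per ha
    agb_density: Mapping[LandCover, float] = field(
        default_factory=lambda: {
            LandCover.PEAT_FOREST: 550.0,
            LandCover.MINERAL_FOREST: 650.0,
            LandCover.AGROFOREST: 300.0,
            LandCover.TIMBER_PLANTATION: 200.0,
            LandCover.OIL_PALM_PLANTATION: 130.0,
            LandCover.AGRICULTURE: 20.0,
            LandCover.SETTLEMENT: 10.0,
            LandCover.DEGRADED_LAND: 40.0,
        }
    )
    peat_stock_density: float = 3000.0
    peat_oxidation_rate: float = 60.0

    def __post_init__(self) -> None:
        for cls in FOREST_CLASSES:
            if self.yields.get(cls, 0.0) != 0.0:
                raise ValueError("forest classes must have zero cultivated yield")
        if any(v < 0 for v in self.yields.values()) or any(
            v < 0 for v in self.agb_density.values()
        ):
            raise ValueError("yields and carbon densities must be non-negative")
        if self.peat_stock_density < 0 or self.peat_oxidation_rate < 0:
            raise ValueError("peat parameters must be non-negative")

    def agb_lookup(self) -> np.ndarray:
        """Dense code -> density lookup array for vectorised accounting."""
        lut = np.zeros(max(LandCover) + 1, dtype=np.float64)
        for cls, d in self.agb_density.items():
            lut[int(cls)] = d
        return lut


@dataclass
class ESAccount:
    """One year's service supply and carbon ledger entry."""

    year: int
    supply: dict[str, float]
    agb_stock: float
    peat_stock: float
    total_stock: float
    annual_emission: float
    annual_sequestration: float = 0.0

    def __post_init__(self) -> None:
        if abs(self.total_stock - (self.agb_stock + self.peat_stock)) > 1e-6:
            raise ValueError("total_stock must equal agb_stock + peat_stock")


def compute_supply(
    grid: LandscapeGrid,
    coeffs: ESCoefficients,
    collection_log: Iterable[Action] = (),
) -> dict[str, float]:
    """This year's provisioning-service supply vector.

    Cultivated services sum ``yield * cell_area`` over mature cells of the
    producing class; NTFPs and logged timber sum over the collect/harvest
    actions in ``collection_log``.
    """
    area = grid.cell_area_ha
    supply = {s: 0.0 for s in SERVICES}
    for cls, commodity in _CULTIVATED_BY_CLASS.items():
        y = coeffs.yields.get(cls, 0.0)
        if y == 0.0:
            continue
        mature = (grid.cover == int(cls)) & (grid.age >= coeffs.maturity.get(cls, 0))
        supply[commodity] += y * area * int(mature.sum())
    for action in collection_log:
        if action.kind == "collect" and action.commodity in coeffs.ntfp_yields:
            supply[action.commodity] += coeffs.ntfp_yields[action.commodity] * area
        elif action.kind == "harvest":
            supply["timber"] += coeffs.logging_yield * area
    return supply


def peat_remaining(grid: LandscapeGrid, coeffs: ESCoefficients) -> np.ndarray:
    """Remaining peat stock density (t CO2e/ha) per cell, floored at zero."""
    peat = (grid.soil == int(Soil.PEAT)).astype(np.float64)
    return peat * np.maximum(coeffs.peat_stock_density - grid.peat_depleted, 0.0)


def compute_carbon_stock(
    grid: LandscapeGrid, coeffs: ESCoefficients
) -> tuple[float, float, float]:
    """(above-ground, peat, total) carbon stock in t CO2e."""
    area = grid.cell_area_ha
    agb = float(coeffs.agb_lookup()[grid.cover].sum()) * area
    peat = float(peat_remaining(grid, coeffs).sum()) * area
    return agb, peat, agb + peat


def annual_emissions(
    prev: LandscapeGrid, cur: LandscapeGrid, coeffs: ESCoefficients
) -> tuple[float, float]:
    """(gross emission, sequestration) between two consecutive annual states.

    Gross emission sums the positive per-cell stock decreases: above-ground
    losses where cover changed to a lower-density class, plus the peat
    oxidised this year.  Above-ground gains are returned as sequestration,
    never netted against the losses.
    """
    if prev.cover.shape != cur.cover.shape:
        raise ValueError("grids must have identical dimensions")
    area = cur.cell_area_ha
    lut = coeffs.agb_lookup()
    delta_agb = (lut[prev.cover] - lut[cur.cover]) * area
    agb_loss = float(delta_agb[delta_agb > 0].sum())
    agb_gain = float(-delta_agb[delta_agb < 0].sum())
    peat_flux = float((peat_remaining(prev, coeffs) - peat_remaining(cur, coeffs)).sum()) * area
    # peat stock is non-increasing, so the flux is a pure emission
    return agb_loss + max(peat_flux, 0.0), agb_gain


def make_account(
    grid: LandscapeGrid,
    coeffs: ESCoefficients,
    collection_log: Iterable[Action] = (),
    emission: float = 0.0,
    sequestration: float = 0.0,
) -> ESAccount:
    agb, peat, total = compute_carbon_stock(grid, coeffs)
    return ESAccount(
        year=grid.year,
        supply=compute_supply(grid, coeffs, collection_log),
        agb_stock=agb,
        peat_stock=peat,
        total_stock=total,
        annual_emission=emission,
        annual_sequestration=sequestration,
    )


def cumulative_emissions(ledger: Sequence[ESAccount]) -> float:
    return float(sum(acc.annual_emission for acc in ledger))


def emission_reduction(baseline: Sequence[ESAccount], alternative: Sequence[ESAccount]) -> float:
    """Percent reduction of cumulative emissions relative to a baseline run.

    ``100 * (sum(baseline) - sum(alternative)) / sum(baseline)``; undefined
    (raises) when the baseline emitted nothing.
    """
    if len(baseline) != len(alternative):
        raise ValueError("ledgers must cover the same number of years")
    base = cumulative_emissions(baseline)
    alt = cumulative_emissions(alternative)
    if base == 0.0:
        raise ZeroDivisionError("baseline emissions are zero; reduction is undefined")
    return 100.0 * (base - alt) / base


def ledger_frame(ledger: Sequence[ESAccount]):
    """Ledger as a DataFrame (services, AG/peat/total carbon, annual emission)."""
    import pandas as pd

    rows = []
    for acc in ledger:
        row = {"year": acc.year}
        row.update({f"supply_{s}": acc.supply.get(s, 0.0) for s in SERVICES})
        row.update(
            {
                "agb_stock": acc.agb_stock,
                "peat_stock": acc.peat_stock,
                "total_stock": acc.total_stock,
                "annual_emission": acc.annual_emission,
                "annual_sequestration": acc.annual_sequestration,
            }
        )
        rows.append(row)
    return pd.DataFrame(rows)


def load_coefficients(path) -> ESCoefficients:
    """Load per-class coefficients from CSV.

    Columns: ``class, cultivated_yield, maturity, agb_density`` plus the
    scalar peat parameters repeated on a ``__peat__`` row
    (``cultivated_yield`` = stock density, ``agb_density`` = oxidation rate).
    """
    import pandas as pd

    from .landscape import COVER_BY_NAME

    df = pd.read_csv(path)
    yields: dict[LandCover, float] = {}
    maturity: dict[LandCover, int] = {}
    agb: dict[LandCover, float] = {}
    peat_stock, peat_rate = 3000.0, 60.0
    for row in df.to_dict("records"):
        name = str(row["class"])
        if name == "__peat__":
            peat_stock = float(row["cultivated_yield"])
            peat_rate = float(row["agb_density"])
            continue
        cls = COVER_BY_NAME[name]
        if float(row["cultivated_yield"]) > 0:
            yields[cls] = float(row["cultivated_yield"])
        maturity[cls] = int(row["maturity"])
        agb[cls] = float(row["agb_density"])
    return ESCoefficients(
        yields=yields,
        maturity=maturity,
        agb_density=agb,
        peat_stock_density=peat_stock,
        peat_oxidation_rate=peat_rate,
    )


def save_coefficients(coeffs: ESCoefficients, path) -> None:
    import pandas as pd

    rows = []
    for cls in LandCover:
        rows.append(
            {
                "class": cls.label,
                "cultivated_yield": coeffs.yields.get(cls, 0.0),
                "maturity": coeffs.maturity.get(cls, 0),
                "agb_density": coeffs.agb_density.get(cls, 0.0),
            }
        )
    rows.append(
        {
            "class": "__peat__",
            "cultivated_yield": coeffs.peat_stock_density,
            "maturity": 0,
            "agb_density": coeffs.peat_oxidation_rate,
        }
    )
    pd.DataFrame(rows).to_csv(path, index=False)
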