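"""Raster landscape representation, ESRI ASCII I/O and synthetic district generation.

The simulated landscape is a dense raster of square plots (default 100 x 100
cells of 0.5 ha each, i.e. a 5000-ha window of a district).  Every cell carries
a land-cover class, a soil class (peat or mineral), per-commodity suitability
scores, an optional concession-zone identifier, an owner, and the number of
years since it was last converted.

Two district presets ship with the package.  They emulate the published
profiles of two Central Kalimantan districts: ``west_kotawaringin`` (52 %
forest cover in 2010, high population pressure) and ``kapuas`` (74 % forest
cover, largely peat, low population growth).  The generator is a pure
function of ``(profile, dims)`` so every test landscape is reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import IntEnum
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from scipy import ndimage


class LandCover(IntEnum):
    """Land-cover classes tracked by the simulator.

    The first six classes are the ones whose area trajectories the scenario
    comparison reports; ``settlement`` and ``degraded_land`` complete the
    partition of the landscape.
    """

    PEAT_FOREST = 1
    MINERAL_FOREST = 2
    AGROFOREST = 3
    TIMBER_PLANTATION = 4
    OIL_PALM_PLANTATION = 5
    AGRICULTURE = 6
    SETTLEMENT = 7
    DEGRADED_LAND = 8

    @property
    def label(self) -> str:
        return self.name.lower()


#: name -> class lookup, accepting the lower-case labels used in config files
COVER_BY_NAME: dict[str, LandCover] = {c.label: c for c in LandCover}

FOREST_CLASSES = (LandCover.PEAT_FOREST, LandCover.MINERAL_FOREST)

#: classes an actor may convert a cell *to* (settlement growth is a separate
#: system-level process, see dynamics.update_settlements)
CONVERTIBLE_TARGETS = frozenset(
    {
        LandCover.AGROFOREST,
        LandCover.AGRICULTURE,
        LandCover.OIL_PALM_PLANTATION,
        LandCover.TIMBER_PLANTATION,
    }
)

#: full transition-target set accepted by dynamics.apply_action
TRANSITION_TARGETS = frozenset(CONVERTIBLE_TARGETS | {LandCover.SETTLEMENT})

#: default raster code map: the enum codes themselves
DEFAULT_CODE_MAP: dict[int, LandCover] = {int(c): c for c in LandCover}


class Soil(IntEnum):
    MINERAL = 0
    PEAT = 1


@dataclass(frozen=True)
class CellView:
    """Read-only view of one cell, as consumed by the policy rules."""

    row: int
    col: int
    cover: LandCover
    soil: Soil
    zone: int  # -1 = no concession
    owner: int  # 0 = unowned, >0 household id, <0 company id
    age: int


@dataclass
class LandscapeGrid:
    """Dense raster landscape.

    Arrays are all ``(height, width)``; ``cover`` holds :class:`LandCover`
    codes, ``soil`` holds :class:`Soil` codes.  ``peat_depleted`` tracks the
    cumulative peat carbon (t CO2e/ha) already oxidised from each peat cell,
    which the carbon accounting subtracts from the standing peat stock.
    """

    cover: np.ndarray
    soil: np.ndarray
    suitability: dict[str, np.ndarray] = field(default_factory=dict)
    zone: np.ndarray | None = None
    owner: np.ndarray | None = None
    age: np.ndarray | None = None
    peat_depleted: np.ndarray | None = None
    cell_area_ha: float = 0.5
    year: int = 2010

    def __post_init__(self) -> None:
        self.cover = np.asarray(self.cover, dtype=np.int16)
        if self.cover.ndim != 2:
            raise ValueError("cover must be a 2-D array")
        self.soil = np.asarray(self.soil, dtype=np.int8)
        if self.soil.shape != self.cover.shape:
            raise ValueError("soil raster shape does not match cover")
        h, w = self.cover.shape
        if self.zone is None:
            self.zone = np.full((h, w), -1, dtype=np.int16)
        if self.owner is None:
            self.owner = np.zeros((h, w), dtype=np.int32)
        if self.age is None:
            self.age = np.zeros((h, w), dtype=np.int16)
        if self.peat_depleted is None:
            self.peat_depleted = np.zeros((h, w), dtype=np.float64)
        if self.cell_area_ha <= 0:
            raise ValueError("cell_area_ha must be positive")

    @property
    def height(self) -> int:
        return self.cover.shape[0]

    @property
    def width(self) -> int:
        return self.cover.shape[1]

    @property
    def n_cells(self) -> int:
        return self.cover.size

    @property
    def total_area_ha(self) -> float:
        return self.n_cells * self.cell_area_ha

    def cell(self, row: int, col: int) -> CellView:
        return CellView(
            row=row,
            col=col,
            cover=LandCover(int(self.cover[row, col])),
            soil=Soil(int(self.soil[row, col])),
            zone=int(self.zone[row, col]),
            owner=int(self.owner[row, col]),
            age=int(self.age[row, col]),
        )

    def suitability_for(self, commodity: str) -> np.ndarray:
        """Suitability map for a commodity; uniform 1.0 if none was supplied."""
        arr = self.suitability.get(commodity)
        if arr is None:
            return np.ones(self.cover.shape, dtype=np.float64)
        return arr

    def copy(self) -> "LandscapeGrid":
        return LandscapeGrid(
            cover=self.cover.copy(),
            soil=self.soil.copy(),
            suitability={k: v.copy() for k, v in self.suitability.items()},
            zone=self.zone.copy(),
            owner=self.owner.copy(),
            age=self.age.copy(),
            peat_depleted=self.peat_depleted.copy(),
            cell_area_ha=self.cell_area_ha,
            year=self.year,
        )


def area_summary(grid: LandscapeGrid) -> dict[LandCover, float]:
    """Fraction of total area occupied by each land-cover class.

    Fractions are cell counts divided by total cells and sum to 1 exactly
    (up to float rounding); classes absent from the grid get 0.0.
    """
    counts = np.bincount(grid.cover.ravel(), minlength=max(LandCover) + 1)
    total = grid.n_cells
    return {c: counts[int(c)] / total for c in LandCover}


def forest_fraction(grid: LandscapeGrid) -> float:
    """Combined peat + mineral forest fraction of the landscape."""
    summ = area_summary(grid)
    return summ[LandCover.PEAT_FOREST] + summ[LandCover.MINERAL_FOREST]


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O
# ---------------------------------------------------------------------------

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, dict[str, float]]:
    """Read an ESRI ASCII grid into an integer array plus its header.

    Row 0 of the returned array is the top raster row, matching reading
    order.  NODATA cells are rejected: the simulation window must be fully
    observed.
    """
    path = Path(path)
    header: dict[str, float] = {}
    data_lines: list[str] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if not data_lines and key in _HEADER_KEYS + ("nodata_value",):
                if len(parts) != 2:
                    raise ValueError(f"malformed header line in {path}: {line!r}")
                header[key] = float(parts[1])
            else:
                data_lines.append(line)
    for key in ("ncols", "nrows"):
        if key not in header:
            raise ValueError(f"malformed ESRI ASCII header in {path}: missing {key}")
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    values = np.loadtxt(data_lines, dtype=np.int64, ndmin=2)
    if values.size != nrows * ncols:
        raise ValueError(
            f"{path}: expected {nrows}x{ncols}={nrows * ncols} values, got {values.size}"
        )
    values = values.reshape(nrows, ncols)
    nodata = header.get("nodata_value")
    if nodata is not None and np.any(values == int(nodata)):
        raise ValueError(f"{path}: NODATA cells are not permitted inside the simulation window")
    return values, header


def write_ascii_grid(
    array: np.ndarray,
    path: str | Path,
    cellsize: float = 1.0,
    nodata: int | None = None,
) -> None:
    array = np.asarray(array)
    nrows, ncols = array.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write("xllcorner 0.0\n")
        fh.write("yllcorner 0.0\n")
        fh.write(f"cellsize {cellsize}\n")
        if nodata is not None:
            fh.write(f"NODATA_value {nodata}\n")
        for row in array:
            fh.write(" ".join(str(int(v)) for v in row) + "\n")


def read_landcover_raster(
    path: str | Path,
    code_map: Mapping[int, LandCover] | None = None,
    soil_path: str | Path | None = None,
    cell_area_ha: float = 0.5,
    year: int = 2010,
) -> LandscapeGrid:
    """Read a land-cover raster (ESRI ASCII, integer class codes).

    ``code_map`` maps raster codes to :class:`LandCover`; every code present
    in the file must appear in it.  If no soil raster is given, soil is
    derived from cover (peat under peat forest, mineral elsewhere).
    """
    code_map = dict(code_map) if code_map is not None else dict(DEFAULT_CODE_MAP)
    values, _ = read_ascii_grid(path)
    codes_present = np.unique(values)
    unknown = [int(c) for c in codes_present if int(c) not in code_map]
    if unknown:
        r, c = np.argwhere(np.isin(values, unknown))[0]
        raise ValueError(
            f"unknown land-cover code(s) {unknown} in {path} "
            f"(first at cell ({int(r)}, {int(c)})); not present in code_map"
        )
    cover = np.zeros(values.shape, dtype=np.int16)
    for code, cls in code_map.items():
        cover[values == code] = int(cls)
    if soil_path is not None:
        soil_values, _ = read_ascii_grid(soil_path)
        if soil_values.shape != cover.shape:
            raise ValueError("soil raster dimensions do not match land-cover raster")
        bad = np.setdiff1d(np.unique(soil_values), [int(s) for s in Soil])
        if bad.size:
            raise ValueError(f"unknown soil code(s) {bad.tolist()} in {soil_path}")
        soil = soil_values.astype(np.int8)
    else:
        soil = np.where(cover == int(LandCover.PEAT_FOREST), int(Soil.PEAT), int(Soil.MINERAL))
    grid = LandscapeGrid(cover=cover, soil=soil, cell_area_ha=cell_area_ha, year=year)
    _check_forest_soil_consistency(grid)
    return grid


def write_landcover_raster(
    grid: LandscapeGrid,
    path: str | Path,
    code_map: Mapping[LandCover, int] | None = None,
) -> None:
    """Write the cover layer as an ESRI ASCII grid; inverse of the reader."""
    if code_map is None:
        code_map = {c: int(c) for c in LandCover}
    present = {LandCover(int(v)) for v in np.unique(grid.cover)}
    missing = sorted(c.label for c in present if c not in code_map)
    if missing:
        raise ValueError(f"class(es) {missing} present in grid but missing from code_map")
    out = np.zeros(grid.cover.shape, dtype=np.int64)
    for cls, code in code_map.items():
        out[grid.cover == int(cls)] = code
    cellsize = math.sqrt(grid.cell_area_ha * 10_000.0)  # metres
    write_ascii_grid(out, path, cellsize=cellsize)


def read_code_map(path: str | Path) -> dict[int, LandCover]:
    """Read a two-column CSV ``code,name`` into a code map."""
    mapping: dict[int, LandCover] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.lower().startswith("code"):
                continue
            code_s, name = (part.strip() for part in line.split(","))
            if name not in COVER_BY_NAME:
                raise ValueError(f"unknown land-cover name {name!r} in {path}")
            mapping[int(code_s)] = COVER_BY_NAME[name]
    return mapping


def _check_forest_soil_consistency(grid: LandscapeGrid) -> None:
    pf = grid.cover == int(LandCover.PEAT_FOREST)
    mf = grid.cover == int(LandCover.MINERAL_FOREST)
    if np.any(grid.soil[pf] != int(Soil.PEAT)):
        raise ValueError("peat_forest cells must lie on peat soil")
    if np.any(grid.soil[mf] != int(Soil.MINERAL)):
        raise ValueError("mineral_forest cells must lie on mineral soil")


# ---------------------------------------------------------------------------
# Synthetic district generator
# ---------------------------------------------------------------------------

#: pseudo-class key: combined forest, split by ``peat_fraction_of_forest``
FOREST_KEY = "forest"


@dataclass(frozen=True)
class DistrictProfile:
    """Recipe for a synthetic district landscape.

    ``fractions`` maps class labels to target area fractions; the pseudo-key
    ``"forest"`` denotes combined forest and is split into peat/mineral
    forest by ``peat_fraction_of_forest``.  ``clumping`` controls spatial
    autocorrelation (0 = spatially random, larger = larger patches).
    ``peat_fraction_nonforest`` places residual peat soil (drained or
    degraded peatland) under a share of non-forest cells adjacent to the
    peat dome.  Demographic fields parameterise the agent population of a
    simulation initialised from this profile.
    """

    name: str
    fractions: Mapping[str, float]
    peat_fraction_of_forest: float = 0.5
    peat_fraction_nonforest: float = 0.1
    n_settlement_seeds: int = 3
    concession_fraction: float = 0.12
    clumping: float = 3.0
    seed: int = 0
    population_growth_rate: float = 0.0
    n_households: int = 200

    def __post_init__(self) -> None:
        total = float(sum(self.fractions.values()))
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1 (got {total!r})")
        if not 0.0 <= self.peat_fraction_of_forest <= 1.0:
            raise ValueError("peat_fraction_of_forest must be in [0, 1]")
        if not 0.0 <= self.concession_fraction <= 1.0:
            raise ValueError("concession_fraction must be in [0, 1]")
        if self.clumping < 0:
            raise ValueError("clumping must be non-negative")


# District presets. Forest cover and population growth follow the published
# 2010 profiles of the two districts (52 % / 4.2 %/yr and 74 % / 0.7 %/yr);
# the non-forest composition is a plausible split consistent with each
# district's described land-use history (oil-palm pressure in West
# Kotawaringin; degraded peat from the failed mega-rice project in Kapuas).
WEST_KOTAWARINGIN = DistrictProfile(
    name="west_kotawaringin",
    fractions={
        FOREST_KEY: 0.52,
        "agroforest": 0.10,
        "timber_plantation": 0.04,
        "oil_palm_plantation": 0.12,
        "agriculture": 0.10,
        "settlement": 0.04,
        "degraded_land": 0.08,
    },
    peat_fraction_of_forest=0.40,
    peat_fraction_nonforest=0.08,
    n_settlement_seeds=4,
    concession_fraction=0.15,
    clumping=3.0,
    seed=0,
    population_growth_rate=0.042,
    n_households=280,
)

KAPUAS = DistrictProfile(
    name="kapuas",
    fractions={
        FOREST_KEY: 0.74,
        "agroforest": 0.08,
        "timber_plantation": 0.02,
        "oil_palm_plantation": 0.03,
        "agriculture": 0.05,
        "settlement": 0.02,
        "degraded_land": 0.06,
    },
    peat_fraction_of_forest=0.60,
    peat_fraction_nonforest=0.30,
    n_settlement_seeds=3,
    concession_fraction=0.10,
    clumping=3.0,
    seed=0,
    population_growth_rate=0.007,
    n_households=190,
)

DISTRICT_PRESETS: dict[str, DistrictProfile] = {
    "west_kotawaringin": WEST_KOTAWARINGIN,
    "kapuas": KAPUAS,
}


def district_preset(name: str, seed: int | None = None) -> DistrictProfile:
    try:
        profile = DISTRICT_PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown district preset {name!r}; available: {sorted(DISTRICT_PRESETS)}"
        ) from None
    if seed is not None:
        profile = replace(profile, seed=seed)
    return profile


def _largest_remainder_counts(fractions: Iterable[float], total: int) -> list[int]:
    """Integer counts summing to ``total``, proportional to ``fractions``."""
    fr = np.asarray(list(fractions), dtype=np.float64)
    raw = fr * total
    counts = np.floor(raw).astype(np.int64)
    short = total - int(counts.sum())
    order = np.argsort(-(raw - counts), kind="stable")
    for i in range(short):
        counts[order[i]] += 1
    return counts.tolist()


def _resolve_class_counts(profile: DistrictProfile, n_cells: int) -> dict[LandCover, int]:
    fr = dict(profile.fractions)
    if FOREST_KEY in fr:
        if "peat_forest" in fr or "mineral_forest" in fr:
            raise ValueError("give either 'forest' or explicit peat/mineral forest, not both")
        forest = fr.pop(FOREST_KEY)
        fr["peat_forest"] = forest * profile.peat_fraction_of_forest
        fr["mineral_forest"] = forest * (1.0 - profile.peat_fraction_of_forest)
    unknown = set(fr) - set(COVER_BY_NAME)
    if unknown:
        raise ValueError(f"unknown land-cover name(s) in profile fractions: {sorted(unknown)}")
    classes = [COVER_BY_NAME[k] for k in fr]
    counts = _largest_remainder_counts(fr.values(), n_cells)
    result = dict(zip(classes, counts))
    if profile.n_settlement_seeds > 0 and result.get(LandCover.SETTLEMENT, 0) == 0:
        raise ValueError(
            "impossible composition: settlement seeds requested but settlement fraction is 0"
        )
    if result.get(LandCover.SETTLEMENT, 0) > 0 and profile.n_settlement_seeds == 0:
        raise ValueError(
            "impossible composition: settlement fraction > 0 but n_settlement_seeds is 0"
        )
    return {c: n for c, n in result.items() if n > 0}


_NEIGH = ((-1, 0), (1, 0), (0, -1), (0, 1))


def _grow_classes(
    counts: dict[int, int],
    seeds_per_class: dict[int, int],
    shape: tuple[int, int],
    rng: np.random.Generator,
    allowed: np.ndarray | None = None,
) -> np.ndarray:
    """Competitive seeded region growing.

    Each class receives its seed cells, then classes grow along 4-neighbour
    frontiers, drawing the next growing class proportionally to its remaining
    quota, until every allowed cell is claimed.  Exact per-class cell counts
    are guaranteed; a class whose frontier stalls is reseeded on a random
    free cell.
    """
    h, w = shape
    out = np.full(shape, -1, dtype=np.int32)
    if allowed is None:
        allowed = np.ones(shape, dtype=bool)
    free_idx = np.flatnonzero(allowed.ravel())
    assert sum(counts.values()) == free_idx.size

    remaining = dict(counts)
    frontiers: dict[int, list[int]] = {c: [] for c in counts}
    free_mask = allowed.copy()

    def claim(cls: int, flat: int) -> None:
        r, c = divmod(flat, w)
        out[r, c] = cls
        free_mask[r, c] = False
        remaining[cls] -= 1
        for dr, dc in _NEIGH:
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and free_mask[rr, cc]:
                frontiers[cls].append(rr * w + cc)

    # place seeds
    seed_cells = rng.choice(free_idx, size=sum(seeds_per_class.values()), replace=False)
    pos = 0
    for cls, n_seeds in seeds_per_class.items():
        for _ in range(n_seeds):
            if remaining[cls] <= 0:
                break
            flat = int(seed_cells[pos])
            pos += 1
            if free_mask.ravel()[flat]:
                claim(cls, flat)
    # grow
    active = [c for c in counts if remaining[c] > 0]
    while active:
        weights = np.array([remaining[c] for c in active], dtype=np.float64)
        cls = active[int(rng.choice(len(active), p=weights / weights.sum()))]
        placed = False
        frontier = frontiers[cls]
        while frontier:
            i = int(rng.integers(len(frontier)))
            flat = frontier[i]
            frontier[i] = frontier[-1]
            frontier.pop()
            if free_mask.ravel()[flat]:
                claim(cls, flat)
                placed = True
                break
        if not placed:
            # frontier exhausted: reseed on a random free cell
            free = np.flatnonzero(free_mask.ravel())
            claim(cls, int(rng.choice(free)))
        if remaining[cls] <= 0:
            active.remove(cls)
    return out


def _grow_single_block(
    free: np.ndarray, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Grow one contiguous block of ~n cells on the free mask.

    Plain random-frontier BFS from a single seed: the region is connected by
    construction.  If the region becomes enclosed before reaching n cells it
    stops early rather than fragmenting.
    """
    h, w = free.shape
    out = np.zeros_like(free)
    free_flat = np.flatnonzero(free.ravel())
    if n <= 0 or free_flat.size == 0:
        return out
    frontier = [int(rng.choice(free_flat))]
    taken = free.copy()
    placed = 0
    while frontier and placed < n:
        i = int(rng.integers(len(frontier)))
        flat = frontier[i]
        frontier[i] = frontier[-1]
        frontier.pop()
        r, c = divmod(flat, w)
        if not taken[r, c]:
            continue
        out[r, c] = True
        taken[r, c] = False
        placed += 1
        for dr, dc in _NEIGH:
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and taken[rr, cc]:
                frontier.append(rr * w + cc)
    return out


def _smooth_noise(shape: tuple[int, int], rng: np.random.Generator, size: int = 9) -> np.ndarray:
    """Spatially autocorrelated suitability surface in [0, 1]."""
    noise = rng.random(shape)
    sm = ndimage.uniform_filter(noise, size=size, mode="reflect")
    lo, hi = sm.min(), sm.max()
    if hi - lo < 1e-12:
        return np.full(shape, 0.5)
    return (sm - lo) / (hi - lo)


def generate_synthetic_district(
    profile: DistrictProfile,
    height: int = 100,
    width: int = 100,
) -> LandscapeGrid:
    """Generate a synthetic district landscape from a profile.

    Deterministic given ``profile.seed``.  Realised class fractions match the
    requested ones to within one cell per class (largest-remainder
    allocation), comfortably inside the +-2 percentage-point contract at
    100 x 100.  Settlements form ``n_settlement_seeds`` clusters, concession
    zones are contiguous blocks covering ``concession_fraction`` of
    non-settlement land, and forest is split into a peat dome and mineral
    forest by ``peat_fraction_of_forest``.
    """
    rng = np.random.default_rng(profile.seed)
    n_cells = height * width
    counts = _resolve_class_counts(profile, n_cells)
    shape = (height, width)

    int_counts = {int(c): n for c, n in counts.items()}
    if profile.clumping <= 0:
        # spatially random assignment
        codes = np.concatenate([np.full(n, c, dtype=np.int32) for c, n in int_counts.items()])
        rng.shuffle(codes)
        cover = codes.reshape(shape)
    else:
        patch = 1.0 + 10.0 * profile.clumping
        seeds = {}
        for c, n in int_counts.items():
            if c == int(LandCover.SETTLEMENT):
                seeds[c] = min(profile.n_settlement_seeds, n)
            else:
                seeds[c] = max(1, min(n, int(round(n / patch))))
        cover = _grow_classes(int_counts, seeds, shape, rng).astype(np.int16)

    # soil: peat under the peat forest plus a residual drained-peat fringe
    soil = np.zeros(shape, dtype=np.int8)
    pf_mask = cover == int(LandCover.PEAT_FOREST)
    soil[pf_mask] = int(Soil.PEAT)
    n_extra = int(round(profile.peat_fraction_nonforest * int((~pf_mask).sum())))
    if n_extra > 0 and pf_mask.any():
        # grow peat soil outward from the peat-forest boundary
        dist = ndimage.distance_transform_cdt(~pf_mask, metric="taxicab")
        candidates = np.flatnonzero((~pf_mask).ravel())
        order = np.lexsort((candidates, dist.ravel()[candidates]))
        soil.ravel()[candidates[order[:n_extra]]] = int(Soil.PEAT)
    elif n_extra > 0:
        flat = rng.choice(np.flatnonzero(~pf_mask.ravel()), size=n_extra, replace=False)
        soil.ravel()[flat] = int(Soil.PEAT)
    # invariant: mineral forest sits on mineral soil
    soil[cover == int(LandCover.MINERAL_FOREST)] = int(Soil.MINERAL)

    # concession zones: contiguous blocks on non-settlement land
    zone = np.full(shape, -1, dtype=np.int16)
    non_settlement = cover != int(LandCover.SETTLEMENT)
    n_zone_cells = int(round(profile.concession_fraction * int(non_settlement.sum())))
    if n_zone_cells > 0:
        n_blocks = 2 if n_zone_cells >= 2 else 1
        block_counts = _largest_remainder_counts([1.0 / n_blocks] * n_blocks, n_zone_cells)
        free = non_settlement.copy()
        for i, n_block in enumerate(block_counts):
            block = _grow_single_block(free, n_block, rng)
            zone[block] = i + 1
            free &= ~block

    suitability = {
        commodity: _smooth_noise(shape, rng)
        for commodity in ("oil_palm", "timber", "rubber", "rice")
    }

    # plantations and fields start at spread-out ages so initial supply is
    # non-zero and maturation staggers
    age = rng.integers(1, 30, size=shape).astype(np.int16)

    grid = LandscapeGrid(
        cover=cover.astype(np.int16),
        soil=soil,
        suitability=suitability,
        zone=zone,
        age=age,
        cell_area_ha=0.5,
        year=2010,
    )
    _check_forest_soil_consistency(grid)
    return grid


def mean_same_class_neighbors(cover: np.ndarray) -> float:
    """Average number of 4-neighbours sharing a cell's class.

    Spatial-autocorrelation summary used to verify that the generator's
    ``clumping`` parameter produces patchier maps.
    """
    same = np.zeros(cover.shape, dtype=np.float64)
    same[:-1, :] += cover[:-1, :] == cover[1:, :]
    same[1:, :] += cover[1:, :] == cover[:-1, :]
    same[:, :-1] += cover[:, :-1] == cover[:, 1:]
    same[:, 1:] += cover[:, 1:] == cover[:, :-1]
    return float(same.mean())
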