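"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from luces.landscape import LandCover, LandscapeGrid, Soil


def make_grid(
    cover,
    soil=None,
    zone=None,
    owner=None,
    age=None,
    suitability=None,
    cell_area_ha: float = 0.5,
    year: int = 2010,
) -> LandscapeGrid:
    """Build a grid from a nested list / array of LandCover codes.

    Soil defaults to peat under peat forest and mineral elsewhere.
    """
    cover = np.asarray(cover, dtype=np.int16)
    if soil is None:
        soil = np.where(cover == int(LandCover.PEAT_FOREST), int(Soil.PEAT), int(Soil.MINERAL))
    grid = LandscapeGrid(
        cover=cover,
        soil=np.asarray(soil, dtype=np.int8),
        suitability=suitability or {},
        cell_area_ha=cell_area_ha,
        year=year,
    )
    if zone is not None:
        grid.zone[:] = np.asarray(zone, dtype=np.int16)
    if owner is not None:
        grid.owner[:] = np.asarray(owner, dtype=np.int32)
    if age is not None:
        grid.age[:] = np.asarray(age, dtype=np.int16)
    return grid


def oracle_allowed_conversion(cover, soil, actor, target, year, scenario, implies_logging=False):
    """Independently coded rule-by-rule permission oracle.

    Written as a literal transcription of the scenario rules, one explicit
    conditional per rule, deliberately avoiding the set-based logic of the
    implementation.
    """
    # rule (a): the moratorium window
    if actor == "company" or (actor == "household" and "household" in scenario.moratorium_actor_scope):
        if actor in scenario.moratorium_actor_scope:
            if cover in scenario.protected_covers:
                if year >= scenario.moratorium_start and year <= scenario.moratorium_end:
                    return False
    # rule (b): company plantations restricted to permitted soils
    if actor == "company":
        if target in (LandCover.OIL_PALM_PLANTATION, LandCover.TIMBER_PLANTATION):
            permitted = False
            for s in scenario.company_plantation_soils:
                if soil == s:
                    permitted = True
            if not permitted:
                return False
    # rule (c): community logging enforcement
    if actor == "household":
        if implies_logging:
            if scenario.community_logging_allowed is False:
                return False
    return True


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
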