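"""Top-down disaggregation of unit counts onto the grid.

Within each admin unit, a cell's share of the unit's count is its weight
divided by the unit's weight total, so per-unit mass is conserved exactly
(up to float rounding) and only weight *ratios* within a unit matter.  The
simple areal-weighting (SAW) baseline is the uniform-weight special case.
Outputs are floating-point person counts; no integerization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Union

import numpy as np

from .admin import AdminSet
from .forest import WeightLayer
from .grids import Grid, UnitRaster

logger = logging.getLogger(__name__)

__all__ = [
    "PopulationGrid",
    "disaggregate",
    "saw_disaggregate",
    "people_per_hectare",
]

CENSUS_VARIANT = "census-year"
PROJECTED_VARIANT = "projected"
ADJUSTED_VARIANT = "projected-UNadj"


@dataclass
class PopulationGrid:
    """An estimated population surface: people per cell (ppp) or hectare (pph)."""

    grid: Grid
    year: int
    variant: str = CENSUS_VARIANT
    kind: str = "ppp"

    def __post_init__(self) -> None:
        inside = self.grid.valid_mask()
        if (self.grid.values[inside] < 0).any():
            raise ValueError("population surface contains negative cells")

    @property
    def total(self) -> float:
        """National total over in-area cells."""
        return float(self.grid.values[self.grid.valid_mask()].sum())


def _unit_cells(units: AdminSet, unit_raster: UnitRaster):
    inside = unit_raster.valid_mask()
    rows, cols = np.nonzero(inside)
    ids = unit_raster.values[rows, cols].astype(int)
    uniq, inv = np.unique(ids, return_inverse=True)
    unknown = set(uniq) - set(units.ids)
    if unknown:
        raise ValueError(f"unit raster has ids absent from AdminSet: {sorted(unknown)}")
    missing = set(units.ids) - set(uniq)
    if missing:
        raise ValueError(f"units own no cells: {sorted(missing)}")
    pops = np.array([units[int(u)].population for u in uniq], dtype=float)
    return rows, cols, uniq, inv, pops


def disaggregate(units: AdminSet, unit_raster: UnitRaster,
                 weights: Union[WeightLayer, Grid]) -> PopulationGrid:
    """Redistribute unit counts proportionally to the weighting layer.

    Cells of a unit whose weights sum to zero while its count is positive
    fall back to uniform shares, with a warning.
    """
    wgrid = weights.grid if isinstance(weights, WeightLayer) else weights
    unit_raster.require_aligned(wgrid, "unit raster and weights")
    rows, cols, uniq, inv, pops = _unit_cells(units, unit_raster)
    w = wgrid.values[rows, cols].astype(float)
    if (w[w != wgrid.nodata] < 0).any():
        raise ValueError("negative weights")
    w[w == wgrid.nodata] = 0.0

    wsum = np.bincount(inv, weights=w, minlength=len(uniq))
    dead = (wsum <= 0) & (pops > 0)
    if dead.any():
        logger.warning("%d units have zero weight mass; using uniform weights "
                       "within them", int(dead.sum()))
        w[np.isin(inv, np.nonzero(dead)[0])] = 1.0
        wsum = np.bincount(inv, weights=w, minlength=len(uniq))
    factor = np.zeros(len(uniq))
    nz = wsum > 0
    factor[nz] = pops[nz] / wsum[nz]

    values = np.full(unit_raster.shape, unit_raster.nodata, dtype=float)
    values[rows, cols] = w * factor[inv]
    grid = Grid(values, unit_raster.cell_size, unit_raster.origin,
                unit_raster.nodata, unit_raster.crs_label)
    return PopulationGrid(grid, year=units.census_year, variant=CENSUS_VARIANT)


def saw_disaggregate(units: AdminSet, unit_raster: UnitRaster) -> PopulationGrid:
    """Simple areal weighting: each cell of a unit gets count / cell count."""
    rows, cols, uniq, inv, pops = _unit_cells(units, unit_raster)
    counts = np.bincount(inv, minlength=len(uniq))
    values = np.full(unit_raster.shape, unit_raster.nodata, dtype=float)
    values[rows, cols] = (pops / counts)[inv]
    grid = Grid(values, unit_raster.cell_size, unit_raster.origin,
                unit_raster.nodata, unit_raster.crs_label)
    return PopulationGrid(grid, year=units.census_year, variant=CENSUS_VARIANT)


def people_per_hectare(ppp: PopulationGrid) -> PopulationGrid:
    """Convert people-per-cell to people-per-hectare."""
    if ppp.kind != "ppp":
        raise ValueError("input must be a ppp surface")
    cell_ha = ppp.grid.cell_size**2 / 10_000.0
    out = ppp.grid.copy()
    inside = out.valid_mask()
    out.values[inside] = out.values[inside] / cell_ha
    return PopulationGrid(out, year=ppp.year, variant=ppp.variant, kind="pph")
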