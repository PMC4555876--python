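"""Raster data model and low-level spatial operators.

The :class:`Grid` is the universal carrier for covariates, weighting layers
and population surfaces: a rectangular, north-up, row-major array in a
projected coordinate system, with a top-left origin and a numeric NoData
sentinel.  Cell footprints are half-open, ``[x, x + cell) x (y - cell, y]``.

Conventions fixed here and relied on everywhere else:

* a cell belongs to the polygon covering its centre; centres on a shared
  boundary go to the unit with the smaller id;
* distances are planar, centre-to-centre, in metres;
* NoData filling resolves ties by the donor earliest in row-major order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import shapely
from scipy import ndimage
from scipy.spatial import cKDTree
from shapely.geometry.base import BaseGeometry

from .admin import AdminSet

logger = logging.getLogger(__name__)

DEFAULT_NODATA = -99999.0

__all__ = [
    "Grid",
    "UnitRaster",
    "rasterize_units",
    "rasterize_geometry",
    "buffer_region",
    "nibble_fill",
    "distance_to",
    "focal_proportion",
    "slope_from_dem",
]


@dataclass
class Grid:
    """A georeferenced 2-D raster.

    Parameters
    ----------
    values
        2-D array, row-major, north-up (row 0 is the northern edge).
    cell_size
        Cell side length in metres.
    origin
        ``(x, y)`` of the top-left corner in projected metres.
    nodata
        Sentinel marking cells outside the data domain.
    crs_label
        Opaque identifier of the projected coordinate system.
    """

    values: np.ndarray
    cell_size: float = 100.0
    origin: tuple[float, float] = (0.0, 0.0)
    nodata: float = DEFAULT_NODATA
    crs_label: str = "local"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("Grid values must be 2-D")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")
        v = self.values
        bad = ~np.isfinite(v) & (v != self.nodata)
        if bad.any():
            raise ValueError("Grid contains non-finite values other than nodata")

    # -- geometry ---------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(minx, miny, maxx, maxy) of the raster footprint."""
        x0, y0 = self.origin
        return (
            x0,
            y0 - self.n_rows * self.cell_size,
            x0 + self.n_cols * self.cell_size,
            y0,
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (x, y) coordinate arrays of every cell centre, shape (nrows, ncols)."""
        x0, y0 = self.origin
        cols = np.arange(self.n_cols)
        rows = np.arange(self.n_rows)
        x = x0 + (cols + 0.5) * self.cell_size
        y = y0 - (rows + 0.5) * self.cell_size
        return np.meshgrid(x, y)

    # -- masks and alignment ---------------------------------------------
    def valid_mask(self) -> np.ndarray:
        return self.values != self.nodata

    def aligned_with(self, other: "Grid") -> bool:
        return (
            self.shape == other.shape
            and self.cell_size == other.cell_size
            and self.origin == other.origin
        )

    def require_aligned(self, other: "Grid", what: str = "grids") -> None:
        if not self.aligned_with(other):
            raise ValueError(f"{what} are not aligned (shape/cell_size/origin differ)")

    def copy(self) -> "Grid":
        return replace(self, values=self.values.copy())

    def like(self, values: np.ndarray, nodata: Optional[float] = None) -> "Grid":
        """A new grid on this grid's frame, carrying ``values``."""
        return Grid(
            values,
            cell_size=self.cell_size,
            origin=self.origin,
            nodata=self.nodata if nodata is None else nodata,
            crs_label=self.crs_label,
        )


@dataclass
class UnitRaster(Grid):
    """A Grid whose non-nodata cells hold admin-unit ids (integers)."""

    unit_ids: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        super().__post_init__()
        present = set(np.unique(self.values[self.values != self.nodata]).astype(int))
        if self.unit_ids and not present <= set(self.unit_ids):
            raise ValueError("UnitRaster contains ids absent from the source AdminSet")


def _frame_for(bounds: tuple[float, float, float, float], cell_size: float):
    """Snap a bounding box to a raster frame: origin top-left, whole cells."""
    minx, miny, maxx, maxy = bounds
    n_cols = max(1, int(np.ceil((maxx - minx) / cell_size - 1e-9)))
    n_rows = max(1, int(np.ceil((maxy - miny) / cell_size - 1e-9)))
    return (minx, maxy), n_rows, n_cols


def buffer_region(units: AdminSet, distance: float) -> BaseGeometry:
    """Outward buffer of the union of unit polygons.

    Defines the processing extent so 'distance to' covariates are not
    distorted by the study-area boundary.
    """
    if distance < 0:
        raise ValueError("buffer distance must be >= 0")
    geom = units.union_geometry()
    if distance == 0:
        return geom
    return geom.buffer(distance)


def rasterize_units(
    units: AdminSet,
    cell_size: float = 100.0,
    extent: Optional[tuple[float, float, float, float]] = None,
    crs_label: str = "local",
) -> UnitRaster:
    """Label every cell with the id of the unit covering its centre.

    Cells whose centre lies in no unit are nodata.  Centres exactly on a
    shared boundary go to the unit with the smaller id.  Any unit too small
    to capture a cell centre is given the cell containing its representative
    interior point, so every unit owns at least one cell.

    Parameters
    ----------
    extent
        Optional (minx, miny, maxx, maxy) frame; defaults to the bounds of
        the union of unit polygons.
    """
    if len(units) == 0:
        raise ValueError("cannot rasterize an empty AdminSet")
    if extent is None:
        extent = units.union_geometry().bounds
    origin, n_rows, n_cols = _frame_for(extent, cell_size)
    labels = np.full((n_rows, n_cols), DEFAULT_NODATA, dtype=float)
    grid = Grid(labels, cell_size, origin, DEFAULT_NODATA, crs_label)
    xs, ys = grid.cell_centers()

    # ascending id order + covers() makes boundary ties go to the smaller id
    for unit in sorted(units, key=lambda u: u.unit_id):
        gminx, gminy, gmaxx, gmaxy = unit.geometry.bounds
        x0, y0 = origin
        c0 = max(0, int((gminx - x0) / cell_size) - 1)
        c1 = min(n_cols, int(np.ceil((gmaxx - x0) / cell_size)) + 1)
        r0 = max(0, int((y0 - gmaxy) / cell_size) - 1)
        r1 = min(n_rows, int(np.ceil((y0 - gminy) / cell_size)) + 1)
        if r0 >= r1 or c0 >= c1:
            continue
        sub_x = xs[r0:r1, c0:c1]
        sub_y = ys[r0:r1, c0:c1]
        hit = shapely.intersects_xy(unit.geometry, sub_x, sub_y)
        free = labels[r0:r1, c0:c1] == DEFAULT_NODATA
        sel = hit & free
        block = labels[r0:r1, c0:c1]
        block[sel] = unit.unit_id
        labels[r0:r1, c0:c1] = block

    # guarantee >= 1 cell per unit (units smaller than a cell)
    owned = set(np.unique(labels[labels != DEFAULT_NODATA]).astype(int))
    for unit in units:
        if unit.unit_id not in owned:
            pt = unit.geometry.representative_point()
            col = int((pt.x - origin[0]) / cell_size)
            row = int((origin[1] - pt.y) / cell_size)
            row = min(max(row, 0), n_rows - 1)
            col = min(max(col, 0), n_cols - 1)
            labels[row, col] = unit.unit_id
            logger.info(
                "unit %d captured no cell centre; assigned cell (%d, %d)",
                unit.unit_id, row, col,
            )
    return UnitRaster(
        labels, cell_size, origin, DEFAULT_NODATA, crs_label,
        unit_ids=frozenset(units.ids),
    )


def rasterize_geometry(
    geom: BaseGeometry,
    cell_size: float,
    extent: Optional[tuple[float, float, float, float]] = None,
    crs_label: str = "local",
) -> Grid:
    """Binary grid: 1 where the cell centre is covered by ``geom``, else 0."""
    if extent is None:
        extent = geom.bounds
    origin, n_rows, n_cols = _frame_for(extent, cell_size)
    grid = Grid(np.zeros((n_rows, n_cols)), cell_size, origin, DEFAULT_NODATA, crs_label)
    xs, ys = grid.cell_centers()
    grid.values[shapely.intersects_xy(geom, xs, ys)] = 1.0
    return grid


def nibble_fill(grid: Grid, mask: Grid) -> Grid:
    """Fill nodata cells inside the mask with the nearest valid cell's value.

    Nearest by Euclidean distance between cell centres; equidistant donors
    resolve to the one earliest in row-major scan order.  Cells outside the
    mask and valid cells are untouched.
    """
    grid.require_aligned(mask, "grid and mask")
    inside = mask.valid_mask()
    valid = grid.valid_mask()
    holes = inside & ~valid
    if not holes.any():
        return grid.copy()
    if not valid.any():
        raise ValueError("grid is entirely nodata; nothing to fill from")

    vr, vc = np.nonzero(valid)
    donors = np.column_stack([vr, vc]).astype(float)
    # row-major rank of each donor, for deterministic tie-breaking
    donor_rank = vr * grid.n_cols + vc
    tree = cKDTree(donors)
    tr, tc = np.nonzero(holes)
    targets = np.column_stack([tr, tc]).astype(float)
    dist, _ = tree.query(targets)

    out = grid.copy()
    for k in range(len(targets)):
        cand = tree.query_ball_point(targets[k], dist[k] + 1e-6)
        dr = vr[cand] - tr[k]
        dc = vc[cand] - tc[k]
        d2 = dr * dr + dc * dc
        best = d2 == d2.min()
        ranks = donor_rank[np.asarray(cand)[best]]
        winner = np.asarray(cand)[best][np.argmin(ranks)]
        out.values[tr[k], tc[k]] = grid.values[vr[winner], vc[winner]]
    return out


def _check_binary(grid: Grid) -> np.ndarray:
    v = grid.values
    ok = (v == 0) | (v == 1) | (v == grid.nodata)
    if not ok.all():
        raise ValueError("grid is not binary (values other than 0/1/nodata)")
    return v == 1


def distance_to(binary: Grid) -> Grid:
    """Planar distance (metres) from each cell centre to the nearest 1-cell."""
    feature = _check_binary(binary)
    if not feature.any():
        raise ValueError("distance_to: no cell equals 1")
    # exact EDT: recover integer squared distances from nearest-feature indices
    ind = ndimage.distance_transform_edt(~feature, return_distances=False,
                                         return_indices=True)
    rr, cc = np.indices(feature.shape)
    dr = ind[0] - rr
    dc = ind[1] - cc
    d2 = (dr * dr + dc * dc).astype(float)
    return binary.like(np.sqrt(d2) * binary.cell_size, nodata=DEFAULT_NODATA)


def focal_proportion(binary: Grid, radius: float = 500.0) -> Grid:
    """Share of 1-cells within a circular window of ``radius`` metres.

    Window membership is by centre distance <= radius, the focal cell
    included; the denominator counts only in-bounds cells, so edge cells are
    normalized by their truncated window.
    """
    feature = _check_binary(binary)
    if radius <= 0:
        raise ValueError("radius must be > 0")
    r_cells = int(radius / binary.cell_size)
    off = np.arange(-r_cells, r_cells + 1)
    dr, dc = np.meshgrid(off, off, indexing="ij")
    kernel = ((dr * dr + dc * dc) * binary.cell_size**2 <= radius**2).astype(np.int64)
    ones = np.ones(feature.shape, dtype=np.int64)
    count = ndimage.convolve(feature.astype(np.int64), kernel, mode="constant", cval=0)
    total = ndimage.convolve(ones, kernel, mode="constant", cval=0)
    return binary.like(count / total, nodata=DEFAULT_NODATA)


def slope_from_dem(dem: Grid) -> Grid:
    """Topographic slope in degrees from finite differences of the DEM.

    Central differences in the interior, one-sided at the borders.
    """
    if dem.n_rows < 2 or dem.n_cols < 2:
        raise ValueError("DEM must be at least 2x2")
    gy, gx = np.gradient(dem.values, dem.cell_size)
    slope = np.degrees(np.arctan(np.hypot(gx, gy)))
    return dem.like(slope, nodata=DEFAULT_NODATA)
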