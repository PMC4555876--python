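"""File I/O: ESRI ASCII grids, GeoJSON admin units, delimited tables.

Rasters are read and written as single-band ESRI ASCII grids (``.asc``), a
plain-text georeferenced format understood by every GIS.  Vector units
travel as GeoJSON FeatureCollections with ``unit_id``, ``level``,
``population``, ``area_km2`` and ``parent_id`` properties; coordinates are
in the projected system the pipeline operates in.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape

from .admin import AdminSet, AdminUnit
from .grids import Grid, UnitRaster

__all__ = [
    "read_ascii_grid",
    "write_ascii_grid",
    "read_units_geojson",
    "write_units_geojson",
    "join_census_counts",
    "read_growth_schedule",
]

PathLike = Union[str, Path]


def write_ascii_grid(grid: Grid, path: PathLike) -> None:
    """Write a grid as an ESRI ASCII raster (cell-corner registration)."""
    minx, miny, _, _ = grid.bounds
    header = (
        f"ncols {grid.n_cols}\n"
        f"nrows {grid.n_rows}\n"
        f"xllcorner {minx:.6f}\n"
        f"yllcorner {miny:.6f}\n"
        f"cellsize {grid.cell_size:.6f}\n"
        f"NODATA_value {grid.nodata:.17g}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        for row in grid.values:
            fh.write(" ".join(f"{v:.17g}" for v in row))
            fh.write("\n")


def read_ascii_grid(path: PathLike, crs_label: str = "local") -> Grid:
    with open(path) as fh:
        header: dict[str, float] = {}
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh, ndmin=2)
    n_rows = int(header["nrows"])
    n_cols = int(header["ncols"])
    if values.shape != (n_rows, n_cols):
        raise ValueError(f"{path}: data shape {values.shape} != header "
                         f"({n_rows}, {n_cols})")
    cell = header["cellsize"]
    origin = (header["xllcorner"], header["yllcorner"] + n_rows * cell)
    return Grid(values, cell, origin, header.get("nodata_value", -9999.0), crs_label)


def write_units_geojson(units: AdminSet, path: PathLike) -> None:
    features = []
    for u in units:
        features.append({
            "type": "Feature",
            "geometry": mapping(u.geometry),
            "properties": {
                "unit_id": u.unit_id,
                "level": u.level,
                "population": u.population,
                "area_km2": u.area_km2,
                "parent_id": u.parent_id,
            },
        })
    doc = {
        "type": "FeatureCollection",
        "census_year": units.census_year,
        "country_code": units.country_code,
        "features": features,
    }
    Path(path).write_text(json.dumps(doc))


def read_units_geojson(
    path: PathLike,
    id_field: str = "unit_id",
    population_field: str = "population",
) -> AdminSet:
    doc = json.loads(Path(path).read_text())
    units = []
    for feat in doc["features"]:
        props = feat["properties"]
        geom = shape(feat["geometry"])
        area = props.get("area_km2") or geom.area / 1e6
        units.append(AdminUnit(
            unit_id=int(props[id_field]),
            level=int(props.get("level", 0)),
            geometry=geom,
            population=int(props.get(population_field, 0)),
            area_km2=float(area),
            parent_id=(None if props.get("parent_id") is None
                       else int(props["parent_id"])),
        ))
    return AdminSet(
        units,
        census_year=int(doc.get("census_year", 0)),
        country_code=str(doc.get("country_code", "XXX")),
    )


def join_census_counts(
    units: AdminSet,
    table: PathLike,
    id_field: str = "unit_id",
    population_field: str = "population",
) -> AdminSet:
    """Replace unit populations with counts joined from a delimited table."""
    df = pd.read_csv(table)
    counts = dict(zip(df[id_field].astype(int), df[population_field].astype(int)))
    return units.with_populations(counts)


def read_growth_schedule(path: PathLike) -> pd.DataFrame:
    """Read the growth-rate schedule table.

    Expected columns: country, census_year, target_year, urban_rate,
    rural_rate, and optionally unpd_total (blank where no external national
    estimate exists).
    """
    df = pd.read_csv(path)
    required = {"census_year", "target_year", "urban_rate", "rural_rate"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"growth schedule missing columns {sorted(missing)}")
    if "unpd_total" not in df.columns:
        df["unpd_total"] = np.nan
    return df


def write_unit_raster(raster: UnitRaster, path: PathLike) -> None:
    write_ascii_grid(raster, path)
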