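"""Seeded synthetic landscapes for testing every pipeline stage offline.

A world is a rectangular tessellation of coarse units refined into
children, a stack of smooth continuous covariates and a categorical
land-cover field with an urban core, and a ground-truth density surface
whose log is a known linear combination of (standardized) covariates plus
smooth spatial noise.  Unit counts are the rounded integral of the truth
over unit cells, with largest-remainder rounding inside each coarse unit
so the two-level hierarchy sums exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import box

from .admin import AdminSet, AdminUnit
from .covariates import CovariateStack, build_stack, mosaic_urban
from .grids import Grid, UnitRaster, rasterize_units
from .temporal import GrowthSchedule

__all__ = ["SyntheticWorld", "make_landscape", "make_growth_schedule"]

DEFAULT_EFFECT = {"lights": 1.2, "elev": -0.8, "dst_blt": -1.0}


@dataclass
class SyntheticWorld:
    """A complete synthetic study area with known ground truth."""

    fine_units: AdminSet
    coarse_units: AdminSet
    stack: CovariateStack
    true_density: Grid          # people per km², noiseless carrier of truth
    fine_raster: UnitRaster
    coarse_raster: UnitRaster
    landcover: Grid
    urban_extent: Grid
    seed: int
    params: dict = field(default_factory=dict)

    @property
    def cell_area_km2(self) -> float:
        return self.true_density.cell_size**2 / 1e6

    def true_cell_population(self) -> np.ndarray:
        return self.true_density.values * self.cell_area_km2


def _near_square_factors(n: int) -> tuple[int, int]:
    best = (1, n)
    for a in range(1, int(np.sqrt(n)) + 1):
        if n % a == 0:
            best = (a, n // a)
    return best


def _split_edges(total: int, parts: int) -> np.ndarray:
    """Near-equal integer partition boundaries: parts+1 edges over [0, total]."""
    return np.round(np.linspace(0, total, parts + 1)).astype(int)


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int],
                  radius: int) -> np.ndarray:
    """Standardized moving-average-filtered white noise."""
    f = ndimage.uniform_filter(rng.standard_normal(shape), size=2 * radius + 1,
                               mode="reflect")
    return (f - f.mean()) / f.std()


def _largest_remainder(real: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation of ``total`` proportional to ``real``, exact sum."""
    real = np.maximum(real, 0.0)
    if real.sum() == 0:
        shares = np.full(len(real), total / len(real))
    else:
        shares = real / real.sum() * total
    floors = np.floor(shares).astype(int)
    short = total - floors.sum()
    frac = shares - floors
    order = np.argsort(-frac, kind="stable")
    floors[order[:short]] += 1
    return floors


def make_landscape(
    seed: int,
    n_rows: int = 120,
    n_cols: int = 120,
    n_coarse: int = 6,
    children_per_coarse: int = 4,
    effect: Optional[Mapping[str, float]] = None,
    noise_sd: float = 0.3,
    cell_size: float = 100.0,
    base_log_density: float = 5.0,
    smooth_radius: int = 8,
    country_code: str = "SYN",
    census_year: int = 2005,
) -> SyntheticWorld:
    """Generate a seeded synthetic world.

    ``effect`` maps covariate-stack names to coefficients of the true
    log-density; covariates are standardized before entering, so effects
    are in log-density units per standard deviation.  ``noise_sd`` scales a
    smooth spatial noise field added on top.
    """
    if n_rows <= 0 or n_cols <= 0 or n_coarse <= 0 or children_per_coarse <= 0:
        raise ValueError("counts must be positive")
    effect = dict(DEFAULT_EFFECT if effect is None else effect)
    rng = np.random.default_rng(seed)
    shape = (n_rows, n_cols)
    origin = (0.0, n_rows * cell_size)

    # --- nested rectangular tessellation --------------------------------
    ca, cb = _near_square_factors(n_coarse)
    fa, fb = _near_square_factors(children_per_coarse)
    row_edges = _split_edges(n_rows, ca)
    col_edges = _split_edges(n_cols, cb)
    if np.diff(row_edges).min() < fa or np.diff(col_edges).min() < fb:
        raise ValueError("grid too small for the requested unit counts")

    def cells_to_box(r0: int, r1: int, c0: int, c1: int):
        return box(c0 * cell_size, (n_rows - r1) * cell_size,
                   c1 * cell_size, (n_rows - r0) * cell_size)

    coarse_units, fine_units = [], []
    cid = 0
    for i in range(ca):
        for j in range(cb):
            cid += 1
            r0, r1 = row_edges[i], row_edges[i + 1]
            c0, c1 = col_edges[j], col_edges[j + 1]
            geom = cells_to_box(r0, r1, c0, c1)
            coarse_units.append(AdminUnit(cid, 1, geom, 0, geom.area / 1e6))
            sub_r = _split_edges(r1 - r0, fa) + r0
            sub_c = _split_edges(c1 - c0, fb) + c0
            k = 0
            for ii in range(fa):
                for jj in range(fb):
                    k += 1
                    if (sub_r[ii + 1] - sub_r[ii]) * (sub_c[jj + 1] - sub_c[jj]) < 4:
                        raise ValueError("fine units would own < 4 cells")
                    g = cells_to_box(sub_r[ii], sub_r[ii + 1],
                                     sub_c[jj], sub_c[jj + 1])
                    fine_units.append(AdminUnit(100 * cid + k, 2, g, 0,
                                                g.area / 1e6, parent_id=cid))

    extent = (0.0, 0.0, n_cols * cell_size, n_rows * cell_size)

    # --- covariate fields ------------------------------------------------
    lights_f = _smooth_field(rng, shape, smooth_radius)
    elev_f = _smooth_field(rng, shape, smooth_radius)
    tmean_f = _smooth_field(rng, shape, smooth_radius)
    lc_f = _smooth_field(rng, shape, smooth_radius)
    core_f = _smooth_field(rng, shape, max(2, smooth_radius // 2))

    def as_grid(v):
        return Grid(v.astype(float), cell_size, origin, crs_label="synthetic")

    urban = core_f > np.quantile(core_f, 0.97)
    builtup = (core_f > np.quantile(core_f, 0.92)) & ~urban
    lc = np.where(lc_f < np.quantile(lc_f, 0.45), 40.0,
                  np.where(lc_f < np.quantile(lc_f, 0.85), 140.0, 11.0))
    lc[builtup] = 240.0
    landcover_raw = as_grid(lc)
    urban_extent = as_grid(urban.astype(float))
    landcover = mosaic_urban(landcover_raw, urban_extent)

    # night lights glow around the built core, plus independent texture
    glow = ndimage.uniform_filter((urban | builtup).astype(float),
                                  size=2 * smooth_radius + 1, mode="reflect")
    glow_z = (glow - glow.mean()) / (glow.std() or 1.0)
    lights = 0.7 * glow_z + 0.5 * lights_f

    continuous = {"lights": as_grid(lights), "elev": as_grid(elev_f),
                  "tmean": as_grid(tmean_f)}

    fine_set = AdminSet(fine_units, census_year, country_code)
    coarse_set = AdminSet(coarse_units, census_year, country_code)
    fine_raster = rasterize_units(fine_set, cell_size, extent=extent,
                                  crs_label="synthetic")
    coarse_raster = rasterize_units(coarse_set, cell_size, extent=extent,
                                    crs_label="synthetic")
    stack = build_stack(landcover, continuous, {}, fine_raster)

    # --- ground-truth density -------------------------------------------
    log_dens = np.full(shape, base_log_density)
    for name, coef in effect.items():
        if name not in stack:
            raise KeyError(f"effect names unknown covariate {name!r}")
        v = stack[name].values
        sd = v.std()
        z = (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)
        log_dens = log_dens + coef * z
    if noise_sd > 0:
        log_dens = log_dens + noise_sd * _smooth_field(rng, shape, smooth_radius)
    true_density = as_grid(np.exp(log_dens))

    # --- unit counts: integrate truth, round inside each coarse unit -----
    cell_pop = np.exp(log_dens) * cell_size**2 / 1e6
    fine_ids = fine_raster.values.astype(int)
    fine_order = sorted(u.unit_id for u in fine_units)
    real = {uid: float(cell_pop[fine_ids == uid].sum()) for uid in fine_order}
    fine_pop: dict[int, int] = {}
    for cu in coarse_units:
        children = [u.unit_id for u in fine_units if u.parent_id == cu.unit_id]
        reals = np.array([real[c] for c in children])
        total = int(round(reals.sum()))
        alloc = _largest_remainder(reals, total)
        fine_pop.update(dict(zip(children, alloc.tolist())))
    fine_set = fine_set.with_populations(fine_pop)
    coarse_pop = {cu.unit_id: sum(fine_pop[u.unit_id] for u in fine_set
                                  if u.parent_id == cu.unit_id)
                  for cu in coarse_units}
    coarse_set = coarse_set.with_populations(coarse_pop)

    return SyntheticWorld(
        fine_units=fine_set,
        coarse_units=coarse_set,
        stack=stack,
        true_density=true_density,
        fine_raster=fine_raster,
        coarse_raster=coarse_raster,
        landcover=landcover,
        urban_extent=urban_extent,
        seed=seed,
        params={
            "n_rows": n_rows, "n_cols": n_cols, "n_coarse": n_coarse,
            "children_per_coarse": children_per_coarse, "effect": effect,
            "noise_sd": noise_sd, "cell_size": cell_size,
            "base_log_density": base_log_density, "smooth_radius": smooth_radius,
        },
    )


def make_growth_schedule(
    seed: int,
    census_year: int,
    target_year: int,
    urban_range: tuple[float, float] = (0.0, 0.04),
    rural_range: tuple[float, float] = (-0.01, 0.02),
    urban_total: Optional[float] = None,
    rural_total: Optional[float] = None,
    perturbation_range: tuple[float, float] = (1.0, 1.0),
) -> GrowthSchedule:
    """Draw a random but seeded growth schedule.

    Rates are uniform over the stated ranges.  When the census-year urban
    and rural totals are supplied, a consistent external national total is
    computed as the closed-form projected total times a perturbation drawn
    from ``perturbation_range``; otherwise ``unpd_total`` is None.
    """
    if target_year < census_year:
        raise ValueError("target year must be >= census year")
    rng = np.random.default_rng(seed)
    u = float(rng.uniform(*urban_range))
    r = float(rng.uniform(*rural_range))
    unpd = None
    if urban_total is not None and rural_total is not None:
        dt = target_year - census_year
        projected = urban_total * np.exp(u * dt) + rural_total * np.exp(r * dt)
        unpd = float(projected * rng.uniform(*perturbation_range))
    return GrowthSchedule(census_year, target_year, u, r, unpd_total=unpd)


def write_world_inputs(world: SyntheticWorld, outdir) -> dict[str, str]:
    """Write a world to disk in the formats the pipeline reads.

    Emits the fine units (GeoJSON, with counts and parent links), the
    land-cover / urban-extent / continuous rasters (ASCII grids), and a
    three-target-year growth schedule with consistent external totals.
    Returns a name → path mapping suitable for a run configuration.
    """
    from .covariates import URBAN_CLASS
    from .io import write_ascii_grid, write_units_geojson

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    def put_grid(name: str, grid: Grid) -> None:
        p = outdir / f"{name}.asc"
        write_ascii_grid(grid, p)
        paths[name] = str(p)

    write_units_geojson(world.fine_units, outdir / "units.geojson")
    paths["units"] = str(outdir / "units.geojson")
    put_grid("landcover", world.landcover)
    put_grid("urban_extent", world.urban_extent)
    for name in ("lights", "elev", "tmean"):
        put_grid(name, world.stack[name])

    cell_pop = world.true_cell_population()
    urban_cells = world.landcover.values == URBAN_CLASS
    urban_total = float(cell_pop[urban_cells].sum())
    rural_total = float(cell_pop[~urban_cells].sum())
    rows = []
    for i, year in enumerate((2010, 2015, 2020)):
        sched = make_growth_schedule(
            world.seed + 1000 + i, world.fine_units.census_year, year,
            urban_total=urban_total, rural_total=rural_total,
            perturbation_range=(0.98, 1.05),
        )
        rows.append({
            "country": world.fine_units.country_code,
            "census_year": sched.census_year,
            "target_year": sched.target_year,
            "urban_rate": sched.urban_rate,
            "rural_rate": sched.rural_rate,
            "unpd_total": sched.unpd_total,
        })
    sched_path = outdir / "growth_schedule.csv"
    pd.DataFrame(rows).to_csv(sched_path, index=False)
    paths["schedule"] = str(sched_path)
    return paths
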