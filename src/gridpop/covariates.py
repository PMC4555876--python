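"""Covariate engineering: land-cover recode, urban mosaic, cls/dst/prp stack,
and zonal aggregation to admin units.

Naming convention for class-derived layers, parseable by :func:`parse_name`:

* ``cls_<k>`` — binary presence of land-cover class (or feature) ``k``
* ``dst_<k>`` — planar distance to the nearest ``k`` cell, metres
* ``prp_<k>`` — proportion of ``k`` cells within the focal radius

Continuous layers keep their own names (``lights``, ``elev``, ``slope``...).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Optional

import numpy as np
import pandas as pd

from .grids import Grid, UnitRaster, distance_to, focal_proportion, nibble_fill

logger = logging.getLogger(__name__)

URBAN_CLASS = 190
RURAL_BUILTUP_CLASS = 240
BUILTUP_CLASSES = (URBAN_CLASS, RURAL_BUILTUP_CLASS)
BLT = "blt"

FOCAL_RADIUS_M = 500.0

__all__ = [
    "CovariateStack",
    "recode_landcover",
    "mosaic_urban",
    "built_up_class",
    "class_presence",
    "build_stack",
    "zonal_aggregate",
    "parse_name",
    "URBAN_CLASS",
    "RURAL_BUILTUP_CLASS",
    "BLT",
]


def parse_name(name: str) -> tuple[Optional[str], str]:
    """Split a covariate name into (family, key); family None for continuous."""
    for fam in ("cls", "dst", "prp"):
        if name.startswith(fam + "_"):
            return fam, name[len(fam) + 1:]
    return None, name


@dataclass
class CovariateStack:
    """An aligned, named collection of covariate grids."""

    grids: dict[str, Grid] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = list(self.grids)
        for name in names[1:]:
            self.grids[names[0]].require_aligned(self.grids[name],
                                                 f"stack members {names[0]!r}/{name!r}")

    def __getitem__(self, name: str) -> Grid:
        return self.grids[name]

    def __contains__(self, name: str) -> bool:
        return name in self.grids

    def __iter__(self) -> Iterator[str]:
        return iter(self.grids)

    def __len__(self) -> int:
        return len(self.grids)

    @property
    def names(self) -> list[str]:
        return list(self.grids)

    def add(self, name: str, grid: Grid) -> None:
        if name in self.grids:
            raise KeyError(f"duplicate covariate name {name!r}")
        if self.grids:
            next(iter(self.grids.values())).require_aligned(grid, f"stack and {name!r}")
        self.grids[name] = grid

    def subset(self, names: list[str]) -> "CovariateStack":
        missing = set(names) - set(self.grids)
        if missing:
            raise KeyError(f"covariates not in stack: {sorted(missing)}")
        return CovariateStack({n: self.grids[n] for n in names})

    def frame(self) -> Grid:
        """Any member grid, as the geometric frame of the stack."""
        return next(iter(self.grids.values()))

    def to_matrix(self, rows: np.ndarray, cols: np.ndarray,
                  names: Optional[list[str]] = None) -> np.ndarray:
        """Extract an (n_cells, p) matrix at the given cell indices."""
        names = names or self.names
        return np.column_stack([self.grids[n].values[rows, cols] for n in names])


def recode_landcover(raw: Grid, mapping: Mapping[int, int],
                     default: Optional[int] = None) -> Grid:
    """Recode raw land-cover codes to the target class set.

    Codes absent from ``mapping`` fall back to ``default``; with no default
    they become nodata, and the count of such cells is logged.
    """
    if not mapping:
        raise ValueError("empty recode mapping")
    out = np.full(raw.shape, raw.nodata, dtype=float)
    unmapped = 0
    codes = np.unique(raw.values[raw.valid_mask()])
    for code in codes:
        sel = raw.values == code
        key = int(code)
        if key in mapping:
            out[sel] = mapping[key]
        elif default is not None:
            out[sel] = default
        else:
            unmapped += int(sel.sum())
    if unmapped:
        logger.warning("recode_landcover: %d cells carry unmapped codes -> nodata",
                       unmapped)
    return raw.like(out)


def mosaic_urban(landcover: Grid, urban_extent: Grid) -> Grid:
    """Overlay the binary urban-extent layer onto the land-cover grid.

    Urban-extent cells become class 190; built-up cells outside the urban
    extent become class 240 (rural built-up); everything else is unchanged.
    """
    landcover.require_aligned(urban_extent, "landcover and urban extent")
    out = landcover.copy()
    built = np.isin(landcover.values, BUILTUP_CLASSES)
    urban = urban_extent.values == 1
    out.values[built & ~urban] = RURAL_BUILTUP_CLASS
    out.values[urban] = URBAN_CLASS
    return out


def class_presence(landcover: Grid, code: int) -> Grid:
    """Binary presence grid of one land-cover class."""
    return landcover.like((landcover.values == code).astype(float))


def built_up_class(landcover: Grid) -> Grid:
    """Binary grid of the combined built-up class (urban 190 + rural 240)."""
    return landcover.like(np.isin(landcover.values, BUILTUP_CLASSES).astype(float))


def build_stack(
    landcover: Optional[Grid],
    continuous: Mapping[str, Grid],
    binary_features: Mapping[str, Grid],
    mask: UnitRaster,
    focal_radius: float = FOCAL_RADIUS_M,
) -> CovariateStack:
    """Assemble the full covariate stack aligned to the study-area mask.

    Every land-cover class present (plus the combined built-up class, plus
    each named binary feature layer) yields a cls/dst/prp triple; classes
    with no presence cell lose their dst/prp layers with a log record.
    Continuous layers are nibble-filled inside the mask and passed through.
    """
    stack = CovariateStack()

    def add_triple(key: str, binary: Grid) -> None:
        stack.add(f"cls_{key}", binary)
        if (binary.values == 1).any():
            stack.add(f"dst_{key}", distance_to(binary))
            stack.add(f"prp_{key}", focal_proportion(binary, focal_radius))
        else:
            logger.warning("class %s has no presence cells; dst_/prp_ dropped", key)

    if landcover is not None:
        mask.require_aligned(landcover, "mask and landcover")
        codes = np.unique(landcover.values[landcover.valid_mask()]).astype(int)
        for code in sorted(codes):
            add_triple(str(code), class_presence(landcover, code))
        if np.isin(landcover.values, BUILTUP_CLASSES).any():
            add_triple(BLT, built_up_class(landcover))
    for name, grid in binary_features.items():
        mask.require_aligned(grid, f"mask and feature {name!r}")
        add_triple(name, grid)
    for name, grid in continuous.items():
        mask.require_aligned(grid, f"mask and covariate {name!r}")
        stack.add(name, nibble_fill(grid, mask))
    return stack


def zonal_aggregate(stack: CovariateStack, unit_raster: UnitRaster) -> pd.DataFrame:
    """Aggregate each covariate to admin units: mean for continuous layers,
    mode for binary ``cls_`` layers (50/50 ties report absence).

    Returns a DataFrame indexed by unit_id, one column per covariate.

    Continuous means use exactly-rounded summation (``math.fsum``), so the
    result is independent of cell ordering down to the last bit.
    """
    frame = stack.frame()
    frame.require_aligned(unit_raster, "stack and unit raster")
    inside = unit_raster.valid_mask()
    ids = unit_raster.values[inside].astype(int)
    uniq, inv = np.unique(ids, return_inverse=True)
    counts = np.bincount(inv)
    order = np.argsort(inv, kind="stable")
    splits = np.cumsum(counts)[:-1]

    data: dict[str, np.ndarray] = {}
    for name in stack.names:
        vals = stack[name].values[inside]
        fam, _ = parse_name(name)
        if fam == "cls":
            ones = np.bincount(inv, weights=vals, minlength=len(uniq))
            data[name] = (ones * 2 > counts).astype(float)  # tie -> 0
        else:
            groups = np.split(vals[order], splits)
            data[name] = np.array(
                [math.fsum(g) / len(g) for g in groups]
            )
    df = pd.DataFrame(data, index=pd.Index(uniq.astype(int), name="unit_id"))
    return df
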