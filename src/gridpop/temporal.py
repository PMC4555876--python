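"""Temporal projection and national-total adjustment.

Census-year surfaces are carried to target years by stratified growth:
urban cells grow at the urban rate, all other in-area cells at the rural
rate.  The growth law is continuous exponential, ``exp(rate · Δt)``, with a
geometric alternative ``(1 + rate)^Δt`` behind a switch.  Adjustment to an
external national estimate is a single multiplicative factor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .dasymetric import ADJUSTED_VARIANT, PROJECTED_VARIANT, PopulationGrid
from .grids import Grid

__all__ = ["GrowthSchedule", "project_population", "unpd_adjust"]

EXPONENTIAL = "exponential"
GEOMETRIC = "geometric"


@dataclass(frozen=True)
class GrowthSchedule:
    """Annual urban/rural growth rates from census year to target year."""

    census_year: int
    target_year: int
    urban_rate: float
    rural_rate: float
    unpd_total: Optional[float] = None

    def __post_init__(self) -> None:
        if self.target_year < self.census_year:
            raise ValueError("target_year must be >= census_year")
        if self.urban_rate <= -1 or self.rural_rate <= -1:
            raise ValueError("growth rates must be > -1")

    def factors(self, law: str = EXPONENTIAL) -> tuple[float, float]:
        """(urban, rural) multiplicative factors over the whole horizon."""
        dt = self.target_year - self.census_year
        if law == EXPONENTIAL:
            return math.exp(self.urban_rate * dt), math.exp(self.rural_rate * dt)
        if law == GEOMETRIC:
            return (1 + self.urban_rate) ** dt, (1 + self.rural_rate) ** dt
        raise ValueError(f"unknown growth law {law!r}")


def project_population(ppp: PopulationGrid, urban_mask: Grid,
                       schedule: GrowthSchedule,
                       law: str = EXPONENTIAL) -> PopulationGrid:
    """Scale urban and rural strata to the schedule's target year."""
    ppp.grid.require_aligned(urban_mask, "population grid and urban mask")
    if ppp.year != schedule.census_year:
        raise ValueError(f"grid year {ppp.year} != schedule census year "
                         f"{schedule.census_year}")
    f_urban, f_rural = schedule.factors(law)
    out = ppp.grid.copy()
    inside = out.valid_mask()
    urban = urban_mask.values == 1
    out.values[inside & urban] *= f_urban
    out.values[inside & ~urban] *= f_rural
    return PopulationGrid(out, year=schedule.target_year,
                          variant=PROJECTED_VARIANT, kind=ppp.kind)


def unpd_adjust(ppp: PopulationGrid, target_total: float) -> PopulationGrid:
    """Rescale every in-area cell so the national total hits ``target_total``."""
    if target_total < 0:
        raise ValueError("target_total must be >= 0")
    current = ppp.total
    if current == 0:
        if target_total > 0:
            raise ValueError("cannot adjust an all-zero surface to a positive total")
        factor = 1.0
    else:
        factor = target_total / current
    out = ppp.grid.copy()
    inside = out.valid_mask()
    out.values[inside] *= factor
    return PopulationGrid(out, year=ppp.year, variant=ADJUSTED_VARIANT,
                          kind=ppp.kind)
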