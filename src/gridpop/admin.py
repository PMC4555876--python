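"""Administrative-unit data model: polygons with census counts.

An :class:`AdminSet` is the census input of the pipeline — a flat collection
of polygon units at a single administrative level, each carrying a unique
integer id, a population count and an area, with optional links to parent
units one level coarser.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Optional

from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union

__all__ = ["AdminUnit", "AdminSet"]


@dataclass(frozen=True)
class AdminUnit:
    """One administrative unit: polygon, id, count, area, optional parent."""

    unit_id: int
    level: int
    geometry: BaseGeometry
    population: int
    area_km2: float
    parent_id: Optional[int] = None

    def __post_init__(self) -> None:
        if self.population < 0:
            raise ValueError(f"unit {self.unit_id}: population must be >= 0")
        if self.area_km2 <= 0:
            raise ValueError(f"unit {self.unit_id}: area_km2 must be > 0")
        if self.geometry.geom_type not in ("Polygon", "MultiPolygon"):
            raise ValueError(
                f"unit {self.unit_id}: geometry must be polygonal, "
                f"got {self.geometry.geom_type}"
            )


@dataclass
class AdminSet:
    """A collection of administrative units at one level.

    Invariants checked on construction: ids unique, populations >= 0,
    areas > 0.  If parent links are present, children of one parent are
    expected to sum to the parent's count; that is asserted where both
    levels are in hand (see :func:`gridpop.validation.aggregate_to_coarser`).
    """

    units: list[AdminUnit]
    census_year: int = 0
    country_code: str = "XXX"
    _by_id: dict[int, AdminUnit] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        ids = [u.unit_id for u in self.units]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate unit ids in AdminSet")
        self._by_id = {u.unit_id: u for u in self.units}

    def __len__(self) -> int:
        return len(self.units)

    def __iter__(self) -> Iterator[AdminUnit]:
        return iter(self.units)

    def __getitem__(self, unit_id: int) -> AdminUnit:
        return self._by_id[unit_id]

    def __contains__(self, unit_id: int) -> bool:
        return unit_id in self._by_id

    @property
    def ids(self) -> list[int]:
        return [u.unit_id for u in self.units]

    @property
    def total_population(self) -> int:
        return sum(u.population for u in self.units)

    @property
    def total_area_km2(self) -> float:
        return sum(u.area_km2 for u in self.units)

    def union_geometry(self) -> BaseGeometry:
        return unary_union([u.geometry for u in self.units])

    def with_populations(self, counts: dict[int, int]) -> "AdminSet":
        """Return a copy with populations replaced from ``counts``."""
        missing = set(self.ids) - set(counts)
        if missing:
            raise KeyError(f"counts missing for units {sorted(missing)}")
        units = [replace(u, population=int(counts[u.unit_id])) for u in self.units]
        return AdminSet(units, self.census_year, self.country_code)
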