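"""Per-unit response variable: natural log of population density.

Density is people per km², from the census count and the unit's projected
area.  The log transform normalizes the heavily right-skewed density
distribution before model fitting.  Zero-population units have no defined
log density; they are excluded from the training table (and logged) but
still receive cells — and a zero share — downstream.
"""

from __future__ import annotations

import logging
import math

import pandas as pd

from .admin import AdminSet

logger = logging.getLogger(__name__)

__all__ = ["log_density"]


def log_density(units: AdminSet) -> pd.DataFrame:
    """Build the training response: one row per populated unit.

    Returns a DataFrame indexed by unit_id with a single ``log_density``
    column, ln(population / area_km2).
    """
    rows: dict[int, float] = {}
    excluded = []
    for u in units:
        if u.population > 0:
            rows[u.unit_id] = math.log(u.population / u.area_km2)
        else:
            excluded.append(u.unit_id)
    if not rows:
        raise ValueError("all units have zero population; no response to fit")
    if excluded:
        logger.info("log_density: excluded %d zero-population units: %s",
                    len(excluded), excluded[:20])
    df = pd.DataFrame({"log_density": pd.Series(rows)})
    df.index.name = "unit_id"
    return df
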