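"""Coarse-to-fine holdout validation and the model metadata report.

The holdout scheme: aggregate the finest units one level up, fit the model
and disaggregate using only the coarse counts, then score the result
against the withheld fine counts.  The fine counts never reach the fit —
the model sees coarse aggregates only.  The same grid is scored for the
uniform-density baseline (SAW), mirroring the published comparison.
"""

from __future__ import annotations

import html
import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd
from shapely.ops import unary_union

from .admin import AdminSet, AdminUnit
from .covariates import CovariateStack, zonal_aggregate
from .dasymetric import PopulationGrid, disaggregate, saw_disaggregate
from .forest import ForestModel, ForestParams, fit_forest, predict_density, select_covariates
from .grids import UnitRaster, rasterize_units
from .response import log_density

__all__ = [
    "ValidationReport",
    "aggregate_to_coarser",
    "unit_sums",
    "error_stats",
    "holdout_compare",
    "avg_spatial_resolution",
    "metadata_report",
]


@dataclass(frozen=True)
class ValidationReport:
    """Error statistics of one disaggregation method at one unit level."""

    method: str                      # "RF" or "SAW"
    unit_level: int
    n_units: int
    rmse: float
    pct_rmse: float
    mae: float
    oob_mse: Optional[float] = None
    pct_var_explained: Optional[float] = None

    def to_row(self) -> dict:
        return {
            "method": self.method,
            "unit_level": self.unit_level,
            "n_units": self.n_units,
            "oob_error": self.oob_mse,
            "pct_var_explained": self.pct_var_explained,
            "rmse": self.rmse,
            "pct_rmse": self.pct_rmse,
            "mae": self.mae,
        }


def aggregate_to_coarser(fine: AdminSet) -> AdminSet:
    """One unit per parent: union geometry, summed counts, level − 1."""
    if any(u.parent_id is None for u in fine):
        raise ValueError("fine units must carry parent_id links")
    groups: dict[int, list[AdminUnit]] = {}
    for u in fine:
        groups.setdefault(u.parent_id, []).append(u)
    units = []
    for pid in sorted(groups):
        children = groups[pid]
        units.append(AdminUnit(
            unit_id=pid,
            level=children[0].level - 1,
            geometry=unary_union([c.geometry for c in children]),
            population=sum(c.population for c in children),
            area_km2=sum(c.area_km2 for c in children),
            parent_id=None,
        ))
    return AdminSet(units, fine.census_year, fine.country_code)


def unit_sums(grid: PopulationGrid, unit_raster: UnitRaster) -> pd.DataFrame:
    """Sum of grid cells per admin unit (exactly-rounded summation)."""
    g = grid.grid
    g.require_aligned(unit_raster, "grid and unit raster")
    inside = unit_raster.valid_mask()
    ids = unit_raster.values[inside].astype(int)
    vals = g.values[inside]
    vals = np.where(vals == g.nodata, 0.0, vals)
    uniq, inv = np.unique(ids, return_inverse=True)
    order = np.argsort(inv, kind="stable")
    splits = np.cumsum(np.bincount(inv))[:-1]
    sums = [math.fsum(chunk) for chunk in np.split(vals[order], splits)]
    return pd.DataFrame({"predicted": sums},
                        index=pd.Index(uniq, name="unit_id"))


def error_stats(predicted: pd.Series, observed: pd.Series,
                method_label: str, unit_level: int = 0) -> ValidationReport:
    """RMSE, %RMSE and MAE of per-unit predictions against observed counts.

    %RMSE is RMSE as a percentage of the mean observed fine-unit count.
    """
    predicted = pd.Series(predicted)
    observed = pd.Series(observed)
    if len(predicted) == 0 or len(observed) == 0:
        raise ValueError("empty prediction/observation tables")
    if set(predicted.index) != set(observed.index):
        raise ValueError("predicted and observed tables cover different units")
    obs = observed.loc[predicted.index].to_numpy(dtype=float)
    pred = predicted.to_numpy(dtype=float)
    err = pred - obs
    rmse = float(np.sqrt(np.mean(err**2)))
    mae = float(np.mean(np.abs(err)))
    mean_obs = float(np.mean(obs))
    if mean_obs == 0:
        raise ValueError("mean observed population is zero; %RMSE undefined")
    return ValidationReport(
        method=method_label,
        unit_level=unit_level,
        n_units=len(obs),
        rmse=rmse,
        pct_rmse=100.0 * rmse / mean_obs,
        mae=mae,
    )


def holdout_compare(
    fine: AdminSet,
    stack: CovariateStack,
    params: ForestParams,
    fine_raster: Optional[UnitRaster] = None,
) -> tuple[ValidationReport, ValidationReport]:
    """Coarse-to-fine holdout: model-weighted vs uniform disaggregation.

    Fits on coarse aggregates only (with covariate elimination), predicts
    the weighting layer, disaggregates the coarse counts both ways, and
    scores per-fine-unit sums against the withheld fine counts.
    """
    coarse = aggregate_to_coarser(fine)
    if len(coarse) < 2:
        raise ValueError("degenerate hierarchy: need >= 2 coarse units")
    frame = stack.frame()
    extent = frame.bounds
    if fine_raster is None:
        fine_raster = rasterize_units(fine, frame.cell_size, extent=extent,
                                      crs_label=frame.crs_label)
    coarse_raster = rasterize_units(coarse, frame.cell_size, extent=extent,
                                    crs_label=frame.crs_label)
    frame.require_aligned(fine_raster, "stack and fine raster")

    zonal = zonal_aggregate(stack, coarse_raster)
    resp = log_density(coarse)          # coarse counts only: no fine leakage
    names, _ = select_covariates(zonal, resp, params)
    model = fit_forest(zonal, resp, params, covariate_names=names,
                       source_country=fine.country_code)
    weights = predict_density(model, stack, coarse_raster)

    rf_grid = disaggregate(coarse, coarse_raster, weights)
    saw_grid = saw_disaggregate(coarse, coarse_raster)

    observed = pd.Series({u.unit_id: float(u.population) for u in fine})
    level = fine.units[0].level
    rf_pred = unit_sums(rf_grid, fine_raster)["predicted"]
    saw_pred = unit_sums(saw_grid, fine_raster)["predicted"]
    rf_report = error_stats(rf_pred, observed, "RF", unit_level=level)
    saw_report = error_stats(saw_pred, observed, "SAW", unit_level=level)
    rf_report = replace(rf_report, oob_mse=model.oob_mse,
                        pct_var_explained=model.pct_var_explained)
    return rf_report, saw_report


def avg_spatial_resolution(area_km2: float, n_units: int) -> float:
    """Effective resolution of an admin partition: √(area / number of units)."""
    if area_km2 <= 0 or n_units <= 0:
        raise ValueError("area and unit count must be positive")
    return math.sqrt(area_km2 / n_units)


def metadata_report(
    model: ForestModel,
    reports: list[ValidationReport],
    provenance: Optional[pd.DataFrame] = None,
    audit: Optional[list[dict]] = None,
) -> str:
    """Render the self-contained HTML metadata report for a fitted model.

    Contains the source country, the prediction (OOB) error, covariate
    importances sorted descending, per-unit OOB prediction intervals
    (central 95% of per-tree OOB predictions), the covariate-elimination
    audit trail and input-dataset provenance.
    """
    esc = html.escape
    lines = [
        "<!DOCTYPE html>",
        "<html><head><meta charset='utf-8'><title>Model metadata</title></head><body>",
        f"<h1>Population model metadata — {esc(model.source_country)}</h1>",
        "<h2>Model</h2><ul>",
        f"<li>Source country: {esc(model.source_country)}</li>",
        f"<li>OOB prediction error (MSE, log density): {model.oob_mse:.6g}</li>",
    ]
    if model.pct_var_explained is not None:
        lines.append(
            f"<li>% variance explained: {model.pct_var_explained:.2f}</li>")
    lines.append(f"<li>Trees: {model.params.n_trees}; terminal node size: "
                 f"{model.params.terminal_node_size}; seed: {model.params.seed}</li>")
    lines.append("</ul>")

    lines.append("<h2>Covariate importance</h2><table border='1'>"
                 "<tr><th>covariate</th><th>importance</th></tr>")
    for name, score in sorted(model.importance.items(), key=lambda kv: -kv[1]):
        lines.append(f"<tr><td>{esc(name)}</td><td>{score:.6g}</td></tr>")
    lines.append("</table>")

    if model.oob_intervals is not None:
        lines.append("<h2>OOB prediction intervals (log density, central 95%)</h2>"
                     "<table border='1'><tr><th>unit</th><th>oob prediction</th>"
                     "<th>2.5%</th><th>97.5%</th></tr>")
        for uid, row in model.oob_intervals.iterrows():
            lines.append(
                f"<tr><td>{uid}</td><td>{row['oob_pred']:.4f}</td>"
                f"<td>{row['lower']:.4f}</td><td>{row['upper']:.4f}</td></tr>")
        lines.append("</table>")

    if audit:
        lines.append("<h2>Covariate elimination</h2><ol>")
        for step in audit:
            lines.append(
                f"<li>iteration {step['iteration']}: "
                f"{len(step['covariates'])} covariates, "
                f"dropped {esc(', '.join(step['dropped']) or 'none')}</li>")
        lines.append("</ol>")

    if reports:
        lines.append("<h2>Holdout validation</h2><table border='1'>"
                     "<tr><th>method</th><th>unit level</th><th>n units</th>"
                     "<th>OOB error</th><th>% var</th><th>RMSE</th>"
                     "<th>%RMSE</th><th>MAE</th></tr>")
        for r in reports:
            oob = "—" if r.oob_mse is None else f"{r.oob_mse:.4f}"
            pv = "—" if r.pct_var_explained is None else f"{r.pct_var_explained:.1f}"
            lines.append(
                f"<tr><td>{esc(r.method)}</td><td>{r.unit_level}</td>"
                f"<td>{r.n_units}</td><td>{oob}</td><td>{pv}</td>"
                f"<td>{r.rmse:.2f}</td><td>{r.pct_rmse:.2f}</td>"
                f"<td>{r.mae:.2f}</td></tr>")
        lines.append("</table>")

    if provenance is not None and len(provenance):
        lines.append("<h2>Input datasets</h2><table border='1'><tr>")
        lines.append("".join(f"<th>{esc(str(c))}</th>" for c in provenance.columns))
        lines.append("</tr>")
        for _, row in provenance.iterrows():
            lines.append("<tr>" + "".join(
                f"<td>{esc(str(v))}</td>" for v in row) + "</tr>")
        lines.append("</table>")

    lines.append("</body></html>")
    return "\n".join(lines)
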