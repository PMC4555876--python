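"""Bagged regression-tree ensemble for the density weighting layer.

Fits a random forest (bootstrap-aggregated trees with random covariate
subsetting at each split) on the per-unit zonal table against log density,
reports out-of-bag (OOB) error and permutation importances, runs the
conservative iterative covariate-elimination loop, and predicts the
per-pixel weighting layer.

The ensemble is backed by :class:`sklearn.ensemble.BaggingRegressor` over
:class:`sklearn.tree.DecisionTreeRegressor` — this exposes each tree's
bootstrap sample (``estimators_samples_``), which the OOB statistics and
the OOB permutation importance need.  Defaults follow the reference
configuration: 500 trees, terminal node size 1, p/3 covariates per split.

Per-cell prediction is the mean over trees of predicted log density,
exponentiated onto the density scale (no back-transform bias correction).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.ensemble import BaggingRegressor
from sklearn.tree import DecisionTreeRegressor

from .covariates import CovariateStack
from .grids import Grid, UnitRaster

logger = logging.getLogger(__name__)

__all__ = [
    "ForestParams",
    "ForestModel",
    "fit_forest",
    "select_covariates",
    "predict_density",
    "cross_predict",
    "WeightLayer",
]


@dataclass(frozen=True)
class ForestParams:
    """Ensemble hyperparameters.

    ``covariates_per_split=None`` means the regression default, ⌊p/3⌋
    (at least 1), resolved at fit time.
    """

    n_trees: int = 500
    terminal_node_size: int = 1
    covariates_per_split: Optional[int] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.terminal_node_size < 1:
            raise ValueError("terminal_node_size must be >= 1")
        if self.covariates_per_split is not None and self.covariates_per_split < 1:
            raise ValueError("covariates_per_split must be >= 1")

    def mtry(self, p: int) -> int:
        if self.covariates_per_split is not None:
            if self.covariates_per_split > p:
                raise ValueError(f"covariates_per_split > number of covariates ({p})")
            return self.covariates_per_split
        return max(1, p // 3)


@dataclass
class ForestModel:
    """A fitted ensemble plus its OOB diagnostics."""

    estimator: BaggingRegressor
    covariate_names: list[str]
    importance: dict[str, float]
    oob_mse: float
    pct_var_explained: Optional[float]
    params: ForestParams
    source_country: str = ""
    unit_ids: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    oob_predictions: Optional[pd.Series] = None
    oob_intervals: Optional[pd.DataFrame] = None
    y_train: Optional[np.ndarray] = None

    def predict_log_density(self, X: np.ndarray) -> np.ndarray:
        """Mean over trees of per-tree predicted log density.

        Trees operate on float32 internally, so the explicit cast here
        changes nothing numerically and skips per-call validation.
        """
        X32 = np.ascontiguousarray(X, dtype=np.float32)
        total = np.zeros(X.shape[0])
        for tree in self.estimator.estimators_:
            total += tree.predict(X32, check_input=False)
        return total / len(self.estimator.estimators_)


@dataclass
class WeightLayer:
    """Predicted density surface (people per km²) with model provenance."""

    grid: Grid
    source_country: str = ""


def _align_training(zonal: pd.DataFrame, response: pd.DataFrame,
                    covariate_names: Optional[list[str]]):
    names = covariate_names or list(zonal.columns)
    common = response.index.intersection(zonal.index)
    X = zonal.loc[common, names].to_numpy(dtype=float)
    y = response.loc[common, "log_density"].to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("zonal table contains non-finite covariate values")
    return common.to_numpy(), names, X, y


def _oob_tree_predictions(est: BaggingRegressor, X: np.ndarray):
    """Per-tree OOB row indices and predictions.

    Returns a list of (oob_row_indices, predictions) pairs, one per tree.
    """
    n = X.shape[0]
    X32 = np.ascontiguousarray(X, dtype=np.float32)
    out = []
    for tree, samples in zip(est.estimators_, est.estimators_samples_):
        mask = np.ones(n, dtype=bool)
        mask[samples] = False
        idx = np.nonzero(mask)[0]
        preds = (tree.predict(np.ascontiguousarray(X32[idx]), check_input=False)
                 if len(idx) else np.empty(0))
        out.append((idx, preds))
    return out


def fit_forest(
    zonal: pd.DataFrame,
    response: pd.DataFrame,
    params: ForestParams,
    covariate_names: Optional[list[str]] = None,
    source_country: str = "",
) -> ForestModel:
    """Fit the bagged ensemble and compute OOB diagnostics.

    ``zonal`` and ``response`` are joined on unit_id (their index); only
    units present in both enter the fit.

    OOB mean-squared error averages, over units, the squared error of the
    mean prediction of trees whose bootstrap excluded the unit.  Percent
    variance explained is 100·(1 − oob_mse / var(y)); it is None when the
    response is constant.  Importance is OOB permutation importance: the
    mean over trees of the increase in that tree's OOB MSE when the
    covariate's OOB values are shuffled.
    """
    unit_ids, names, X, y = _align_training(zonal, response, covariate_names)
    n, p = X.shape
    if n < 2:
        raise ValueError("need at least 2 units with finite response to fit")
    mtry = params.mtry(p)
    est = BaggingRegressor(
        estimator=DecisionTreeRegressor(
            min_samples_leaf=params.terminal_node_size,
            max_features=mtry,
        ),
        n_estimators=params.n_trees,
        bootstrap=True,
        random_state=params.seed,
        n_jobs=1,
    )
    est.fit(X, y)

    per_tree = _oob_tree_predictions(est, X)
    pred_sum = np.zeros(n)
    pred_cnt = np.zeros(n, dtype=int)
    tree_mse = np.full(len(per_tree), np.nan)
    for t, (idx, preds) in enumerate(per_tree):
        pred_sum[idx] += preds
        pred_cnt[idx] += 1
        if len(idx):
            tree_mse[t] = np.mean((preds - y[idx]) ** 2)
    seen = pred_cnt > 0
    if not seen.any():
        raise ValueError("no out-of-bag observations; increase n_trees")
    if not seen.all():
        logger.warning("%d units never out-of-bag; excluded from OOB error",
                       int((~seen).sum()))
    oob_pred = np.full(n, np.nan)
    oob_pred[seen] = pred_sum[seen] / pred_cnt[seen]
    oob_mse = float(np.mean((oob_pred[seen] - y[seen]) ** 2))
    var_y = float(np.var(y, ddof=1)) if n > 1 else 0.0
    pct_var = None if var_y == 0 else 100.0 * (1.0 - oob_mse / var_y)

    # OOB permutation importance, deterministic under params.seed
    rng = np.random.default_rng(params.seed)
    X32 = np.ascontiguousarray(X, dtype=np.float32)
    importance: dict[str, float] = {}
    for j, name in enumerate(names):
        deltas = []
        for t, (idx, _) in enumerate(per_tree):
            if not len(idx) or np.isnan(tree_mse[t]):
                continue
            Xp = np.ascontiguousarray(X32[idx])
            Xp[:, j] = Xp[rng.permutation(len(idx)), j]
            preds = est.estimators_[t].predict(Xp, check_input=False)
            mse_perm = np.mean((preds - y[idx]) ** 2)
            deltas.append(mse_perm - tree_mse[t])
        importance[name] = float(np.mean(deltas)) if deltas else 0.0

    # central 95% OOB prediction interval per unit, from per-tree predictions
    by_unit: list[list[float]] = [[] for _ in range(n)]
    for idx, preds in per_tree:
        for i, pr in zip(idx, preds):
            by_unit[i].append(pr)
    lo = np.full(n, np.nan)
    hi = np.full(n, np.nan)
    for i, vals in enumerate(by_unit):
        if vals:
            lo[i], hi[i] = np.percentile(vals, [2.5, 97.5])
    intervals = pd.DataFrame(
        {"oob_pred": oob_pred, "lower": lo, "upper": hi},
        index=pd.Index(unit_ids, name="unit_id"),
    )

    return ForestModel(
        estimator=est,
        covariate_names=list(names),
        importance=importance,
        oob_mse=oob_mse,
        pct_var_explained=pct_var,
        params=params,
        source_country=source_country,
        unit_ids=unit_ids,
        oob_predictions=pd.Series(oob_pred, index=intervals.index, name="oob_pred"),
        oob_intervals=intervals,
        y_train=y,
    )


def select_covariates(
    zonal: pd.DataFrame,
    response: pd.DataFrame,
    params: ForestParams,
    covariate_names: Optional[list[str]] = None,
    confirm_rounds: int = 8,
) -> tuple[list[str], list[dict]]:
    """Conservative iterative covariate elimination.

    Repeatedly fit, drop every covariate whose permutation importance is
    <= 0, and refit; terminate when all remaining importances are positive
    or a single covariate remains.

    A single all-positive fit is a weak stopping signal: the permutation
    importance of a covariate carrying no signal is a zero-mean draw whose
    sign is close to a coin flip, so stopping at the first all-positive fit
    retains such covariates about half the time.  Termination therefore
    additionally requires the all-positive state to persist over
    ``confirm_rounds`` consecutive refits with fresh bootstrap/permutation
    randomness (seed offset per round, so the run is still deterministic).
    Any non-positive score during confirmation triggers the drop and resets
    the count.  ``confirm_rounds=0`` reproduces the plain first-stop rule.

    Returns the terminal name list and a per-iteration audit trail.
    """
    names = list(covariate_names or zonal.columns)
    audit: list[dict] = []
    iteration = 0
    clean_streak = 0
    while True:
        iteration += 1
        round_params = ForestParams(
            n_trees=params.n_trees,
            terminal_node_size=params.terminal_node_size,
            covariates_per_split=params.covariates_per_split,
            seed=params.seed + (iteration - 1) * 7919,
        )
        model = fit_forest(zonal, response, round_params, covariate_names=names)
        dropped = [n for n in names if model.importance[n] <= 0]
        kept = [n for n in names if model.importance[n] > 0]
        audit.append({
            "iteration": iteration,
            "covariates": list(names),
            "importance": dict(model.importance),
            "oob_mse": model.oob_mse,
            "pct_var_explained": model.pct_var_explained,
            "dropped": dropped,
            "confirmation": not dropped,
        })
        if not kept:
            best = max(names, key=lambda n: model.importance[n])
            logger.warning("elimination emptied the covariate set; keeping %r", best)
            return [best], audit
        if len(kept) == 1:
            return kept, audit
        if dropped:
            clean_streak = 0
            names = kept
        else:
            clean_streak += 1
            if clean_streak >= max(1, confirm_rounds):
                return kept, audit


def predict_density(model: ForestModel, stack: CovariateStack,
                    mask: UnitRaster) -> WeightLayer:
    """Predict the weighting layer: per-cell density, nodata outside the mask.

    Each in-mask cell gets exp(mean over trees of predicted log density).
    """
    missing = [n for n in model.covariate_names if n not in stack]
    if missing:
        raise ValueError(f"stack is missing model covariates: {missing}")
    stack.frame().require_aligned(mask, "stack and mask")
    rows, cols = np.nonzero(mask.valid_mask())
    X = stack.to_matrix(rows, cols, model.covariate_names)
    for j, name in enumerate(model.covariate_names):
        if (X[:, j] == stack[name].nodata).any():
            raise ValueError(f"covariate {name!r} has nodata inside the mask; "
                             "nibble-fill before predicting")
    density = np.exp(model.predict_log_density(X))
    values = np.full(mask.shape, mask.nodata, dtype=float)
    values[rows, cols] = density
    grid = Grid(values, mask.cell_size, mask.origin, mask.nodata, mask.crs_label)
    return WeightLayer(grid, source_country=model.source_country)


def cross_predict(donor_model: ForestModel, target_stack: CovariateStack,
                  target_mask: UnitRaster) -> WeightLayer:
    """Predict a target country's weighting layer with a donor-country model.

    Identical contract to :func:`predict_density`; the returned layer's
    provenance records the donor model's source country.
    """
    return predict_density(donor_model, target_stack, target_mask)
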