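# gridpop

Random-forest dasymetric population mapping: disaggregate administrative-unit
census counts onto a fine regular grid using a model-predicted density
weighting layer, project the result to target years with urban/rural growth
rates, adjust national totals to external estimates, and validate against
simple areal weighting (SAW) with a coarse-to-fine holdout.

## How it works

1. **Prepare** — admin polygons are buffered (10 km default) and rasterized
   (100 m default); continuous covariate rasters are NoData-filled from
   nearest neighbours ("nibble"); the land-cover grid is recoded, mosaicked
   with a binary urban extent (urban 190 / rural built-up 240) and expanded
   into `cls_`/`dst_`/`prp_` covariates (presence, planar distance,
   proportion within a 500 m circular window), including the combined
   built-up class `blt`.
2. **Fit** — per-unit covariate aggregates (mean / binary mode) are fitted
   against the natural-log population density with a bagged regression-tree
   ensemble (500 trees, terminal node size 1, p/3 covariates per split).
   Out-of-bag permutation importance drives a conservative iterative
   covariate elimination; OOB MSE and % variance explained are reported.
3. **Predict & disaggregate** — per-cell predicted log density is averaged
   over trees and exponentiated into a weighting layer; each unit's count is
   split across its cells proportionally to the weights (mass is conserved
   exactly per unit). Outputs: people per cell (ppp) and per hectare (pph).
4. **Project & adjust** — urban and rural strata grow at separate annual
   rates, `exp(rate * dt)` by default; optional rescaling to an external
   national total (`_UNadj` products).
5. **Validate** — counts are aggregated one admin level up, the model is
   fitted on the coarse aggregates only, and both the model-weighted and the
   uniform (SAW) disaggregation are scored against the withheld fine counts
   (RMSE, %RMSE, MAE).

A seeded synthetic-landscape generator (`gridpop.synthfix`) produces a
two-level admin hierarchy, covariate stack and ground-truth density surface,
so the whole pipeline runs and is tested without any external data.

## CLI

```bash
# generate a synthetic world plus a ready-made config.yaml
gridpop synth --seed 1 --out demo/

# full pipeline: 14 rasters (ppp/pph x census-year/2010/2015/2020 x
# unadjusted/UNadj) + an HTML model metadata report + manifest.json
gridpop pipeline --config demo/config.yaml

# coarse-to-fine holdout: RF vs SAW comparison table
gridpop validate --config demo/config.yaml
```

Output rasters follow the `<ISO>_{ppp|pph}_v<ver>_<YEAR>[_UNadj].asc`
naming scheme. Exit code 2 marks configuration errors, 1 a stage failure.

The config is YAML; keys: `units` (GeoJSON), optional `census` (CSV joined
on unit id), `landcover`, `urban_extent`, `continuous` (name -> path),
`binary_features`, `recode` (raw -> target class table), `schedule` (CSV:
census_year, target_year, urban_rate, rural_rate, optional unpd_total),
`forest` (n_trees, terminal_node_size, covariates_per_split, seed),
`growth_law` (`exponential`|`geometric`), `urban_stratum` (`urban`|`blt`),
`buffer_m`, `focal_radius_m`, `version`, `output_dir`.

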