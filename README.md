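# stproj

Space-time projection kriging for disease incidence mapping.

The package implements two routes for estimating a yearly, point-referenced
incidence surface from sparse observations:

* **Projection route (STP).** Fit a multiplicative separable space-time
  covariance `c0·exp(−3|h|²/αs² − 3τ/αt)` to the detrended
  log(incidence+1) residuals, solve the spread-speed quadratic
  `αt·τ·v² − 2αt·|h|·v − αs² = 0` for the admissible root (the one keeping
  the projected lag `r̂ = |h| − vτ` positive), collapse the pairwise speed
  surface into one representative speed, map every record onto the
  traveling frame `ŝ = s − v·(t − t0)`, fit an exponential covariance
  `c·exp(−3r̂/α)` in that planar domain, run ordinary kriging there, and
  back-transform the estimates onto `(s, t)`.
* **Space-time baseline (STOK).** Ordinary kriging directly in
  `R² × T` with the separable covariance, neighborhoods of at most 50 data
  within 10 km / 2 yr ranked by covariance.

Because the registry data the method was developed on are not public, the
package ships a traveling-random-field simulator (exact dense
Cholesky draw on the projected coordinates, so the frozen-field identity
`Z(s,t) = Z(s − vt, 0)` holds bit-exactly), a township-like layout
generator, and an age-structure generator for indirect standardization —
everything downstream is testable offline.

## Layout

| module | contents |
|---|---|
| `stproj.synthetic` | traveling-field simulator, layouts, age structures |
| `stproj.preprocess` | indirect age standardization, log(x+1), moving-window detrending |
| `stproj.covariance` | empirical covariance (space-time and projected), AIC model fitting |
| `stproj.projection` | speed quadratic, projected lags, velocity surface/collapse, coordinate transform |
| `stproj.kriging` | ordinary-kriging engine (projected-domain and space-time) |
| `stproj.validation` | k-fold CV, ME/MAE/RMSE, STP-vs-STOK experiment |
| `stproj.io` / `stproj.cli` | CSV schemas, run configuration, command line |

## Command line

```bash
# simulate a traveling field (incidence.csv + truth.csv)
stproj simulate --n-locations 200 --years 2008:2012 --speed -8000 \
    --sill 0.5 --trend-amplitude 2 --seed 0 --out out/sim

# fit the space-time covariance and export the velocity surface
stproj fit-covariance --input out/sim/incidence.csv --out out/fit
stproj velocity --input out/sim/incidence.csv --out out/fit

# estimate at targets (or a regular grid) with either route
stproj krige-stp  --input out/sim/incidence.csv --grid-cell-m 5000 --out out/maps
stproj krige-stok --input out/sim/incidence.csv --grid-cell-m 5000 --out out/maps

# 10-fold cross-validation of both routes on identical folds
stproj crossvalidate --input out/sim/incidence.csv --method both --k 10 \
    --seed 0 --out out/cv

# indirect age standardization of raw case counts
stproj standardize --cases cases.csv --population pop.csv \
    --reference rates.csv --out out/std
```

Every run writes a `run_config.yaml` with the fully-resolved settings and
package version next to its outputs. The incidence CSV schema is
`town_id, x_m, y_m, year, incidence_per_1e5` (planar metres, integer
years, rates per 100,000).

Representative-speed strategies: `variogram_match` (default in
`RunConfig`; scans candidate speeds and minimizes the cross-year residual
variogram at short projected range), `paircount_mean`, `median`, and
`fixed:<value>`.

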