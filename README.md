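# socgwr

Soil organic carbon (SOC) stock mapping with **geographically weighted
regression (GWR)**, from layered soil profiles to climate-scenario
projections, on planar grids with synthetic landscapes of known truth.

The package is for soil biogeochemists and geospatial modellers who want a
tested, reproducible implementation of the continental-scale SOC workflow:
fixed-depth profile stocks, per-ecoregion outlier screening, Box-Cox
normalization of the skewed stock response, collinearity pruning and
significance-constrained best-subset predictor selection, GWR with a
data-driven adaptive bandwidth, gridded prediction, space-for-time climate
projection, and per-ecoregion reporting.

## The model

A site's 0–100 cm stock is the fixed-depth integral over its layers,

    S = sum_layers (c/100) * rho * t * 100        [Mg/ha]

with SOC concentration *c* (% by mass), bulk density *rho* (g/cm³) and the
layer thickness *t* (cm) inside the window. Stocks are normalized with a
Box-Cox transform z = (y^λ − 1)/λ (ln y at λ = 0), λ estimated by profile
likelihood. The regression allows every coefficient to vary over space:

    z(u) = β₀(u) + Σ_k β_k(u) x_k(u) + ε,
    β̂(u) = (XᵀW(u)X)⁻¹ XᵀW(u) z,

where W(u) holds bisquare kernel weights w_i = (1 − (d_i/b(u))²)² for
d_i < b(u). The bandwidth is **adaptive**: b(u) is the distance to the k-th
nearest calibration point, and k is chosen by minimizing the corrected
Akaike criterion

    AICc = 2n ln σ̂ + n ln 2π + n (n + tr S) / (n − 2 − tr S),

with tr S the hat-matrix trace (effective number of parameters). Scenario
projection is space-for-time: the fitted coefficient field is held fixed,
only the temperature and precipitation layers are replaced per decade, and
the model is re-evaluated cell by cell; stocks aggregate to ecoregion
totals in Tg and national totals in Pg.

## Worked example

`examples/04_gwr_coefficient_recovery.py` builds a 60×60 landscape (800 m
cells) whose intercept, temperature and precipitation coefficients drift
smoothly in space, samples 800 sites, and fits GWR on the 75% training
split:

```
adaptive bandwidth: k = 28 neighbors (AICc -238.6, effective parameters 115.3)
  corr(true, estimated) for beta_intercept: 0.973
  corr(true, estimated) for beta_temperature: 0.896
  corr(true, estimated) for beta_precipitation: 0.946
held-out R^2 (Mg/ha): GWR 0.986 vs global OLS 0.347
```

The AICc search settles on a 28-neighbor kernel; the estimated local
coefficient surfaces correlate 0.90–0.97 with the true ones, and on
held-out sites the spatial model explains 99% of stock variance where a
single global regression explains 35% — the gap is exactly the spatially
varying structure GWR exists to capture.

The other examples cover profile/stock round trips (`01`), outlier and
Box-Cox screening (`02`), predictor selection (`03`), decadal scenario
projection with regional Tg accounting (`05`), and the full pipeline from
a config file (`06`). The same pipeline runs from the shell:

```sh
socgwr run-all --config examples/config.yaml --outdir my_run
```

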