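"""Space-for-time climate-scenario projection with regional accounting.

Fits the spatial model, maps baseline stocks over the grid, then replaces
only the temperature and precipitation layers decade by decade and tracks
the national stock total (Pg) and per-ecoregion totals (Tg).
"""

import numpy as np

from socgwr import (
    BoxCoxTransform,
    GWRConfig,
    SyntheticTruth,
    aggregate_by_region,
    decadal_series,
    difference_map,
    fit_gwr,
    generate_future_climate,
    generate_landscape,
    generate_observations,
    generate_predictor_fields,
    predict_stock_map,
    project_scenario,
)

grid = generate_landscape(30, 30, 800.0, 4, seed=31)
stack = generate_predictor_fields(
    grid, ["temperature", "precipitation"], smoothness=3, seed=32
)
truth = SyntheticTruth(
    coefficient_surfaces={
        "intercept": np.full(grid.shape, 14.0),
        "temperature": np.full(grid.shape, -1.0),  # warming always hurts here
        "precipitation": np.full(grid.shape, 0.5),
    },
    lambda_true=0.5,
    noise_sd=0.2,
)
obs, _ = generate_observations(grid, stack, truth, 250, seed=33)
names = ["intercept", "temperature", "precipitation"]
X = np.column_stack([np.ones(len(obs)), obs["temperature"], obs["precipitation"]])
bc = BoxCoxTransform(lambda_=0.5, loglik=0.0)
fit = fit_gwr(X, bc.apply(obs["stock_mg_ha"].to_numpy()),
              obs[["x", "y"]].to_numpy(), GWRConfig(k_range=(30, len(obs))), names)

baseline = predict_stock_map(fit, stack, bc)
print(f"baseline: mean {np.nanmean(baseline.values):.1f} Mg/ha, "
      f"total {baseline.total_tg():.2f} Tg")

decades = list(range(2030, 2101, 10))
warming = generate_future_climate(
    stack, decades, temp_delta_per_decade=0.3, precip_factor_per_decade=0.98,
    seed=34, tag="high_emission",
)
series = decadal_series(fit, stack, warming, bc)
print(series.to_string(index=False,
                       formatters={"total_pg": "{:.5f}".format,
                                   "mean_mg_ha": "{:.1f}".format,
                                   "min_mg_ha": "{:.1f}".format,
                                   "max_mg_ha": "{:.1f}".format}))

final = project_scenario(fit, stack, warming, 2100, bc)
delta = difference_map(final, baseline)
print(f"2100 minus baseline: mean change {np.nanmean(delta.values):.1f} Mg/ha")
summary = aggregate_by_region(final)
print(summary.to_string(index=False, float_format="%.2f"))
print("-> with an everywhere-negative temperature coefficient, steady "
      "warming drains the stock total decade by decade; regional Tg totals "
      "sum exactly to the national total")
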