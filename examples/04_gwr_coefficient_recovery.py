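"""Geographically weighted regression recovering spatially varying truth.

Fits GWR with an AICc-selected adaptive bandwidth on a landscape whose
regression coefficients drift smoothly in space, then compares the local
estimates against the known coefficient surfaces and against a global OLS
baseline on held-out sites.
"""

import numpy as np
import statsmodels.api as sm

from socgwr import (
    BoxCoxTransform,
    GWRConfig,
    SyntheticTruth,
    fit_gwr,
    generate_landscape,
    generate_observations,
    generate_predictor_fields,
    predict_gwr,
    train_test_split,
)
from socgwr import test_r2 as r2_stock
from socgwr.landscape import _smooth_field

grid = generate_landscape(60, 60, 800.0, 5, seed=21)
stack = generate_predictor_fields(
    grid, ["temperature", "precipitation"], smoothness=3, seed=22
)
rng = np.random.default_rng(23)
surfaces = {
    "intercept": 20.0 + _smooth_field(rng, grid.shape, 15.0),
    "temperature": -0.8 + 0.5 * _smooth_field(rng, grid.shape, 15.0),
    "precipitation": 0.6 + 0.5 * _smooth_field(rng, grid.shape, 15.0),
}
z0 = surfaces["intercept"] + sum(surfaces[n] * stack[n] for n in stack.names)
truth = SyntheticTruth(surfaces, lambda_true=0.5, noise_sd=0.1 * float(z0.std()))
obs, rec = generate_observations(grid, stack, truth, 800, seed=24)

train, test = train_test_split(obs, 0.75, seed=1)
names = ["intercept", "temperature", "precipitation"]
Xtr = np.column_stack([np.ones(len(train)), train["temperature"], train["precipitation"]])
Xte = np.column_stack([np.ones(len(test)), test["temperature"], test["precipitation"]])
bc = BoxCoxTransform(lambda_=truth.lambda_true, loglik=0.0)
ztr = bc.apply(train["stock_mg_ha"].to_numpy())

fit = fit_gwr(Xtr, ztr, train[["x", "y"]].to_numpy(),
              GWRConfig(kernel="bisquare", k_range=(20, len(train))), names)
print(f"adaptive bandwidth: k = {fit.k_selected} neighbors "
      f"(AICc {fit.aicc:.1f}, effective parameters {fit.trace_S:.1f})")
for j, nm in enumerate(names):
    r = np.corrcoef(fit.local_coefficients[:, j],
                    rec.loc[train.index, f"beta_{nm}"])[0, 1]
    print(f"  corr(true, estimated) for beta_{nm}: {r:.3f}")

y_gwr = predict_gwr(fit, test[["x", "y"]].to_numpy(), Xte, transform=bc)
ols = sm.OLS(ztr, Xtr).fit()
y_ols = bc.invert(Xte @ ols.params, out_of_domain="nan")
obs_y = test["stock_mg_ha"].to_numpy()
print(f"held-out R^2 (Mg/ha): GWR {r2_stock(y_gwr, obs_y):.3f} "
      f"vs global OLS {r2_stock(y_ols, obs_y):.3f}")
print("-> local coefficients track the true surfaces and the spatial model "
      "clearly out-predicts the global one")
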