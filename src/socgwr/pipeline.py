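"""Pipeline stages chaining the full analysis on disk.

Each stage reads its inputs from the run's output directory, does one step
of the workflow, and writes its artifacts back there, so stages can be run
independently (a missing upstream artifact is a named error).  ``run_all``
chains simulate -> preprocess -> screen -> fit -> predict -> project ->
report.  Every stage appends to ``run_manifest.json`` (inputs, seeds,
thresholds, package version) and no stage mutates its inputs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .diagnostics import coefficient_pca, region_bias, test_r2
from .errors import MissingInputError
from .grids import PredictorStack
from .gwr import GWRConfig, GWRFit, fit_gwr, predict_gwr
from .io import (
    FLOAT_FMT,
    read_observations,
    read_profiles,
    read_scenario,
    read_stack,
    read_stock_map,
    write_observations,
    write_profiles_csv,
    write_scenario,
    write_stack,
    write_stock_map,
)
from .landscape import (
    SyntheticTruth,
    _smooth_field,
    generate_future_climate,
    generate_landscape,
    generate_observations,
    generate_predictor_fields,
    generate_profiles,
)
from .projection import (
    aggregate_by_region,
    decadal_series,
    difference_map,
    predict_stock_map,
)
from .rasters import write_ascii_grid
from .report import build_report
from .screening import (
    best_subset_select,
    correlation_prune,
    nonlinearity_screen,
    train_test_split,
)
from .soilprofiles import filter_outliers_iqr, stocks_from_profiles
from .transforms import BoxCoxTransform, fit_boxcox

log = logging.getLogger(__name__)

#: default true coefficient surfaces of the synthetic data-generating
#: process, on the transformed (Box-Cox) scale: (baseline level, amplitude
#: of the smooth spatial variation).  Predictors absent here have a truly
#: zero coefficient and act as decoys for the screening stage.
TRUTH_COEFFICIENTS = {
    "intercept": (20.0, 1.0),
    "temperature": (-1.2, 0.4),
    "precipitation": (0.9, 0.3),
    "npp": (0.6, 0.2),
}


def _update_manifest(outdir: Path, stage: str, info: dict) -> None:
    mpath = outdir / "run_manifest.json"
    manifest = json.loads(mpath.read_text()) if mpath.exists() else {}
    manifest[stage] = {"package_version": __version__, **info}
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True))


def _require(path: Path, what: str) -> Path:
    if not path.exists():
        raise MissingInputError(f"{what} not found at {path}; run the prior stage first")
    return path


def _truth_surfaces(stack: PredictorStack, smoothness: float, seed: int):
    rng = np.random.default_rng(seed)
    surfaces = {}
    for name in ["intercept", *stack.names]:
        level, amp = TRUTH_COEFFICIENTS.get(name, (0.0, 0.0))
        if amp > 0:
            surfaces[name] = level + amp * _smooth_field(rng, stack.grid.shape, smoothness)
        else:
            surfaces[name] = np.full(stack.grid.shape, level)
    return surfaces


def simulate(cfg: RunConfig, outdir: str | Path | None = None) -> Path:
    """Generate the synthetic study: landscape, predictors, truth,
    observations, profiles, and per-scenario decadal climate layers."""
    outdir = Path(outdir or cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    grid = generate_landscape(
        cfg.nx, cfg.ny, cfg.cell_size, cfg.n_regions, cfg.stage_seed(1)
    )
    stack = generate_predictor_fields(
        grid,
        cfg.continuous_predictors,
        [tuple(s) for s in cfg.categorical_predictors],
        smoothness=cfg.smoothness,
        seed=cfg.stage_seed(2),
    )
    truth = SyntheticTruth(
        coefficient_surfaces=_truth_surfaces(stack, cfg.smoothness * 2, cfg.stage_seed(3)),
        lambda_true=cfg.lambda_true,
        noise_sd=cfg.noise_sd,
    )
    obs, truth_rec = generate_observations(grid, stack, truth, cfg.n_obs, cfg.stage_seed(4))
    profiles = generate_profiles(obs, cfg.layers_per_profile, cfg.stage_seed(5))

    write_stack(stack, outdir / "stack")
    write_observations(obs, outdir / "observations.csv")
    truth_rec.to_csv(outdir / "truth_records.csv", index=False, float_format=FLOAT_FMT)
    write_profiles_csv(profiles, outdir / "profiles.csv")
    tdir = outdir / "truth_surfaces"
    tdir.mkdir(exist_ok=True)
    for name, surf in truth.coefficient_surfaces.items():
        write_ascii_grid(tdir / f"beta_{name}.asc", surf, grid)
    for i, (tag, spec) in enumerate(sorted(cfg.scenarios.items())):
        scen = generate_future_climate(
            stack,
            cfg.decades,
            spec["temp_delta_per_decade"],
            spec["precip_factor_per_decade"],
            seed=cfg.stage_seed(6 + i),
            tag=tag,
        )
        write_scenario(scen, outdir / f"scenario_{tag}", grid)
    _update_manifest(
        outdir,
        "simulate",
        {
            "seeds": [cfg.stage_seed(i) for i in range(1, 6 + len(cfg.scenarios))],
            "lambda_true": cfg.lambda_true,
            "noise_sd": cfg.noise_sd,
            "n_obs": cfg.n_obs,
        },
    )
    return outdir


def preprocess(cfg: RunConfig, outdir=None) -> Path:
    """Recompute 0-100 cm stocks from the layered profiles, join predictor
    values, and remove per-region 1.5*IQR outliers."""
    outdir = Path(outdir or cfg.outdir)
    profiles = read_profiles(_require(outdir / "profiles.csv", "profile table"))
    obs = read_observations(_require(outdir / "observations.csv", "observation table"))
    stocks = stocks_from_profiles(profiles)
    merged = obs.drop(columns=["stock_mg_ha"]).merge(
        stocks[["id", "stock_mg_ha"]], on="id", how="inner"
    )
    cols = ["id", "x", "y", "region", "stock_mg_ha"]
    merged = merged[cols + [c for c in merged.columns if c not in cols]]
    kept, removed = filter_outliers_iqr(merged, k=cfg.iqr_k)
    write_observations(kept, outdir / "observations_filtered.csv")
    write_observations(removed, outdir / "outliers_removed.csv")
    _update_manifest(
        outdir,
        "preprocess",
        {"iqr_k": cfg.iqr_k, "n_in": len(merged), "n_removed": len(removed)},
    )
    return outdir


def screen(cfg: RunConfig, outdir=None) -> Path:
    """Split, fit Box-Cox on the training stocks, prune collinear
    predictors, and choose the significant best subset."""
    outdir = Path(outdir or cfg.outdir)
    table = read_observations(
        _require(outdir / "observations_filtered.csv", "filtered observations")
    )
    stack = read_stack(_require(outdir / "stack" / "stack.json", "predictor stack"))
    predictors = stack.names

    train, test = train_test_split(table, cfg.train_fraction, cfg.stage_seed(7))
    bc = fit_boxcox(train["stock_mg_ha"].to_numpy())
    train = train.assign(transformed_stock=bc.apply(train["stock_mg_ha"].to_numpy()))
    test = test.assign(transformed_stock=bc.apply(test["stock_mg_ha"].to_numpy()))

    # priority encodes which predictor's effect on SOC is better established:
    # the configured continuous order (climate first), then everything else
    priority = cfg.priority or (
        [c for c in cfg.continuous_predictors if c in predictors]
        + [c for c in predictors if c not in cfg.continuous_predictors]
    )
    X_train = train[predictors]
    pruned, rep = correlation_prune(X_train, cfg.corr_threshold, priority)
    nonlin = nonlinearity_screen(X_train, train["transformed_stock"])
    selected, sel_r2 = best_subset_select(
        pruned, train["transformed_stock"], alpha=cfg.alpha
    )

    write_observations(train, outdir / "train.csv")
    write_observations(test, outdir / "test.csv")
    if rep.correlation_matrix is not None:
        rep.correlation_matrix.to_csv(outdir / "correlation_matrix.csv", float_format=FLOAT_FMT)
    pd.DataFrame(
        rep.dropped_by_correlation, columns=["dropped", "kept", "r"]
    ).to_csv(outdir / "dropped_pairs.csv", index=False, float_format=FLOAT_FMT)
    nonlin.to_csv(outdir / "nonlinearity.csv", index=False, float_format=FLOAT_FMT)
    screening = {
        "selected_predictors": selected,
        "selection_r2": sel_r2,
        "split_sizes": [len(train), len(test)],
        "boxcox_lambda": bc.lambda_,
        "boxcox_loglik": bc.loglik,
        "dropped_by_correlation": [list(t) for t in rep.dropped_by_correlation],
        "surviving_predictors": list(pruned.columns),
    }
    (outdir / "screening.json").write_text(json.dumps(screening, indent=2, sort_keys=True))
    _update_manifest(
        outdir,
        "screen",
        {
            "seed": cfg.stage_seed(7),
            "corr_threshold": cfg.corr_threshold,
            "alpha": cfg.alpha,
            "train_fraction": cfg.train_fraction,
            "selected": selected,
        },
    )
    return outdir


def _load_screening(outdir: Path) -> dict:
    return json.loads(
        _require(outdir / "screening.json", "screening report").read_text()
    )


def _design(table: pd.DataFrame, names: list[str]) -> np.ndarray:
    cols = [
        np.ones(len(table)) if n == "intercept" else table[n].to_numpy(dtype=float)
        for n in names
    ]
    return np.column_stack(cols)


def fit(cfg: RunConfig, outdir=None) -> Path:
    """Fit the GWR model on the training partition."""
    outdir = Path(outdir or cfg.outdir)
    screening = _load_screening(outdir)
    train = read_observations(_require(outdir / "train.csv", "training table"))
    names = ["intercept", *screening["selected_predictors"]]
    X = _design(train, names)
    coords = train[["x", "y"]].to_numpy(dtype=float)
    z = train["transformed_stock"].to_numpy(dtype=float)
    p = X.shape[1]
    k_range = (
        cfg.k_min if cfg.k_min is not None else max(p + 2, 20),
        cfg.k_max if cfg.k_max is not None else len(train),
    )
    gcfg = GWRConfig(
        kernel=cfg.kernel, k_range=k_range, ridge_jitter=cfg.ridge_jitter
    )
    gfit = fit_gwr(X, z, coords, gcfg, predictor_names=names)

    out = pd.DataFrame({"x": coords[:, 0], "y": coords[:, 1], "z": z,
                        "residual": gfit.residuals, "region": train["region"].to_numpy()})
    for j, n in enumerate(names):
        out[f"beta_{n}"] = gfit.local_coefficients[:, j]
        out[f"X_{n}"] = X[:, j]
    out.to_csv(outdir / "gwr_fit.csv", index=False, float_format="%.10g")
    summary = {
        "predictor_names": names,
        "k_selected": gfit.k_selected,
        "trace_S": gfit.trace_S,
        "sigma_hat": gfit.sigma_hat,
        "aicc": gfit.aicc,
        "kernel": cfg.kernel,
        "k_range": list(k_range),
        "ridge_jitter": cfg.ridge_jitter,
    }
    (outdir / "gwr_summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    _update_manifest(outdir, "fit", summary)
    return outdir


def load_gwr_fit(outdir: Path) -> GWRFit:
    """Reconstruct a fitted GWR model from the fit stage's artifacts."""
    outdir = Path(outdir)
    summary = json.loads(_require(outdir / "gwr_summary.json", "GWR summary").read_text())
    table = pd.read_csv(_require(outdir / "gwr_fit.csv", "GWR fit table"))
    names = summary["predictor_names"]
    X = table[[f"X_{n}" for n in names]].to_numpy(dtype=float)
    betas = table[[f"beta_{n}" for n in names]].to_numpy(dtype=float)
    return GWRFit(
        predictor_names=names,
        calibration_coords=table[["x", "y"]].to_numpy(dtype=float),
        calibration_X=X,
        calibration_z=table["z"].to_numpy(dtype=float),
        local_coefficients=betas,
        k_selected=summary["k_selected"],
        trace_S=summary["trace_S"],
        sigma_hat=summary["sigma_hat"],
        aicc=summary["aicc"],
        residuals=table["residual"].to_numpy(dtype=float),
        config=GWRConfig(
            kernel=summary["kernel"],
            k_range=tuple(summary["k_range"]),
            ridge_jitter=summary["ridge_jitter"],
        ),
    )


def predict(cfg: RunConfig, outdir=None) -> Path:
    """Baseline stock map over the full grid plus test-set evaluation."""
    outdir = Path(outdir or cfg.outdir)
    gfit = load_gwr_fit(outdir)
    screening = _load_screening(outdir)
    bc = BoxCoxTransform(lambda_=screening["boxcox_lambda"], loglik=screening["boxcox_loglik"])
    stack = read_stack(_require(outdir / "stack" / "stack.json", "predictor stack"))
    test = read_observations(_require(outdir / "test.csv", "test table"))

    baseline = predict_stock_map(gfit, stack, bc, scenario="current")
    write_stock_map(baseline, outdir / "baseline_stock.asc")
    aggregate_by_region(baseline).to_csv(
        outdir / "region_summary.csv", index=False, float_format=FLOAT_FMT
    )

    Xt = _design(test, gfit.predictor_names)
    y_pred, z_pred = predict_gwr(
        gfit, test[["x", "y"]].to_numpy(dtype=float), Xt, transform=bc,
        return_transformed=True,
    )
    pred = test[["id", "x", "y", "region", "stock_mg_ha"]].assign(
        predicted_mg_ha=y_pred, predicted_z=z_pred
    )
    pred.to_csv(outdir / "test_predictions.csv", index=False, float_format=FLOAT_FMT)
    bias = region_bias(y_pred, test["stock_mg_ha"].to_numpy(), test["region"].to_numpy())
    bias.to_csv(outdir / "region_bias.csv", index=False, float_format=FLOAT_FMT)
    metrics = {
        "test_r2_stock_scale": test_r2(y_pred, test["stock_mg_ha"].to_numpy()),
        "test_r2_transformed_scale": test_r2(
            z_pred, test["transformed_stock"].to_numpy()
        ),
        "n_test": int(len(test)),
    }
    (outdir / "metrics.json").write_text(json.dumps(metrics, indent=2, sort_keys=True))
    _update_manifest(outdir, "predict", metrics)
    return outdir


def project(cfg: RunConfig, outdir=None) -> Path:
    """Decadal space-for-time projection for every configured scenario."""
    outdir = Path(outdir or cfg.outdir)
    gfit = load_gwr_fit(outdir)
    screening = _load_screening(outdir)
    bc = BoxCoxTransform(lambda_=screening["boxcox_lambda"], loglik=screening["boxcox_loglik"])
    stack = read_stack(_require(outdir / "stack" / "stack.json", "predictor stack"))
    baseline = read_stock_map(
        _require(outdir / "baseline_stock.asc", "baseline stock map")
    )
    baseline.grid.region_labels = stack.grid.region_labels
    info = {}
    for tag in sorted(cfg.scenarios):
        scen = read_scenario(
            _require(outdir / f"scenario_{tag}" / "scenario.json", f"scenario {tag}")
        )
        # drop overrides for predictors the screening did not retain
        retained = {
            y: {n: a for n, a in d.items() if n in gfit.predictor_names}
            for y, d in scen.overrides.items()
        }
        scen.overrides = retained
        series = decadal_series(gfit, stack, scen, bc)
        series.to_csv(
            outdir / f"decadal_series_{tag}.csv", index=False, float_format=FLOAT_FMT
        )
        final = scen.decades[-1]
        from .projection import project_scenario  # local import avoids cycle at module load

        fmap = project_scenario(gfit, stack, scen, final, bc)
        write_stock_map(fmap, outdir / f"stock_{tag}_{final}.asc")
        write_stock_map(
            difference_map(fmap, baseline), outdir / f"diff_{tag}_{final}.asc"
        )
        aggregate_by_region(fmap, stack.grid.region_labels).to_csv(
            outdir / f"region_summary_{tag}.csv", index=False, float_format=FLOAT_FMT
        )
        info[tag] = {"final_total_pg": float(series["total_pg"].iloc[-1])}
    _update_manifest(outdir, "project", info)
    return outdir


def report(cfg: RunConfig, outdir=None) -> dict:
    """Assemble the report bundle (tables, PCA, summary text)."""
    outdir = Path(outdir or cfg.outdir)
    gfit = load_gwr_fit(outdir)
    train = pd.read_csv(_require(outdir / "gwr_fit.csv", "GWR fit table"))
    pca = None
    if train["region"].nunique() >= 3 and len(gfit.predictor_names) >= 2:
        pca = coefficient_pca(gfit, train["region"].to_numpy())
    bundle = build_report(outdir, cfg, pca=pca)
    _update_manifest(outdir, "report", {"sections": sorted(bundle)})
    return bundle


def run_all(cfg: RunConfig, outdir=None) -> dict:
    outdir = Path(outdir or cfg.outdir)
    simulate(cfg, outdir)
    preprocess(cfg, outdir)
    screen(cfg, outdir)
    fit(cfg, outdir)
    predict(cfg, outdir)
    project(cfg, outdir)
    return report(cfg, outdir)
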