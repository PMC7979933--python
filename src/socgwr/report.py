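"""Report bundle: the run's tables and summaries gathered in one place.

Emits an ecoregion stock/residual table (current and scenario totals side
by side), a combined decadal series, the screening and GWR summaries, the
coefficient-PCA tables, and a plain-text overview.  All CSV numbers
round-trip losslessly at 6 significant digits and outputs are byte-stable
across reruns of the same configuration.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .errors import MissingInputError
from .io import FLOAT_FMT


def _need(path: Path, what: str) -> Path:
    if not path.exists():
        raise MissingInputError(f"report needs {what} ({path.name}); run earlier stages")
    return path


def build_report(outdir, cfg, pca=None) -> dict:
    """Collect pipeline artifacts into ``<outdir>/report``.

    Returns a mapping of section name -> written file path.
    """
    outdir = Path(outdir)
    rdir = outdir / "report"
    rdir.mkdir(parents=True, exist_ok=True)
    bundle: dict[str, Path] = {}

    # ecoregion table: current + per-scenario totals + test-set bias
    current = pd.read_csv(_need(outdir / "region_summary.csv", "regional summary"))
    table2 = current.rename(
        columns={"mean_stock_mg_ha": "stock_mg_ha", "total_tg": "total_tg_current"}
    )[["region", "stock_mg_ha", "total_tg_current", "cell_count", "area_ha"]]
    for tag in sorted(cfg.scenarios):
        scen = pd.read_csv(
            _need(outdir / f"region_summary_{tag}.csv", f"{tag} regional summary")
        )
        table2 = table2.merge(
            scen[["region", "total_tg"]].rename(columns={"total_tg": f"total_tg_{tag}"}),
            on="region",
        )
    bias = pd.read_csv(_need(outdir / "region_bias.csv", "regional bias table"))
    table2["region"] = table2["region"].astype(str)
    bias = bias[["region", "mean_residual", "bias_percent"]].assign(
        region=bias["region"].astype(str)
    )
    table2 = table2.merge(bias, on="region", how="left")
    p = rdir / "ecoregion_stocks.csv"
    table2.to_csv(p, index=False, float_format=FLOAT_FMT)
    bundle["ecoregion_stocks"] = p

    # combined decadal series
    frames = []
    for tag in sorted(cfg.scenarios):
        s = pd.read_csv(_need(outdir / f"decadal_series_{tag}.csv", f"{tag} series"))
        frames.append(s.assign(scenario=tag))
    series = pd.concat(frames, ignore_index=True)[
        ["scenario", "year", "min_mg_ha", "max_mg_ha", "mean_mg_ha", "total_pg"]
    ]
    p = rdir / "decadal_series.csv"
    series.to_csv(p, index=False, float_format=FLOAT_FMT)
    bundle["decadal_series"] = p

    # screening + GWR summaries pass through
    screening = json.loads(_need(outdir / "screening.json", "screening report").read_text())
    gwr = json.loads(_need(outdir / "gwr_summary.json", "GWR summary").read_text())
    metrics = json.loads(_need(outdir / "metrics.json", "test metrics").read_text())
    p = rdir / "model_summary.json"
    p.write_text(
        json.dumps(
            {"screening": screening, "gwr": gwr, "test_metrics": metrics},
            indent=2,
            sort_keys=True,
        )
    )
    bundle["model_summary"] = p

    if pca is not None:
        pca.loadings.to_csv(rdir / "pca_loadings.csv", float_format=FLOAT_FMT)
        pca.scores.to_csv(rdir / "pca_scores.csv", float_format=FLOAT_FMT)
        pd.DataFrame(
            {
                "component": [f"PC{i + 1}" for i in range(len(pca.explained_variance))],
                "eigenvalue": pca.explained_variance,
                "explained_fraction": pca.explained_fraction,
            }
        ).to_csv(rdir / "pca_explained.csv", index=False, float_format=FLOAT_FMT)
        bundle["pca_loadings"] = rdir / "pca_loadings.csv"
        bundle["pca_scores"] = rdir / "pca_scores.csv"
        bundle["pca_explained"] = rdir / "pca_explained.csv"

    maps = sorted(str(q.relative_to(outdir)) for q in outdir.glob("*.asc"))
    p = rdir / "map_files.json"
    p.write_text(json.dumps(maps, indent=2))
    bundle["map_files"] = p

    lines = [
        "SOC-GWR run summary",
        "===================",
        f"selected predictors: {', '.join(screening['selected_predictors']) or '(null model)'}",
        f"box-cox lambda: {screening['boxcox_lambda']:.4f}",
        f"split sizes (train, test): {tuple(screening['split_sizes'])}",
        f"adaptive bandwidth k: {gwr['k_selected']} ({gwr['kernel']} kernel)",
        f"effective parameters trace(S): {gwr['trace_S']:.2f}  AICc: {gwr['aicc']:.2f}",
        f"test R^2 (Mg/ha scale): {metrics['test_r2_stock_scale']:.4f}",
        f"test R^2 (transformed scale): {metrics['test_r2_transformed_scale']:.4f}",
        "grand-total stock (Tg): "
        + f"{current.loc[current['region'] == 'TOTAL', 'total_tg'].iloc[0]:.6g}",
    ]
    p = rdir / "summary.txt"
    p.write_text("\n".join(lines) + "\n")
    bundle["summary"] = p
    return bundle
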