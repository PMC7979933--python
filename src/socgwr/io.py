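"""Tabular and manifest I/O: profiles, observations, stacks, stock maps.

Profiles travel as one CSV row per layer (id, x, y, region, top, bottom,
soc_pct, bd); observation tables as one CSV row per site; predictor stacks
as a directory of per-layer ASCII grids plus a JSON manifest mapping layer
name to file.  All tables are written with 6-significant-digit floats so a
CSV round trip is lossless at that precision, and CSV output is fully
deterministic (no timestamps, fixed column order).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import CoRegistrationError, InvalidArgumentError, MissingInputError
from .grids import LandscapeGrid, PredictorStack
from .landscape import ScenarioSet
from .projection import StockMap
from .rasters import read_ascii_grid, write_ascii_grid
from .soilprofiles import SoilLayer, SoilProfile

FLOAT_FMT = "%.6g"

PROFILE_COLUMNS = ["id", "x", "y", "region", "top", "bottom", "soc_pct", "bd"]


def write_profiles_csv(profiles, path) -> None:
    rows = [
        (p.id, p.x, p.y, p.region_label,
         l.top_depth, l.bottom_depth, l.soc_concentration, l.bulk_density)
        for p in profiles
        for l in p.layers
    ]
    pd.DataFrame(rows, columns=PROFILE_COLUMNS).to_csv(
        path, index=False, float_format=FLOAT_FMT
    )


def read_profiles(path) -> list[SoilProfile]:
    """Parse a layer-per-row profile CSV; malformed rows are rejected with
    their (1-based data) line number."""
    path = Path(path)
    if not path.exists():
        raise MissingInputError(str(path))
    df = pd.read_csv(path)
    missing = [c for c in PROFILE_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidArgumentError(f"{path}: missing columns {missing}")
    profiles = []
    for pid, sub in df.groupby("id", sort=True):
        layers = []
        for i, row in sub.iterrows():
            try:
                layers.append(
                    SoilLayer(
                        top_depth=float(row["top"]),
                        bottom_depth=float(row["bottom"]),
                        soc_concentration=float(row["soc_pct"]),
                        bulk_density=float(row["bd"]),
                    )
                )
            except (InvalidArgumentError, ValueError) as e:
                raise InvalidArgumentError(f"{path}: row {i + 1}: {e}") from None
        first = sub.iloc[0]
        profiles.append(
            SoilProfile(
                id=int(pid),
                x=float(first["x"]),
                y=float(first["y"]),
                region_label=int(first["region"]),
                layers=layers,
            )
        )
    return profiles


def write_observations(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_observations(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise MissingInputError(str(path))
    df = pd.read_csv(path)
    for c in ("id", "x", "y", "region", "stock_mg_ha"):
        if c not in df.columns:
            raise InvalidArgumentError(f"{path}: missing column {c!r}")
    return df


def write_stack(stack: PredictorStack, directory, manifest_name="stack.json") -> Path:
    """Write each layer (and the region raster) as an ASCII grid plus a
    JSON manifest; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    layer_files = {}
    for name, arr in stack.layers.items():
        fname = f"{name}.asc"
        write_ascii_grid(directory / fname, arr, stack.grid)
        layer_files[name] = fname
    write_ascii_grid(
        directory / "regions.asc",
        stack.grid.region_labels.astype(float),
        stack.grid,
        fmt="%d",
    )
    manifest = {
        "layers": layer_files,
        "indicator_names": list(stack.indicator_names),
        "regions": "regions.asc",
    }
    mpath = directory / manifest_name
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return mpath


def read_stack(manifest_path) -> PredictorStack:
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise MissingInputError(str(manifest_path))
    manifest = json.loads(manifest_path.read_text())
    base = manifest_path.parent
    layers = {}
    geom = None
    for name, fname in sorted(manifest["layers"].items()):
        fpath = base / fname
        if not fpath.exists():
            raise MissingInputError(f"manifest references missing file {fpath}")
        vals, g = read_ascii_grid(fpath)
        if geom is None:
            geom = g
        elif not geom.same_geometry(g):
            raise CoRegistrationError(f"layer {name!r} geometry differs")
        layers[name] = vals
    labels, g = read_ascii_grid(base / manifest["regions"])
    if not geom.same_geometry(g):
        raise CoRegistrationError("region raster geometry differs from layers")
    geom.region_labels = np.nan_to_num(labels, nan=0.0).astype(int)
    return PredictorStack(
        grid=geom, layers=layers, indicator_names=list(manifest.get("indicator_names", []))
    )


def write_stock_map(smap: StockMap, path) -> None:
    write_ascii_grid(path, smap.values, smap.grid)


def read_stock_map(path, scenario="current", year=None) -> StockMap:
    vals, geom = read_ascii_grid(path)
    return StockMap(grid=geom, values=vals, scenario=scenario, year=year)


def write_scenario(scenario: ScenarioSet, directory, grid: LandscapeGrid) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = {}
    for year in scenario.decades:
        files = {}
        for name, arr in scenario.overrides[year].items():
            fname = f"{year}_{name}.asc"
            write_ascii_grid(directory / fname, arr, grid)
            files[name] = fname
        entries[str(year)] = files
    mpath = directory / "scenario.json"
    mpath.write_text(
        json.dumps(
            {"tag": scenario.tag, "decades": scenario.decades, "overrides": entries},
            indent=2,
            sort_keys=True,
        )
    )
    return mpath


def read_scenario(manifest_path) -> ScenarioSet:
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise MissingInputError(str(manifest_path))
    m = json.loads(manifest_path.read_text())
    base = manifest_path.parent
    overrides = {}
    for year_s, files in m["overrides"].items():
        layers = {}
        for name, fname in sorted(files.items()):
            vals, _ = read_ascii_grid(base / fname)
            layers[name] = vals
        overrides[int(year_s)] = layers
    return ScenarioSet(
        decades=[int(y) for y in m["decades"]],
        overrides=overrides,
        tag=m.get("tag", "scenario"),
    )
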