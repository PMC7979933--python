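"""Space-for-time scenario projection and zonal stock accounting.

The fitted local-coefficient field beta_hat(u) *is* the model: under a
climate scenario only the temperature and precipitation predictor layers are
replaced, every other predictor (and the coefficients) is held constant, and
the model is re-evaluated per grid cell and per decade.  Stocks aggregate to
ecoregions as  total[Tg] = sum(stock[Mg/ha] * cell_area[ha]) * 1e-6  and to
national decadal series in Pg (1 Pg = 1000 Tg).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CoRegistrationError, InvalidArgumentError, MissingLayerError
from .grids import LandscapeGrid, PredictorStack
from .gwr import GWRFit, predict_gwr
from .landscape import ScenarioSet
from .transforms import BoxCoxTransform

log = logging.getLogger(__name__)


@dataclass
class StockMap:
    """Gridded SOC stocks (Mg/ha); NaN cells are missing."""

    grid: LandscapeGrid
    values: np.ndarray = field(repr=False)
    scenario: str = "current"
    year: int | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise CoRegistrationError(
                f"values shape {self.values.shape} != grid {self.grid.shape}"
            )

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    def total_tg(self) -> float:
        """Whole-map total stock in Tg over non-missing cells."""
        return float(np.nansum(self.values) * self.grid.cell_area_ha * 1e-6)


def predict_stock_map(
    fit: GWRFit,
    stack: PredictorStack,
    transform: BoxCoxTransform,
    overrides: dict[str, np.ndarray] | None = None,
    scenario: str = "current",
    year: int | None = None,
) -> StockMap:
    """Evaluate the GWR model at every cell center of the stack's grid."""
    grid = stack.grid
    try:
        Xg = stack.design_matrix(fit.predictor_names, overrides)
    except KeyError as e:
        raise MissingLayerError(str(e)) from None
    y = predict_gwr(fit, grid.cell_centers(), Xg, transform=transform)
    return StockMap(grid=grid, values=y.reshape(grid.shape), scenario=scenario, year=year)


def project_scenario(
    fit: GWRFit,
    baseline: PredictorStack,
    overrides: ScenarioSet,
    decade: int,
    transform: BoxCoxTransform,
) -> StockMap:
    """Re-predict the stock map for one decade of a scenario.

    All predictors stay at baseline except the scenario's override layers;
    cells with any missing predictor value come out missing.
    """
    if decade not in overrides.overrides:
        raise InvalidArgumentError(f"scenario has no decade {decade}")
    layer_over = overrides.overrides[decade]
    unknown = [n for n in layer_over if n not in fit.predictor_names]
    if unknown:
        raise InvalidArgumentError(
            f"override layers {unknown} are not predictors of the fitted model"
        )
    for name, arr in layer_over.items():
        if np.asarray(arr).shape != baseline.grid.shape:
            raise CoRegistrationError(
                f"override {name!r} shape {np.asarray(arr).shape} != "
                f"baseline grid {baseline.grid.shape}"
            )
    return predict_stock_map(
        fit, baseline, transform, overrides=layer_over,
        scenario=overrides.tag, year=decade,
    )


def difference_map(a: StockMap, b: StockMap) -> StockMap:
    """Cell-wise a - b; missing wherever either side is missing."""
    if not a.grid.same_geometry(b.grid):
        raise CoRegistrationError("stock maps are not co-registered")
    return StockMap(
        grid=a.grid,
        values=a.values - b.values,
        scenario=f"{a.scenario}-minus-{b.scenario}",
        year=a.year,
    )


def aggregate_by_region(
    smap: StockMap,
    region_labels: np.ndarray | None = None,
    cell_size: float | None = None,
) -> pd.DataFrame:
    """Per-ecoregion mean stock, area, and total (Tg), plus a TOTAL row.

    Means are over non-missing cells; area counts non-missing cells only.
    The grand-total row aggregates the whole map ignoring labels and equals
    the sum of the regional totals.
    """
    labels = smap.grid.region_labels if region_labels is None else np.asarray(region_labels)
    if labels.shape != smap.values.shape:
        raise CoRegistrationError("label grid not co-registered with the stock map")
    cell_area_ha = (
        smap.grid.cell_area_ha if cell_size is None else cell_size**2 / 1e4
    )
    vals = smap.values.ravel()
    labs = labels.ravel()
    ok = ~np.isnan(vals)
    rows = []
    for lab in np.unique(labs):
        sel = ok & (labs == lab)
        n = int(sel.sum())
        if n == 0:
            rows.append((lab, np.nan, 0, 0.0, 0.0))
            continue
        mean = float(vals[sel].mean())
        area = n * cell_area_ha
        rows.append((lab, mean, n, area, float(vals[sel].sum()) * cell_area_ha * 1e-6))
    df = pd.DataFrame(
        rows, columns=["region", "mean_stock_mg_ha", "cell_count", "area_ha", "total_tg"]
    )
    n_all = int(ok.sum())
    grand = pd.DataFrame(
        [
            (
                "TOTAL",
                float(vals[ok].mean()) if n_all else np.nan,
                n_all,
                n_all * cell_area_ha,
                float(vals[ok].sum()) * cell_area_ha * 1e-6 if n_all else 0.0,
            )
        ],
        columns=df.columns,
    )
    return pd.concat([df, grand], ignore_index=True)


def decadal_series(
    fit: GWRFit,
    baseline: PredictorStack,
    scenario: ScenarioSet,
    transform: BoxCoxTransform,
) -> pd.DataFrame:
    """One summary row per decade: min/max/mean stock (Mg/ha) and total (Pg)."""
    if not scenario.decades:
        raise InvalidArgumentError("scenario has no decades")
    rows = []
    for year in scenario.decades:
        m = project_scenario(fit, baseline, scenario, year, transform)
        v = m.values[~m.missing_mask]
        rows.append(
            (
                year,
                float(v.min()),
                float(v.max()),
                float(v.mean()),
                m.total_tg() * 1e-3,
            )
        )
    return pd.DataFrame(
        rows, columns=["year", "min_mg_ha", "max_mg_ha", "mean_mg_ha", "total_pg"]
    )


def compare_external_soc(ours: StockMap, external: StockMap) -> StockMap:
    """Block-average our fine map onto an external coarse grid, then difference.

    Fine cells are assigned to the coarse cell containing their center and
    averaged (simple mean); the returned map is (our block mean - external)
    on the external geometry.  Coarse cells covering no fine cell, or where
    the external value is missing, are missing.
    """
    cg = external.grid
    fine = ours.grid
    cs = cg.cell_size
    cx = np.floor(
        (fine.cell_centers()[:, 0] - (cg.origin_x - cs / 2)) / cs
    ).astype(int)
    cy = np.floor(
        (fine.cell_centers()[:, 1] - (cg.origin_y - cs / 2)) / cs
    ).astype(int)
    vals = ours.values.ravel()
    inside = (cx >= 0) & (cx < cg.nx) & (cy >= 0) & (cy < cg.ny) & ~np.isnan(vals)
    if not inside.any():
        raise CoRegistrationError("external grid does not overlap the stock map")
    flat = cy[inside] * cg.nx + cx[inside]
    sums = np.bincount(flat, weights=vals[inside], minlength=cg.n_cells)
    counts = np.bincount(flat, minlength=cg.n_cells)
    with np.errstate(invalid="ignore", divide="ignore"):
        block = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    diff = block.reshape(cg.shape) - external.values
    return StockMap(
        grid=cg,
        values=diff,
        scenario=f"{ours.scenario}-minus-{external.scenario}",
        year=ours.year,
    )
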