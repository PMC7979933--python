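"""Synthetic landscape generator: the study conditions in miniature.

The observational basis of the analysis this package reproduces is a set of
georeferenced soil profiles scattered over ecoregions, with co-registered
climate / vegetation / soil-class raster predictors.  This module fabricates
all of it with a *known* spatially varying truth so that every downstream
stage (stock computation, screening, geographically weighted regression,
scenario projection) can be validated against ground truth:

* ecoregion partitions as Voronoi patches of random seed points,
* smooth continuous predictor fields (Gaussian-filtered white noise,
  standardized to mean 0 / variance 1),
* categorical layers by quantile-slicing an independent smooth field,
  emitted as one-hot indicators with the reference class dropped,
* spatially varying coefficient surfaces beta_k(s),
* a positively skewed SOC response built through an inverse Box-Cox
  transform of the local linear predictor plus Gaussian noise,
* layered soil profiles that integrate exactly back to each site's stock,
* decadal temperature / precipitation override layers for scenarios.

Every generator is bit-reproducible given its arguments and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial.distance import cdist

from .errors import (
    DegenerateTruthError,
    InvalidArgumentError,
    MissingLayerError,
)
from .grids import LandscapeGrid, PredictorStack, regions_are_contiguous
from .soilprofiles import SoilLayer, SoilProfile, compute_profile_stock
from .transforms import boxcox_invert

#: canonical column names of an observation table
OBS_COLUMNS = ("id", "x", "y", "region", "stock_mg_ha")


@dataclass
class SyntheticTruth:
    """Known data-generating process on a landscape.

    ``coefficient_surfaces`` maps predictor name (plus ``"intercept"``) to a
    (ny, nx) surface of true local coefficients beta_k(s) on the transformed
    response scale.  ``lambda_true`` is the Box-Cox exponent linking the
    linear predictor to the reported stock; ``noise_sd`` the SD of additive
    Gaussian noise on the transformed scale.
    """

    coefficient_surfaces: dict[str, np.ndarray]
    lambda_true: float
    noise_sd: float

    def __post_init__(self):
        if self.noise_sd < 0:
            raise InvalidArgumentError("noise_sd must be >= 0")
        if "intercept" not in self.coefficient_surfaces:
            raise InvalidArgumentError("truth must include an 'intercept' surface")
        for name, s in self.coefficient_surfaces.items():
            if not np.all(np.isfinite(s)):
                raise InvalidArgumentError(f"coefficient surface {name!r} not finite")


@dataclass
class ScenarioSet:
    """Per-decade replacement layers for a named subset of predictors.

    ``overrides[year]`` maps predictor name -> (ny, nx) replacement layer.
    All other predictors are held constant under projection (space-for-time).
    """

    decades: list[int]
    overrides: dict[int, dict[str, np.ndarray]]
    tag: str = "scenario"

    def __post_init__(self):
        years = list(self.decades)
        if any(b <= a for a, b in zip(years, years[1:])):
            raise InvalidArgumentError("decade years must be strictly increasing")
        missing = [y for y in years if y not in self.overrides]
        if missing:
            raise InvalidArgumentError(f"no override layers for decades {missing}")

    @property
    def overridden_names(self) -> list[str]:
        return sorted({n for d in self.overrides.values() for n in d})


def generate_landscape(nx, ny, cell_size, n_regions, seed) -> LandscapeGrid:
    """Partition an ``nx x ny`` grid into ``n_regions`` Voronoi ecoregions.

    Region labels are the nearest-seed-point partition from ``n_regions``
    points drawn uniformly over the domain.  Draws are repeated (from the
    same deterministic stream) until every region is non-empty and
    4-connected, which Voronoi cells of well-separated seeds almost always
    are on the first attempt.
    """
    if nx < 2 or ny < 2 or cell_size <= 0:
        raise InvalidArgumentError("need nx, ny >= 2 and cell_size > 0")
    if n_regions < 1 or n_regions > nx * ny:
        raise InvalidArgumentError("need 1 <= n_regions <= nx*ny")
    rng = np.random.default_rng(seed)
    grid = LandscapeGrid(nx=nx, ny=ny, cell_size=cell_size)
    if n_regions == 1:
        return grid
    centers = grid.cell_centers()
    for _ in range(50):
        pts = np.column_stack(
            [
                rng.uniform(grid.origin_x, grid.origin_x + (nx - 1) * cell_size, n_regions),
                rng.uniform(grid.origin_y, grid.origin_y + (ny - 1) * cell_size, n_regions),
            ]
        )
        labels = np.argmin(cdist(centers, pts), axis=1).reshape(ny, nx)
        grid.region_labels = labels
        if len(np.unique(labels)) == n_regions and regions_are_contiguous(grid):
            return grid
    raise InvalidArgumentError(
        f"could not draw {n_regions} non-empty contiguous regions on a {nx}x{ny} grid"
    )


def _smooth_field(rng, shape, smoothness):
    """Standardized Gaussian-filtered white noise; ``smoothness`` is the
    kernel SD in cells (the correlation length of the field)."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=smoothness, mode="reflect")
    return (f - f.mean()) / f.std()


def generate_predictor_fields(
    grid: LandscapeGrid,
    continuous_names,
    categorical_specs=(),
    smoothness: float = 5.0,
    seed: int = 0,
) -> PredictorStack:
    """Smooth continuous fields plus one-hot categorical layers.

    Continuous fields are white Gaussian noise convolved with an isotropic
    Gaussian kernel of SD ``smoothness`` cells, then standardized to mean 0
    and variance 1 over the grid.  Each ``(name, n_classes)`` categorical
    spec quantile-thresholds an independent smooth field into equal-count
    bands and emits ``n_classes - 1`` indicator layers named
    ``{name}_class{j}`` (class 0 is the dropped reference).
    """
    if smoothness < 1:
        raise InvalidArgumentError("smoothness must be >= 1 cell")
    names = list(continuous_names)
    all_names = names + [
        f"{nm}_class{j}" for nm, k in categorical_specs for j in range(1, k)
    ]
    if len(set(all_names)) != len(all_names):
        raise InvalidArgumentError("duplicate predictor names")
    rng = np.random.default_rng(seed)
    layers: dict[str, np.ndarray] = {}
    for nm in names:
        layers[nm] = _smooth_field(rng, grid.shape, smoothness)
    indicator_names = []
    for nm, k in categorical_specs:
        if k < 2:
            raise InvalidArgumentError(f"categorical {nm!r} needs >= 2 classes")
        base = _smooth_field(rng, grid.shape, smoothness)
        edges = np.quantile(base, np.linspace(0, 1, k + 1)[1:-1])
        cls = np.searchsorted(edges, base, side="right")
        for j in range(1, k):
            lname = f"{nm}_class{j}"
            layers[lname] = (cls == j).astype(float)
            indicator_names.append(lname)
    return PredictorStack(grid=grid, layers=layers, indicator_names=indicator_names)


def generate_observations(
    grid: LandscapeGrid,
    stack: PredictorStack,
    truth: SyntheticTruth,
    n: int,
    seed: int,
):
    """Sample ``n`` distinct cells and generate SOC stocks from the truth.

    On the transformed scale z_i = beta_0(s_i) + sum_k beta_k(s_i) x_k(s_i)
    + eps_i with eps_i ~ N(0, noise_sd^2); the reported stock is the
    Box-Cox inverse of z_i at ``lambda_true`` and is strictly positive.
    Noise draws whose z leaves the inverse's domain are redrawn (per row, up
    to 100 attempts) before failing.

    Returns ``(observations, truth_records)``: a pandas observation table
    (id, x, y, region, stock_mg_ha, one column per predictor) and a
    co-indexed table of the true local coefficients and noiseless/noisy
    linear predictor at each sampled cell.
    """
    import pandas as pd

    if n < 1 or n > grid.n_cells:
        raise InvalidArgumentError("need 1 <= n <= number of cells")
    missing = [p for p in stack.names if p not in truth.coefficient_surfaces]
    if missing:
        raise InvalidArgumentError(f"truth lacks coefficient surfaces for {missing}")
    rng = np.random.default_rng(seed)
    flat = rng.choice(grid.n_cells, size=n, replace=False)
    centers = grid.cell_centers()[flat]
    regions = grid.region_labels.ravel()[flat]
    X = stack.values_at_cells(flat)
    betas = {
        k: surf.ravel()[flat] for k, surf in truth.coefficient_surfaces.items()
    }
    z0 = betas["intercept"].copy()
    for j, nm in enumerate(stack.names):
        z0 += betas[nm] * X[:, j]

    lam = truth.lambda_true
    z = z0 + rng.normal(0.0, truth.noise_sd, size=n)
    if lam != 0.0:
        for _ in range(100):
            bad = lam * z + 1 <= 0
            if not bad.any():
                break
            z[bad] = z0[bad] + rng.normal(0.0, truth.noise_sd, size=int(bad.sum()))
        else:
            raise DegenerateTruthError(
                "Box-Cox inverse undefined after 100 noise redraws; "
                "truth surfaces and noise_sd are inconsistent with lambda_true"
            )
    y = boxcox_invert(z, lam)

    obs = pd.DataFrame(
        {
            "id": np.arange(n),
            "x": centers[:, 0],
            "y": centers[:, 1],
            "region": regions,
            "stock_mg_ha": y,
        }
    )
    for j, nm in enumerate(stack.names):
        obs[nm] = X[:, j]
    rec = pd.DataFrame({"id": np.arange(n), "z_noiseless": z0, "z": z})
    for k in truth.coefficient_surfaces:
        rec[f"beta_{k}"] = betas[k]
    return obs, rec


def generate_profiles(observations, layers_per_profile: int, seed: int):
    """Expand each observation into a layered 0-100 cm soil profile.

    Layer thicknesses are Dirichlet-tiled over 0-100 cm; raw SOC
    concentrations and bulk densities are drawn positive and the
    concentrations rescaled so the fixed-depth stock integral reproduces the
    observation's stock to ~1e-9 relative error.
    """
    if layers_per_profile < 1:
        raise InvalidArgumentError("layers_per_profile must be >= 1")
    rng = np.random.default_rng(seed)
    profiles = []
    for row in observations.itertuples(index=False):
        thick = rng.dirichlet(np.full(layers_per_profile, 5.0)) * 100.0
        bounds = np.concatenate([[0.0], np.cumsum(thick)])
        bounds[-1] = 100.0
        soc = rng.uniform(0.2, 5.0, layers_per_profile)
        bd = rng.uniform(0.8, 1.8, layers_per_profile)
        raw = float(np.sum(soc * bd * np.diff(bounds)))
        soc *= row.stock_mg_ha / raw
        layers = [
            SoilLayer(
                top_depth=float(bounds[i]),
                bottom_depth=float(bounds[i + 1]),
                soc_concentration=float(soc[i]),
                bulk_density=float(bd[i]),
            )
            for i in range(layers_per_profile)
        ]
        profiles.append(
            SoilProfile(
                id=int(row.id),
                x=float(row.x),
                y=float(row.y),
                region_label=int(row.region),
                layers=layers,
            )
        )
    return profiles


def generate_future_climate(
    stack: PredictorStack,
    decades,
    temp_delta_per_decade: float,
    precip_factor_per_decade: float,
    seed: int,
    temperature_name: str = "temperature",
    precipitation_name: str = "precipitation",
    perturbation_sd: float = 0.0,
    perturbation_smoothness: float = 5.0,
    floor_at_zero: bool | str = "auto",
    tag: str = "scenario",
) -> ScenarioSet:
    """Decadal override layers: an additive temperature trend and a
    multiplicative precipitation trend, optionally with a smooth zero-mean
    spatial perturbation on temperature.

    Decade index is 1-based: the i-th listed decade shifts temperature by
    ``i * temp_delta_per_decade`` and scales precipitation by
    ``precip_factor_per_decade ** i``, floored at 0.  The floor only makes
    sense for physically non-negative precipitation; with ``"auto"`` it is
    applied exactly when the baseline layer is non-negative everywhere, so
    standardized anomaly layers pass through unfloored.
    """
    for nm in (temperature_name, precipitation_name):
        if nm not in stack:
            raise MissingLayerError(nm)
    rng = np.random.default_rng(seed)
    t0 = stack[temperature_name]
    p0 = stack[precipitation_name]
    if floor_at_zero == "auto":
        floor_at_zero = bool((p0 >= 0).all())
    overrides = {}
    for i, year in enumerate(decades, start=1):
        if perturbation_sd > 0:
            pert = _smooth_field(rng, stack.grid.shape, perturbation_smoothness)
            pert = (pert - pert.mean()) * perturbation_sd
        else:
            pert = 0.0
        precip = p0 * precip_factor_per_decade**i
        if floor_at_zero:
            precip = np.maximum(precip, 0.0)
        overrides[int(year)] = {
            temperature_name: t0 + i * temp_delta_per_decade + pert,
            precipitation_name: precip,
        }
    return ScenarioSet(decades=[int(y) for y in decades], overrides=overrides, tag=tag)
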