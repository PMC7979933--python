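"""Shared fixtures: small synthetic landscapes and a heterogeneous
parameter-recovery dataset reused across GWR and acceptance tests."""

from __future__ import annotations

import numpy as np
import pytest

from socgwr import (
    GWRConfig,
    SyntheticTruth,
    generate_landscape,
    generate_observations,
    generate_predictor_fields,
)
from socgwr.landscape import _smooth_field


@pytest.fixture(scope="session")
def small_grid():
    return generate_landscape(20, 20, 800.0, 4, seed=42)


@pytest.fixture(scope="session")
def small_stack(small_grid):
    return generate_predictor_fields(
        small_grid,
        ["temperature", "precipitation"],
        [("soil_order", 3)],
        smoothness=3,
        seed=7,
    )


def constant_truth(grid, stack, coefficients, lambda_true=1.0, noise_sd=0.0):
    """Truth with spatially constant coefficient surfaces."""
    surfaces = {
        name: np.full(grid.shape, coefficients.get(name, 0.0))
        for name in ["intercept", *stack.names]
    }
    return SyntheticTruth(
        coefficient_surfaces=surfaces, lambda_true=lambda_true, noise_sd=noise_sd
    )


@pytest.fixture(scope="session")
def constant_dataset(small_grid, small_stack):
    """Noise-free identity-transform observations from constant coefficients."""
    truth = constant_truth(
        small_grid,
        small_stack,
        {"intercept": 10.0, "temperature": -0.5, "precipitation": 0.4},
        lambda_true=1.0,
        noise_sd=0.0,
    )
    obs, rec = generate_observations(small_grid, small_stack, truth, 150, seed=5)
    return obs, rec, truth


def make_hetero_dataset(seed: int, n: int = 800, nx: int = 60, ny: int = 60,
                        truth_smoothness: float = 15.0):
    """Landscape with smoothly varying coefficient surfaces: 2 continuous
    predictors, truth correlation length ``truth_smoothness`` cells, noise
    at 10% of the signal SD, Box-Cox exponent 0.5."""
    # predictor fields vary on a short scale (3 cells) relative to the
    # coefficient regimes (15 cells) so local slopes are identifiable
    grid = generate_landscape(nx, ny, 800.0, 5, seed=seed)
    stack = generate_predictor_fields(
        grid, ["temperature", "precipitation"], smoothness=3, seed=seed + 1
    )
    rng = np.random.default_rng(seed + 2)
    surfaces = {
        "intercept": 20.0 + 1.0 * _smooth_field(rng, grid.shape, truth_smoothness),
        "temperature": -0.8 + 0.5 * _smooth_field(rng, grid.shape, truth_smoothness),
        "precipitation": 0.6 + 0.5 * _smooth_field(rng, grid.shape, truth_smoothness),
    }
    # noise scaled to 10% of the SD of the noiseless linear predictor
    z0 = surfaces["intercept"] + sum(
        surfaces[nm] * stack[nm] for nm in stack.names
    )
    truth = SyntheticTruth(
        coefficient_surfaces=surfaces,
        lambda_true=0.5,
        noise_sd=0.1 * float(z0.std()),
    )
    obs, rec = generate_observations(grid, stack, truth, n, seed=seed + 3)
    return grid, stack, truth, obs, rec


@pytest.fixture(scope="session")
def hetero_dataset():
    return make_hetero_dataset(seed=11)


def wls_oracle(X, z, w):
    """Independent dense weighted-least-squares route: scale rows by
    sqrt(w) and solve by lstsq (never touches the package's solver)."""
    sw = np.sqrt(np.asarray(w, dtype=float))
    beta, *_ = np.linalg.lstsq(X * sw[:, None], z * sw, rcond=None)
    return beta


@pytest.fixture
def gwr_config():
    return GWRConfig(kernel="bisquare")
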