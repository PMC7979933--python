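"""Scenario projection, difference maps, zonal aggregation, unit chain."""

import numpy as np
import pandas as pd
import pytest

from socgwr import (
    BoxCoxTransform,
    GWRConfig,
    LandscapeGrid,
    ScenarioSet,
    StockMap,
    aggregate_by_region,
    compare_external_soc,
    decadal_series,
    difference_map,
    fit_gwr,
    generate_future_climate,
    generate_observations,
    predict_stock_map,
    project_scenario,
)
from socgwr.errors import CoRegistrationError, InvalidArgumentError

from conftest import constant_truth


@pytest.fixture(scope="module")
def fitted_model(small_grid, small_stack):
    """GWR fit on noise-free data with a constant, all-negative temperature
    coefficient; lambda = 0.5 keeps stocks positive."""
    truth = constant_truth(
        small_grid,
        small_stack,
        {"intercept": 12.0, "temperature": -1.0, "precipitation": 0.5},
        lambda_true=0.5,
        noise_sd=0.0,
    )
    obs, _ = generate_observations(small_grid, small_stack, truth, 180, seed=3)
    names = ["intercept", "temperature", "precipitation"]
    X = np.column_stack(
        [np.ones(len(obs)), obs["temperature"], obs["precipitation"]]
    )
    bc = BoxCoxTransform(lambda_=0.5, loglik=0.0)
    z = bc.apply(obs["stock_mg_ha"].to_numpy())
    fit = fit_gwr(X, z, obs[["x", "y"]].to_numpy(),
                  GWRConfig(k_range=(30, len(obs))), names)
    return fit, bc


def uniform_map(value, nx=10, ny=10, cell_size=1000.0, labels=None):
    g = LandscapeGrid(nx=nx, ny=ny, cell_size=cell_size, region_labels=labels)
    return StockMap(grid=g, values=np.full((ny, nx), float(value)))


class TestProjectScenario:
    def test_null_scenario_reproduces_baseline_cell_for_cell(
        self, small_stack, fitted_model
    ):
        fit, bc = fitted_model
        baseline = predict_stock_map(fit, small_stack, bc)
        scen = generate_future_climate(small_stack, [2030], 0.0, 1.0, seed=0,
                                       floor_at_zero=False)
        proj = project_scenario(fit, small_stack, scen, 2030, bc)
        np.testing.assert_array_equal(proj.values, baseline.values)

    def test_warming_with_negative_coefficient_lowers_every_cell(
        self, small_stack, fitted_model
    ):
        fit, bc = fitted_model
        assert (fit.local_coefficients[:, 1] < 0).all()
        baseline = predict_stock_map(fit, small_stack, bc)
        scen = ScenarioSet(
            decades=[2100],
            overrides={2100: {"temperature": small_stack["temperature"] + 2.0}},
        )
        proj = project_scenario(fit, small_stack, scen, 2100, bc)
        ok = ~np.isnan(proj.values) & ~np.isnan(baseline.values)
        assert (proj.values[ok] <= baseline.values[ok]).all()

    def test_unknown_override_predictor_rejected(self, small_stack, fitted_model):
        fit, bc = fitted_model
        scen = ScenarioSet(
            decades=[2030], overrides={2030: {"ndvi": small_stack["temperature"]}}
        )
        with pytest.raises(InvalidArgumentError):
            project_scenario(fit, small_stack, scen, 2030, bc)


class TestDifferenceMap:
    def test_identical_maps_difference_to_zero(self):
        a = uniform_map(110.0)
        assert (difference_map(a, a).values == 0.0).all()

    def test_uniform_difference(self):
        assert (difference_map(uniform_map(110.0), uniform_map(100.0)).values == 10.0).all()

    def test_matches_cell_loop_oracle_with_missing(self):
        rng = np.random.default_rng(0)
        g = LandscapeGrid(nx=6, ny=5, cell_size=800.0)
        av = rng.uniform(0, 100, (5, 6))
        bv = rng.uniform(0, 100, (5, 6))
        av[2, 3] = np.nan
        d = difference_map(StockMap(g, av), StockMap(g, bv))
        for iy in range(5):
            for ix in range(6):
                e = av[iy, ix] - bv[iy, ix]
                if np.isnan(e):
                    assert np.isnan(d.values[iy, ix])
                else:
                    assert d.values[iy, ix] == pytest.approx(e)

    def test_geometry_mismatch(self):
        with pytest.raises(CoRegistrationError):
            difference_map(uniform_map(1, nx=10), uniform_map(1, nx=11))


class TestAggregateByRegion:
    def test_unit_conversion_100_tg_over_1e6_ha(self):
        # 10x10 cells of 1 km^2 = 100 ha each -> 1e4 ha... scale up:
        # 100x100 cells of 1000 m -> 100 ha/cell * 1e4 cells = 1e6 ha
        m = uniform_map(100.0, nx=100, ny=100, cell_size=1000.0)
        out = aggregate_by_region(m)
        total = out.loc[out.region == "TOTAL", "total_tg"].iloc[0]
        assert total == pytest.approx(100.0)
        assert out.loc[out.region == "TOTAL", "area_ha"].iloc[0] == pytest.approx(1e6)

    def test_two_equal_regions_grand_mean_and_additivity(self):
        labels = np.zeros((10, 10), dtype=int)
        labels[:, 5:] = 1
        vals = np.where(labels == 0, 10.0, 30.0)
        g = LandscapeGrid(nx=10, ny=10, cell_size=800.0, region_labels=labels)
        out = aggregate_by_region(StockMap(g, vals))
        by = out.set_index("region")
        assert by.loc["TOTAL", "mean_stock_mg_ha"] == pytest.approx(20.0)
        assert by.loc["TOTAL", "total_tg"] == pytest.approx(
            by.loc[0, "total_tg"] + by.loc[1, "total_tg"]
        )

    def test_matches_per_cell_loop_oracle(self):
        rng = np.random.default_rng(1)
        labels = rng.integers(0, 5, (8, 8))
        vals = rng.uniform(0, 300, (8, 8))
        vals[0, 0] = np.nan
        g = LandscapeGrid(nx=8, ny=8, cell_size=800.0, region_labels=labels)
        out = aggregate_by_region(StockMap(g, vals)).set_index("region")
        for lab in range(5):
            acc, n = 0.0, 0
            for iy in range(8):
                for ix in range(8):
                    if labels[iy, ix] == lab and not np.isnan(vals[iy, ix]):
                        acc += vals[iy, ix]
                        n += 1
            assert out.loc[lab, "mean_stock_mg_ha"] == pytest.approx(acc / n)
            assert out.loc[lab, "total_tg"] == pytest.approx(acc * 64.0 * 1e-6)

    def test_conservation_grand_total_equals_unlabelled_total(self):
        rng = np.random.default_rng(2)
        labels = rng.integers(0, 5, (20, 20))
        vals = rng.uniform(0, 500, (20, 20))
        g = LandscapeGrid(nx=20, ny=20, cell_size=800.0, region_labels=labels)
        m = StockMap(g, vals)
        out = aggregate_by_region(m)
        grand = out.loc[out.region == "TOTAL", "total_tg"].iloc[0]
        assert abs(grand - m.total_tg()) <= 1e-6 * abs(m.total_tg())
        assert abs(out[out.region != "TOTAL"]["total_tg"].sum() - grand) <= 1e-6 * grand

    def test_empty_region_reported_missing(self):
        labels = np.zeros((4, 4), dtype=int)
        labels[0, 0] = 1
        vals = np.full((4, 4), 50.0)
        vals[0, 0] = np.nan
        g = LandscapeGrid(nx=4, ny=4, cell_size=800.0, region_labels=labels)
        out = aggregate_by_region(StockMap(g, vals)).set_index("region")
        assert np.isnan(out.loc[1, "mean_stock_mg_ha"])
        assert out.loc[1, "total_tg"] == 0.0


class TestDecadalSeries:
    def test_null_scenario_gives_constant_rows(self, small_stack, fitted_model):
        fit, bc = fitted_model
        scen = generate_future_climate(small_stack, [2030, 2040, 2050], 0.0, 1.0,
                                       seed=0, floor_at_zero=False)
        tab = decadal_series(fit, small_stack, scen, bc)
        assert len(tab) == 3
        for col in ("min_mg_ha", "max_mg_ha", "mean_mg_ha", "total_pg"):
            assert tab[col].nunique() == 1

    def test_monotone_warming_with_negative_coefficients(self, small_stack, fitted_model):
        fit, bc = fitted_model
        decades = [2030, 2040, 2050, 2060]
        overrides = {
            y: {"temperature": small_stack["temperature"] + 0.5 * (i + 1)}
            for i, y in enumerate(decades)
        }
        scen = ScenarioSet(decades=decades, overrides=overrides)
        tab = decadal_series(fit, small_stack, scen, bc)
        assert (np.diff(tab["total_pg"]) <= 1e-12).all()

    def test_single_decade_composition(self, small_stack, fitted_model):
        fit, bc = fitted_model
        scen = ScenarioSet(
            decades=[2030],
            overrides={2030: {"temperature": small_stack["temperature"] + 1.0}},
        )
        tab = decadal_series(fit, small_stack, scen, bc)
        m = project_scenario(fit, small_stack, scen, 2030, bc)
        assert tab["total_pg"].iloc[0] == pytest.approx(m.total_tg() * 1e-3)
        assert tab["mean_mg_ha"].iloc[0] == pytest.approx(np.nanmean(m.values))


class TestCompareExternal:
    def coarse(self, fine_grid, factor, values):
        g = LandscapeGrid(
            nx=fine_grid.nx // factor,
            ny=fine_grid.ny // factor,
            cell_size=fine_grid.cell_size * factor,
            origin_x=fine_grid.origin_x + (factor - 1) * fine_grid.cell_size / 2,
            origin_y=fine_grid.origin_y + (factor - 1) * fine_grid.cell_size / 2,
        )
        return StockMap(grid=g, values=values, scenario="external")

    def test_self_comparison_is_zero(self):
        rng = np.random.default_rng(3)
        g = LandscapeGrid(nx=8, ny=8, cell_size=800.0)
        fine = StockMap(g, rng.uniform(0, 100, (8, 8)))
        block = fine.values.reshape(4, 2, 4, 2).mean(axis=(1, 3))
        ext = self.coarse(g, 2, block)
        diff = compare_external_soc(fine, ext)
        np.testing.assert_allclose(diff.values, 0.0, atol=1e-12)

    def test_covered_cells_average(self):
        g = LandscapeGrid(nx=4, ny=4, cell_size=800.0)
        vals = np.tile(np.array([100.0, 200.0, 300.0, 500.0]), (4, 1))
        fine = StockMap(g, vals)
        ext = self.coarse(g, 2, np.zeros((2, 2)))
        diff = compare_external_soc(fine, ext)
        # each coarse cell averages its 2x2 covered fine cells
        assert diff.values[0, 0] == pytest.approx(150.0)
        assert diff.values[0, 1] == pytest.approx(400.0)

    def test_four_to_one_matches_loop_oracle(self):
        rng = np.random.default_rng(4)
        g = LandscapeGrid(nx=8, ny=8, cell_size=800.0)
        fine = StockMap(g, rng.uniform(0, 100, (8, 8)))
        ext_vals = rng.uniform(0, 100, (2, 2))
        ext = self.coarse(g, 4, ext_vals)
        diff = compare_external_soc(fine, ext)
        for cy in range(2):
            for cx in range(2):
                block = fine.values[cy * 4:(cy + 1) * 4, cx * 4:(cx + 1) * 4].mean()
                assert diff.values[cy, cx] == pytest.approx(block - ext_vals[cy, cx])

    def test_disjoint_extents_error(self):
        g = LandscapeGrid(nx=4, ny=4, cell_size=800.0)
        fine = StockMap(g, np.ones((4, 4)))
        far = LandscapeGrid(nx=2, ny=2, cell_size=1600.0, origin_x=1e7, origin_y=1e7)
        with pytest.raises(CoRegistrationError):
            compare_external_soc(fine, StockMap(far, np.ones((2, 2))))
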