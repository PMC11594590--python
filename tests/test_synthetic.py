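import numpy as np
import pytest
from scipy.stats import chisquare

from pestrisk.grid import Raster
from pestrisk.synthetic import (
    FutureDelta,
    PrecipRegime,
    ScenarioSpec,
    TemperatureParams,
    apply_future_delta,
    generate_climate_grid,
    sample_occurrences,
)


def _simple_spec(**kwargs):
    defaults = dict(
        extent=(-20.0, 20.0, -30.0, 30.0),
        resolution_arcmin=120.0,
        regimes=(PrecipRegime(-30.0, 30.0, 800.0, "uniform"),),
        seed=3,
    )
    defaults.update(kwargs)
    return ScenarioSpec(**defaults)


class TestGenerateClimateGrid:
    def test_degenerate_constant_climate(self):
        spec = _simple_spec(
            temperature=TemperatureParams(equatorial_mean=20.0, lapse=0.0, seasonal_amplitude=0.0)
        )
        grid = generate_climate_grid(spec)
        assert np.allclose(grid.tavg, 20.0)
        assert np.ptp(grid.tmin) == 0.0 and np.ptp(grid.tmax) == 0.0

    def test_linear_lapse_sets_annual_mean(self):
        # one cell centred exactly at 45 N: annual mean must be 27 - 0.6*45 = 0
        spec = ScenarioSpec(
            extent=(0.0, 1.0, 44.5, 45.5),
            resolution_arcmin=60.0,
            temperature=TemperatureParams(equatorial_mean=27.0, lapse=0.6),
            regimes=(PrecipRegime(40.0, 50.0, 500.0, "uniform"),),
        )
        grid = generate_climate_grid(spec)
        assert grid.tavg.mean(axis=0)[0, 0] == pytest.approx(0.0, abs=1e-9)

    def test_seed_determinism_is_bit_identical(self):
        spec = _simple_spec(precip_noise_cv=0.5, temp_noise_sd=1.0)
        a = generate_climate_grid(spec)
        b = generate_climate_grid(spec)
        assert np.array_equal(a.tmin, b.tmin)
        assert np.array_equal(a.rain, b.rain)

    def test_hemispheric_phase_inversion(self):
        grid = generate_climate_grid(_simple_spec())
        lat = grid.geometry.lat_centers()
        north = np.flatnonzero(lat > 0)
        for i in north:
            j = np.argmin(np.abs(lat + lat[i]))  # mirror row
            for m in range(12):
                assert grid.tavg[m, i, 0] == pytest.approx(
                    grid.tavg[(m + 6) % 12, j, 0], abs=1e-9
                )

    def test_physical_invariants_over_random_specs(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            spec = ScenarioSpec(
                extent=(-10.0, 10.0, -20.0, 20.0),
                resolution_arcmin=600.0,
                temperature=TemperatureParams(
                    equatorial_mean=rng.uniform(-5, 35),
                    lapse=rng.uniform(0, 1),
                    seasonal_amplitude=rng.uniform(0, 40),
                    diurnal_range=rng.uniform(0, 15),
                ),
                regimes=(
                    PrecipRegime(
                        -20.0, 20.0, rng.uniform(0, 4000),
                        rng.choice(["uniform", "summer-wet", "winter-wet", "arid"]),
                    ),
                ),
                seed=int(rng.integers(0, 2**31)),
                precip_noise_cv=rng.uniform(0, 1),
                temp_noise_sd=rng.uniform(0, 3),
            )
            grid = generate_climate_grid(spec)  # ClimateGrid validates on build
            assert np.all(grid.tmin <= grid.tmax)
            assert np.all(grid.rain >= 0)

    def test_uncovered_latitudes_raise(self):
        spec = _simple_spec(regimes=(PrecipRegime(-30.0, 0.0, 500.0, "uniform"),))
        with pytest.raises(ValueError, match="regimes do not cover"):
            generate_climate_grid(spec)

    def test_invalid_extent_raises(self):
        with pytest.raises(ValueError):
            _simple_spec(extent=(20.0, -20.0, -30.0, 30.0))


class TestFutureDelta:
    def test_identity_delta(self):
        grid = generate_climate_grid(_simple_spec())
        out = apply_future_delta(grid, FutureDelta(warming=0.0))
        assert np.array_equal(out.tmax, grid.tmax)
        assert np.array_equal(out.rain, grid.rain)

    def test_uniform_warming_shifts_tmax_exactly(self):
        grid = generate_climate_grid(_simple_spec())
        out = apply_future_delta(grid, FutureDelta(warming=2.0))
        assert np.allclose(out.tmax - grid.tmax, 2.0)
        assert np.allclose(out.tmin - grid.tmin, 2.0)

    def test_band_factor_halves_rain_in_band_only(self):
        grid = generate_climate_grid(_simple_spec())
        out = apply_future_delta(grid, FutureDelta(band_factors=((0.0, 30.0, 0.5),)))
        lat = grid.geometry.lat_centers()
        north = lat >= 0
        assert np.allclose(out.rain[:, north, :], 0.5 * grid.rain[:, north, :])
        assert np.array_equal(out.rain[:, ~north, :], grid.rain[:, ~north, :])

    def test_negative_factor_raises(self):
        with pytest.raises(ValueError):
            FutureDelta(band_factors=((0.0, 10.0, -0.5),))


class TestSampleOccurrences:
    def _geom_raster(self, values):
        from pestrisk.grid import GridGeometry

        values = np.asarray(values, dtype=float)
        geom = GridGeometry(0.0, float(values.shape[0]), 60.0, *values.shape)
        return Raster(values, geom)

    def test_point_mass_truth_puts_all_points_in_that_cell(self):
        truth = np.zeros((4, 5))
        truth[2, 3] = 1.0
        raster = self._geom_raster(truth)
        occ = sample_occurrences(raster, 10, seed=0)
        row, col = raster.geometry.cell_of(occ["lon"].to_numpy(), occ["lat"].to_numpy())
        assert np.all(row == 2) and np.all(col == 3)

    def test_uniform_truth_is_multinomially_uniform(self):
        raster = self._geom_raster(np.ones((5, 8)))
        occ = sample_occurrences(raster, 10_000, seed=1)
        row, col = raster.geometry.cell_of(occ["lon"].to_numpy(), occ["lat"].to_numpy())
        counts = np.bincount(row * 8 + col, minlength=40)
        assert chisquare(counts).pvalue > 0.01

    def test_seed_determinism(self):
        raster = self._geom_raster(np.random.default_rng(0).uniform(0, 1, (4, 4)))
        a = sample_occurrences(raster, 50, seed=9)
        b = sample_occurrences(raster, 50, seed=9)
        assert a.equals(b)

    def test_all_zero_truth_raises(self):
        with pytest.raises(ValueError, match="all zero"):
            sample_occurrences(self._geom_raster(np.zeros((3, 3))), 5, seed=0)
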