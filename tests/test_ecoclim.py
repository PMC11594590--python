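import numpy as np
import pytest

from pestrisk.climate import ClimateGrid
from pestrisk.ecoclim import (
    BucketConfig,
    EcoclimaticIndexEngine,
    WEEKS,
    accumulate_stress,
    annual_growth_index,
    classify_ei,
    ecoclimatic_index,
    interpolate_weekly,
    moisture_index_week,
    soil_moisture_series,
    stress_index,
    temperature_index_week,
)
from pestrisk.grid import GridGeometry
from pestrisk.params import sweetgum_parameters
from pestrisk.synthetic import band_rows

HOST = sweetgum_parameters()


class TestWeeklyInterpolation:
    def test_constant_monthly_series_stays_constant(self):
        w = interpolate_weekly(np.full(12, 20.0), np.full(12, 20.0), np.full(12, 30.0))
        assert np.allclose(w.tavg, 20.0)

    def test_annual_rain_total_is_conserved(self):
        rng = np.random.default_rng(5)
        rain = rng.uniform(0, 300, 12)
        w = interpolate_weekly(np.zeros(12), np.ones(12), rain)
        assert w.rain.sum() == pytest.approx(rain.sum(), abs=1e-6)

    def test_interpolation_does_not_overshoot(self):
        t = np.tile([0.0, 10.0], 6)
        w = interpolate_weekly(t, t, np.ones(12))
        assert w.tavg.min() >= 0.0 and w.tavg.max() <= 10.0

    def test_missing_month_raises(self):
        with pytest.raises(ValueError):
            interpolate_weekly(np.zeros(11), np.zeros(11), np.zeros(11))
        bad = np.zeros(12)
        bad[3] = np.nan
        with pytest.raises(ValueError, match="missing"):
            interpolate_weekly(bad, bad, np.zeros(12))


class TestGrowthResponses:
    def test_host_optimum_band_scores_one(self):
        assert temperature_index_week(24.0, HOST) == 1.0
        assert moisture_index_week(0.6, HOST) == 1.0

    def test_lower_thresholds_score_zero(self):
        assert temperature_index_week(10.0, HOST) == 0.0  # DV0 boundary
        assert moisture_index_week(0.1, HOST) == 0.0       # SM0 boundary

    def test_linear_ramp_values(self):
        assert temperature_index_week(13.0, HOST) == pytest.approx(0.5)  # (13-10)/(16-10)
        assert moisture_index_week(0.3, HOST) == pytest.approx(0.5)      # (0.3-0.1)/(0.5-0.1)

    def test_matches_piecewise_linear_reference_on_random_draws(self):
        rng = np.random.default_rng(77)
        for _ in range(200):
            a, b, c, d = np.sort(rng.uniform(-10, 45, 4))
            if len({a, b, c, d}) < 4:
                continue
            p = HOST.replace(DV0=a, DV1=b, DV2=c, DV3=d)
            x = rng.uniform(-15, 50, 50)
            ref = np.interp(x, [a, b, c, d], [0.0, 1.0, 1.0, 0.0], left=0.0, right=0.0)
            assert np.allclose(temperature_index_week(x, p), ref, atol=1e-12)

    def test_widening_optimum_never_decreases_gia(self):
        rng = np.random.default_rng(8)
        tavg = rng.uniform(0, 40, WEEKS)
        mi = np.ones(WEEKS)
        narrow = annual_growth_index(temperature_index_week(tavg, HOST), mi)
        wide = annual_growth_index(
            temperature_index_week(tavg, HOST.replace(DV1=14.0, DV2=34.0)), mi
        )
        assert wide >= narrow

    def test_annual_growth_index_examples(self):
        ones = np.ones(WEEKS)
        assert annual_growth_index(ones, ones) == pytest.approx(100.0)
        assert annual_growth_index(ones, np.zeros(WEEKS)) == pytest.approx(0.0)
        half = np.zeros(WEEKS)
        half[:26] = 1.0
        assert annual_growth_index(half, ones) == pytest.approx(50.0)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            annual_growth_index(np.ones(52), np.ones(51))


def _constant_weekly(tavg: float, rain_per_week: float):
    from pestrisk.ecoclim import WeeklyClimate

    t = np.full(WEEKS, tavg)
    return WeeklyClimate(tmin=t, tmax=t, tavg=t, rain=np.full(WEEKS, rain_per_week))


class TestSoilMoisture:
    def test_drought_is_monotone_drying_to_zero(self):
        sm = soil_moisture_series(_constant_weekly(25.0, 0.0))
        assert np.all(np.diff(sm) <= 1e-12)
        assert sm[-1] == pytest.approx(0.0, abs=1e-6)

    def test_deluge_saturates_at_the_upper_clamp(self):
        bucket = BucketConfig()
        sm = soil_moisture_series(_constant_weekly(10.0, 500.0), bucket)
        assert np.allclose(sm, bucket.sm_max)

    def test_constant_forcing_converges_to_interior_fixed_point(self):
        # below field capacity the equilibrium solves rain = et_coeff * tavg * m
        bucket = BucketConfig()
        tavg, rain = 20.0, 25.0
        sm = soil_moisture_series(_constant_weekly(tavg, rain), bucket)
        assert abs(sm[0] - sm[-1]) < 1e-6
        assert sm[-1] == pytest.approx(rain / (bucket.et_coeff * tavg), rel=1e-3)

    def test_nonpositive_capacity_raises(self):
        with pytest.raises(ValueError):
            BucketConfig(capacity_mm=0.0)


class TestStressAccumulation:
    def test_no_exceedance_means_no_stress(self):
        assert accumulate_stress(np.zeros(WEEKS), 0.9) == 0.0

    def test_zero_rate_means_no_stress(self):
        assert accumulate_stress(np.full(WEEKS, 5.0), 0.0) == 0.0

    def test_single_week_exceedance_saturates(self):
        exc = np.zeros(WEEKS)
        exc[30] = 2.0
        # min(100, 100*0.9*2) for a single stress week, identical in both schemes
        assert accumulate_stress(exc, 0.9, "compounding") == 100.0
        assert accumulate_stress(exc, 0.9, "linear") == 100.0

    def test_linear_scheme_value(self):
        exc = np.zeros(WEEKS)
        exc[[4, 9]] = [1.0, 2.0]
        assert accumulate_stress(exc, 0.1, "linear") == pytest.approx(30.0)
        # compounding weights the second stress week twice
        assert accumulate_stress(exc, 0.1, "compounding") == pytest.approx(50.0)

    def test_negative_exceedance_raises(self):
        bad = np.zeros(WEEKS)
        bad[0] = -1.0
        with pytest.raises(ValueError):
            accumulate_stress(bad, 0.5)


class TestIndexAlgebra:
    def test_stress_index_examples(self):
        assert stress_index(0, 0, 0, 0) == 1.0
        assert stress_index(100, 20, 30, 0) == 0.0
        assert stress_index(50, 50, 0, 0) == pytest.approx(0.25)

    def test_stress_index_out_of_range_raises(self):
        with pytest.raises(ValueError):
            stress_index(120, 0, 0, 0)

    def test_ecoclimatic_index_examples(self):
        assert ecoclimatic_index(100.0, 1.0, 0.0) == 100.0
        assert ecoclimatic_index(80.0, 0.0, 0.0) == 0.0
        assert ecoclimatic_index(50.0, 0.5, 0.0) == pytest.approx(25.0)
        assert ecoclimatic_index(50.0, 1.0, 100.0) == 0.0

    def test_increasing_any_stress_never_increases_ei(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            comps = rng.uniform(0, 100, 5)
            gia = rng.uniform(0, 100)
            ei = ecoclimatic_index(gia, stress_index(*comps[:4]), comps[4])
            j = rng.integers(0, 5)
            bumped = comps.copy()
            bumped[j] = min(100.0, bumped[j] + rng.uniform(0, 30))
            ei2 = ecoclimatic_index(gia, stress_index(*bumped[:4]), bumped[4])
            assert ei2 <= ei + 1e-12

    def test_habitat_classification_bounds(self):
        ei = np.array([0.0, 1e-9, 14.9, 15.0, 15.1, 30.0, 30.1, 45.0, 100.0])
        expect = np.array([0, 1, 1, 1, 2, 2, 3, 3, 3])
        assert np.array_equal(classify_ei(ei), expect)


def _uniform_grid(tmin, tmax, rain_month, n=4):
    geom = GridGeometry(0.0, 10.0, 60.0, n, n)
    shape = (12, n, n)
    return ClimateGrid(
        tmin=np.full(shape, tmin), tmax=np.full(shape, tmax),
        rain=np.full(shape, rain_month), geometry=geom,
    )


class TestEngineOnGrids:
    def test_constant_optimal_climate_scores_ei_100(self):
        # tavg 24 in the optimum band; rain tuned to the interior moisture optimum
        grid = _uniform_grid(20.0, 28.0, 130.0)
        res = EcoclimaticIndexEngine(HOST).run_grid(grid)
        assert np.allclose(res.ei, 100.0)
        assert np.all(res.habitat_class == 3)

    def test_arctic_band_is_killed_by_cold_stress(self):
        grid = _uniform_grid(-40.0, -30.0, 50.0)
        res = EcoclimaticIndexEngine(HOST).run_grid(grid)
        assert np.all(res.cold_stress == 100.0)
        assert np.all(res.ei == 0.0)

    def test_geometry_is_preserved(self, coarse_grid, coarse_ei):
        assert coarse_ei.geometry == coarse_grid.geometry
        assert coarse_ei.ei.shape == coarse_grid.geometry.shape

    def test_ei_never_exceeds_gia(self, coarse_ei):
        assert np.all(coarse_ei.ei <= coarse_ei.gia + 1e-9)

    def test_zero_stress_rates_reduce_ei_to_gia(self, coarse_grid):
        calm = HOST.replace(THCS=0.0, THHS=0.0, HDS=0.0, HWS=0.0, PHW=0.0)
        res = EcoclimaticIndexEngine(calm).run_grid(coarse_grid)
        assert np.allclose(res.ei, res.gia)

    def test_archetype_geography(self, coarse_grid, coarse_ei):
        geom = coarse_grid.geometry
        assert np.all(coarse_ei.ei[band_rows(geom, "humid_subtropical")] > 30.0)
        arid = band_rows(geom, "arid")
        assert np.all(coarse_ei.ei[arid] == 0.0)
        assert np.all(coarse_ei.dry_stress[arid] == 100.0)
        polar = band_rows(geom, "polar")
        assert np.all(coarse_ei.ei[polar] == 0.0)
        assert np.all(coarse_ei.cold_stress[polar] == 100.0)

    def test_location_trace_matches_grid_run(self, coarse_grid, coarse_ei):
        row, col = 30, 10
        out = EcoclimaticIndexEngine(HOST).run_location(
            coarse_grid.tmin[:, row, col],
            coarse_grid.tmax[:, row, col],
            coarse_grid.rain[:, row, col],
        )
        assert out["EI"] == pytest.approx(coarse_ei.ei[row, col], abs=1e-9)
        assert len(out["trace"]) == WEEKS
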