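import numpy as np
import pandas as pd
import pytest

from pestrisk.grid import GridGeometry, Raster, cell_area_grid
from pestrisk.overlay import (
    RegionLabels,
    area_by_class,
    difference_raster,
    host_mask,
    longitude_sector_regions,
    mask_extract,
    masked_land_area,
    percent_change,
    suitable_area_totals,
)

GEOM = GridGeometry(0.0, 20.0, 60.0, 20, 30)


def _raster(values):
    return Raster(np.asarray(values, dtype=float), GEOM)


class TestHostMask:
    def test_binary_rule(self):
        ei = np.zeros(GEOM.shape)
        ei[3, 4] = 0.001
        ei[5, 6] = 42.0
        mask = host_mask(_raster(ei))
        assert mask.values[0, 0] == 0.0
        assert mask.values[3, 4] == 1.0  # any positive EI counts as host presence
        assert mask.values[5, 6] == 1.0

    def test_all_zero_ei_gives_all_zero_mask(self):
        assert np.all(host_mask(_raster(np.zeros(GEOM.shape))).values == 0.0)


class TestMaskExtract:
    def test_identity_under_all_ones_mask(self):
        rng = np.random.default_rng(0)
        suit = _raster(rng.uniform(0, 1, GEOM.shape))
        out = mask_extract(suit, _raster(np.ones(GEOM.shape)))
        assert np.array_equal(out.values, suit.values)

    def test_all_zeros_mask_gives_all_nodata(self):
        suit = _raster(np.random.default_rng(1).uniform(0, 1, GEOM.shape))
        out = mask_extract(suit, _raster(np.zeros(GEOM.shape)))
        assert np.isnan(out.values).all()

    def test_masked_cell_count(self):
        mask_vals = (np.random.default_rng(2).uniform(0, 1, GEOM.shape) > 0.5).astype(float)
        out = mask_extract(_raster(np.ones(GEOM.shape)), _raster(mask_vals))
        assert (~np.isnan(out.values)).sum() == int(mask_vals.sum())

    def test_geometry_mismatch_raises(self):
        other = GridGeometry(0.0, 20.0, 60.0, 10, 30)
        with pytest.raises(ValueError, match="geometries differ"):
            mask_extract(_raster(np.ones(GEOM.shape)), Raster(np.ones((10, 30)), other))


class TestDifferenceRaster:
    def test_equal_scenarios_give_zero_change(self):
        a = _raster(np.random.default_rng(3).uniform(0, 1, GEOM.shape))
        assert np.allclose(difference_raster(a, a).values, 0.0)

    def test_antisymmetry(self):
        rng = np.random.default_rng(4)
        a, b = _raster(rng.uniform(0, 1, GEOM.shape)), _raster(rng.uniform(0, 1, GEOM.shape))
        assert np.allclose(difference_raster(a, b).values, -difference_raster(b, a).values)

    def test_forced_arithmetic_and_nodata_propagation(self):
        cur = np.full(GEOM.shape, 0.2)
        fut = np.full(GEOM.shape, 0.7)
        cur[0, 0] = np.nan
        diff = difference_raster(_raster(fut), _raster(cur))
        assert diff.values[1, 1] == pytest.approx(0.5)
        assert np.isnan(diff.values[0, 0])


class TestAreaAccounting:
    def test_single_region_single_class_conserves_total(self):
        regions = RegionLabels(np.zeros(GEOM.shape, dtype=int), GEOM, {0: "world"})
        table = area_by_class(_raster(np.zeros(GEOM.shape)), regions, ("only",))
        assert table["area_1e4_km2"].sum() == pytest.approx(
            cell_area_grid(GEOM).sum() / 1e4, rel=1e-12
        )

    def test_region_split_is_additive(self):
        classes = _raster((np.random.default_rng(5).uniform(0, 1, GEOM.shape) > 0.5).astype(float))
        one = RegionLabels(np.zeros(GEOM.shape, dtype=int), GEOM)
        two = longitude_sector_regions(GEOM, 2)
        labels = ("low", "high")
        t1 = area_by_class(classes, one, labels)
        t2 = area_by_class(classes, two, labels)
        for ci in (0, 1):
            total_one = t1.loc[t1["class_index"] == ci, "area_1e4_km2"].sum()
            total_two = t2.loc[t2["class_index"] == ci, "area_1e4_km2"].sum()
            assert total_two == pytest.approx(total_one, rel=1e-9)

    def test_empty_class_rows_are_present_with_zero(self):
        regions = RegionLabels(np.zeros(GEOM.shape, dtype=int), GEOM)
        table = area_by_class(_raster(np.zeros(GEOM.shape)), regions, ("a", "b", "c"))
        assert len(table) == 3
        assert table.loc[table["class"] == "c", "area_1e4_km2"].iloc[0] == 0.0

    def test_class_areas_sum_to_masked_land_area(self):
        rng = np.random.default_rng(6)
        codes = rng.integers(0, 3, GEOM.shape).astype(float)
        codes[rng.uniform(0, 1, GEOM.shape) < 0.2] = np.nan  # no-data holes
        raster = _raster(codes)
        regions = longitude_sector_regions(GEOM, 3)
        table = area_by_class(raster, regions, ("a", "b", "c"))
        land = masked_land_area(raster, regions)
        merged = table.groupby("region")["area_1e4_km2"].sum()
        for _, row in land.iterrows():
            assert merged[row["region"]] == pytest.approx(row["area_1e4_km2"], rel=1e-6)

    def test_change_sign_areas_partition_land(self):
        rng = np.random.default_rng(7)
        cur = _raster(rng.uniform(0, 1, GEOM.shape))
        fut = _raster(rng.uniform(0, 1, GEOM.shape))
        diff = difference_raster(fut, cur).values
        areas = cell_area_grid(GEOM)
        pos = areas[diff > 0].sum()
        neg = areas[diff < 0].sum()
        zero = areas[diff == 0].sum()
        assert pos + neg + zero == pytest.approx(areas.sum(), rel=1e-12)


class TestPercentChange:
    def test_equal_totals_give_zero(self):
        assert percent_change(10.0, 10.0) == 0.0

    def test_total_loss_gives_100(self):
        assert percent_change(10.0, 0.0) == 100.0

    def test_expansion_is_negative(self):
        assert percent_change(10.0, 12.0) == pytest.approx(-20.0)

    def test_nonpositive_current_raises(self):
        with pytest.raises(ValueError):
            percent_change(0.0, 5.0)


def test_suitable_area_totals_class_threshold():
    table = pd.DataFrame(
        {
            "region": ["r"] * 6,
            "class_index": [0, 1, 2] * 2,
            "class": ["unsuitable", "very_low", "low"] * 2,
            "scenario": ["current"] * 3 + ["future"] * 3,
            "area_1e4_km2": [5.0, 3.0, 2.0, 4.0, 2.0, 1.0],
        }
    )
    incl = suitable_area_totals(table, min_class_index=1)
    assert incl.loc[incl["scenario"] == "current", "area_1e4_km2"].iloc[0] == 5.0
    excl = suitable_area_totals(table, min_class_index=2)
    assert excl.loc[excl["scenario"] == "future", "area_1e4_km2"].iloc[0] == 1.0
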