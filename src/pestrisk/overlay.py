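"""Host-mask overlay, change rasters, and latitude-corrected area accounting.

The host-constrained pest map keeps pest suitability only where the host's
ecoclimatic index is positive. Areas are true spherical cell areas summed per
region and suitability class, reported in 10^4 km^2 to match the scale on
which headline habitat totals are usually printed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import GridGeometry, Raster, cell_area_grid

AREA_UNIT_KM2 = 1e4  # tables are in units of 10^4 km^2


def host_mask(ei_raster: Raster) -> Raster:
    """Binary host-presence raster: 1 where EI > 0, 0 where EI = 0."""
    vals = ei_raster.values
    mask = np.where(np.isnan(vals), np.nan, (vals > 0).astype(float))
    return Raster(mask, ei_raster.geometry, meta={"layer": "host_mask"})


def mask_extract(suitability: Raster, mask: Raster) -> Raster:
    """Keep suitability where mask = 1; everything else becomes no-data."""
    if suitability.geometry != mask.geometry:
        raise ValueError("suitability and mask geometries differ")
    vals = np.where(mask.values == 1.0, suitability.values, np.nan)
    return Raster(vals, suitability.geometry, meta={**suitability.meta, "masked": True})


def difference_raster(future: Raster, current: Raster) -> Raster:
    """Per-cell future minus current; no-data where either input is no-data."""
    if future.geometry != current.geometry:
        raise ValueError("future and current geometries differ")
    return Raster(
        future.values - current.values,
        future.geometry,
        meta={"layer": "suitability_change", "sign": "future_minus_current"},
    )


@dataclass
class RegionLabels:
    """Per-cell region ids with a land mask; id -1 marks sea/off-region."""

    ids: np.ndarray
    geometry: GridGeometry
    names: dict = field(default_factory=dict)  # id -> region name

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=int)
        if self.ids.shape != self.geometry.shape:
            raise ValueError("region ids shape does not match geometry")
        present = set(np.unique(self.ids[self.ids >= 0]).tolist())
        unnamed = present - set(self.names)
        if unnamed:
            self.names = {**{i: f"region_{i}" for i in unnamed}, **self.names}

    @property
    def land(self) -> np.ndarray:
        return self.ids >= 0


def longitude_sector_regions(geometry: GridGeometry, n_sectors: int = 6) -> RegionLabels:
    """Synthetic continent-like partition: equal longitude sectors, all land."""
    lon = geometry.lon_centers()
    edges = np.linspace(geometry.lon_min, geometry.lon_max, n_sectors + 1)
    sector = np.clip(np.searchsorted(edges, lon, side="right") - 1, 0, n_sectors - 1)
    ids = np.repeat(sector[None, :], geometry.n_rows, axis=0)
    names = {i: f"sector_{i}" for i in range(n_sectors)}
    return RegionLabels(ids=ids, geometry=geometry, names=names)


def area_by_class(
    class_raster: Raster,
    regions: RegionLabels,
    class_labels: tuple,
    scenario: str = "current",
) -> pd.DataFrame:
    """Area table: one row per (region, class), in 10^4 km^2.

    No-data cells are excluded; every (region, class) combination appears,
    including empty ones, so totals are directly comparable across scenarios.
    """
    if class_raster.geometry != regions.geometry:
        raise ValueError("class raster and region geometries differ")
    areas = cell_area_grid(class_raster.geometry)
    codes = class_raster.values
    valid = regions.land & ~np.isnan(codes)
    rows = []
    for rid, rname in sorted(regions.names.items()):
        in_region = valid & (regions.ids == rid)
        for ci, cname in enumerate(class_labels):
            total = areas[in_region & (codes == ci)].sum()
            rows.append(
                {
                    "region": rname,
                    "class_index": ci,
                    "class": cname,
                    "scenario": scenario,
                    "area_1e4_km2": total / AREA_UNIT_KM2,
                }
            )
    return pd.DataFrame(rows)


def masked_land_area(class_raster: Raster, regions: RegionLabels) -> pd.DataFrame:
    """Per-region land area covered by valid (non-nodata) class cells, 10^4 km^2."""
    areas = cell_area_grid(class_raster.geometry)
    valid = regions.land & ~np.isnan(class_raster.values)
    rows = [
        {"region": rname, "area_1e4_km2": areas[valid & (regions.ids == rid)].sum() / AREA_UNIT_KM2}
        for rid, rname in sorted(regions.names.items())
    ]
    return pd.DataFrame(rows)


def suitable_area_totals(
    area_table: pd.DataFrame, min_class_index: int = 1
) -> pd.DataFrame:
    """Total suitable area per scenario, counting classes >= ``min_class_index``.

    With five Jenks classes, ``min_class_index=1`` counts everything above
    'unsuitable' (very low included) and 2 excludes the lowest suitable class.
    """
    sel = area_table[area_table["class_index"] >= min_class_index]
    return sel.groupby("scenario", as_index=False)["area_1e4_km2"].sum()


def percent_change(current_total: float, future_total: float) -> float:
    """Percent reduction from current to future (negative = expansion)."""
    if current_total <= 0:
        raise ValueError("current total must be positive")
    return 100.0 * (current_total - future_total) / current_total
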