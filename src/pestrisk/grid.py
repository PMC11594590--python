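"""Geographic grid geometry, in-memory rasters, and plain-text raster I/O.

All grids are cell-centered WGS84 geographic grids with row 0 at the northern
edge. Rasters are read and written as ESRI ASCII grids (``.asc``), a plain-text
interchange format understood by every desktop GIS.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

EARTH_RADIUS_KM = 6371.0


@dataclass(frozen=True)
class GridGeometry:
    """Regular geographic grid.

    Parameters
    ----------
    lon_min, lat_max : float
        Western and northern *edges* of the grid, degrees.
    res_arcmin : float
        Cell size in arcminutes (square cells).
    n_rows, n_cols : int
        Grid shape; row 0 is the northernmost row.
    """

    lon_min: float
    lat_max: float
    res_arcmin: float
    n_rows: int
    n_cols: int

    def __post_init__(self) -> None:
        if self.res_arcmin <= 0:
            raise ValueError(f"resolution must be positive, got {self.res_arcmin}")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")
        if not (-180.0 <= self.lon_min <= 180.0) or not (-90.0 <= self.lat_max <= 90.0):
            raise ValueError("grid origin outside geographic bounds")
        if self.lat_max - self.n_rows * self.res_deg < -90.0 - 1e-9:
            raise ValueError("grid extends south of -90 degrees")

    @property
    def res_deg(self) -> float:
        return self.res_arcmin / 60.0

    @property
    def lon_max(self) -> float:
        return self.lon_min + self.n_cols * self.res_deg

    @property
    def lat_min(self) -> float:
        return self.lat_max - self.n_rows * self.res_deg

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    def lat_centers(self) -> np.ndarray:
        """Latitudes of row centers, north to south, shape (n_rows,)."""
        return self.lat_max - (np.arange(self.n_rows) + 0.5) * self.res_deg

    def lon_centers(self) -> np.ndarray:
        return self.lon_min + (np.arange(self.n_cols) + 0.5) * self.res_deg

    def cell_of(self, lon: np.ndarray, lat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Row/col indices of the cells containing the given points."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.lon_min) / self.res_deg).astype(int)
        row = np.floor((self.lat_max - lat) / self.res_deg).astype(int)
        # points exactly on the east/south edge belong to the last cell
        col = np.clip(col, 0, self.n_cols - 1)
        row = np.clip(row, 0, self.n_rows - 1)
        inside = (
            (lon >= self.lon_min - 1e-9)
            & (lon <= self.lon_max + 1e-9)
            & (lat >= self.lat_min - 1e-9)
            & (lat <= self.lat_max + 1e-9)
        )
        if not np.all(inside):
            raise ValueError("point(s) outside grid extent")
        return row, col

    def to_dict(self) -> dict:
        return {
            "lon_min": self.lon_min,
            "lat_max": self.lat_max,
            "res_arcmin": self.res_arcmin,
            "n_rows": self.n_rows,
            "n_cols": self.n_cols,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GridGeometry":
        return cls(**d)


def cell_area_km2(lat_center: np.ndarray, res_arcmin: float) -> np.ndarray:
    """Area of a geographic cell centred at ``lat_center``.

    Spherical band formula R^2 * dlon * (sin(lat_top) - sin(lat_bottom)) with
    R = 6371 km, exact on the sphere.
    """
    lat = np.asarray(lat_center, dtype=float)
    if np.any(np.abs(lat) > 90.0):
        raise ValueError("latitude outside [-90, 90]")
    half = res_arcmin / 60.0 / 2.0
    top = np.clip(lat + half, -90.0, 90.0)
    bot = np.clip(lat - half, -90.0, 90.0)
    dlon = math.radians(res_arcmin / 60.0)
    return EARTH_RADIUS_KM**2 * dlon * (np.sin(np.radians(top)) - np.sin(np.radians(bot)))


def cell_area_grid(geometry: GridGeometry) -> np.ndarray:
    """Per-cell areas (km^2) for a grid, shape (n_rows, n_cols)."""
    row_areas = cell_area_km2(geometry.lat_centers(), geometry.res_arcmin)
    return np.repeat(row_areas[:, None], geometry.n_cols, axis=1)


@dataclass
class Raster:
    """A single georeferenced field. ``np.nan`` marks no-data cells."""

    values: np.ndarray
    geometry: GridGeometry
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.geometry.shape:
            raise ValueError(
                f"raster shape {self.values.shape} does not match geometry {self.geometry.shape}"
            )

    @property
    def nodata_count(self) -> int:
        return int(np.isnan(self.values).sum())

    def same_geometry(self, other: "Raster") -> bool:
        return self.geometry == other.geometry


NODATA = -9999.0


def write_ascii_grid(raster: Raster, path: str | Path) -> None:
    """Write a raster as an ESRI ASCII grid with a JSON metadata sidecar."""
    path = Path(path)
    g = raster.geometry
    header = (
        f"ncols {g.n_cols}\n"
        f"nrows {g.n_rows}\n"
        f"xllcorner {g.lon_min:.10f}\n"
        f"yllcorner {g.lat_min:.10f}\n"
        f"cellsize {g.res_deg:.10f}\n"
        f"NODATA_value {NODATA}\n"
    )
    vals = np.where(np.isnan(raster.values), NODATA, raster.values)
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt="%.6g")
    if raster.meta:
        Path(str(path) + ".json").write_text(json.dumps(raster.meta, indent=2))


def read_ascii_grid(path: str | Path) -> Raster:
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh, ndmin=2)
    n_rows = int(header["nrows"])
    n_cols = int(header["ncols"])
    res_deg = header["cellsize"]
    geometry = GridGeometry(
        lon_min=header["xllcorner"],
        lat_max=header["yllcorner"] + n_rows * res_deg,
        res_arcmin=res_deg * 60.0,
        n_rows=n_rows,
        n_cols=n_cols,
    )
    nodata = header.get("nodata_value", NODATA)
    values = np.where(values == nodata, np.nan, values)
    meta_path = Path(str(path) + ".json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return Raster(values=values, geometry=geometry, meta=meta)


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km between points given in degrees."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float)) for x in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))
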