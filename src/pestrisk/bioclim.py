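"""Standard bioclimatic predictors (bio1..bio19) from monthly climate.

Definitions follow the common WorldClim dialect: quarters are the best of the
12 wrapping 3-consecutive-month windows, temperature seasonality (bio4) is
100 times the standard deviation of monthly means, and precipitation
seasonality (bio15) is the coefficient of variation of monthly totals with
1 mm added to the mean to keep arid cells finite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .climate import ClimateGrid, MONTHS
from .grid import GridGeometry, Raster, read_ascii_grid, write_ascii_grid

BIOCLIM_NAMES = tuple(f"bio{i}" for i in range(1, 20))

BIOCLIM_DESCRIPTIONS = {
    "bio1": "annual mean temperature",
    "bio2": "mean diurnal range",
    "bio3": "isothermality (bio2/bio7 * 100)",
    "bio4": "temperature seasonality (std * 100)",
    "bio5": "max temperature of warmest month",
    "bio6": "min temperature of coldest month",
    "bio7": "temperature annual range",
    "bio8": "mean temperature of wettest quarter",
    "bio9": "mean temperature of driest quarter",
    "bio10": "mean temperature of warmest quarter",
    "bio11": "mean temperature of coldest quarter",
    "bio12": "annual precipitation",
    "bio13": "precipitation of wettest month",
    "bio14": "precipitation of driest month",
    "bio15": "precipitation seasonality (cv)",
    "bio16": "precipitation of wettest quarter",
    "bio17": "precipitation of driest quarter",
    "bio18": "precipitation of warmest quarter",
    "bio19": "precipitation of coldest quarter",
}


@dataclass
class BioclimStack:
    """The 19 bioclim layers on one grid geometry, shaped (19, rows, cols)."""

    values: np.ndarray
    geometry: GridGeometry
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(BIOCLIM_NAMES),) + self.geometry.shape:
            raise ValueError("bioclim stack must be (19, n_rows, n_cols)")

    def layer(self, name: str) -> np.ndarray:
        return self.values[BIOCLIM_NAMES.index(name)]

    def raster(self, name: str) -> Raster:
        return Raster(self.layer(name), self.geometry, meta={"layer": name})

    def sample_points(self, lon: np.ndarray, lat: np.ndarray) -> pd.DataFrame:
        """Feature table of the 19 variables at point locations (cell lookup)."""
        row, col = self.geometry.cell_of(lon, lat)
        data = {name: self.values[i, row, col] for i, name in enumerate(BIOCLIM_NAMES)}
        return pd.DataFrame(data)

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for i, name in enumerate(BIOCLIM_NAMES):
            write_ascii_grid(Raster(self.values[i], self.geometry), directory / f"{name}.asc")
        (directory / "bioclim.json").write_text(
            json.dumps({"geometry": self.geometry.to_dict(), "meta": self.meta}, indent=2)
        )

    @classmethod
    def load(cls, directory: str | Path) -> "BioclimStack":
        directory = Path(directory)
        manifest = json.loads((directory / "bioclim.json").read_text())
        geometry = GridGeometry.from_dict(manifest["geometry"])
        values = np.stack(
            [read_ascii_grid(directory / f"{name}.asc").values for name in BIOCLIM_NAMES]
        )
        return cls(values=values, geometry=geometry, meta=manifest.get("meta", {}))


def _quarter_windows(arr: np.ndarray) -> np.ndarray:
    """(12, ...) -> (12, ...) sums over wrapping 3-month windows starting at each month."""
    return arr + np.roll(arr, -1, axis=0) + np.roll(arr, -2, axis=0)


def derive_bioclim(grid: ClimateGrid) -> BioclimStack:
    """Compute bio1..bio19 from a monthly climate grid."""
    tmin, tmax, rain = grid.tmin, grid.tmax, grid.rain
    if any(np.any(np.isnan(a)) for a in (tmin, tmax, rain)):
        raise ValueError("climate grid contains missing months/cells")
    tavg = grid.tavg

    q_rain = _quarter_windows(rain)                 # quarter precip totals
    q_temp = _quarter_windows(tavg) / 3.0           # quarter mean temps
    wettest_q = np.argmax(q_rain, axis=0)
    driest_q = np.argmin(q_rain, axis=0)
    warmest_q = np.argmax(q_temp, axis=0)
    coldest_q = np.argmin(q_temp, axis=0)

    def take(stack: np.ndarray, idx: np.ndarray) -> np.ndarray:
        return np.take_along_axis(stack, idx[None, ...], axis=0)[0]

    bio = {}
    bio["bio1"] = tavg.mean(axis=0)
    bio["bio2"] = (tmax - tmin).mean(axis=0)
    bio["bio4"] = tavg.std(axis=0, ddof=1) * 100.0
    bio["bio5"] = tmax.max(axis=0)
    bio["bio6"] = tmin.min(axis=0)
    bio["bio7"] = bio["bio5"] - bio["bio6"]
    with np.errstate(divide="ignore", invalid="ignore"):
        bio["bio3"] = np.where(bio["bio7"] > 0, bio["bio2"] / bio["bio7"] * 100.0, 0.0)
    bio["bio8"] = take(q_temp, wettest_q)
    bio["bio9"] = take(q_temp, driest_q)
    bio["bio10"] = take(q_temp, warmest_q)
    bio["bio11"] = take(q_temp, coldest_q)
    bio["bio12"] = rain.sum(axis=0)
    bio["bio13"] = rain.max(axis=0)
    bio["bio14"] = rain.min(axis=0)
    bio["bio15"] = rain.std(axis=0, ddof=1) / (1.0 + bio["bio12"] / MONTHS) * 100.0
    bio["bio16"] = take(q_rain, wettest_q)
    bio["bio17"] = take(q_rain, driest_q)
    bio["bio18"] = take(q_rain, warmest_q)
    bio["bio19"] = take(q_rain, coldest_q)

    values = np.stack([bio[name] for name in BIOCLIM_NAMES])
    return BioclimStack(values=values, geometry=grid.geometry, meta={"scenario": grid.scenario})
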