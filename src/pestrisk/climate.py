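"""Monthly climate grids: the canonical input of both niche models."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .grid import GridGeometry, Raster, read_ascii_grid, write_ascii_grid

MONTHS = 12
CORE_VARIABLES = ("tmin", "tmax", "rain")
HUMIDITY_VARIABLES = ("rh09", "rh15")


@dataclass
class ClimateGrid:
    """Monthly climatology for one scenario on a geographic grid.

    Arrays are shaped (12, n_rows, n_cols). ``tmin``/``tmax`` are monthly mean
    daily extremes (deg C), ``rain`` monthly precipitation (mm). Relative
    humidity at 09:00 / 15:00 (%) is carried for completeness but not consumed
    by the default moisture model.
    """

    tmin: np.ndarray
    tmax: np.ndarray
    rain: np.ndarray
    geometry: GridGeometry
    scenario: str = "current"
    rh09: np.ndarray | None = None
    rh15: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in CORE_VARIABLES:
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            expected = (MONTHS,) + self.geometry.shape
            if arr.shape != expected:
                raise ValueError(f"{name} has shape {arr.shape}, expected {expected}")
        for name in HUMIDITY_VARIABLES:
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                setattr(self, name, arr)
                if arr.shape != (MONTHS,) + self.geometry.shape:
                    raise ValueError(f"{name} has wrong shape {arr.shape}")
        self.validate()

    def validate(self) -> None:
        if np.any(self.tmin > self.tmax + 1e-9):
            raise ValueError("tmin exceeds tmax somewhere")
        if np.any(self.rain < 0):
            raise ValueError("negative precipitation")
        for name in HUMIDITY_VARIABLES:
            arr = getattr(self, name)
            if arr is not None and (np.any(arr < 0) or np.any(arr > 100)):
                raise ValueError(f"{name} outside [0, 100]")

    @property
    def tavg(self) -> np.ndarray:
        return (self.tmin + self.tmax) / 2.0

    def variables(self) -> dict[str, np.ndarray]:
        out = {name: getattr(self, name) for name in CORE_VARIABLES}
        for name in HUMIDITY_VARIABLES:
            if getattr(self, name) is not None:
                out[name] = getattr(self, name)
        return out

    def save(self, directory: str | Path) -> None:
        """Write one ASCII grid per variable and month, plus a JSON manifest."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, arr in self.variables().items():
            for m in range(MONTHS):
                write_ascii_grid(
                    Raster(arr[m], self.geometry),
                    directory / f"{name}_{m + 1:02d}.asc",
                )
        manifest = {
            "scenario": self.scenario,
            "geometry": self.geometry.to_dict(),
            "variables": list(self.variables()),
            "meta": self.meta,
        }
        (directory / "climate.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "ClimateGrid":
        directory = Path(directory)
        manifest = json.loads((directory / "climate.json").read_text())
        geometry = GridGeometry.from_dict(manifest["geometry"])
        arrays: dict[str, np.ndarray] = {}
        for name in manifest["variables"]:
            stack = [
                read_ascii_grid(directory / f"{name}_{m + 1:02d}.asc").values
                for m in range(MONTHS)
            ]
            arrays[name] = np.stack(stack)
        return cls(
            geometry=geometry,
            scenario=manifest["scenario"],
            meta=manifest.get("meta", {}),
            **arrays,
        )
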