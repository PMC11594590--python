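"""Occurrence records: spatial rarefaction and pseudo-absence sampling.

Occurrence sets are plain DataFrames with columns ``lon``, ``lat``, ``label``
(presence | pseudo_absence) and ``source``, read and written as CSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .grid import GridGeometry, haversine_km

COLUMNS = ("lon", "lat", "label", "source")


def make_occurrence_set(
    lon, lat, label: str = "presence", source: str = "unknown"
) -> pd.DataFrame:
    df = pd.DataFrame({"lon": lon, "lat": lat})
    df["label"] = label
    df["source"] = source
    validate_occurrences(df)
    return df


def validate_occurrences(df: pd.DataFrame) -> None:
    missing = [c for c in ("lon", "lat") if c not in df.columns]
    if missing:
        raise ValueError(f"occurrence table missing columns: {missing}")
    if np.any(np.abs(df["lat"].to_numpy()) > 90) or np.any(np.abs(df["lon"].to_numpy()) > 180):
        raise ValueError("occurrence coordinates outside geographic bounds")


def read_occurrences(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "label" not in df.columns:
        df["label"] = "presence"
    if "source" not in df.columns:
        df["source"] = Path(path).name
    validate_occurrences(df)
    return df[list(COLUMNS)]


def write_occurrences(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def rarefy_occurrences(df: pd.DataFrame, buffer_km: float = 10.0) -> pd.DataFrame:
    """Greedy spatial thinning in input order.

    A point is kept iff it lies at least ``buffer_km`` (great-circle) from
    every already-kept point, so the result is deterministic and idempotent.
    Duplicate coordinates are removed by construction.
    """
    if buffer_km <= 0:
        raise ValueError("buffer radius must be positive")
    validate_occurrences(df)
    lon = df["lon"].to_numpy(dtype=float)
    lat = df["lat"].to_numpy(dtype=float)
    kept: list[int] = []
    for i in range(len(df)):
        if not kept:
            kept.append(i)
            continue
        d = haversine_km(lon[kept], lat[kept], lon[i], lat[i])
        if np.all(d >= buffer_km):
            kept.append(i)
    return df.iloc[kept].reset_index(drop=True)


def generate_pseudo_absences(
    geometry: GridGeometry,
    n: int,
    presences: pd.DataFrame | None,
    exclusion_km: float = 10.0,
    seed: int = 0,
    land_mask: np.ndarray | None = None,
    max_attempts: int = 10_000,
) -> pd.DataFrame:
    """Uniform-random background points at least ``exclusion_km`` from presences.

    Cells are drawn uniformly from land cells (all cells if no mask is given)
    and jittered within the cell; draws closer than the exclusion radius to
    any presence are rejected. Raises if the eligible area is too small to
    yield ``n`` points within ``max_attempts`` draws.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if exclusion_km < 0:
        raise ValueError("exclusion radius must be non-negative")
    if land_mask is not None and land_mask.shape != geometry.shape:
        raise ValueError("land mask shape does not match geometry")
    rng = np.random.default_rng(seed)
    if land_mask is None:
        eligible = np.arange(geometry.n_cells)
    else:
        eligible = np.flatnonzero(land_mask.ravel())
        if eligible.size == 0:
            raise ValueError("land mask has no land cells")
    p_lon = p_lat = None
    if presences is not None and len(presences) > 0:
        p_lon = presences["lon"].to_numpy(dtype=float)
        p_lat = presences["lat"].to_numpy(dtype=float)

    out_lon: list[float] = []
    out_lat: list[float] = []
    attempts = 0
    while len(out_lon) < n:
        batch = min(max(n - len(out_lon), 64), max_attempts - attempts)
        if batch <= 0:
            raise ValueError(
                f"could not place {n} pseudo-absences within {max_attempts} attempts; "
                "eligible area too small for the exclusion radius"
            )
        attempts += batch
        idx = eligible[rng.integers(0, eligible.size, size=batch)]
        rows, cols = np.unravel_index(idx, geometry.shape)
        lon = geometry.lon_min + (cols + rng.uniform(0, 1, size=batch)) * geometry.res_deg
        lat = geometry.lat_max - (rows + rng.uniform(0, 1, size=batch)) * geometry.res_deg
        if p_lon is not None and exclusion_km > 0:
            d = haversine_km(
                lon[:, None], lat[:, None], p_lon[None, :], p_lat[None, :]
            ).min(axis=1)
            ok = d >= exclusion_km
            lon, lat = lon[ok], lat[ok]
        take = min(n - len(out_lon), lon.size)
        out_lon.extend(lon[:take])
        out_lat.extend(lat[:take])
    return make_occurrence_set(out_lon, out_lat, label="pseudo_absence", source="background")
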