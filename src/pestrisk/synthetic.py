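"""Synthetic climate scenarios and occurrence samples.

The generator emulates the statistical structure the downstream analysis
assumes: a geographic grid with a linear latitudinal temperature lapse and a
sinusoidal seasonal cycle (phase inverted between hemispheres), latitude-band
precipitation regimes (tropical-wet, arid, humid-subtropical, temperate,
polar), a future scenario expressed as uniform warming plus per-band
precipitation scaling, and presence points sampled proportionally to a known
suitability surface. Everything is a pure function of its spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .climate import ClimateGrid, MONTHS
from .grid import GridGeometry, Raster


@dataclass(frozen=True)
class TemperatureParams:
    """Latitude/season temperature model.

    Monthly mean temperature at latitude phi and month m is
    ``equatorial_mean - lapse*|phi| + seasonal_amplitude*(phi/90)*cos(2*pi*(m-6)/12)``
    so the seasonal swing grows linearly toward the poles and is six months
    out of phase across the equator. ``diurnal_range`` separates tmax and tmin
    symmetrically about the mean.
    """

    equatorial_mean: float = 27.0   # deg C, annual mean at the equator
    lapse: float = 0.6              # deg C per degree latitude
    seasonal_amplitude: float = 24.0  # deg C at the poles
    diurnal_range: float = 8.0      # deg C


@dataclass(frozen=True)
class PrecipRegime:
    """One latitude band's precipitation climate (signed latitudes)."""

    lat_min: float
    lat_max: float
    annual_mm: float
    pattern: str = "uniform"  # uniform | summer-wet | winter-wet | arid
    name: str = ""

    def __post_init__(self) -> None:
        if self.lat_min >= self.lat_max:
            raise ValueError("regime band must have lat_min < lat_max")
        if self.annual_mm < 0:
            raise ValueError("annual precipitation must be non-negative")
        if self.pattern not in ("uniform", "summer-wet", "winter-wet", "arid"):
            raise ValueError(f"unknown precipitation pattern {self.pattern!r}")


@dataclass(frozen=True)
class FutureDelta:
    """Scenario perturbation: uniform warming + per-band rain scaling."""

    warming: float = 0.0
    band_factors: tuple = ()  # tuples (lat_min, lat_max, factor); 1.0 elsewhere

    def __post_init__(self) -> None:
        for lo, hi, f in self.band_factors:
            if f < 0:
                raise ValueError("precipitation scaling factor must be non-negative")
            if lo >= hi:
                raise ValueError("delta band must have lat_min < lat_max")

    def factor_for(self, lat: np.ndarray) -> np.ndarray:
        out = np.ones_like(np.asarray(lat, dtype=float))
        for lo, hi, f in self.band_factors:
            out = np.where((lat >= lo) & (lat < hi), f, out)
        return out


@dataclass(frozen=True)
class ScenarioSpec:
    """Complete recipe for one synthetic world."""

    extent: tuple = (-180.0, 180.0, -90.0, 90.0)  # lon_min, lon_max, lat_min, lat_max
    resolution_arcmin: float = 60.0
    temperature: TemperatureParams = TemperatureParams()
    regimes: tuple = ()
    future: FutureDelta = FutureDelta()
    seed: int = 0
    temp_noise_sd: float = 0.0     # deg C, per-cell annual-mean offset
    precip_noise_cv: float = 0.0   # lognormal cv, per cell and month

    def __post_init__(self) -> None:
        lon_min, lon_max, lat_min, lat_max = self.extent
        if not (-180.0 <= lon_min < lon_max <= 180.0):
            raise ValueError("invalid longitude extent")
        if not (-90.0 <= lat_min < lat_max <= 90.0):
            raise ValueError("invalid latitude extent")
        if self.resolution_arcmin <= 0:
            raise ValueError("resolution must be positive")
        if self.temp_noise_sd < 0 or self.precip_noise_cv < 0:
            raise ValueError("noise levels must be non-negative")

    def geometry(self) -> GridGeometry:
        lon_min, lon_max, lat_min, lat_max = self.extent
        res = self.resolution_arcmin / 60.0
        return GridGeometry(
            lon_min=lon_min,
            lat_max=lat_max,
            res_arcmin=self.resolution_arcmin,
            n_rows=int(round((lat_max - lat_min) / res)),
            n_cols=int(round((lon_max - lon_min) / res)),
        )


def _monthly_fractions(pattern: str, lat: np.ndarray) -> np.ndarray:
    """(12, n) monthly share of annual rain; summer/winter phased per hemisphere."""
    m = np.arange(MONTHS)
    harmonic = np.cos(2 * np.pi * (m - 6) / MONTHS)  # +1 in northern summer
    if pattern in ("uniform", "arid"):
        return np.full((MONTHS, lat.size), 1.0 / MONTHS)
    sign = np.where(lat >= 0, 1.0, -1.0)
    amp = 0.8 if pattern == "summer-wet" else -0.8
    frac = 1.0 + amp * harmonic[:, None] * sign[None, :]
    return frac / frac.sum(axis=0, keepdims=True)


def generate_climate_grid(spec: ScenarioSpec, scenario: str = "current") -> ClimateGrid:
    """Build the monthly climate grid for a scenario spec.

    ``scenario="future"`` applies the spec's :class:`FutureDelta` to the
    current fields (identical noise realisation, so the pair is paired).
    """
    if scenario not in ("current", "future"):
        raise ValueError(f"scenario must be 'current' or 'future', got {scenario!r}")
    geom = spec.geometry()
    lat = geom.lat_centers()
    t = spec.temperature
    m = np.arange(MONTHS)
    seasonal = (
        t.seasonal_amplitude
        * (lat[None, :] / 90.0)
        * np.cos(2 * np.pi * (m[:, None] - 6) / MONTHS)
    )  # (12, n_rows)
    mean_t = t.equatorial_mean - t.lapse * np.abs(lat)  # (n_rows,)
    tavg = (mean_t[None, :] + seasonal)[:, :, None] * np.ones((1, 1, geom.n_cols))

    rng = np.random.default_rng(spec.seed)
    if spec.temp_noise_sd > 0:
        tavg = tavg + rng.normal(0.0, spec.temp_noise_sd, size=geom.shape)[None, :, :]
    tmin = tavg - t.diurnal_range / 2.0
    tmax = tavg + t.diurnal_range / 2.0

    rain = np.zeros((MONTHS,) + geom.shape)
    covered = np.zeros(geom.n_rows, dtype=bool)
    for regime in spec.regimes:
        rows = (lat >= regime.lat_min) & (lat < regime.lat_max) & ~covered
        if not rows.any():
            continue
        covered |= rows
        frac = _monthly_fractions(regime.pattern, lat[rows])  # (12, n_sel)
        rain[:, rows, :] = (regime.annual_mm * frac)[:, :, None]
    if not covered.all():
        missing = lat[~covered]
        raise ValueError(
            f"precipitation regimes do not cover latitudes {missing.min():.2f}..{missing.max():.2f}"
        )
    if spec.precip_noise_cv > 0:
        sigma = np.sqrt(np.log1p(spec.precip_noise_cv**2))
        noise = rng.lognormal(-sigma**2 / 2.0, sigma, size=(MONTHS,) + geom.shape)
        rain = rain * noise

    # simple humidity fields consistent with the wetness of each cell
    wet = np.clip(rain.sum(axis=0) / 1500.0, 0.0, 1.0)
    rh09 = np.broadcast_to(np.clip(45.0 + 50.0 * wet, 5.0, 98.0), (MONTHS,) + geom.shape).copy()
    rh15 = np.clip(rh09 - 15.0, 5.0, 98.0)

    grid = ClimateGrid(
        tmin=tmin, tmax=tmax, rain=rain, rh09=rh09, rh15=rh15,
        geometry=geom, scenario="current", meta={"seed": spec.seed},
    )
    if scenario == "future":
        grid = apply_future_delta(grid, spec.future)
    return grid


def apply_future_delta(grid: ClimateGrid, delta: FutureDelta) -> ClimateGrid:
    """Shift temperatures and scale band precipitation; geometry unchanged."""
    lat2d = np.repeat(grid.geometry.lat_centers()[:, None], grid.geometry.n_cols, axis=1)
    factor = delta.factor_for(lat2d)[None, :, :]
    return ClimateGrid(
        tmin=grid.tmin + delta.warming,
        tmax=grid.tmax + delta.warming,
        rain=grid.rain * factor,
        rh09=None if grid.rh09 is None else grid.rh09,
        rh15=None if grid.rh15 is None else grid.rh15,
        geometry=grid.geometry,
        scenario="future",
        meta={**grid.meta, "warming": delta.warming},
    )


def sample_occurrences(
    truth: Raster, n: int, seed: int, label: str = "presence", source: str = "synthetic"
) -> pd.DataFrame:
    """Sample point records with cell probability proportional to a truth surface.

    Values must lie in [0, 1] (no-data treated as 0); points are jittered
    uniformly within their cell. Returns a DataFrame (lon, lat, label, source).
    """
    vals = np.where(np.isnan(truth.values), 0.0, truth.values)
    if np.any(vals < 0) or np.any(vals > 1):
        raise ValueError("truth surface values must lie in [0, 1]")
    total = vals.sum()
    if total <= 0:
        raise ValueError("truth surface is all zero")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    flat_p = (vals / total).ravel()
    idx = rng.choice(flat_p.size, size=n, replace=True, p=flat_p)
    rows, cols = np.unravel_index(idx, vals.shape)
    g = truth.geometry
    lon = g.lon_min + (cols + rng.uniform(0, 1, size=n)) * g.res_deg
    lat = g.lat_max - (rows + rng.uniform(0, 1, size=n)) * g.res_deg
    return pd.DataFrame({"lon": lon, "lat": lat, "label": label, "source": source})


# --------------------------------------------------------------------------
# bundled scenarios (the default study conditions)

# archetype bands of the default globe, on absolute latitude
ARCHETYPE_BANDS = {
    "tropical_wet": (0.0, 8.0),
    "arid": (8.0, 14.0),
    "humid_subtropical": (14.0, 24.0),
    "temperate": (24.0, 65.0),
    "polar": (65.0, 90.0),
}


def _mirror(regimes: list[PrecipRegime]) -> tuple:
    """Expand |lat| band definitions into symmetric signed-latitude bands."""
    out = []
    for r in regimes:
        out.append(replace(r, lat_min=r.lat_min, lat_max=r.lat_max))
        out.append(replace(r, lat_min=-r.lat_max, lat_max=-r.lat_min, name=r.name + "_s"))
    return tuple(out)


def default_global_scenario(resolution_arcmin: float = 60.0, seed: int = 0) -> ScenarioSpec:
    """The bundled synthetic globe with five archetype climate bands.

    Rain totals are chosen so the host archetypes exist by construction:
    a humid-subtropical band inside the growth optimum, a hot desert whose
    soil moisture sits below the wilting point year-round, and a polar band
    whose winter minima cross the cold-stress threshold.
    """
    regimes = _mirror(
        [
            PrecipRegime(*ARCHETYPE_BANDS["tropical_wet"], 2600.0, "uniform", "tropical_wet"),
            PrecipRegime(*ARCHETYPE_BANDS["arid"], 25.0, "arid", "arid"),
            PrecipRegime(
                *ARCHETYPE_BANDS["humid_subtropical"], 850.0, "summer-wet", "humid_subtropical"
            ),
            PrecipRegime(*ARCHETYPE_BANDS["temperate"], 600.0, "uniform", "temperate"),
            PrecipRegime(*ARCHETYPE_BANDS["polar"], 200.0, "uniform", "polar"),
        ]
    )
    future = FutureDelta(
        warming=2.0,
        band_factors=(
            (-8.0, 8.0, 1.1),       # wet get wetter
            (-14.0, -8.0, 0.9),     # dry get drier
            (8.0, 14.0, 0.9),
            (14.0, 24.0, 1.1),
            (-24.0, -14.0, 1.1),
        ),
    )
    return ScenarioSpec(
        extent=(-180.0, 180.0, -90.0, 90.0),
        resolution_arcmin=resolution_arcmin,
        regimes=regimes,
        future=future,
        seed=seed,
    )


def band_rows(geometry: GridGeometry, band: str) -> np.ndarray:
    """Boolean row mask of an archetype band on a grid.

    Uses the same half-open signed intervals as the generator's mirrored
    regimes ([lo, hi) in the north, [-hi, -lo) in the south), so boundary
    rows are attributed consistently.
    """
    lo, hi = ARCHETYPE_BANDS[band]
    lat = geometry.lat_centers()
    return ((lat >= lo) & (lat < hi)) | ((lat >= -hi) & (lat < -lo))


def parameter_recovery_scenario(resolution_arcmin: float = 90.0, seed: int = 0) -> ScenarioSpec:
    """A noisy world for predictor-recovery experiments.

    A single moderate precipitation regime with strong independent per-cell,
    per-month lognormal noise: dry-month rainfall then varies within latitude
    bands, decorrelating precipitation predictors from the temperature field.
    """
    return ScenarioSpec(
        extent=(-180.0, 180.0, -60.0, 60.0),
        resolution_arcmin=resolution_arcmin,
        regimes=(PrecipRegime(-60.0, 60.0, 900.0, "uniform", "everywhere"),),
        future=FutureDelta(warming=2.0),
        seed=seed,
        precip_noise_cv=0.8,
    )
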