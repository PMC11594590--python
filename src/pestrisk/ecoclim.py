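"""Mechanistic ecoclimatic-index engine.

A CLIMEX-style annual model: weekly temperature and soil-moisture growth
responses are combined into an Annual Growth Index (GIA, 0-100); accumulated
cold, heat, dry, wet and hot-wet stresses discount it multiplicatively into
the Ecoclimatic Index

    EI = GIA * (1-CS/100)(1-HS/100)(1-DS/100)(1-WS/100) * (1-HW/100)

on a 0-100 scale, where 0 means the location cannot sustain the species and
100 is optimal year-round. The stress-interaction term of the original
formulation is fixed at 1; hot-wet stress enters as a fifth complement factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .climate import ClimateGrid, MONTHS
from .grid import GridGeometry, Raster
from .params import SpeciesParameters

WEEKS = 52
_YEAR_DAYS = 365.0

EI_CLASS_LABELS = ("unfavorable", "marginal", "favorable", "highly_favorable")
# class upper bounds on the EI scale: 0 / (0,15] / (15,30] / (30,100]
EI_CLASS_BOUNDS = (0.0, 15.0, 30.0)


# --------------------------------------------------------------------------
# monthly -> weekly bridge


def _interp_matrix() -> np.ndarray:
    """(52, 12) periodic linear-interpolation weights, month midpoints to week centers."""
    month_mid = (np.arange(MONTHS) + 0.5) * _YEAR_DAYS / MONTHS
    week_mid = (np.arange(WEEKS) + 0.5) * _YEAR_DAYS / WEEKS
    W = np.zeros((WEEKS, MONTHS))
    for w, t in enumerate(week_mid):
        j = int(np.searchsorted(month_mid, t))
        lo, hi = (j - 1) % MONTHS, j % MONTHS
        t_lo = month_mid[lo] if j > 0 else month_mid[lo] - _YEAR_DAYS
        t_hi = month_mid[hi] if j < MONTHS else month_mid[hi] + _YEAR_DAYS
        frac = (t - t_lo) / (t_hi - t_lo)
        W[w, lo] += 1 - frac
        W[w, hi] += frac
    return W


def _rain_matrix() -> np.ndarray:
    """(52, 12) matrix splitting each month's rain evenly over its weeks."""
    week_mid = (np.arange(WEEKS) + 0.5) * _YEAR_DAYS / WEEKS
    month_of_week = np.minimum((week_mid / (_YEAR_DAYS / MONTHS)).astype(int), MONTHS - 1)
    counts = np.bincount(month_of_week, minlength=MONTHS)
    M = np.zeros((WEEKS, MONTHS))
    M[np.arange(WEEKS), month_of_week] = 1.0 / counts[month_of_week]
    return M


_W_TEMP = _interp_matrix()
_W_RAIN = _rain_matrix()


@dataclass
class WeeklyClimate:
    """52-week climate series; arrays are (52,) or (52, n_locations)."""

    tmin: np.ndarray
    tmax: np.ndarray
    tavg: np.ndarray
    rain: np.ndarray

    def __post_init__(self) -> None:
        for name in ("tmin", "tmax", "tavg", "rain"):
            arr = np.atleast_1d(np.asarray(getattr(self, name), dtype=float))
            if arr.shape[0] != WEEKS:
                raise ValueError(f"{name} must have 52 weekly values, got {arr.shape[0]}")
            setattr(self, name, arr)
        if np.any(self.rain < 0):
            raise ValueError("negative weekly rain")
        if np.any(self.tmin > self.tavg + 1e-9) or np.any(self.tavg > self.tmax + 1e-9):
            raise ValueError("weekly temperatures must satisfy tmin <= tavg <= tmax")


def interpolate_weekly(
    monthly_tmin: np.ndarray, monthly_tmax: np.ndarray, monthly_rain: np.ndarray
) -> WeeklyClimate:
    """Derive a 52-week series from 12 monthly values.

    Temperatures are piecewise-linearly interpolated between month midpoints
    (periodic over the year); monthly rain is split evenly over the weeks whose
    centers fall in that month, so the annual total is conserved exactly.
    Accepts (12,) vectors or (12, n) stacks.
    """
    tmin, tmax, rain = (
        np.atleast_1d(np.asarray(a, dtype=float)) for a in (monthly_tmin, monthly_tmax, monthly_rain)
    )
    for name, arr in (("tmin", tmin), ("tmax", tmax), ("rain", rain)):
        if arr.shape[0] != MONTHS:
            raise ValueError(f"monthly {name} must have 12 values, got {arr.shape[0]}")
        if np.any(np.isnan(arr)):
            raise ValueError(f"monthly {name} contains missing values")
    w_tmin = _W_TEMP @ tmin
    w_tmax = _W_TEMP @ tmax
    return WeeklyClimate(
        tmin=w_tmin, tmax=w_tmax, tavg=(w_tmin + w_tmax) / 2.0, rain=_W_RAIN @ rain
    )


# --------------------------------------------------------------------------
# growth responses


def _trapezoid(x: np.ndarray, a: float, b: float, c: float, d: float) -> np.ndarray:
    """Piecewise-linear response: 0 at/below a, 1 on [b, c], 0 at/above d."""
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    if b > a:
        up = (x > a) & (x < b)
        out[up] = (x[up] - a) / (b - a)
    out[(x >= b) & (x <= c)] = 1.0
    if d > c:
        down = (x > c) & (x < d)
        out[down] = (d - x[down]) / (d - c)
    return out


def temperature_index_week(tavg, p: SpeciesParameters) -> np.ndarray:
    """Weekly temperature growth response TI in [0, 1] (trapezoid over DV0..DV3)."""
    return _trapezoid(tavg, p.DV0, p.DV1, p.DV2, p.DV3)


def moisture_index_week(sm, p: SpeciesParameters) -> np.ndarray:
    """Weekly soil-moisture growth response MI in [0, 1] (trapezoid over SM0..SM3)."""
    sm = np.asarray(sm, dtype=float)
    if np.any(sm < 0):
        raise ValueError("soil moisture must be non-negative")
    return _trapezoid(sm, p.SM0, p.SM1, p.SM2, p.SM3)


def annual_growth_index(ti_weekly: np.ndarray, mi_weekly: np.ndarray) -> np.ndarray:
    """GIA = 100 * mean over 52 weeks of TI_w * MI_w."""
    ti = np.atleast_1d(np.asarray(ti_weekly, dtype=float))
    mi = np.atleast_1d(np.asarray(mi_weekly, dtype=float))
    if ti.shape != mi.shape or ti.shape[0] != WEEKS:
        raise ValueError("TI and MI must both be 52-week series of equal shape")
    return 100.0 * np.mean(ti * mi, axis=0)


# --------------------------------------------------------------------------
# soil-moisture bucket


@dataclass(frozen=True)
class BucketConfig:
    """Single-layer weekly water balance.

    Moisture is a fraction of ``capacity_mm``; values above 1 denote storage
    above field capacity, drained at ``drainage`` per week. Evaporative demand
    is ``et_coeff * max(tavg, 0)`` mm/week, limited by available moisture.
    """

    capacity_mm: float = 100.0
    et_coeff: float = 2.0      # mm week^-1 degC^-1
    drainage: float = 0.25     # week^-1, applied to moisture above field capacity
    sm_max: float = 3.0        # hard upper clamp, fraction of capacity
    initial: float = 0.5
    spinup_years: int = 1

    def __post_init__(self) -> None:
        if self.capacity_mm <= 0:
            raise ValueError("bucket capacity must be positive")
        if self.et_coeff < 0 or self.drainage < 0 or self.sm_max <= 0:
            raise ValueError("bucket coefficients must be non-negative, sm_max positive")


def soil_moisture_series(weekly: WeeklyClimate, bucket: BucketConfig = BucketConfig()) -> np.ndarray:
    """Weekly soil-moisture fractions, one spun-up year (52 values).

    The recurrence is iterated ``spinup_years + 1`` times over the same annual
    forcing, starting from ``bucket.initial``; the final year is returned.
    """
    rain = weekly.rain / bucket.capacity_mm
    demand = bucket.et_coeff * np.maximum(weekly.tavg, 0.0) / bucket.capacity_mm
    m = np.full(rain.shape[1:] if rain.ndim > 1 else (), bucket.initial, dtype=float)
    out = np.empty_like(rain)
    for year in range(bucket.spinup_years + 1):
        for w in range(WEEKS):
            evap = demand[w] * np.minimum(m, 1.0)
            drain = bucket.drainage * np.maximum(m - 1.0, 0.0)
            m = np.clip(m + rain[w] - evap - drain, 0.0, bucket.sm_max)
            if year == bucket.spinup_years:
                out[w] = m
    return out


# --------------------------------------------------------------------------
# stress accumulation


def accumulate_stress(exceedance: np.ndarray, rate: float, scheme: str = "compounding") -> np.ndarray:
    """Annual stress total in [0, 100] from a 52-week exceedance series.

    ``compounding`` (default) weights each week's exceedance by the running
    count of stressful weeks, so persistent stress builds approximately
    quadratically — the simplest monotone analogue of exponential stress
    accumulation. ``linear`` sums exceedances unweighted. Both are scaled by
    ``100 * rate`` and capped at 100. For a single stressful week the two
    schemes coincide.
    """
    exc = np.atleast_1d(np.asarray(exceedance, dtype=float))
    if exc.shape[0] != WEEKS:
        raise ValueError("exceedance series must have 52 weeks")
    if np.any(exc < 0):
        raise ValueError("exceedance must be non-negative")
    if rate < 0:
        raise ValueError("stress rate must be non-negative")
    if scheme == "compounding":
        weights = np.cumsum(exc > 0, axis=0)
        total = np.sum(exc * weights, axis=0)
    elif scheme == "linear":
        total = np.sum(exc, axis=0)
    else:
        raise ValueError(f"unknown accumulation scheme {scheme!r}")
    return np.minimum(100.0, 100.0 * rate * total)


def stress_index(cs, hs, ds, ws) -> np.ndarray:
    """SI = product of the four stress complements, in [0, 1]."""
    cs, hs, ds, ws = (np.asarray(x, dtype=float) for x in (cs, hs, ds, ws))
    for name, x in (("CS", cs), ("HS", hs), ("DS", ds), ("WS", ws)):
        if np.any(x < 0) or np.any(x > 100):
            raise ValueError(f"{name} outside [0, 100]")
    return (1 - cs / 100.0) * (1 - hs / 100.0) * (1 - ds / 100.0) * (1 - ws / 100.0)


def ecoclimatic_index(gia, si, hot_wet_stress=0.0) -> np.ndarray:
    """EI = GIA * SI * (1 - HW/100), clamped to [0, 100]."""
    gia, si, hw = (np.asarray(x, dtype=float) for x in (gia, si, hot_wet_stress))
    if np.any(gia < 0) or np.any(gia > 100):
        raise ValueError("GIA outside [0, 100]")
    if np.any(si < 0) or np.any(si > 1):
        raise ValueError("SI outside [0, 1]")
    if np.any(hw < 0) or np.any(hw > 100):
        raise ValueError("hot-wet stress outside [0, 100]")
    return np.clip(gia * si * (1 - hw / 100.0), 0.0, 100.0)


def classify_ei(ei) -> np.ndarray:
    """Habitat class codes: 0 unfavorable (EI=0), 1 marginal (0,15],
    2 favorable (15,30], 3 highly favorable (>30)."""
    ei = np.asarray(ei, dtype=float)
    return (
        (ei > EI_CLASS_BOUNDS[0]).astype(int)
        + (ei > EI_CLASS_BOUNDS[1]).astype(int)
        + (ei > EI_CLASS_BOUNDS[2]).astype(int)
    )


# --------------------------------------------------------------------------
# full engine


@dataclass
class EIResult:
    """Per-cell outputs of the ecoclimatic engine (2-D arrays)."""

    geometry: GridGeometry
    gia: np.ndarray
    ti_mean: np.ndarray
    mi_mean: np.ndarray
    cold_stress: np.ndarray
    heat_stress: np.ndarray
    dry_stress: np.ndarray
    wet_stress: np.ndarray
    hot_wet_stress: np.ndarray
    si: np.ndarray
    ei: np.ndarray
    habitat_class: np.ndarray

    def ei_raster(self) -> Raster:
        return Raster(self.ei, self.geometry, meta={"layer": "EI", "scale": "0-100"})

    def class_raster(self) -> Raster:
        return Raster(
            self.habitat_class.astype(float),
            self.geometry,
            meta={"layer": "habitat_class", "classes": list(EI_CLASS_LABELS)},
        )


class EcoclimaticIndexEngine:
    """Runs the weekly mechanistic pipeline over a monthly climate grid.

    Parameters
    ----------
    species : SpeciesParameters
        Trapezoid thresholds and stress threshold/rate pairs.
    bucket : BucketConfig
        Water-balance configuration.
    accumulation : {"compounding", "linear"}
        Weekly stress accumulation scheme.
    """

    def __init__(
        self,
        species: SpeciesParameters,
        bucket: BucketConfig = BucketConfig(),
        accumulation: str = "compounding",
    ) -> None:
        if accumulation not in ("compounding", "linear"):
            raise ValueError(f"unknown accumulation scheme {accumulation!r}")
        self.species = species
        self.bucket = bucket
        self.accumulation = accumulation

    def get_params(self) -> dict:
        return {
            "species": self.species,
            "bucket": self.bucket,
            "accumulation": self.accumulation,
        }

    def set_params(self, **params) -> "EcoclimaticIndexEngine":
        for key, value in params.items():
            if key not in ("species", "bucket", "accumulation"):
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    # -- per-location ------------------------------------------------------

    def _weekly_components(self, weekly: WeeklyClimate) -> dict[str, np.ndarray]:
        p = self.species
        sm = soil_moisture_series(weekly, self.bucket)
        ti = temperature_index_week(weekly.tavg, p)
        mi = moisture_index_week(sm, p)
        exc = {
            "cold": np.maximum(0.0, p.TTCS - weekly.tmin),
            "heat": np.maximum(0.0, weekly.tavg - p.TTHS),
            "dry": np.maximum(0.0, p.SMDS - sm),
            "wet": np.maximum(0.0, sm - p.SMWS),
            "hot_wet": np.maximum(0.0, weekly.tavg - p.TTHW) * (sm > p.MTHW),
        }
        return {"sm": sm, "ti": ti, "mi": mi, **{f"exc_{k}": v for k, v in exc.items()}}

    def run_location(
        self, monthly_tmin: np.ndarray, monthly_tmax: np.ndarray, monthly_rain: np.ndarray
    ) -> dict:
        """Full result for one location; 'trace' is a 52-row weekly DataFrame."""
        weekly = interpolate_weekly(monthly_tmin, monthly_tmax, monthly_rain)
        c = self._weekly_components(weekly)
        p = self.species
        rates = {"cold": p.THCS, "heat": p.THHS, "dry": p.HDS, "wet": p.HWS, "hot_wet": p.PHW}
        totals = {
            k: float(accumulate_stress(c[f"exc_{k}"], r, self.accumulation))
            for k, r in rates.items()
        }
        gia = float(annual_growth_index(c["ti"], c["mi"]))
        si = float(stress_index(totals["cold"], totals["heat"], totals["dry"], totals["wet"]))
        ei = float(ecoclimatic_index(gia, si, totals["hot_wet"]))
        trace = pd.DataFrame(
            {
                "week": np.arange(1, WEEKS + 1),
                "tavg": weekly.tavg,
                "tmin": weekly.tmin,
                "rain": weekly.rain,
                "soil_moisture": c["sm"],
                "TI": c["ti"],
                "MI": c["mi"],
                **{f"exc_{k}": c[f"exc_{k}"] for k in rates},
            }
        )
        return {
            "GIA": gia,
            "SI": si,
            "EI": ei,
            "habitat_class": EI_CLASS_LABELS[int(classify_ei(ei))],
            "stress_totals": totals,
            "trace": trace,
        }

    # -- gridded -----------------------------------------------------------

    def run_grid(self, grid: ClimateGrid, chunk_cells: int = 200_000) -> EIResult:
        """Apply the weekly pipeline to every cell; geometry is preserved."""
        g = grid.geometry
        n = g.n_cells
        flat = {
            name: np.asarray(getattr(grid, name), dtype=float).reshape(MONTHS, n)
            for name in ("tmin", "tmax", "rain")
        }
        out = {
            name: np.empty(n)
            for name in (
                "gia", "ti_mean", "mi_mean", "cold", "heat", "dry", "wet", "hot_wet", "si", "ei",
            )
        }
        p = self.species
        rates = {"cold": p.THCS, "heat": p.THHS, "dry": p.HDS, "wet": p.HWS, "hot_wet": p.PHW}
        for start in range(0, n, chunk_cells):
            sl = slice(start, min(start + chunk_cells, n))
            try:
                weekly = interpolate_weekly(
                    flat["tmin"][:, sl], flat["tmax"][:, sl], flat["rain"][:, sl]
                )
                c = self._weekly_components(weekly)
            except ValueError as err:
                row, col = divmod(start, g.n_cols)
                raise ValueError(
                    f"cell block starting at row {row}, col {col}: {err}"
                ) from err
            totals = {
                k: accumulate_stress(c[f"exc_{k}"], r, self.accumulation)
                for k, r in rates.items()
            }
            gia = annual_growth_index(c["ti"], c["mi"])
            si = stress_index(totals["cold"], totals["heat"], totals["dry"], totals["wet"])
            out["gia"][sl] = gia
            out["ti_mean"][sl] = np.mean(c["ti"], axis=0)
            out["mi_mean"][sl] = np.mean(c["mi"], axis=0)
            for k in rates:
                out[k][sl] = totals[k]
            out["si"][sl] = si
            out["ei"][sl] = ecoclimatic_index(gia, si, totals["hot_wet"])
        shape = g.shape
        return EIResult(
            geometry=g,
            gia=out["gia"].reshape(shape),
            ti_mean=out["ti_mean"].reshape(shape),
            mi_mean=out["mi_mean"].reshape(shape),
            cold_stress=out["cold"].reshape(shape),
            heat_stress=out["heat"].reshape(shape),
            dry_stress=out["dry"].reshape(shape),
            wet_stress=out["wet"].reshape(shape),
            hot_wet_stress=out["hot_wet"].reshape(shape),
            si=out["si"].reshape(shape),
            ei=out["ei"].reshape(shape),
            habitat_class=classify_ei(out["ei"].reshape(shape)),
        )


def run_ei_grid(
    grid: ClimateGrid,
    species: SpeciesParameters,
    bucket: BucketConfig = BucketConfig(),
    accumulation: str = "compounding",
) -> EIResult:
    """Convenience wrapper over :class:`EcoclimaticIndexEngine`."""
    return EcoclimaticIndexEngine(species, bucket, accumulation).run_grid(grid)
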