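"""End-to-end pipeline: synthetic data -> host EI -> pest SDM -> overlay -> report.

Each stage reads and writes only declared files under the output directory,
so stages can be re-run and tested independently. A JSON manifest records the
configuration, seeds and output hashes of a run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bioclim import BIOCLIM_NAMES, BioclimStack, derive_bioclim
from .climate import ClimateGrid
from .ecoclim import (
    BucketConfig, EI_CLASS_LABELS, EcoclimaticIndexEngine, classify_ei,
)
from .grid import Raster, read_ascii_grid, write_ascii_grid
from .jenks import SUITABILITY_LABELS, JenksBreaks
from .occurrences import (
    generate_pseudo_absences, rarefy_occurrences, read_occurrences, write_occurrences,
)
from .overlay import (
    area_by_class, difference_raster, host_mask, longitude_sector_regions,
    mask_extract, percent_change, suitable_area_totals,
)
from .params import PARAMETER_KEYS, SpeciesParameters, sweetgum_parameters
from .sdm import (
    RandomForestSuitability, cross_validate, predict_suitability_raster, variable_importance,
)
from .synthetic import default_global_scenario, generate_climate_grid, sample_occurrences

log = logging.getLogger("pestrisk")


@dataclass
class PipelineConfig:
    """Everything a full run needs; see the CLI for the file-based form."""

    output_dir: str = "pestrisk_run"
    seed: int = 0
    # synthetic-data stage
    resolution_arcmin: float = 120.0
    n_occurrences: int = 120
    # file inputs (populated by simulate-data, or user-provided)
    current_climate: str | None = None
    future_climate: str | None = None
    occurrences: str | None = None
    species_params: str | None = None
    # model settings
    buffer_km: float = 10.0
    n_pseudo_absences: int = 80
    exclusion_km: float = 10.0
    cv_folds: int = 10
    train_fraction: float = 0.7
    n_estimators: int = 500
    n_suitability_classes: int = 5
    n_regions: int = 6
    stages: tuple = ("simulate-data", "host-ei", "pest-sdm", "overlay", "report")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stages"] = list(self.stages)
        return d

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        return cls(**data)

    def out(self, *parts: str) -> Path:
        return Path(self.output_dir).joinpath(*parts)


def validate_inputs(config: PipelineConfig) -> dict:
    """Pre-flight checks; returns {'fatal': [...], 'warnings': [...]} without raising."""
    fatal: list[str] = []
    warnings_: list[str] = []
    geoms = {}
    for key in ("current_climate", "future_climate"):
        path = getattr(config, key)
        if path is None:
            continue
        if not Path(path, "climate.json").exists():
            fatal.append(f"{key}: climate directory {path} missing or incomplete")
            continue
        try:
            manifest = json.loads(Path(path, "climate.json").read_text())
            geoms[key] = tuple(sorted(manifest["geometry"].items()))
        except Exception as err:  # malformed manifest is fatal, not a crash
            fatal.append(f"{key}: unreadable manifest ({err})")
    if len(set(geoms.values())) > 1:
        fatal.append("current and future climate grids have different geometry")
    if config.occurrences is not None:
        if not Path(config.occurrences).exists():
            fatal.append(f"occurrences file {config.occurrences} not found")
        else:
            df = pd.read_csv(config.occurrences)
            if not {"lon", "lat"} <= set(df.columns):
                fatal.append("occurrences file lacks lon/lat columns")
            else:
                bad = (df["lat"].abs() > 90) | (df["lon"].abs() > 180)
                if bad.any():
                    fatal.append(f"{int(bad.sum())} occurrence(s) outside geographic bounds")
    if config.species_params is not None:
        p = Path(config.species_params)
        if not p.exists():
            fatal.append(f"species parameter file {p} not found")
        else:
            data = yaml.safe_load(p.read_text()) or {}
            missing = [k for k in PARAMETER_KEYS if k not in data]
            if missing:
                fatal.append(f"species parameter file missing keys: {missing}")
    if config.n_pseudo_absences < config.cv_folds:
        warnings_.append("fewer pseudo-absences than folds; folds may be degenerate")
    return {"fatal": fatal, "warnings": warnings_}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _species(config: PipelineConfig) -> SpeciesParameters:
    if config.species_params:
        return SpeciesParameters.from_file(config.species_params)
    return sweetgum_parameters()


def stage_simulate_data(config: PipelineConfig) -> list[Path]:
    """Generate the bundled synthetic scenario pair and pest occurrences."""
    spec = default_global_scenario(config.resolution_arcmin, seed=config.seed)
    current = generate_climate_grid(spec, "current")
    future = generate_climate_grid(spec, "future")
    cur_dir, fut_dir = config.out("climate_current"), config.out("climate_future")
    current.save(cur_dir)
    future.save(fut_dir)
    config.current_climate = str(cur_dir)
    config.future_climate = str(fut_dir)

    # pest occurrences track the host's favourable climate
    engine = EcoclimaticIndexEngine(_species(config))
    ei = engine.run_grid(current)
    truth = Raster(ei.ei / 100.0, current.geometry)
    occ = sample_occurrences(truth, config.n_occurrences, seed=config.seed + 1)
    occ_path = config.out("occurrences.csv")
    write_occurrences(occ, occ_path)
    config.occurrences = str(occ_path)
    return [cur_dir / "climate.json", fut_dir / "climate.json", occ_path]


def stage_host_ei(config: PipelineConfig) -> list[Path]:
    species = _species(config)
    engine = EcoclimaticIndexEngine(species)
    outputs = []
    for key in ("current", "future"):
        grid = ClimateGrid.load(getattr(config, f"{key}_climate"))
        result = engine.run_grid(grid)
        ei_path = config.out(f"host_ei_{key}.asc")
        write_ascii_grid(result.ei_raster(), ei_path)
        cls_path = config.out(f"host_class_{key}.asc")
        write_ascii_grid(result.class_raster(), cls_path)
        outputs += [ei_path, cls_path]
        log.info("host EI (%s): %d cells, %d favourable",
                 key, grid.geometry.n_cells, int((result.ei > 0).sum()))
    return outputs


def stage_pest_sdm(config: PipelineConfig) -> list[Path]:
    current = ClimateGrid.load(config.current_climate)
    future = ClimateGrid.load(config.future_climate)
    stacks = {"current": derive_bioclim(current), "future": derive_bioclim(future)}

    presences = rarefy_occurrences(read_occurrences(config.occurrences), config.buffer_km)
    absences = generate_pseudo_absences(
        current.geometry, config.n_pseudo_absences, presences,
        exclusion_km=config.exclusion_km, seed=config.seed + 2,
    )
    pts = pd.concat([presences, absences], ignore_index=True)
    labels = (pts["label"] == "presence").astype(int).to_numpy()
    features = stacks["current"].sample_points(pts["lon"].to_numpy(), pts["lat"].to_numpy())

    model = RandomForestSuitability(n_estimators=config.n_estimators, random_state=config.seed)
    report = cross_validate(
        features, labels, model=model, k=config.cv_folds,
        train_fraction=config.train_fraction, seed=config.seed,
    )
    model.fit(features, labels)
    importance = variable_importance(model, features, labels, seed=config.seed)

    outputs = []
    eval_path = config.out("evaluation.json")
    eval_path.write_text(json.dumps(report.to_dict(), indent=2))
    imp_path = config.out("variable_importance.csv")
    importance.to_csv(imp_path, header=True)
    train_path = config.out("training_points.csv")
    write_occurrences(pts, train_path)
    outputs += [eval_path, imp_path, train_path]

    for key, stack in stacks.items():
        prob = predict_suitability_raster(model, stack)
        prob_path = config.out(f"pest_suitability_{key}.asc")
        write_ascii_grid(prob, prob_path)
        # natural-breaks classes are recomputed per scenario layer
        jenks = JenksBreaks(n_classes=config.n_suitability_classes).fit(prob.values)
        codes = jenks.transform(prob.values).astype(float)
        codes[np.isnan(prob.values)] = np.nan
        cls = Raster(codes, prob.geometry,
                     meta={"layer": "suitability_class",
                           "classes": list(jenks.class_labels()),
                           "breaks": [float(b) for b in jenks.breaks_]})
        cls_path = config.out(f"pest_class_{key}.asc")
        write_ascii_grid(cls, cls_path)
        outputs += [prob_path, cls_path]
    return outputs


def stage_overlay(config: PipelineConfig) -> list[Path]:
    outputs = []
    masked_prob = {}
    for key in ("current", "future"):
        ei = read_ascii_grid(config.out(f"host_ei_{key}.asc"))
        mask = host_mask(ei)
        mask_path = config.out(f"host_mask_{key}.asc")
        write_ascii_grid(mask, mask_path)
        prob = read_ascii_grid(config.out(f"pest_suitability_{key}.asc"))
        extracted = mask_extract(prob, mask)
        ext_path = config.out(f"pest_suitability_masked_{key}.asc")
        write_ascii_grid(extracted, ext_path)
        masked_prob[key] = extracted
        cls = read_ascii_grid(config.out(f"pest_class_{key}.asc"))
        cls_masked = mask_extract(cls, mask)
        cls_masked.meta = cls.meta
        clsm_path = config.out(f"pest_class_masked_{key}.asc")
        write_ascii_grid(cls_masked, clsm_path)
        outputs += [mask_path, ext_path, clsm_path]
    diff = difference_raster(masked_prob["future"], masked_prob["current"])
    diff_path = config.out("pest_suitability_change.asc")
    write_ascii_grid(diff, diff_path)
    outputs.append(diff_path)
    return outputs


def stage_report(config: PipelineConfig) -> list[Path]:
    regions = None
    tables = []
    for key in ("current", "future"):
        cls = read_ascii_grid(config.out(f"pest_class_masked_{key}.asc"))
        if regions is None:
            regions = longitude_sector_regions(cls.geometry, config.n_regions)
        labels = tuple(cls.meta.get("classes", SUITABILITY_LABELS))
        tables.append(area_by_class(cls, regions, labels, scenario=key))
    table = pd.concat(tables, ignore_index=True)
    table_path = config.out("area_by_class.csv")
    table.to_csv(table_path, index=False)

    totals_incl = suitable_area_totals(table, min_class_index=1)
    totals_excl = suitable_area_totals(table, min_class_index=2)

    def _total(df: pd.DataFrame, scenario: str) -> float:
        return float(df.loc[df["scenario"] == scenario, "area_1e4_km2"].sum())

    summary = {
        "suitable_area_1e4_km2": {
            "including_lowest_class": {s: _total(totals_incl, s) for s in ("current", "future")},
            "excluding_lowest_class": {s: _total(totals_excl, s) for s in ("current", "future")},
        },
    }
    for key, totals in (("including_lowest_class", totals_incl),
                        ("excluding_lowest_class", totals_excl)):
        cur, fut = _total(totals, "current"), _total(totals, "future")
        summary[f"percent_reduction_{key}"] = percent_change(cur, fut) if cur > 0 else None
    summary_path = config.out("area_summary.json")
    summary_path.write_text(json.dumps(summary, indent=2))
    return [table_path, summary_path]


STAGES = {
    "simulate-data": stage_simulate_data,
    "host-ei": stage_host_ei,
    "pest-sdm": stage_pest_sdm,
    "overlay": stage_overlay,
    "report": stage_report,
}


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages in order and write a run manifest."""
    report = validate_inputs(config)
    if report["fatal"]:
        raise ValueError("input validation failed: " + "; ".join(report["fatal"]))
    Path(config.output_dir).mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "config": config.to_dict(),
        "validation_warnings": report["warnings"],
        "stages": {},
    }
    for name in config.stages:
        if name not in STAGES:
            raise ValueError(f"unknown stage {name!r}")
        t0 = time.perf_counter()
        try:
            outputs = STAGES[name](config)
        except Exception as err:
            raise RuntimeError(f"stage {name!r} failed: {err}") from err
        manifest["stages"][name] = {
            "seconds": round(time.perf_counter() - t0, 3),
            "outputs": {str(p): _sha256(Path(p)) for p in outputs},
        }
        log.info("stage %s done in %.2fs", name, manifest["stages"][name]["seconds"])
    manifest["config"] = config.to_dict()  # includes paths filled in by stages
    manifest_path = config.out("manifest.json")
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest
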