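"""Run configuration, validation, and the end-to-end yield-mapping pipeline.

A run is described by one YAML file.  The pipeline stages mirror the
mapping workflow: (optional) NDVI-to-LAI retrieval, aggregation of the LAI
map series into per-cell observation series, per-cell SAFY calibration,
A_LAI extraction, yield regression, and map writing.  Re-running with an
identical configuration reproduces identical outputs; a checksum manifest
is written to make that checkable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .calibrate import read_observations_csv
from .forcing import read_climate_csv, to_season_day
from .params import CalibrationBounds, SafyParameters
from .rasters import NdviLaiRelation, ndvi_to_lai, read_raster, write_raster
from .spatial import LaiMapSeries, SegmentMap, spatialize
from .yields import DEFAULT_WINDOW, YieldRegression, fit_yield_regression, read_samples_csv

__all__ = ["RunConfig", "ConfigError", "StageError", "validate_config", "load_config", "run_pipeline"]

logger = logging.getLogger("safy")

_KNOWN_KEYS = {
    "seed", "out_dir", "climate", "a_lai_window", "cell_px", "min_cover",
    "bounds", "parameters", "calibrated", "lai_manifest", "ndvi_manifest",
    "ndvi_lai_relation", "segments", "segment_regimes", "models", "samples",
    "strata",
}


class ConfigError(ValueError):
    """Invalid run configuration; carries the full list of problems."""

    def __init__(self, errors):
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))


class StageError(RuntimeError):
    """A pipeline stage failed; names the stage and the offending entity."""


@dataclass(frozen=True)
class RunConfig:
    climate: Path
    out_dir: Path
    segments: Path | None = None
    lai_manifest: Path | None = None
    ndvi_manifest: Path | None = None
    ndvi_lai_relation: NdviLaiRelation | None = None
    segment_regimes: Path | None = None
    models: dict = field(default_factory=dict)  # stratum -> model file path
    samples: Path | None = None
    strata: tuple = ("all",)
    a_lai_window: tuple[int, int] = DEFAULT_WINDOW
    cell_px: int = 10
    min_cover: float = 0.5
    bounds: CalibrationBounds = CalibrationBounds()
    parameters: SafyParameters = SafyParameters()
    seed: int = 0


def validate_config(raw: dict, base: Path = Path(".")) -> RunConfig:
    """Check a parsed config dict; raise ConfigError listing every problem found."""
    errors: list[str] = []
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        errors.append(f"unknown config key(s): {sorted(unknown)}")

    def path_of(key, required=False):
        val = raw.get(key)
        if val is None:
            if required:
                errors.append(f"missing required key: {key}")
            return None
        p = base / str(val)
        if not p.exists():
            errors.append(f"{key}: path does not exist: {p}")
        return p

    climate = path_of("climate", required=True)
    segments = path_of("segments")
    lai_manifest = path_of("lai_manifest")
    ndvi_manifest = path_of("ndvi_manifest")
    samples = path_of("samples")
    segment_regimes = path_of("segment_regimes")

    if lai_manifest is not None and ndvi_manifest is not None:
        errors.append("provide lai_manifest or ndvi_manifest, not both")

    window = tuple(raw.get("a_lai_window", DEFAULT_WINDOW))
    if len(window) != 2 or window[0] > window[1]:
        errors.append(f"a_lai_window must be [lo, hi] with lo <= hi, got {list(window)}")

    cell_px = int(raw.get("cell_px", 10))
    if cell_px < 1:
        errors.append("cell_px must be >= 1")

    bounds = CalibrationBounds()
    if "bounds" in raw:
        try:
            bounds = CalibrationBounds(**{k: tuple(v) for k, v in raw["bounds"].items()})
        except (TypeError, ValueError) as exc:
            errors.append(f"bounds: {exc}")

    params = SafyParameters()
    if "parameters" in raw:
        try:
            params = SafyParameters.from_dict(raw["parameters"])
        except (TypeError, ValueError) as exc:
            errors.append(f"parameters: {exc}")

    calibrated = raw.get("calibrated", ["d0", "elue", "stt"])
    if sorted(calibrated) != ["d0", "elue", "stt"]:
        errors.append(f"calibrated subset must be [d0, elue, stt], got {calibrated}")

    relation = None
    if "ndvi_lai_relation" in raw:
        try:
            relation = NdviLaiRelation.from_dict(raw["ndvi_lai_relation"])
        except (KeyError, TypeError, ValueError) as exc:
            errors.append(f"ndvi_lai_relation: {exc}")
    if ndvi_manifest is not None and relation is None:
        errors.append("ndvi_manifest requires an ndvi_lai_relation")

    models = {}
    for stratum, mpath in (raw.get("models") or {}).items():
        p = base / str(mpath)
        if not p.exists():
            errors.append(f"models.{stratum}: path does not exist: {p}")
        models[str(stratum)] = p
    if samples is None and not models:
        errors.append("need either fitted model files (models) or a training cohort (samples)")

    seed = raw.get("seed", 0)
    if not isinstance(seed, int):
        errors.append(f"seed must be an integer, got {seed!r}")

    if errors:
        raise ConfigError(errors)

    return RunConfig(
        climate=climate,
        out_dir=base / str(raw.get("out_dir", "safy_run")),
        segments=segments,
        lai_manifest=lai_manifest,
        ndvi_manifest=ndvi_manifest,
        ndvi_lai_relation=relation,
        segment_regimes=segment_regimes,
        models=models,
        samples=samples,
        strata=tuple(raw.get("strata", ("all",))),
        a_lai_window=(int(window[0]), int(window[1])),
        cell_px=cell_px,
        min_cover=float(raw.get("min_cover", 0.5)),
        bounds=bounds,
        parameters=params,
        seed=int(seed),
    )


def load_config(path) -> RunConfig:
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(["config file must contain a mapping"])
    return validate_config(raw, base=path.parent)


def _read_manifest(path: Path, season_start) -> tuple[list[int], list]:
    df = pd.read_csv(path, parse_dates=["date"])
    if not {"path", "date"} <= set(df.columns):
        raise StageError(f"manifest {path}: needs 'path' and 'date' columns")
    df = df.sort_values("date")
    days, rasters = [], []
    for _, row in df.iterrows():
        days.append(to_season_day(row["date"].date(), season_start))
        rasters.append(read_raster(path.parent / str(row["path"])))
    return days, rasters


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full yield-mapping chain and return the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        return _run_pipeline(config, out)
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run_pipeline(config: RunConfig, out: Path) -> Path:
    forcing = read_climate_csv(config.climate)
    logger.info("climate: %d days starting %s (seed %d)", len(forcing),
                forcing.season_start, config.seed)

    # Stage: yield model (fit from cohort or load fitted files).
    regressions: dict[str, YieldRegression] = {}
    if config.models:
        for stratum, path in config.models.items():
            regressions[stratum] = YieldRegression.from_file(path)
    else:
        cohort = read_samples_csv(config.samples)
        for stratum in config.strata:
            try:
                regressions[stratum] = fit_yield_regression(cohort, stratum)
            except ValueError as exc:
                raise StageError(f"fit-yield[{stratum}]: {exc}") from exc
    for stratum, reg in regressions.items():
        reg.to_file(out / f"model_{stratum}.txt")
        logger.info("model %s: slope=%.4f intercept=%.3f n=%d", stratum, reg.slope,
                    reg.intercept, reg.n)

    # Stage: LAI map series (direct, or retrieved from NDVI).
    series = None
    if config.lai_manifest is not None or config.ndvi_manifest is not None:
        manifest = config.lai_manifest or config.ndvi_manifest
        try:
            days, rasters = _read_manifest(manifest, forcing.season_start)
        except OSError as exc:
            raise StageError(f"lai-maps: {exc}") from exc
        if config.ndvi_manifest is not None:
            rasters = [ndvi_to_lai(r, config.ndvi_lai_relation) for r in rasters]
        series = LaiMapSeries(days=tuple(days), rasters=tuple(rasters))
        logger.info("lai maps: %d dates on a %s grid", len(days), rasters[0].shape)

    if series is not None:
        if config.segments is None:
            raise StageError("spatialize: a segment map is required alongside LAI maps")
        seg_raster = read_raster(config.segments)
        regimes = {}
        if config.segment_regimes is not None:
            df = pd.read_csv(config.segment_regimes)
            regimes = dict(zip(df["segment"].astype(int), df["regime"].astype(str)))
        segments = SegmentMap(labels=seg_raster.data.astype(int), regimes=regimes)

        result = spatialize(
            series, segments, forcing, regressions,
            bounds=config.bounds, fixed=config.parameters,
            cell_px=config.cell_px, window=config.a_lai_window,
            seed=config.seed, min_cover=config.min_cover,
        )
        for name, raster in result.maps.items():
            write_raster(raster, out / f"{name}.tif")
        result.table.to_csv(out / "cells.csv", index=False)
        logger.info("spatialize: %d cells retained", len(result.table))

    manifest = {
        p.name: _sha256(p)
        for p in sorted(out.iterdir())
        if p.is_file() and p.name not in ("manifest.json", "run.log")
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    logger.info("wrote %d outputs", len(manifest))
    return out
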