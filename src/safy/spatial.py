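"""Per-segment yield mapping from multi-date LAI rasters.

The chain mirrors the plot-level procedure, applied wall-to-wall: the
scene is tiled into square cells (default 10 x 10 pixels) to damp local
heterogeneity within a segment; each cell's multi-date mean LAI forms a
sparse observation series; SAFY is calibrated per cell; the calibrated
trajectory yields A_LAI over the maximum-growth window; and the stratum's
yield regression converts A_LAI to grain yield.  Outputs are per-cell maps
of the three calibrated parameters, A_LAI and yield, plus a tidy table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibrate import LaiObservationSet, calibrate
from .forcing import ClimateForcing
from .params import CalibrationBounds, SafyParameters
from .rasters import BandRaster
from .simulate import run_safy
from .yields import DEFAULT_WINDOW, YieldRegression, compute_a_lai

__all__ = ["SegmentMap", "LaiMapSeries", "CellObservations", "SpatializationResult",
           "aggregate_cells", "spatialize"]


@dataclass(frozen=True)
class SegmentMap:
    """Integer segment labels on the scene grid; 0 is background/non-cereal."""

    labels: np.ndarray
    regimes: dict = field(default_factory=dict)  # label -> "irrigated" | "rainfed"

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 2 or not np.issubdtype(labels.dtype, np.integer):
            raise ValueError("segment labels must be a 2-D integer grid")
        if (labels < 0).any():
            raise ValueError("segment labels must be non-negative")
        object.__setattr__(self, "labels", labels)


@dataclass(frozen=True)
class LaiMapSeries:
    """LAI rasters at a handful of acquisition dates (season-day indices)."""

    days: tuple
    rasters: tuple

    def __post_init__(self) -> None:
        days = tuple(int(d) for d in self.days)
        rasters = tuple(self.rasters)
        if len(days) != len(rasters) or not days:
            raise ValueError("need one raster per acquisition day, at least one")
        if not all(a < b for a, b in zip(days, days[1:])):
            raise ValueError("acquisition days must be strictly increasing")
        ref = rasters[0]
        if not all(r.same_grid(ref) for r in rasters):
            raise ValueError("all LAI rasters must share one grid")
        object.__setattr__(self, "days", days)
        object.__setattr__(self, "rasters", rasters)


@dataclass(frozen=True)
class CellObservations:
    """One retained cell: its block position, owning segment and LAI series."""

    row: int  # block row (cell units)
    col: int
    segment: int
    n_pixels: int  # pixels of the owning segment inside the cell
    obs: LaiObservationSet


def aggregate_cells(
    series: LaiMapSeries,
    segments: SegmentMap,
    cell_px: int = 10,
    min_cover: float = 0.5,
) -> list[CellObservations]:
    """Tile the scene into cell_px x cell_px blocks and build per-cell LAI series.

    A cell is assigned to the segment owning the majority of its
    non-background pixels (ties to the smaller label); cells whose
    non-background cover is below ``min_cover`` are dropped.  The cell's
    observation at each date is the mean LAI over the owning segment's
    pixels inside the cell, ignoring nodata.
    """
    if cell_px < 1:
        raise ValueError("cell_px must be >= 1")
    labels = segments.labels
    if labels.shape != series.rasters[0].shape:
        raise ValueError("segment map and LAI rasters are not on the same grid")

    h, w = labels.shape
    cells: list[CellObservations] = []
    for r0 in range(0, h - cell_px + 1, cell_px):
        for c0 in range(0, w - cell_px + 1, cell_px):
            block = labels[r0 : r0 + cell_px, c0 : c0 + cell_px]
            fg = block[block > 0]
            if fg.size < min_cover * block.size:
                continue
            winners, counts = np.unique(fg, return_counts=True)
            seg = int(winners[np.argmax(counts)])  # np.unique sorts: ties -> smaller label
            mask = block == seg
            vals = []
            for ras in series.rasters:
                px = ras.data[r0 : r0 + cell_px, c0 : c0 + cell_px][mask]
                vals.append(float(np.nanmean(px)) if np.isfinite(px).any() else np.nan)
            vals = np.array(vals)
            keep = np.isfinite(vals)
            if not keep.any():
                continue
            obs = LaiObservationSet(
                plot_id=f"cell_{r0 // cell_px}_{c0 // cell_px}",
                days=np.array(series.days)[keep],
                values=np.maximum(vals[keep], 0.0),
            )
            cells.append(
                CellObservations(row=r0 // cell_px, col=c0 // cell_px, segment=seg,
                                 n_pixels=int(mask.sum()), obs=obs)
            )
    return cells


@dataclass(frozen=True)
class SpatializationResult:
    """Per-cell parameter and yield maps on the scene grid, plus the cell table."""

    maps: dict  # name -> BandRaster for elue, d0, stt, a_lai, yield_qx_ha
    table: pd.DataFrame


def spatialize(
    series: LaiMapSeries,
    segments: SegmentMap,
    forcing: ClimateForcing,
    regressions: dict,
    bounds: CalibrationBounds = CalibrationBounds(),
    fixed: SafyParameters = SafyParameters(),
    cell_px: int = 10,
    window: tuple[int, int] = DEFAULT_WINDOW,
    seed: int = 0,
    min_cover: float = 0.5,
) -> SpatializationResult:
    """Calibrate SAFY per cell and convert the fitted trajectories to a yield map.

    ``regressions`` maps regime names to fitted `YieldRegression` objects;
    a cell whose segment regime has no entry falls back to the "all"
    regression, and a missing fallback is an error.  The yield raster is
    computed by applying each cell's regression to the A_LAI raster
    pixelwise — the mapping stage adds no arithmetic of its own.
    Deterministic for a given seed.
    """
    cells = aggregate_cells(series, segments, cell_px=cell_px, min_cover=min_cover)
    shape = segments.labels.shape
    grid = {
        name: np.full(shape, np.nan)
        for name in ("elue", "d0", "stt", "a_lai", "slope", "intercept")
    }

    cache: dict = {}
    rows = []
    for cell in cells:
        regime = segments.regimes.get(cell.segment, "unknown")
        reg: YieldRegression | None = regressions.get(regime) or regressions.get("all")
        if reg is None:
            raise ValueError(
                f"no yield regression for regime {regime!r} (segment {cell.segment}) "
                "and no 'all' fallback supplied"
            )
        key = (tuple(cell.obs.days.tolist()), tuple(np.round(cell.obs.values, 9).tolist()))
        if key not in cache:
            fit = calibrate(cell.obs, forcing, bounds=bounds, fixed=fixed, seed=seed)
            traj = run_safy(fixed.with_calibrated(fit.d0, fit.elue, fit.stt), forcing)
            cache[key] = (fit, compute_a_lai(traj, window))
        fit, a_lai = cache[key]

        r0, c0 = cell.row * cell_px, cell.col * cell_px
        block = segments.labels[r0 : r0 + cell_px, c0 : c0 + cell_px]
        mask = block == cell.segment
        for name, val in (("elue", fit.elue), ("d0", fit.d0), ("stt", fit.stt),
                          ("a_lai", a_lai), ("slope", reg.slope), ("intercept", reg.intercept)):
            grid[name][r0 : r0 + cell_px, c0 : c0 + cell_px][mask] = val

        rows.append(
            {
                "cell_row": cell.row, "cell_col": cell.col, "segment": cell.segment,
                "regime": regime, "n_pixels": cell.n_pixels, "n_obs": fit.n_obs,
                "d0": fit.d0, "elue": fit.elue, "stt": fit.stt,
                "rmse_lai": fit.rmse_lai, "a_lai": a_lai,
                "yield_qx_ha": float(max(reg.slope * a_lai + reg.intercept, 0.0)),
                "stratum": reg.stratum,
            }
        )

    # The yield map is the regression applied to the A_LAI map, nothing more.
    yield_grid = np.maximum(grid["slope"] * grid["a_lai"] + grid["intercept"], 0.0)

    ref = series.rasters[0]
    maps = {
        name: BandRaster(data=grid[name], pixel_size=ref.pixel_size, origin=ref.origin)
        for name in ("elue", "d0", "stt", "a_lai")
    }
    maps["yield_qx_ha"] = BandRaster(data=yield_grid, pixel_size=ref.pixel_size, origin=ref.origin)
    return SpatializationResult(maps=maps, table=pd.DataFrame(rows))
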