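"""Synthetic inputs emulating a semi-arid cereal season.

Everything the pipeline consumes can be generated here: daily climate for
a November-July season, plots with plausible SAFY parameters, sparse LAI
observation series, yield cohorts spanning the observed 11-85 qx/ha range
with a mean near 32 qx/ha, and multi-date LAI raster scenes with a segment
map and full truth tables.  Every generator is a pure function of its
(seed, config) arguments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibrate import LaiObservationSet
from .forcing import ClimateForcing
from .params import CalibrationBounds, SafyParameters
from .rasters import BandRaster
from .simulate import SafyTrajectory, run_safy
from .spatial import LaiMapSeries, SegmentMap
from .yields import DEFAULT_WINDOW, YieldSample, compute_a_lai

__all__ = [
    "PLOT_SAMPLING_BOUNDS",
    "CohortConfig",
    "SceneConfig",
    "generate_climate",
    "sample_plot",
    "generate_lai_observations",
    "generate_cohort",
    "generate_scene",
]

#: Sampling support for synthetic plots.  Narrower than the calibration
#: search box: elue below 0.8 g/MJ gives near-dead crops, and the d0/stt
#: corner (late emergence with a very high senescence threshold) describes
#: a crop that never senesces within the season — neither occurs on real
#: cereal plots, whose LAI peaks and declines between February and May.
PLOT_SAMPLING_BOUNDS = CalibrationBounds(
    d0=(15.0, 100.0), elue=(0.8, 4.0), stt=(400.0, 1200.0)
)

#: Generating yield ~ A_LAI lines per stratum (slope qx/ha per LAI day,
#: intercept qx/ha), matching the reference regressions.
DEFAULT_GENERATING_LINES = {
    "all": (0.33, 17.97),
    "irrigated": (0.39, 16.68),
    "rainfed": (0.45, 16.05),
}


def generate_climate(seed: int = 0, length: int = 270,
                     season_start=None) -> ClimateForcing:
    """Seasonal sinusoid climate with daily noise for a Nov-Jul season.

    Air temperature runs from a winter minimum near 8 degC (mid January)
    to an early-summer maximum near 28 degC; global radiation from about
    8 to 28 MJ m-2 day-1, floored at 0.
    """
    if length < 250:
        raise ValueError("a season needs at least 250 days")
    rng = np.random.default_rng(seed)
    d = np.arange(1, length + 1)
    ta = 18.0 - 10.0 * np.cos(2 * np.pi * (d - 75) / 365.0) + rng.normal(0, 1.5, length)
    rg = 18.0 - 10.0 * np.cos(2 * np.pi * (d - 51) / 365.0) + rng.normal(0, 2.0, length)
    kwargs = {} if season_start is None else {"season_start": season_start}
    return ClimateForcing(rg=np.maximum(rg, 0.0), ta=ta, **kwargs)


def sample_plot(
    seed: int,
    bounds: CalibrationBounds = PLOT_SAMPLING_BOUNDS,
    fixed: SafyParameters = SafyParameters(),
) -> SafyParameters:
    """Draw (d0, elue, stt) uniformly within the sampling support."""
    rng = np.random.default_rng(seed)
    d0 = rng.integers(int(bounds.d0[0]), int(bounds.d0[1]) + 1)
    elue = rng.uniform(*bounds.elue)
    stt = rng.uniform(*bounds.stt)
    return fixed.with_calibrated(d0, elue, stt)


def _observation_days(rng, n_dates: int, lo: int = 30, hi: int = 200,
                      min_gap: int = 14) -> np.ndarray:
    """Roughly even acquisition days over [lo, hi] with jitter and a spacing floor."""
    base = np.linspace(lo, hi, n_dates)
    spacing = (hi - lo) / max(n_dates - 1, 1)
    amp = max(min((spacing - min_gap) / 2.0 - 0.5, 12.0), 0.0)
    days = np.round(base + rng.uniform(-amp, amp, n_dates)).astype(int)
    return np.sort(np.clip(days, lo, hi))


def generate_lai_observations(
    trajectory: SafyTrajectory,
    n_dates: int = 5,
    noise_sd: float = 0.0,
    seed: int = 0,
    plot_id: str = "synthetic",
) -> LaiObservationSet:
    """Sample the simulated LAI at a handful of campaign-like dates.

    Dates are spread over season days 30-200 with at least 14 days between
    visits, echoing a two-to-three-week revisit cadence; observations are
    the simulated LAI plus Gaussian noise, floored at 0.
    """
    rng = np.random.default_rng(seed)
    days = _observation_days(rng, n_dates)
    values = trajectory.lai_at(days) + rng.normal(0, noise_sd, n_dates)
    return LaiObservationSet(plot_id=plot_id, days=days, values=np.maximum(values, 0.0))


@dataclass(frozen=True)
class CohortConfig:
    """Configuration of a synthetic yield cohort.

    With defaults, plots draw A_LAI uniformly on [0, 75] LAI day, receive a
    water regime (65% irrigated, matching the share of irrigated plots in
    the reference campaigns) and a crop label, take their yield from the
    regime's generating line plus Gaussian noise (sd 7.5 qx/ha, the scale
    of the published validation error), and are clipped to the observed
    11-85 qx/ha range.  The A_LAI upper bound is set so the clipped cohort
    mean lands at the observed 32 qx/ha.
    """

    n_plots: int = 1000
    a_lai_range: tuple[float, float] = (0.0, 75.0)
    yield_noise_sd: float = 7.5
    p_irrigated: float = 0.65
    p_wheat: float = 0.5
    generating_lines: dict = field(default_factory=lambda: dict(DEFAULT_GENERATING_LINES))
    stratify_by_regime: bool = True
    yield_floor: float | None = 11.0
    yield_cap: float | None = 85.0
    season: str = "synthetic"

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_irrigated <= 1.0 or not 0.0 <= self.p_wheat <= 1.0:
            raise ValueError("stratum proportions must lie in [0, 1]")
        if self.yield_noise_sd < 0:
            raise ValueError("yield noise sd must be non-negative")
        if (self.yield_floor is not None and self.yield_cap is not None
                and not self.yield_floor < self.yield_cap):
            raise ValueError("yield floor must be below the cap")


def generate_cohort(config: CohortConfig = CohortConfig(), seed: int = 0) -> list[YieldSample]:
    """Draw a cohort of plots with A_LAI, strata labels and noisy yields."""
    rng = np.random.default_rng(seed)
    n = config.n_plots
    a_lai = rng.uniform(*config.a_lai_range, n)
    irrigated = rng.random(n) < config.p_irrigated
    wheat = rng.random(n) < config.p_wheat
    noise = rng.normal(0.0, config.yield_noise_sd, n)

    samples = []
    for i in range(n):
        regime = "irrigated" if irrigated[i] else "rainfed"
        stratum = regime if config.stratify_by_regime else "all"
        slope, intercept = config.generating_lines[stratum]
        y = slope * a_lai[i] + intercept + noise[i]
        if config.yield_floor is not None:
            y = max(y, config.yield_floor)
        if config.yield_cap is not None:
            y = min(y, config.yield_cap)
        samples.append(
            YieldSample(
                plot_id=f"plot_{i:04d}",
                a_lai=float(a_lai[i]),
                yield_measured=float(max(y, 0.0)),
                crop="wheat" if wheat[i] else "barley",
                regime=regime,
                season=config.season,
            )
        )
    return samples


@dataclass(frozen=True)
class SceneConfig:
    """Configuration of a synthetic multi-date LAI scene.

    Segments are non-overlapping rectangles laid out on a grid with a
    background margin between and around them; every pixel of a segment
    shares the segment's simulated trajectory, plus optional pixel noise.
    """

    size_px: int = 200
    pixel_size: float = 10.0
    n_segments: int = 8
    margin_px: int = 4
    n_dates: int = 5
    obs_days: tuple | None = None  # explicit season-day indices, else generated
    lai_noise_sd: float = 0.0
    p_irrigated: float = 0.65

    def __post_init__(self) -> None:
        if self.n_segments < 1 or self.size_px < 20:
            raise ValueError("scene needs at least one segment and 20 px")


def generate_scene(
    config: SceneConfig = SceneConfig(),
    forcing: ClimateForcing | None = None,
    fixed: SafyParameters = SafyParameters(),
    window: tuple[int, int] = DEFAULT_WINDOW,
    seed: int = 0,
):
    """Render a synthetic scene: LAI map series, segment map and truth tables.

    Returns ``(series, segments, truth)`` where ``truth`` is a DataFrame
    with each segment's generating parameters, its A_LAI over the yield
    window and the yield implied by the regime's generating line.
    """
    rng = np.random.default_rng(seed)
    if forcing is None:
        forcing = generate_climate(seed=int(rng.integers(2**31)))

    # Lay segments on a near-square grid of rectangles.
    ncols = int(np.ceil(np.sqrt(config.n_segments)))
    nrows = int(np.ceil(config.n_segments / ncols))
    m = config.margin_px
    cell_h = (config.size_px - m) // nrows
    cell_w = (config.size_px - m) // ncols
    if cell_h <= m or cell_w <= m:
        raise ValueError("scene too small for the requested segment count and margin")

    labels = np.zeros((config.size_px, config.size_px), dtype=int)
    regimes: dict[int, str] = {}
    rows = []
    if config.obs_days is not None:
        days = np.sort(np.asarray(config.obs_days, dtype=int))
    else:
        days = _observation_days(rng, config.n_dates)

    lai_stack = np.full((len(days), config.size_px, config.size_px), np.nan)
    for s in range(config.n_segments):
        label = s + 1
        r, c = divmod(s, ncols)
        r0, c0 = m + r * cell_h, m + c * cell_w
        r1, c1 = r0 + cell_h - m, c0 + cell_w - m
        labels[r0:r1, c0:c1] = label

        params = sample_plot(int(rng.integers(2**31)), fixed=fixed)
        traj = run_safy(params, forcing)
        regime = "irrigated" if rng.random() < config.p_irrigated else "rainfed"
        regimes[label] = regime
        slope, intercept = DEFAULT_GENERATING_LINES[regime]
        a_lai = compute_a_lai(traj, window)

        seg_lai = traj.lai_at(days)
        for k in range(len(days)):
            tile = np.full((r1 - r0, c1 - c0), seg_lai[k])
            if config.lai_noise_sd > 0:
                tile = np.maximum(tile + rng.normal(0, config.lai_noise_sd, tile.shape), 0.0)
            lai_stack[k, r0:r1, c0:c1] = tile

        rows.append(
            {
                "segment": label, "regime": regime,
                "d0": params.d0, "elue": params.elue, "stt": params.stt,
                "a_lai": a_lai,
                "yield_qx_ha": max(slope * a_lai + intercept, 0.0),
                "n_pixels": int((r1 - r0) * (c1 - c0)),
            }
        )

    rasters = tuple(
        BandRaster(data=lai_stack[k], pixel_size=config.pixel_size,
                   date=str(forcing.date_of(int(days[k]))))
        for k in range(len(days))
    )
    series = LaiMapSeries(days=tuple(int(d) for d in days), rasters=rasters)
    return series, SegmentMap(labels=labels, regimes=regimes), pd.DataFrame(rows)
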