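"""Daily climate forcing for one agricultural season.

The season-day convention used throughout the package: day index 1 is
1 November of the sowing year, so a Mediterranean cereal season
(November-July) fits in roughly 270 days.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta

import numpy as np
import pandas as pd

__all__ = ["ClimateForcing", "read_climate_csv", "write_climate_csv", "to_season_day"]


@dataclass(frozen=True)
class ClimateForcing:
    """Per-day global radiation and mean air temperature series.

    ``rg[i]`` and ``ta[i]`` are the forcing for season day ``i + 1``.
    """

    rg: np.ndarray  # MJ m-2 day-1
    ta: np.ndarray  # degC
    season_start: date = date(2010, 11, 1)

    def __post_init__(self) -> None:
        rg = np.asarray(self.rg, dtype=float)
        ta = np.asarray(self.ta, dtype=float)
        object.__setattr__(self, "rg", rg)
        object.__setattr__(self, "ta", ta)
        if rg.shape != ta.shape or rg.ndim != 1:
            raise ValueError("rg and ta must be 1-D arrays of equal length")
        if not (np.isfinite(rg).all() and np.isfinite(ta).all()):
            raise ValueError("climate forcing contains non-finite values")
        if (rg < 0).any():
            raise ValueError("global radiation must be non-negative")

    def __len__(self) -> int:
        return self.rg.size

    @property
    def days(self) -> np.ndarray:
        """Season-day indices (1-based)."""
        return np.arange(1, len(self) + 1)

    def date_of(self, day: int) -> date:
        return self.season_start + timedelta(days=int(day) - 1)


def to_season_day(d: date, season_start: date) -> int:
    """Convert a calendar date to the 1-based season-day index."""
    return (d - season_start).days + 1


def read_climate_csv(path) -> ClimateForcing:
    """Read a climate file with columns ``date, rg_mj_m2, ta_c`` (one row per day)."""
    df = pd.read_csv(path, parse_dates=["date"])
    missing = {"date", "rg_mj_m2", "ta_c"} - set(df.columns)
    if missing:
        raise ValueError(f"climate file missing column(s): {sorted(missing)}")
    df = df.sort_values("date").reset_index(drop=True)
    start = df["date"].iloc[0].date()
    expected = pd.date_range(start, periods=len(df), freq="D")
    if not (df["date"] == expected).all():
        raise ValueError("climate file must contain consecutive daily rows")
    return ClimateForcing(
        rg=df["rg_mj_m2"].to_numpy(float),
        ta=df["ta_c"].to_numpy(float),
        season_start=start,
    )


def write_climate_csv(forcing: ClimateForcing, path) -> None:
    dates = pd.date_range(forcing.season_start, periods=len(forcing), freq="D")
    pd.DataFrame(
        {"date": dates.strftime("%Y-%m-%d"), "rg_mj_m2": forcing.rg, "ta_c": forcing.ta}
    ).to_csv(path, index=False)
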