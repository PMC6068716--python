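"""Forward simulation of the SAFY daily crop growth model.

SAFY is a light-use-efficiency model: each day of the vegetative period,
global radiation Rg is reduced to absorbed photosynthetically active
radiation through the climatic efficiency eps_c and the Beer-Lambert
interception efficiency 1 - exp(-k_ext * LAI), then converted to dry
above-ground mass (DAM) through the effective light-use efficiency ELUE,
modulated by a temperature stress factor FT(Ta):

    dDAM = Rg * eps_c * (1 - exp(-k_ext * LAI)) * ELUE * FT(Ta)

A fraction Pl(SMT) = 1 - pl_a * exp(pl_b * SMT) of new biomass goes to
leaves and is converted to leaf area through the specific leaf area SLA.
Once accumulated air temperature SMT exceeds the threshold STT the canopy
senesces at rate LAI * (SMT - STT) / Rs.  Grain filling starts on the day
leaf production stops (Pl reaches 0) and accumulates DAM * Py per day.

The simulator is vectorized over parameter candidates: `run_safy_batch`
advances every candidate in lock-step through the season, which is what
makes grid-based calibration cheap.  `run_safy` is the single-vector case.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from .forcing import ClimateForcing
from .params import SafyParameters

__all__ = [
    "light_interception",
    "temperature_stress",
    "leaf_partition",
    "grain_filling_start_smt",
    "SafyState",
    "SafyTrajectory",
    "step",
    "run_safy",
    "run_safy_batch",
]

#: g m-2 -> quintals per hectare (1 quintal = 100 kg).
G_M2_TO_QX_HA = 0.1


def light_interception(lai, k_ext):
    """Beer-Lambert fraction of PAR intercepted by a canopy of the given LAI."""
    lai = np.asarray(lai, dtype=float)
    if (lai < 0).any():
        raise ValueError("LAI must be non-negative")
    if k_ext <= 0:
        raise ValueError("k_ext must be positive")
    out = -np.expm1(-k_ext * lai)
    return float(out) if out.ndim == 0 else out


def temperature_stress(ta, params: SafyParameters):
    """Cardinal-temperature beta stress factor in [0, 1].

    Zero at or below t_min and at or above t_max, one at t_opt, with the
    shape controlled by the exponent beta_t.
    """
    ta = np.asarray(ta, dtype=float)
    tmn, top, tmx, b = params.t_min, params.t_opt, params.t_max, params.beta_t
    below = 1.0 - ((top - ta) / (top - tmn)) ** b
    above = 1.0 - ((ta - top) / (tmx - top)) ** b
    out = np.clip(np.where(ta <= top, below, above), 0.0, 1.0)
    out = np.where((ta <= tmn) | (ta >= tmx), 0.0, out)
    return float(out) if out.ndim == 0 else out


def leaf_partition(smt, pl_a, pl_b):
    """Fraction of new biomass allocated to leaves, 1 - pl_a*exp(pl_b*smt), clipped to [0, 1]."""
    smt = np.asarray(smt, dtype=float)
    out = np.clip(1.0 - pl_a * np.exp(pl_b * smt), 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def grain_filling_start_smt(pl_a: float, pl_b: float) -> float:
    """Accumulated temperature at which leaf production stops and grain filling begins.

    Solves 1 - pl_a*exp(pl_b*smt) = 0.  Returns +inf when leaf production
    never stops (pl_a == 0 or pl_b <= 0 with pl_a < 1), 0 when it never
    starts (pl_a >= 1).
    """
    if pl_a >= 1.0:
        return 0.0
    if pl_a <= 0.0 or pl_b <= 0.0:
        return math.inf
    return math.log(1.0 / pl_a) / pl_b


@dataclass(frozen=True)
class SafyState:
    """Model state at the end of one season day."""

    day: int
    dam: float  # g m-2
    lai: float
    gy: float  # g m-2
    smt: float  # degC day since emergence
    senescent: bool


def step(state: SafyState, rg: float, ta: float, params: SafyParameters) -> SafyState:
    """Advance the model by one day (post-emergence).

    Partitioning and senescence are evaluated at the start-of-day
    accumulated temperature; grain filling uses the end-of-day biomass.
    """
    if state.day + 1 < params.d0:
        raise ValueError("step() applies from emergence onward; earlier days hold the zero state")
    if not (math.isfinite(rg) and math.isfinite(ta)):
        raise ValueError(f"non-finite forcing on season day {state.day + 1}")

    ft = temperature_stress(ta, params)
    d_dam = max(rg * params.eps_c * light_interception(state.lai, params.k_ext) * params.elue * ft, 0.0)
    pl = leaf_partition(state.smt, params.pl_a, params.pl_b)
    d_lai_plus = d_dam * pl * params.sla if pl > 0 else 0.0
    d_lai_minus = state.lai * (state.smt - params.stt) / params.rs if state.smt > params.stt else 0.0

    dam = max(state.dam + d_dam, 0.0)
    lai = max(state.lai + d_lai_plus - d_lai_minus, 0.0)
    gy = state.gy + (dam * params.py if state.smt >= grain_filling_start_smt(params.pl_a, params.pl_b) else 0.0)
    smt = state.smt + max(ta, 0.0)
    return SafyState(day=state.day + 1, dam=dam, lai=lai, gy=max(gy, 0.0), smt=smt,
                     senescent=state.smt > params.stt or state.senescent)


@dataclass(frozen=True)
class SafyTrajectory:
    """Daily DAM, LAI, GY and accumulated temperature over a full season."""

    dam: np.ndarray
    lai: np.ndarray
    gy: np.ndarray
    smt: np.ndarray
    params: SafyParameters
    forcing: ClimateForcing

    def __len__(self) -> int:
        return self.lai.size

    @property
    def days(self) -> np.ndarray:
        return np.arange(1, len(self) + 1)

    @property
    def gy_qx_ha(self) -> np.ndarray:
        return self.gy * G_M2_TO_QX_HA

    def lai_at(self, day) -> np.ndarray:
        """LAI on the given 1-based season day(s); exact daily-grid lookup."""
        idx = np.asarray(day, dtype=int) - 1
        if (idx < 0).any() or (idx >= len(self)).any():
            raise ValueError("requested day outside the simulated season")
        return self.lai[idx]

    def to_frame(self) -> pd.DataFrame:
        dates = pd.date_range(self.forcing.season_start, periods=len(self), freq="D")
        return pd.DataFrame(
            {
                "day_index": self.days,
                "date": dates.strftime("%Y-%m-%d"),
                "dam_g_m2": self.dam,
                "lai": self.lai,
                "gy_g_m2": self.gy,
                "gy_qx_ha": self.gy_qx_ha,
                "smt_c_day": self.smt,
            }
        )


def run_safy_batch(
    d0: np.ndarray,
    elue: np.ndarray,
    stt: np.ndarray,
    fixed: SafyParameters,
    forcing: ClimateForcing,
    full: bool = False,
    record_days: np.ndarray | None = None,
):
    """Simulate many (d0, elue, stt) candidates sharing fixed parameters.

    All candidates advance through the season in lock-step; per-day work is
    a handful of vectorized operations, so evaluating thousands of
    candidates costs little more than one.

    Parameters
    ----------
    d0, elue, stt : array-like, shape (m,)
        Calibrated-subset candidates.  d0 is rounded to whole days.
    fixed : SafyParameters
        Source of the remaining parameters.
    full : bool
        When True also return dam, gy and smt histories.
    record_days : array-like of int, optional
        When given, only these season days are recorded (calibration needs
        LAI at a handful of observation days, not the whole history).

    Returns
    -------
    lai : ndarray, shape (n_days, m) or (len(record_days), m)
        Daily LAI per candidate; without ``record_days`` row i is season
        day i + 1.
    extras : dict of ndarray, only when ``full``
        ``dam``, ``gy``, ``smt`` histories of the same shape.
    """
    d0 = np.atleast_1d(np.asarray(d0, dtype=float)).round().astype(int)
    elue = np.broadcast_to(np.atleast_1d(np.asarray(elue, dtype=float)), d0.shape).copy()
    stt = np.broadcast_to(np.atleast_1d(np.asarray(stt, dtype=float)), d0.shape).copy()
    m = d0.size
    n = len(forcing)
    if n < int(d0.max()) + 1:
        raise ValueError(f"forcing ({n} days) must cover emergence day {int(d0.max())} + 1")

    if record_days is not None and full:
        raise ValueError("record_days and full are mutually exclusive")
    if record_days is not None:
        record_days = np.asarray(record_days, dtype=np.int64)
        row_of = np.full(n + 1, -1, dtype=np.int64)
        row_of[record_days] = np.arange(record_days.size)
        n_rows = record_days.size
    else:
        row_of = np.arange(-1, n, dtype=np.int64)  # day d -> row d-1
        n_rows = n

    p = fixed
    gf_start = grain_filling_start_smt(p.pl_a, p.pl_b)
    pl0 = leaf_partition(0.0, p.pl_a, p.pl_b)
    ft_all = np.asarray(temperature_stress(forcing.ta, p), dtype=float)
    ta_pos = np.maximum(forcing.ta, 0.0)

    lai_hist = np.empty((n_rows, m))
    shape_full = (n, m) if full else (0, 0)
    dam_hist = np.empty(shape_full)
    gy_hist = np.empty(shape_full)
    smt_hist = np.empty(shape_full)

    _simulate_kernel(
        d0.astype(np.int64), elue, stt, forcing.rg.astype(float), ft_all, ta_pos,
        p.k_ext, p.eps_c, p.sla, p.pl_a, p.pl_b, p.rs, p.py, p.dam0,
        gf_start, pl0, row_of, lai_hist, dam_hist, gy_hist, smt_hist, full,
    )
    if full:
        return lai_hist, {"dam": dam_hist, "gy": gy_hist, "smt": smt_hist}
    return lai_hist


@njit(cache=True)
def _simulate_kernel(d0, elue, stt, rg, ft, ta_pos, k_ext, eps_c, sla, pl_a, pl_b,
                     rs, py, dam0, gf_start, pl0, row_of, lai_hist, dam_hist,
                     gy_hist, smt_hist, full):  # pragma: no cover - via run_safy_batch
    n = rg.size
    for c in range(d0.size):
        dam = 0.0
        lai = 0.0
        gy = 0.0
        smt = 0.0
        for i in range(n):
            day = i + 1
            if day > d0[c]:
                d_dam = rg[i] * eps_c * -math.expm1(-k_ext * lai) * elue[c] * ft[i]
                if d_dam < 0.0:
                    d_dam = 0.0
                pl = 1.0 - pl_a * math.exp(pl_b * smt)
                if pl < 0.0:
                    pl = 0.0
                elif pl > 1.0:
                    pl = 1.0
                d_lai = d_dam * pl * sla
                if smt > stt[c]:
                    d_lai -= lai * (smt - stt[c]) / rs
                dam = dam + d_dam
                lai = lai + d_lai
                if lai < 0.0:
                    lai = 0.0
                if smt >= gf_start:
                    gy = gy + dam * py
                smt = smt + ta_pos[i]
            elif day == d0[c]:
                dam = dam0
                lai = dam0 * pl0 * sla
                smt = ta_pos[i]
            row = row_of[day]
            if row >= 0:
                lai_hist[row, c] = lai
            if full:
                dam_hist[i, c] = dam
                gy_hist[i, c] = gy
                smt_hist[i, c] = smt


def run_safy(params: SafyParameters, forcing: ClimateForcing) -> SafyTrajectory:
    """Simulate one full season for a single parameter vector.

    Days before emergence hold the all-zero state; on day d0 the crop
    initializes with dam0 of biomass and the corresponding leaf area.
    Deterministic: identical inputs give bit-identical trajectories.
    """
    lai, extras = run_safy_batch(
        np.array([params.d0]), np.array([params.elue]), np.array([params.stt]),
        fixed=params, forcing=forcing, full=True,
    )
    return SafyTrajectory(
        dam=extras["dam"][:, 0].copy(),
        lai=lai[:, 0].copy(),
        gy=extras["gy"][:, 0].copy(),
        smt=extras["smt"][:, 0].copy(),
        params=params,
        forcing=forcing,
    )
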