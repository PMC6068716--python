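"""Per-plot estimation of (d0, elue, stt) by LAI RMSE minimization.

Three SAFY parameters depend strongly on local conditions — the emergence
day d0, the effective light-use efficiency elue, and the senescence
thermal-time threshold stt — and are fitted per plot so that the simulated
LAI best matches the sparse observed LAI, in the root-mean-square sense.

The objective is cheap but non-smooth in d0 (a whole-day index), so the
search is a dense vectorized grid over the 3-D box followed by a local
refinement around the grid optimum and a Nelder-Mead polish of the two
continuous parameters at neighbouring integer d0 values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import qmc

from .forcing import ClimateForcing
from .params import CalibrationBounds, SafyParameters
from .simulate import SafyTrajectory, run_safy, run_safy_batch

__all__ = ["LaiObservationSet", "CalibrationResult", "lai_rmse", "calibrate",
           "read_observations_csv"]


@dataclass(frozen=True)
class LaiObservationSet:
    """Sparse LAI observations for one plot (season-day index, LAI value)."""

    plot_id: str
    days: np.ndarray
    values: np.ndarray
    sd: np.ndarray | None = None

    def __post_init__(self) -> None:
        days = np.asarray(self.days, dtype=int)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "days", days)
        object.__setattr__(self, "values", values)
        if days.size == 0:
            raise ValueError("observation set is empty")
        if days.size != values.size:
            raise ValueError("days and values must have equal length")
        if not (np.diff(days) > 0).all():
            raise ValueError("observation days must be strictly increasing")
        if (values < 0).any():
            raise ValueError("LAI observations must be non-negative")

    def __len__(self) -> int:
        return self.days.size


@dataclass(frozen=True)
class CalibrationResult:
    plot_id: str
    d0: int
    elue: float
    stt: float
    rmse_lai: float
    n_obs: int
    converged: bool
    n_evaluations: int
    seed: int | None = None


def lai_rmse(trajectory: SafyTrajectory, obs: LaiObservationSet) -> float:
    """RMSE between simulated and observed LAI, matched exactly on the daily grid."""
    sim = trajectory.lai_at(obs.days)
    return float(np.sqrt(np.mean((sim - obs.values) ** 2)))


def read_observations_csv(path, season_start) -> list[LaiObservationSet]:
    """Read per-plot observations from a CSV with plot_id, date, lai[, lai_sd] columns."""
    from .forcing import to_season_day

    df = pd.read_csv(path, parse_dates=["date"])
    missing = {"plot_id", "date", "lai"} - set(df.columns)
    if missing:
        raise ValueError(f"observation file missing column(s): {sorted(missing)}")
    out = []
    for pid, grp in df.groupby("plot_id", sort=True):
        grp = grp.sort_values("date")
        days = np.array([to_season_day(d.date(), season_start) for d in grp["date"]])
        sd = grp["lai_sd"].to_numpy(float) if "lai_sd" in grp.columns else None
        out.append(LaiObservationSet(str(pid), days, grp["lai"].to_numpy(float), sd))
    return out


def _grid_rmse(d0, elue, stt, fixed, forcing, obs_days, obs_vals):
    """Vectorized RMSE of every (d0, elue, stt) candidate against the observations."""
    sim = run_safy_batch(d0, elue, stt, fixed=fixed, forcing=forcing,
                         record_days=obs_days)  # (n_obs, m)
    return np.sqrt(np.mean((sim - obs_vals[:, None]) ** 2, axis=0))


def _lex_best(rmse, d0, elue, stt, tol=1e-12):
    """Index of the minimum RMSE; exact ties broken toward the smallest d0, then elue, then stt."""
    best = rmse.min()
    tied = np.flatnonzero(rmse <= best + tol)
    order = np.lexsort((stt[tied], elue[tied], d0[tied]))
    return tied[order[0]]


def calibrate(
    obs: LaiObservationSet,
    forcing: ClimateForcing,
    bounds: CalibrationBounds = CalibrationBounds(),
    fixed: SafyParameters = SafyParameters(),
    seed: int | None = 0,
    n_starts: int = 8,
) -> CalibrationResult:
    """Fit (d0, elue, stt) for one plot by minimizing the LAI RMSE over the bound box.

    Deterministic for a given seed (the seed drives the Latin-hypercube
    polish starts).  All-zero observation sets are flagged non-identifiable
    (``converged=False``) rather than raising.  Fewer than three
    observations triggers a warning: three parameters are being fitted.

    Returns the best parameter set found; the reported ``rmse_lai`` is the
    objective re-evaluated at the returned parameters.
    """
    if len(obs) < 3:
        warnings.warn(
            f"plot {obs.plot_id}: fitting 3 parameters to {len(obs)} observation(s)",
            stacklevel=2,
        )
    if int(obs.days.max()) > len(forcing):
        raise ValueError("observation days extend beyond the climate forcing")

    identifiable = bool((obs.values > 0).any())

    # Simulating past the last observation cannot change the objective.
    horizon = int(obs.days.max())
    short = ClimateForcing(forcing.rg[:horizon], forcing.ta[:horizon], forcing.season_start)

    d0_lo, d0_hi = int(np.ceil(bounds.d0[0])), int(np.floor(min(bounds.d0[1], horizon - 1)))
    obs_days, obs_vals = obs.days, obs.values
    n_eval = 0

    # Stage 1: full-box grid, dense (step 1) along the non-smooth d0 axis.
    # The objective has compensating (elue, stt) basins at different
    # emergence days, so no d0 value is discarded before its inner problem
    # has been optimized.
    d0_g = np.arange(d0_lo, d0_hi + 1)
    n_d0 = d0_g.size
    elue_g = np.linspace(bounds.elue[0], bounds.elue[1], 31)
    stt_g = np.linspace(bounds.stt[0], bounds.stt[1], 25)
    D, E, S = (a.ravel() for a in np.meshgrid(d0_g, elue_g, stt_g, indexing="ij"))
    r = _grid_rmse(D, E, S, fixed, short, obs_days, obs_vals)
    n_eval += r.size
    r3 = r.reshape(n_d0, elue_g.size, stt_g.size)

    # Stage 2: shrinking local grids refine (elue, stt) for every d0 at
    # once.  The inner problem is itself multimodal — early senescence with
    # a larger elue can mimic a weak late-senescing crop — so each d0
    # carries one start per block of the stt axis.
    n_blocks = 4
    edges = np.linspace(0, stt_g.size, n_blocks + 1).astype(int)
    starts_e, starts_s, starts_r = [], [], []
    for b in range(n_blocks):
        sub = r3[:, :, edges[b] : edges[b + 1]]
        flat = sub.reshape(n_d0, -1).argmin(axis=1)
        width = edges[b + 1] - edges[b]
        starts_e.append(elue_g[flat // width])
        starts_s.append(stt_g[edges[b] + flat % width])
        starts_r.append(sub.reshape(n_d0, -1).min(axis=1))
    best_e = np.column_stack(starts_e)  # (n_d0, n_blocks)
    best_s = np.column_stack(starts_s)
    best_r = np.column_stack(starts_r)

    span_e = elue_g[1] - elue_g[0]
    span_s = stt_g[1] - stt_g[0]
    off = np.linspace(-1.0, 1.0, 7)
    oe, os_ = (a.ravel() for a in np.meshgrid(off, off, indexing="ij"))
    D = np.repeat(d0_g, n_blocks * oe.size)
    rows = np.arange(n_d0)[:, None], np.arange(n_blocks)[None, :]
    for _ in range(9):
        E = np.clip(best_e[..., None] + span_e * oe, *bounds.elue)
        S = np.clip(best_s[..., None] + span_s * os_, *bounds.stt)
        r = _grid_rmse(D, E.ravel(), S.ravel(), fixed, short, obs_days, obs_vals)
        n_eval += r.size
        r2 = r.reshape(n_d0, n_blocks, oe.size)
        j = r2.argmin(axis=2)
        rmin = np.take_along_axis(r2, j[..., None], axis=2)[..., 0]
        improved = rmin < best_r
        best_e = np.where(improved, np.take_along_axis(E, j[..., None], axis=2)[..., 0], best_e)
        best_s = np.where(improved, np.take_along_axis(S, j[..., None], axis=2)[..., 0], best_s)
        best_r = np.minimum(best_r, rmin)
        span_e *= 0.45
        span_s *= 0.45

    # Collapse the inner starts: per d0 keep the best block.
    jb = best_r.argmin(axis=1)
    best_e = best_e[np.arange(n_d0), jb]
    best_s = best_s[np.arange(n_d0), jb]
    best_r = best_r[np.arange(n_d0), jb]

    i = _lex_best(best_r, d0_g, best_e, best_s)
    best = (int(d0_g[i]), float(best_e[i]), float(best_s[i]), float(best_r[i]))

    # Stage 3: Nelder-Mead polish at the leading d0 values, plus seeded
    # Latin-hypercube restarts at the incumbent.
    def objective(x, d0_val):
        nonlocal n_eval
        n_eval += 1
        return float(
            _grid_rmse(np.array([d0_val]), np.array([x[0]]), np.array([x[1]]),
                       fixed, short, obs_days, obs_vals)[0]
        )

    rng = np.random.default_rng(seed)
    sampler = qmc.LatinHypercube(d=2, seed=rng)
    lhs = qmc.scale(sampler.random(max(n_starts - 3, 1)),
                    [bounds.elue[0], bounds.stt[0]], [bounds.elue[1], bounds.stt[1]])

    def polish(d0_val, x0):
        nonlocal best
        res = minimize(
            objective, x0, args=(d0_val,), method="Nelder-Mead",
            bounds=[bounds.elue, bounds.stt],
            options={"xatol": 1e-7, "fatol": 1e-13, "maxfev": 200},
        )
        cand = (int(d0_val), float(res.x[0]), float(res.x[1]), float(res.fun))
        if cand[3] < best[3] - 1e-15 or (
            cand[3] <= best[3] + 1e-15 and cand[:3] < best[:3]
        ):
            best = cand

    for k in np.argsort(best_r, kind="stable")[:3]:
        polish(int(d0_g[k]), [best_e[k], best_s[k]])
    for x0 in lhs:
        polish(best[0], x0)

    params = fixed.with_calibrated(best[0], best[1], best[2])
    rmse = lai_rmse(run_safy(params, forcing), obs)
    return CalibrationResult(
        plot_id=obs.plot_id,
        d0=params.d0,
        elue=params.elue,
        stt=params.stt,
        rmse_lai=rmse,
        n_obs=len(obs),
        converged=identifiable,
        n_evaluations=n_eval,
        seed=seed,
    )
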