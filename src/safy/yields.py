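"""Grain-yield estimation from the LAI integral over the maximum-growth window.

The yield predictor A_LAI is the sum of daily LAI over season days 146-157
(25 March - 5 April with day 1 = 1 November), the period of maximum canopy
development.  Measured grain yields (quintals per hectare) are regressed
linearly on A_LAI, either over all cereals or within a stratum (crop type
or water regime).  Reference coefficients fitted on the original Merguellil
cohort are provided in `REFERENCE_REGRESSIONS` for prediction without a
local cohort.

Validation follows a repeated-holdout scheme: the cohort is split into
three disjoint folds of (near-)equal size, the model is fitted on two and
scored on the third, rotating through the folds, and the whole split is
repeated with fresh fold assignments; overall accuracy is the average over
all runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .simulate import SafyTrajectory

__all__ = [
    "DEFAULT_WINDOW",
    "REFERENCE_REGRESSIONS",
    "YieldSample",
    "YieldRegression",
    "ValidationReport",
    "compute_a_lai",
    "fit_yield_regression",
    "predict_yield",
    "confidence_bands",
    "validate_holdout",
    "read_samples_csv",
    "write_samples_csv",
]

#: Season-day window of maximum canopy growth, endpoints inclusive.
DEFAULT_WINDOW = (146, 157)

STRATA = ("all", "wheat", "barley", "irrigated", "rainfed")


@dataclass(frozen=True)
class YieldSample:
    """One plot's A_LAI and (optionally) its measured grain yield."""

    plot_id: str
    a_lai: float  # LAI day
    yield_measured: float | None = None  # qx/ha
    crop: str = "unknown"  # wheat | barley | unknown
    regime: str = "unknown"  # irrigated | rainfed | unknown
    season: str = ""

    def __post_init__(self) -> None:
        if self.a_lai < 0:
            raise ValueError("a_lai must be non-negative")
        if self.yield_measured is not None and self.yield_measured < 0:
            raise ValueError("measured yield must be non-negative")

    def in_stratum(self, stratum: str) -> bool:
        if stratum == "all":
            return True
        if stratum in ("wheat", "barley"):
            return self.crop == stratum
        if stratum in ("irrigated", "rainfed"):
            return self.regime == stratum
        raise ValueError(f"unknown stratum {stratum!r}; expected one of {STRATA}")


@dataclass(frozen=True)
class YieldRegression:
    """OLS fit of grain yield on A_LAI for one stratum."""

    stratum: str
    slope: float  # qx/ha per LAI day
    intercept: float  # qx/ha
    n: int
    r2: float
    residual_sd: float  # qx/ha
    x_mean: float = 0.0
    x_ss: float = 1.0  # sum of squared deviations of training a_lai

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for k, v in self.__dict__.items():
                fh.write(f"{k}: {v}\n")

    @classmethod
    def from_file(cls, path) -> "YieldRegression":
        kv = {}
        with open(path) as fh:
            for line in fh:
                if ":" in line:
                    k, v = line.split(":", 1)
                    kv[k.strip()] = v.strip()
        return cls(
            stratum=kv["stratum"],
            slope=float(kv["slope"]),
            intercept=float(kv["intercept"]),
            n=int(kv["n"]),
            r2=float(kv["r2"]),
            residual_sd=float(kv["residual_sd"]),
            x_mean=float(kv.get("x_mean", 0.0)),
            x_ss=float(kv.get("x_ss", 1.0)),
        )


#: Regression lines fitted on the original two-season Merguellil cohort
#: (all cereals, and the irrigated / rain-fed strata).  Usable for
#: prediction when no local training cohort is available; n, r2 and the
#: band bookkeeping fields are not published and are left unset.
REFERENCE_REGRESSIONS = {
    "all": YieldRegression("all", slope=0.33, intercept=17.97, n=0, r2=float("nan"),
                           residual_sd=float("nan")),
    "irrigated": YieldRegression("irrigated", slope=0.39, intercept=16.68, n=0,
                                 r2=float("nan"), residual_sd=float("nan")),
    "rainfed": YieldRegression("rainfed", slope=0.45, intercept=16.05, n=0,
                               r2=float("nan"), residual_sd=float("nan")),
}


@dataclass(frozen=True)
class ValidationReport:
    stratum: str
    r2_runs: np.ndarray
    rmse_runs: np.ndarray
    seed: int

    @property
    def r2_mean(self) -> float:
        return float(np.mean(self.r2_runs))

    @property
    def rmse_mean(self) -> float:
        return float(np.mean(self.rmse_runs))


def compute_a_lai(trajectory: SafyTrajectory, window: tuple[int, int] = DEFAULT_WINDOW) -> float:
    """LAI integral over the maximum-growth window, as a daily rectangle-rule sum.

    The model is a daily recurrence, so the integral is the plain sum of
    daily LAI over ``window[0]..window[1]`` inclusive — 12 terms for the
    default window (season days 146-157).
    """
    lo, hi = int(window[0]), int(window[1])
    if lo > hi:
        raise ValueError(f"window must satisfy lo <= hi, got ({lo}, {hi})")
    if lo < 1 or hi > len(trajectory):
        raise ValueError(f"window ({lo}, {hi}) outside the simulated season of {len(trajectory)} days")
    return float(trajectory.lai[lo - 1 : hi].sum())


def _stratum_xy(samples, stratum):
    xs, ys = [], []
    for s in samples:
        if s.yield_measured is not None and s.in_stratum(stratum):
            xs.append(s.a_lai)
            ys.append(s.yield_measured)
    return np.asarray(xs), np.asarray(ys)


def fit_yield_regression(samples, stratum: str = "all") -> YieldRegression:
    """Ordinary least squares of measured yield on A_LAI within a stratum."""
    x, y = _stratum_xy(samples, stratum)
    if x.size < 3:
        raise ValueError(f"stratum {stratum!r} has {x.size} usable samples; need at least 3")
    if np.ptp(x) == 0:
        raise ValueError(f"degenerate design: all a_lai identical in stratum {stratum!r}")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    resid_sd = float(np.sqrt(res.ssr / res.df_resid)) if res.df_resid > 0 else 0.0
    return YieldRegression(
        stratum=stratum,
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        n=int(res.nobs),
        r2=float(res.rsquared),
        residual_sd=resid_sd,
        x_mean=float(x.mean()),
        x_ss=float(((x - x.mean()) ** 2).sum()),
    )


def predict_yield(reg: YieldRegression, a_lai):
    """Predicted grain yield slope*a_lai + intercept, floored at 0 qx/ha."""
    a = np.asarray(a_lai, dtype=float)
    if (a < 0).any():
        raise ValueError("a_lai must be non-negative")
    out = np.maximum(reg.slope * a + reg.intercept, 0.0)
    return float(out) if out.ndim == 0 else out


def confidence_bands(reg: YieldRegression, a_lai_grid, level: float = 0.95):
    """Confidence band of the conditional mean and prediction band for new plots.

    Returns a DataFrame with the fitted line and two pairs of limits: the
    inner band (uncertainty of the regression mean) and the outer band
    (that plus residual scatter, containing future observations).  Both are
    narrowest at the training mean of A_LAI and widen with leverage.
    """
    from scipy import stats

    if not 0.0 < level < 1.0:
        raise ValueError("confidence level must lie in (0, 1)")
    if reg.n < 3:
        raise ValueError("bands require a regression fitted on at least 3 samples")
    x = np.asarray(a_lai_grid, dtype=float)
    fit = reg.slope * x + reg.intercept
    t = stats.t.ppf(0.5 + level / 2.0, reg.n - 2)
    lev = 1.0 / reg.n + (x - reg.x_mean) ** 2 / reg.x_ss
    half_mean = t * reg.residual_sd * np.sqrt(lev)
    half_pred = t * reg.residual_sd * np.sqrt(1.0 + lev)
    return pd.DataFrame(
        {
            "a_lai": x,
            "fit": fit,
            "mean_lo": fit - half_mean,
            "mean_hi": fit + half_mean,
            "pred_lo": fit - half_pred,
            "pred_hi": fit + half_pred,
        }
    )


def validate_holdout(samples, stratum: str = "all", n_folds: int = 3,
                     n_repeats: int = 10, seed: int = 0) -> ValidationReport:
    """Repeated holdout validation of the yield ~ A_LAI regression.

    Each repeat shuffles the stratum's samples into ``n_folds`` disjoint
    folds whose sizes differ by at most one; each fold in turn is held out,
    the regression is fitted on the rest, and holdout R2 and RMSE are
    recorded.  The report carries every run plus the averages.
    """
    x, y = _stratum_xy(samples, stratum)
    if n_folds > x.size:
        raise ValueError(f"cannot make {n_folds} folds from {x.size} samples")
    rng = np.random.default_rng(seed)
    r2s, rmses = [], []
    for _ in range(n_repeats):
        perm = rng.permutation(x.size)
        folds = np.array_split(perm, n_folds)
        for k in range(n_folds):
            test = folds[k]
            train = np.concatenate([folds[j] for j in range(n_folds) if j != k])
            res = sm.OLS(y[train], sm.add_constant(x[train])).fit()
            pred = res.params[0] + res.params[1] * x[test]
            err = y[test] - pred
            rmses.append(float(np.sqrt(np.mean(err**2))))
            ss_tot = float(((y[test] - y[test].mean()) ** 2).sum())
            r2s.append(1.0 - float((err**2).sum()) / ss_tot if ss_tot > 0 else 1.0)
    return ValidationReport(stratum=stratum, r2_runs=np.array(r2s),
                            rmse_runs=np.array(rmses), seed=seed)


def read_samples_csv(path) -> list[YieldSample]:
    """Read a cohort from a CSV with plot_id, a_lai, yield_qx_ha, crop, regime, season."""
    df = pd.read_csv(path)
    out = []
    for _, r in df.iterrows():
        y = r.get("yield_qx_ha")
        out.append(
            YieldSample(
                plot_id=str(r["plot_id"]),
                a_lai=float(r["a_lai"]),
                yield_measured=None if pd.isna(y) else float(y),
                crop=str(r.get("crop", "unknown")),
                regime=str(r.get("regime", "unknown")),
                season=str(r.get("season", "")),
            )
        )
    return out


def write_samples_csv(samples, path) -> None:
    pd.DataFrame(
        {
            "plot_id": [s.plot_id for s in samples],
            "a_lai": [s.a_lai for s in samples],
            "yield_qx_ha": [s.yield_measured for s in samples],
            "crop": [s.crop for s in samples],
            "regime": [s.regime for s in samples],
            "season": [s.season for s in samples],
        }
    ).to_csv(path, index=False)
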