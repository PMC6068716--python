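"""Parameter vector of the SAFY crop growth model and calibration bounds.

The model carries fourteen parameters.  Three of them — the emergence day
``d0``, the effective light-use efficiency ``elue`` and the thermal-time
threshold for senescence onset ``stt`` — depend strongly on local
agro-environmental conditions and are the ones estimated per plot.  The
remaining eleven are held at a-priori values taken from prior experimental
work on cereals; they are exposed here as ordinary fields so a user can
override any of them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Iterable

__all__ = ["SafyParameters", "CalibrationBounds", "DEFAULT_BOUNDS"]

#: Names of the per-plot calibrated subset, in canonical order.
CALIBRATED = ("d0", "elue", "stt")


@dataclass(frozen=True)
class SafyParameters:
    """Full SAFY parameter vector.

    Parameters
    ----------
    d0 : int
        Emergence day, expressed as a season-day index (day 1 = 1 November).
    elue : float
        Effective light-use efficiency, g dry mass per MJ of absorbed PAR.
    stt : float
        Cumulative thermal time at which leaf senescence begins, degC day.
    k_ext : float
        Beer-Lambert light-extinction coefficient of the canopy.
    eps_c : float
        Climatic efficiency: fraction of global radiation that is PAR.
    sla : float
        Specific leaf area, m2 of leaf per g of leaf dry mass.
    pl_a, pl_b : float
        Coefficients of the leaf-partition function
        ``Pl(smt) = 1 - pl_a * exp(pl_b * smt)`` (clipped to [0, 1]).
    rs : float
        Senescence rate scale, degC day; larger values mean slower decline.
    py : float
        Daily grain partition fraction, per day.
    t_min, t_opt, t_max : float
        Cardinal temperatures of the temperature-stress function, degC.
    beta_t : float
        Shape exponent of the temperature-stress function.
    dam0 : float
        Above-ground dry mass at emergence, g m-2.
    """

    d0: int = 60
    elue: float = 1.8
    stt: float = 900.0
    k_ext: float = 0.5
    eps_c: float = 0.48
    sla: float = 0.022
    pl_a: float = 0.15
    pl_b: float = 0.002
    rs: float = 6000.0
    py: float = 0.005
    t_min: float = 0.0
    t_opt: float = 15.0
    t_max: float = 37.0
    beta_t: float = 2.0
    dam0: float = 4.2

    def __post_init__(self) -> None:
        if not (self.t_min < self.t_opt < self.t_max):
            raise ValueError(
                f"cardinal temperatures must satisfy t_min < t_opt < t_max, "
                f"got ({self.t_min}, {self.t_opt}, {self.t_max})"
            )
        if not 0.0 <= self.py <= 1.0:
            raise ValueError(f"py must lie in [0, 1], got {self.py}")
        for name in ("sla", "rs", "dam0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def with_calibrated(self, d0: float, elue: float, stt: float) -> "SafyParameters":
        """Return a copy with the calibrated subset replaced."""
        return replace(self, d0=int(round(d0)), elue=float(elue), stt=float(stt))

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "SafyParameters":
        known = {f.name for f in fields(cls)}
        extra = set(d) - known - {"calibrated"}
        if extra:
            raise ValueError(f"unknown SAFY parameter(s): {sorted(extra)}")
        return cls(**{k: v for k, v in d.items() if k in known})


@dataclass(frozen=True)
class CalibrationBounds:
    """Search box for the calibrated subset (d0, elue, stt).

    Defaults are the published ranges observed on the test plots:
    d0 in [15, 120] days, elue in [0, 10] g/MJ, stt in [200, 1800] degC day.
    """

    d0: tuple[float, float] = (15.0, 120.0)
    elue: tuple[float, float] = (0.0, 10.0)
    stt: tuple[float, float] = (200.0, 1800.0)

    def __post_init__(self) -> None:
        for name in ("d0", "elue", "stt"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"bound for {name} must have lower < upper, got ({lo}, {hi})")

    def contains(self, d0: float, elue: float, stt: float, atol: float = 1e-9) -> bool:
        return (
            self.d0[0] - atol <= d0 <= self.d0[1] + atol
            and self.elue[0] - atol <= elue <= self.elue[1] + atol
            and self.stt[0] - atol <= stt <= self.stt[1] + atol
        )


DEFAULT_BOUNDS = CalibrationBounds()
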