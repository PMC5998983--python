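"""Progenitor cell-cycle length and division rate.

The division rate of the progenitor population is tied to the cell-cycle
length T_C by

    rho(t) = ln(2) / T_C(t)

so that a purely self-amplifying population (all divisions symmetric
proliferative) doubles exactly once per cell cycle. T_C is measured in
hours and the simulation time axis in embryonic days, so the rate in
per-day units is ``ln(2) * 24 / T_C``.

Two cell-cycle models are provided: a constant T_C (the species average),
and an age-dependent T_C(t) interpolated linearly through measured
(embryonic day, hours) anchors — e.g. the mouse cycle lengthens from
10.2 h at E12 to 18.4 h at E16, while the macaque cycle rises from 23 h
at E40 to 54 h at E60 and falls back to 27 h by E80. Outside the anchor
range the nearest segment is extrapolated linearly by default (floored at
a 1 h minimum), or held at the boundary value with ``extrapolation="hold"``.
A ``scale`` multiplier supports hypothetical uniformly longer cycles
(e.g. human variants at 1.5x or 2x the macaque baseline).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .species import species_cell_cycle_data

__all__ = [
    "CellCycleModel",
    "constant_cycle",
    "age_dependent_cycle",
    "for_species",
    "cell_cycle_length",
    "division_rate",
    "MIN_TC_HOURS",
]

LN2 = math.log(2.0)
HOURS_PER_DAY = 24.0

#: Positive floor applied to extrapolated cell-cycle lengths (hours).
MIN_TC_HOURS = 1.0


@dataclass(frozen=True)
class CellCycleModel:
    """Constant or age-dependent progenitor cell-cycle length.

    Attributes
    ----------
    mode:
        ``"constant"`` or ``"age_dependent"``.
    Tc_constant:
        Cell-cycle length in hours (constant mode).
    anchors:
        Ordered ``(embryonic day, hours)`` pairs (age-dependent mode);
        anchor days must be strictly increasing.
    scale:
        Dimensionless multiplier applied to T_C everywhere (default 1).
    extrapolation:
        ``"linear"`` continues the nearest segment's slope outside the
        anchor range (floored at :data:`MIN_TC_HOURS`); ``"hold"`` keeps
        the boundary anchor value.
    """

    mode: str
    Tc_constant: Optional[float] = None
    anchors: Optional[tuple[tuple[float, float], ...]] = None
    scale: float = 1.0
    extrapolation: str = "linear"

    def __post_init__(self) -> None:
        if self.mode not in ("constant", "age_dependent"):
            raise ValueError(f"unknown cell-cycle mode {self.mode!r}")
        if self.scale <= 0:
            raise ValueError(f"scale must be positive, got {self.scale}")
        if self.extrapolation not in ("linear", "hold"):
            raise ValueError(f"unknown extrapolation rule {self.extrapolation!r}")
        if self.mode == "constant":
            if self.Tc_constant is None or self.Tc_constant <= 0:
                raise ValueError("constant mode requires a positive Tc_constant")
        else:
            if not self.anchors or len(self.anchors) < 2:
                raise ValueError("age-dependent mode requires >= 2 anchors")
            days = [d for d, _ in self.anchors]
            if any(b <= a for a, b in zip(days, days[1:])):
                raise ValueError("anchor days must be strictly increasing")
            if any(h <= 0 for _, h in self.anchors):
                raise ValueError("anchor cell-cycle lengths must be positive")

    def breakpoint_days(self, window: tuple[float, float]) -> list[float]:
        """Anchor days that fall strictly inside ``window`` (kinks of T_C)."""
        if self.mode == "constant":
            return []
        t0, tF = window
        return [d for d, _ in self.anchors if t0 < d < tF]


def constant_cycle(Tc_hours: float, scale: float = 1.0) -> CellCycleModel:
    """A constant cell-cycle model."""
    return CellCycleModel(mode="constant", Tc_constant=Tc_hours, scale=scale)


def age_dependent_cycle(
    anchors: Sequence[tuple[float, float]],
    scale: float = 1.0,
    extrapolation: str = "linear",
) -> CellCycleModel:
    """An age-dependent cell-cycle model through the given anchors."""
    return CellCycleModel(
        mode="age_dependent",
        anchors=tuple((float(d), float(h)) for d, h in anchors),
        scale=scale,
        extrapolation=extrapolation,
    )


def for_species(
    name: str, mode: str = "constant", scale: float = 1.0, extrapolation: str = "linear"
) -> CellCycleModel:
    """Build the packaged cell-cycle model for a registered species."""
    data = species_cell_cycle_data(name)
    if mode == "constant":
        return constant_cycle(data["constant_hours"], scale=scale)
    return age_dependent_cycle(data["anchors"], scale=scale, extrapolation=extrapolation)


def cell_cycle_length(model: CellCycleModel, t):
    """T_C at embryonic day ``t`` (hours); vectorized over ``t``.

    Age-dependent models interpolate linearly through the anchors and
    extrapolate per ``model.extrapolation``, with extrapolated values
    floored at :data:`MIN_TC_HOURS` before scaling.
    """
    t = np.asarray(t, dtype=float)
    if model.mode == "constant":
        out = np.full_like(t, model.scale * model.Tc_constant)
        return out if out.ndim else float(out)
    days = np.array([d for d, _ in model.anchors])
    hours = np.array([h for _, h in model.anchors])
    if model.extrapolation == "hold":
        tc = np.interp(t, days, hours)
    else:
        tc = np.interp(t, days, hours)
        lo_slope = (hours[1] - hours[0]) / (days[1] - days[0])
        hi_slope = (hours[-1] - hours[-2]) / (days[-1] - days[-2])
        tc = np.where(t < days[0], hours[0] + lo_slope * (t - days[0]), tc)
        tc = np.where(t > days[-1], hours[-1] + hi_slope * (t - days[-1]), tc)
        tc = np.maximum(tc, MIN_TC_HOURS)
    tc = model.scale * tc
    return tc if tc.ndim else float(tc)


def division_rate(model: CellCycleModel, t):
    """Division rate rho(t) = ln(2) * 24 / T_C(t), in per-day units."""
    return LN2 * HOURS_PER_DAY / cell_cycle_length(model, t)
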