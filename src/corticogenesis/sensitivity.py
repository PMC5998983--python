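"""Local sensitivity of the neurogenic output to strategy parameters.

Around a reference strategy theta*, each of the four strategy coordinates
is swept in turn (the others held fixed) and the normalized deviation of
the final per-founder neuron output is recorded:

    S(theta) = |N(tF; theta) - N(tF; theta*)| / N(tF; theta*)

By construction S(theta*) = 0 and S >= 0. Because the output is measured
per founder, S is independent of the founder-population size. Sweep
points that would violate the strategy constraints are dropped (and
reported on the curve).

The default report sweeps each parameter over +/-20% of its admissible
range: the (0, 1) probability range for alpha0, alphaS and betaF, and
the neurogenesis window for tS. Comparable relative sweeps make the
per-parameter maxima rankable; with the fitted species strategies the
switch time tS dominates.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .cell_cycle import CellCycleModel
from .model import DEFAULT_STEP, simulate
from .species import SpeciesParams
from .strategy import DEFAULT_TERMINAL_ALPHA, Strategy, validate_strategy

__all__ = ["SensitivityCurve", "local_sensitivity", "sensitivity_report", "PARAMETERS"]

PARAMETERS = ("alpha0", "alphaS", "betaF", "tS")

#: Fraction of each parameter's admissible range swept on either side.
DEFAULT_SWEEP_HALF_WIDTH = 0.20

#: Number of sweep points per curve (odd, so theta* itself is included).
DEFAULT_SWEEP_POINTS = 9


@dataclass(frozen=True)
class SensitivityCurve:
    """One parameter's sensitivity sweep around the reference strategy."""

    parameter: str
    sweep_values: np.ndarray
    sensitivity_values: np.ndarray
    reference: float
    dropped_values: tuple[float, ...] = ()

    @property
    def max_sensitivity(self) -> float:
        return float(np.max(self.sensitivity_values))

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parameter": self.parameter,
                "theta": self.sweep_values,
                "sensitivity": self.sensitivity_values,
            }
        )


def _admissible_range(
    parameter: str, species: SpeciesParams
) -> tuple[float, float]:
    if parameter == "tS":
        return species.window
    return (0.0, 1.0)


def default_sweep(
    reference: Strategy,
    species: SpeciesParams,
    parameter: str,
    half_width: float = DEFAULT_SWEEP_HALF_WIDTH,
    n_points: int = DEFAULT_SWEEP_POINTS,
) -> np.ndarray:
    """Evenly spaced sweep spanning +/-``half_width`` of the admissible range."""
    lo, hi = _admissible_range(parameter, species)
    center = getattr(reference, parameter)
    delta = half_width * (hi - lo)
    return np.linspace(center - delta, center + delta, n_points)


def local_sensitivity(
    reference: Strategy,
    species: SpeciesParams,
    cycle: CellCycleModel,
    parameter: str,
    sweep=None,
    step: float = DEFAULT_STEP,
    terminal_alpha: str = DEFAULT_TERMINAL_ALPHA,
) -> SensitivityCurve:
    """Sweep one strategy parameter and score the output deviation.

    Parameters
    ----------
    parameter:
        One of ``alpha0``, ``alphaS``, ``betaF``, ``tS``.
    sweep:
        Values to substitute for the parameter; defaults to
        :func:`default_sweep`. Values producing an invalid strategy are
        dropped and listed in ``dropped_values``.
    """
    if parameter not in PARAMETERS:
        raise ValueError(f"unknown parameter {parameter!r}; expected one of {PARAMETERS}")
    ok, reasons = validate_strategy(reference, species.window)
    if not ok:
        raise ValueError("invalid reference strategy: " + "; ".join(reasons))
    if sweep is None:
        sweep = default_sweep(reference, species, parameter)
    sweep = np.asarray(sweep, dtype=float)

    ref_out = simulate(
        reference, cycle, species.window, step=step, terminal_alpha=terminal_alpha
    ).final_neurons
    if ref_out <= 0.0:
        raise ZeroDivisionError("reference output is zero; cannot normalize")

    kept, dropped, sens = [], [], []
    for value in sweep:
        candidate = replace(reference, **{parameter: float(value)})
        valid, _ = validate_strategy(candidate, species.window)
        if not valid:
            dropped.append(float(value))
            continue
        out = simulate(
            candidate, cycle, species.window, step=step, terminal_alpha=terminal_alpha
        ).final_neurons
        kept.append(float(value))
        sens.append(abs(out - ref_out) / ref_out)
    return SensitivityCurve(
        parameter=parameter,
        sweep_values=np.asarray(kept),
        sensitivity_values=np.asarray(sens),
        reference=float(getattr(reference, parameter)),
        dropped_values=tuple(dropped),
    )


def sensitivity_report(
    reference: Strategy,
    species: SpeciesParams,
    cycle: CellCycleModel,
    half_width: float = DEFAULT_SWEEP_HALF_WIDTH,
    n_points: int = DEFAULT_SWEEP_POINTS,
    step: float = DEFAULT_STEP,
    terminal_alpha: str = DEFAULT_TERMINAL_ALPHA,
) -> dict[str, SensitivityCurve]:
    """Sensitivity curves for all four strategy parameters.

    Each parameter is swept over the same fraction of its admissible
    range so the per-parameter maxima are directly comparable.
    """
    return {
        parameter: local_sensitivity(
            reference,
            species,
            cycle,
            parameter,
            sweep=default_sweep(reference, species, parameter, half_width, n_points),
            step=step,
            terminal_alpha=terminal_alpha,
        )
        for parameter in PARAMETERS
    }


def report_frame(curves: dict[str, SensitivityCurve]) -> pd.DataFrame:
    """Long-format (parameter, theta, sensitivity) table of a report."""
    return pd.concat([c.as_frame() for c in curves.values()], ignore_index=True)
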