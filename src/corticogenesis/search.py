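"""Exhaustive search of the division-strategy space.

A species' developmental strategy is identified by enumerating every
4-tuple (alpha0, alphaS, betaF, tS) on a lattice, integrating the
per-founder system for each, and scoring how well the trajectory places
the deeper-layer fraction phi of its final neuron output by the
deeper-layer completion time tM:

    N(tF) = N(tM) / phi + eps

The tuple with minimal |eps| is the fitted strategy. Two objective forms
are available: ``eq4_absolute`` scores the residual above in per-founder
neuron units, ``fraction_error`` scores the scale-free |N(tM)/N(tF) - phi|.
The default lattice uses 0.1 steps in the three probabilities and 0.5-day
steps in tS — the resolution at which fitted strategies are reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cell_cycle import CellCycleModel
from .model import DEFAULT_STEP, simulate_batch
from .species import SpeciesParams
from .strategy import DEFAULT_TERMINAL_ALPHA, Strategy, validate_strategy

__all__ = ["SearchGrid", "SearchResult", "default_grid", "fit_strategy", "OBJECTIVES"]

OBJECTIVES = ("eq4_absolute", "fraction_error")


@dataclass(frozen=True)
class SearchGrid:
    """Candidate values per strategy coordinate, plus the objective."""

    alpha0_values: tuple[float, ...]
    alphaS_values: tuple[float, ...]
    betaF_values: tuple[float, ...]
    tS_values: tuple[float, ...]
    objective: str = "eq4_absolute"

    def __post_init__(self) -> None:
        if self.objective not in OBJECTIVES:
            raise ValueError(
                f"unknown objective {self.objective!r}; expected one of {OBJECTIVES}"
            )
        if not (
            self.alpha0_values
            and self.alphaS_values
            and self.betaF_values
            and self.tS_values
        ):
            raise ValueError("every grid dimension must be non-empty")


@dataclass(frozen=True)
class SearchResult:
    """Outcome of an exhaustive strategy search."""

    best: Strategy
    epsilon: float
    ranked_table: pd.DataFrame  # columns: alpha0, alphaS, betaF, tS, epsilon

    @property
    def n_evaluated(self) -> int:
        return len(self.ranked_table)


def _lattice(lo: float, hi: float, step: float) -> tuple[float, ...]:
    n = int(round((hi - lo) / step))
    return tuple(round(lo + i * step, 10) for i in range(n + 1))


def default_grid(
    species: SpeciesParams, objective: str = "eq4_absolute"
) -> SearchGrid:
    """The standard search lattice for a species.

    Probabilities in 0.1 steps (alpha0 up to 0.9; alphaS and betaF up to
    1.0) and switch times every 0.5 day strictly inside the neurogenesis
    window. Pairs with alphaS <= alpha0 are excluded at enumeration time.
    """
    return SearchGrid(
        alpha0_values=_lattice(0.1, 0.9, 0.1),
        alphaS_values=_lattice(0.2, 1.0, 0.1),
        betaF_values=_lattice(0.1, 1.0, 0.1),
        tS_values=_lattice(species.t0 + 0.5, species.tF - 0.5, 0.5),
        objective=objective,
    )


def _enumerate_valid(
    grid: SearchGrid, window: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """All grid tuples passing the strategy-validity constraints."""
    a0g, aSg, bFg, tSg = np.meshgrid(
        np.asarray(grid.alpha0_values, dtype=float),
        np.asarray(grid.alphaS_values, dtype=float),
        np.asarray(grid.betaF_values, dtype=float),
        np.asarray(grid.tS_values, dtype=float),
        indexing="ij",
    )
    a0 = a0g.ravel()
    aS = aSg.ravel()
    bF = bFg.ravel()
    tS = tSg.ravel()
    t0, tF = window
    # vectorized form of validate_strategy's constraints
    keep = (
        (a0 > 0.0)
        & (a0 < 1.0)
        & (aS > a0)
        & (aS <= 1.0)
        & (bF > 0.0)
        & (bF <= 1.0)
        & (tS > t0)
        & (tS < tF)
    )
    return a0[keep], aS[keep], bF[keep], tS[keep]


def fit_strategy(
    species: SpeciesParams,
    cycle: CellCycleModel,
    grid: SearchGrid | None = None,
    step: float = DEFAULT_STEP,
    terminal_alpha: str = DEFAULT_TERMINAL_ALPHA,
) -> SearchResult:
    """Exhaustively score every valid strategy on the grid.

    Every candidate is integrated on the per-founder system (P0 = 1,
    exploiting linearity in the founder population) and scored by the
    grid's objective against the species' (tM, phi) layering target.
    Ties are broken lexicographically on (tS, alpha0, alphaS, betaF),
    smallest first, so results are deterministic.

    Returns
    -------
    SearchResult
        Best strategy, its mismatch ``epsilon``, and the full table of
        evaluated tuples sorted by increasing epsilon.
    """
    if grid is None:
        grid = default_grid(species)
    a0, aS, bF, tS = _enumerate_valid(grid, species.window)
    if len(a0) == 0:
        raise ValueError("no valid strategy tuples on the search grid")
    for coord in (species.tM,):
        if not species.t0 < coord < species.tF:
            raise ValueError(f"tM={coord} outside the neurogenesis window")
    P_q, N_q = simulate_batch(
        a0,
        aS,
        bF,
        tS,
        cycle,
        species.window,
        query_times=[species.tM, species.tF],
        step=step,
        terminal_alpha=terminal_alpha,
    )
    N_tM, N_tF = N_q[0], N_q[1]
    if grid.objective == "eq4_absolute":
        eps = np.abs(N_tF - N_tM / species.phi)
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            eps = np.abs(N_tM / N_tF - species.phi)
        eps = np.where(N_tF > 0.0, eps, np.inf)

    table = pd.DataFrame(
        {"alpha0": a0, "alphaS": aS, "betaF": bF, "tS": tS, "epsilon": eps}
    )
    table = table.sort_values(
        ["epsilon", "tS", "alpha0", "alphaS", "betaF"],
        kind="mergesort",
        ignore_index=True,
    )
    top = table.iloc[0]
    best = Strategy(
        float(top.alpha0), float(top.alphaS), float(top.betaF), float(top.tS)
    )
    ok, reasons = validate_strategy(best, species.window)
    assert ok, reasons
    return SearchResult(best=best, epsilon=float(top.epsilon), ranked_table=table)
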