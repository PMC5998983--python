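"""Two-population dynamics of cortical neurogenesis.

The progenitor population P and neuron population N evolve as

    dP/dt = rho(t) * P * (1 - alpha(t) - 2 beta(t)),   P(t0) = P0,
    dN/dt = rho(t) * P * (alpha(t) + 2 beta(t)),       N(t0) = 0,

where rho(t) is the division rate set by the cell-cycle length, alpha(t)
the probability of an asymmetric neurogenic division and beta(t) the
probability of a symmetric neurogenic division. A symmetric proliferative
division adds one progenitor (factor 1 - alpha - 2 beta combines the +1
of SymP with the -1 of SymN); each SymN division converts one progenitor
into two neurons, hence the factor 2.

The system is linear in P0, so the per-founder solution (P0 = 1) carries
all shape information; absolute runs are that solution scaled by P0.

Integration is fixed-step classic Runge-Kutta (RK4) on a uniform grid
with every kink of the right-hand side (the strategy switch tS and the
cell-cycle anchor days) inserted exactly as grid points, keeping the
integrand smooth within each step. For constant alpha, beta the system
has a closed-form solution (:func:`closed_form_constant`) used as an
independent oracle for the integrator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cell_cycle import CellCycleModel, division_rate
from .strategy import (
    DEFAULT_TERMINAL_ALPHA,
    Strategy,
    alpha_beta,
    resolve_terminal_alpha,
    validate_strategy,
)

__all__ = [
    "Trajectory",
    "simulate",
    "simulate_constant",
    "simulate_batch",
    "closed_form_constant",
    "deeper_layer_fraction",
    "DEFAULT_STEP",
]

#: Default integration step (days); all strategy/anchor breakpoints on the
#: standard 0.5-day search lattice are exact multiples of it.
DEFAULT_STEP = 0.01


@dataclass(frozen=True)
class Trajectory:
    """Time course of the progenitor and neuron populations.

    ``P`` and ``N`` are per-founder counts when ``P0 == 1`` (often
    written P-tilde and N-tilde), absolute counts otherwise.
    """

    times: np.ndarray
    P: np.ndarray
    N: np.ndarray
    P0: float

    def progenitors_at(self, t) -> float | np.ndarray:
        """P at time ``t``, linearly interpolated on the stored grid."""
        return np.interp(t, self.times, self.P)

    def neurons_at(self, t) -> float | np.ndarray:
        """N at time ``t``, linearly interpolated on the stored grid."""
        return np.interp(t, self.times, self.N)

    @property
    def final_neurons(self) -> float:
        return float(self.N[-1])

    @property
    def final_progenitors(self) -> float:
        return float(self.P[-1])


def _time_grid(
    window: tuple[float, float], step: float, breakpoints=()
) -> np.ndarray:
    """Uniform grid over the window with breakpoints inserted exactly."""
    t0, tF = window
    if step <= 0:
        raise ValueError(f"step must be positive, got {step}")
    n = max(1, int(round((tF - t0) / step)))
    grid = t0 + (tF - t0) * np.arange(n + 1) / n
    extra = [b for b in breakpoints if t0 < b < tF]
    if extra:
        grid = np.union1d(grid, np.asarray(extra, dtype=float))
        # drop near-duplicates from float noise between the union sources
        keep = np.concatenate(([True], np.diff(grid) > step * 1e-6))
        grid = grid[keep]
        grid[-1] = tF
    return grid


def _rk4(times: np.ndarray, ab_at, rho_at, P0, record: bool):
    """Integrate the system along ``times``.

    ``ab_at(t)`` returns (alpha, beta) — scalars or per-candidate arrays —
    and ``rho_at(t)`` the scalar division rate. With ``record`` the full
    trajectory is stored; otherwise only the state at each grid point is
    kept transiently (the caller snapshots what it needs).
    """
    P = np.asarray(P0, dtype=float) + 0.0
    N = np.zeros_like(P)
    Ps = [P.copy()] if record else None
    Ns = [N.copy()] if record else None
    snapshots = {}
    for i in range(len(times) - 1):
        t, t_next = times[i], times[i + 1]
        h = t_next - t
        tm = t + 0.5 * h
        a1, b1 = ab_at(t)
        a2, b2 = ab_at(tm)
        a4, b4 = ab_at(t_next)
        m1 = a1 + 2.0 * b1
        m2 = a2 + 2.0 * b2
        m4 = a4 + 2.0 * b4
        r1, r2, r4 = rho_at(t), rho_at(tm), rho_at(t_next)
        # dP/dt = r*(1-m)*P ; dN/dt = r*m*P
        k1 = r1 * (1.0 - m1) * P
        p2 = P + 0.5 * h * k1
        k2 = r2 * (1.0 - m2) * p2
        p3 = P + 0.5 * h * k2
        k3 = r2 * (1.0 - m2) * p3
        p4 = P + h * k3
        k4 = r4 * (1.0 - m4) * p4
        n1 = r1 * m1 * P
        n2 = r2 * m2 * p2
        n3 = r2 * m2 * p3
        n4 = r4 * m4 * p4
        P = P + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        N = N + (h / 6.0) * (n1 + 2.0 * n2 + 2.0 * n3 + n4)
        if record:
            Ps.append(P.copy())
            Ns.append(N.copy())
    if record:
        return np.array(Ps), np.array(Ns)
    return P, N


def simulate(
    strategy: Strategy,
    cycle: CellCycleModel,
    window: tuple[float, float],
    P0: float = 1.0,
    step: float = DEFAULT_STEP,
    terminal_alpha: str = DEFAULT_TERMINAL_ALPHA,
) -> Trajectory:
    """Integrate the neurogenesis system for one strategy.

    Parameters
    ----------
    strategy:
        A valid division strategy for ``window``.
    cycle:
        Cell-cycle model supplying rho(t).
    window:
        The neurogenesis window (t0, tF) in embryonic days.
    P0:
        Founder population; 1 gives the per-founder (normalized) system.
    step:
        Nominal RK4 step in days.
    terminal_alpha:
        Convention for alpha(tF); see :mod:`corticogenesis.strategy`.

    Returns
    -------
    Trajectory
        P(t), N(t) on the integration grid (strategy switch and
        cell-cycle anchors included exactly as grid points).
    """
    ok, reasons = validate_strategy(strategy, window)
    if not ok:
        raise ValueError("invalid strategy: " + "; ".join(reasons))
    breakpoints = [strategy.tS] + cycle.breakpoint_days(window)
    times = _time_grid(window, step, breakpoints)

    def ab_at(t):
        return alpha_beta(strategy, t, window, terminal_alpha)

    def rho_at(t):
        return division_rate(cycle, t)

    P, N = _rk4(times, ab_at, rho_at, float(P0), record=True)
    if not (np.all(np.isfinite(P)) and np.all(np.isfinite(N))):
        raise FloatingPointError("non-finite state during integration")
    return Trajectory(times=times, P=P, N=N, P0=float(P0))


def simulate_constant(
    alpha: float,
    beta: float,
    cycle: CellCycleModel,
    window: tuple[float, float],
    P0: float = 1.0,
    step: float = DEFAULT_STEP,
) -> Trajectory:
    """Integrate with *constant* division probabilities.

    Bypasses the two-phase strategy shape; used for degenerate regimes
    (pure doubling, pure asymmetric divisions) and for cross-checking the
    integrator against :func:`closed_form_constant`.
    """
    if not (0.0 <= alpha <= 1.0 and 0.0 <= beta <= 1.0 and alpha + beta <= 1.0):
        raise ValueError(f"constant probabilities invalid: alpha={alpha}, beta={beta}")
    times = _time_grid(window, step, cycle.breakpoint_days(window))
    a = float(alpha)
    b = float(beta)
    P, N = _rk4(
        times,
        lambda t: (a, b),
        lambda t: division_rate(cycle, t),
        float(P0),
        record=True,
    )
    return Trajectory(times=times, P=P, N=N, P0=float(P0))


def simulate_batch(
    alpha0: np.ndarray,
    alphaS: np.ndarray,
    betaF: np.ndarray,
    tS: np.ndarray,
    cycle: CellCycleModel,
    window: tuple[float, float],
    query_times,
    step: float = DEFAULT_STEP,
    terminal_alpha: str = DEFAULT_TERMINAL_ALPHA,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate many strategies simultaneously on one shared grid.

    All candidates advance in lock-step over a grid containing every
    distinct switch time and cell-cycle anchor, so each candidate's kinks
    fall exactly on grid points. Per-founder initial conditions (P0 = 1)
    are used; absolute solutions follow by linear scaling.

    Returns
    -------
    (P, N):
        Arrays of shape ``(len(query_times), n_candidates)`` holding the
        state at each requested time (which must be grid points, e.g.
        tM and tF).
    """
    t0, tF = window
    a0 = np.asarray(alpha0, dtype=float)
    aS = np.asarray(alphaS, dtype=float)
    bF = np.asarray(betaF, dtype=float)
    ts = np.asarray(tS, dtype=float)
    aF = resolve_terminal_alpha(bF, terminal_alpha)

    breakpoints = sorted(set(np.unique(ts)) | set(cycle.breakpoint_days(window)))
    times = _time_grid(window, step, breakpoints)
    query_times = np.asarray(query_times, dtype=float)
    q_idx = np.searchsorted(times, query_times)
    q_idx = np.clip(q_idx, 0, len(times) - 1)
    if not np.allclose(times[q_idx], query_times, atol=step * 1e-3):
        raise ValueError("query_times must coincide with integration grid points")

    up_slope = (aS - a0) / np.maximum(ts - t0, 1e-300)
    a_down = (aF - aS) / np.maximum(tF - ts, 1e-300)
    b_down = bF / np.maximum(tF - ts, 1e-300)

    def ab_at(t):
        phase1 = t <= ts
        alpha = np.where(phase1, a0 + up_slope * (t - t0), aS + a_down * (t - ts))
        beta = np.where(phase1, 0.0, b_down * (t - ts))
        return alpha, beta

    def rho_at(t):
        return division_rate(cycle, t)

    P = np.ones_like(a0, dtype=float)
    N = np.zeros_like(P)
    out_P = np.empty((len(query_times), len(P)))
    out_N = np.empty_like(out_P)
    want = {int(i): k for k, i in enumerate(q_idx)}
    if 0 in want:
        out_P[want[0]] = P
        out_N[want[0]] = N
    for i in range(len(times) - 1):
        t, t_next = times[i], times[i + 1]
        h = t_next - t
        tm = t + 0.5 * h
        a1, b1 = ab_at(t)
        a2, b2 = ab_at(tm)
        a4, b4 = ab_at(t_next)
        m1 = a1 + 2.0 * b1
        m2 = a2 + 2.0 * b2
        m4 = a4 + 2.0 * b4
        r1, r2, r4 = rho_at(t), rho_at(tm), rho_at(t_next)
        k1 = r1 * (1.0 - m1) * P
        p2 = P + 0.5 * h * k1
        k2 = r2 * (1.0 - m2) * p2
        p3 = P + 0.5 * h * k2
        k3 = r2 * (1.0 - m2) * p3
        p4 = P + h * k3
        k4 = r4 * (1.0 - m4) * p4
        N = N + (h / 6.0) * (r1 * m1 * P + 2.0 * r2 * m2 * (p2 + p3) + r4 * m4 * p4)
        P = P + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        j = want.get(i + 1)
        if j is not None:
            out_P[j] = P
            out_N[j] = N
    return out_P, out_N


def closed_form_constant(
    alpha: float,
    beta: float,
    rho: float,
    window: tuple[float, float],
    P0: float,
    t,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact solution for constant alpha, beta and rho.

    With k = 1 - alpha - 2 beta,

        P(t) = P0 exp(rho k (t - t0))
        N(t) = P0 (alpha + 2 beta) / k * (exp(rho k (t - t0)) - 1),  k != 0
        N(t) = rho P0 (alpha + 2 beta) (t - t0),                     k == 0

    The sign of k separates extinction (k < 0), a constant progenitor
    pool (k = 0) and unbounded growth (k > 0).
    """
    if alpha + beta > 1.0 + 1e-12:
        raise ValueError("alpha + beta must not exceed 1")
    t0, _ = window
    tau = np.asarray(t, dtype=float) - t0
    k = 1.0 - alpha - 2.0 * beta
    m = alpha + 2.0 * beta
    P = P0 * np.exp(rho * k * tau)
    if k == 0.0:
        N = rho * P0 * m * tau
    else:
        N = P0 * m / k * np.expm1(rho * k * tau)
    return P, N


def deeper_layer_fraction(traj: Trajectory, tM: float) -> float:
    """Fraction of the final neuron output already produced by day ``tM``.

    Under inside-first/outside-last layering, neurons born before tM
    populate the deeper (infragranular) layers, so N(tM)/N(tF) is the
    model's deeper-layer fraction, comparable to the anatomical phi.
    """
    t0, tF = float(traj.times[0]), float(traj.times[-1])
    if not t0 < tM < tF:
        raise ValueError(f"tM={tM} outside the open window ({t0}, {tF})")
    n_final = traj.final_neurons
    if n_final <= 0.0:
        raise ZeroDivisionError("final neuron count is zero; fraction undefined")
    return float(traj.neurons_at(tM)) / n_final
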