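"""Time-dependent division strategies.

Cortical progenitors divide in one of three modes: symmetric proliferative
(SymP, two progenitors), asymmetric neurogenic (AsymN, one progenitor and
one neuron) and symmetric neurogenic (SymN, two neurons). The probability
of each mode is modulated over the neurogenesis window (t0, tF) by a
two-step piecewise-linear strategy parameterized by the 4-tuple
(alpha0, alphaS, betaF, tS):

* phase 1, t0 <= t <= tS: the AsymN probability alpha(t) rises linearly
  from alpha0 to alphaS while the SymN probability beta(t) is zero;
* phase 2, tS <= t <= tF: beta(t) rises linearly from 0 to betaF while
  alpha(t) falls linearly from alphaS to a terminal value alphaF.

The SymP probability is the remainder 1 - alpha(t) - beta(t). Two
conventions for the terminal AsymN value are supported: ``"zero"``
(alphaF = 0, the default — asymmetric divisions vanish by tF, leaving a
residual proliferative fraction 1 - betaF for gliogenesis) and
``"complement"`` (alphaF = 1 - betaF, so SymP vanishes at tF instead).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

__all__ = [
    "Strategy",
    "DivisionProbabilities",
    "TERMINAL_ALPHA_CONVENTIONS",
    "alpha_beta",
    "division_probabilities",
    "validate_strategy",
]

#: Supported conventions for the terminal AsymN probability alpha(tF).
TERMINAL_ALPHA_CONVENTIONS = ("zero", "complement")

#: Package-wide default convention (see module docstring).
DEFAULT_TERMINAL_ALPHA = "zero"


@dataclass(frozen=True)
class Strategy:
    """A division strategy 4-tuple.

    Attributes
    ----------
    alpha0:
        AsymN probability at neurogenesis onset t0, in (0, 1).
    alphaS:
        AsymN probability at the switch time tS, in (alpha0, 1].
    betaF:
        SymN probability at the end of neurogenesis tF, in (0, 1].
    tS:
        Switch time (embryonic day), strictly inside the window.
    """

    alpha0: float
    alphaS: float
    betaF: float
    tS: float

    def astuple(self) -> tuple[float, float, float, float]:
        return (self.alpha0, self.alphaS, self.betaF, self.tS)

    @classmethod
    def from_sequence(cls, values: Iterable[float]) -> "Strategy":
        a0, aS, bF, tS = (float(v) for v in values)
        return cls(a0, aS, bF, tS)


@dataclass(frozen=True)
class DivisionProbabilities:
    """The three division-mode probabilities at one time point.

    ``p_sym_p + p_asym_n + p_sym_n == 1`` exactly (the proliferative
    probability is computed as the remainder).
    """

    p_sym_p: float
    p_asym_n: float
    p_sym_n: float


def resolve_terminal_alpha(betaF, convention):
    """The terminal AsymN probability alpha(tF) for a given convention.

    ``convention`` is ``"zero"``, ``"complement"`` or a number in
    [0, 1 - betaF] (clipped to that admissible interval, which keeps the
    probability simplex respected at tF). Vectorized over ``betaF``.
    """
    bF = np.asarray(betaF, dtype=float)
    if convention == "zero":
        return np.zeros_like(bF)
    if convention == "complement":
        return 1.0 - bF
    if isinstance(convention, (int, float)) and not isinstance(convention, bool):
        return np.clip(float(convention), 0.0, 1.0 - bF)
    raise ValueError(
        f"unknown terminal-alpha convention {convention!r}; "
        f"expected one of {TERMINAL_ALPHA_CONVENTIONS} or a number"
    )


def alpha_beta(
    strategy: Strategy,
    t,
    window: tuple[float, float],
    terminal_alpha: str = DEFAULT_TERMINAL_ALPHA,
):
    """Evaluate alpha(t) and beta(t); ``t`` may be a scalar or array.

    Vectorized over ``t`` (and over strategy fields supplied as arrays,
    which the batch integrator exploits). Values of ``t`` are assumed to
    lie within the window.
    """
    t0, tF = window
    a0 = np.asarray(strategy.alpha0, dtype=float)
    aS = np.asarray(strategy.alphaS, dtype=float)
    bF = np.asarray(strategy.betaF, dtype=float)
    tS = np.asarray(strategy.tS, dtype=float)
    aF = resolve_terminal_alpha(bF, terminal_alpha)
    t = np.asarray(t, dtype=float)
    # fractional progress within each phase; guard the degenerate denominators
    up = np.clip((t - t0) / np.maximum(tS - t0, 1e-300), 0.0, 1.0)
    down = np.clip((t - tS) / np.maximum(tF - tS, 1e-300), 0.0, 1.0)
    in_phase1 = t <= tS
    alpha = np.where(in_phase1, a0 + (aS - a0) * up, aS + (aF - aS) * down)
    beta = np.where(in_phase1, 0.0, bF * down)
    return alpha, beta


def division_probabilities(
    strategy: Strategy,
    t: float,
    window: tuple[float, float],
    terminal_alpha: str = DEFAULT_TERMINAL_ALPHA,
) -> DivisionProbabilities:
    """The (SymP, AsymN, SymN) probabilities at embryonic day ``t``.

    Raises
    ------
    ValueError
        If ``t`` lies outside the window or the strategy is invalid for it.
    """
    t0, tF = window
    if not t0 <= t <= tF:
        raise ValueError(f"t={t} outside the neurogenesis window ({t0}, {tF})")
    ok, reasons = validate_strategy(strategy, window)
    if not ok:
        raise ValueError("invalid strategy: " + "; ".join(reasons))
    alpha, beta = alpha_beta(strategy, t, window, terminal_alpha)
    alpha = float(alpha)
    beta = float(beta)
    # valid strategies keep both phases' linear segments inside the simplex
    assert -1e-12 <= alpha <= 1 + 1e-12 and -1e-12 <= beta <= 1 + 1e-12
    assert alpha + beta <= 1 + 1e-12
    return DivisionProbabilities(
        p_sym_p=1.0 - alpha - beta, p_asym_n=alpha, p_sym_n=beta
    )


def validate_strategy(
    strategy: Strategy, window: tuple[float, float]
) -> tuple[bool, list[str]]:
    """Check the biological-relevance constraints on a strategy.

    Requires 0 < alpha0 < 1, alpha0 < alphaS <= 1, 0 < betaF <= 1 and
    t0 < tS < tF (the closed upper bound 1 is admitted for alphaS and
    betaF, matching fitted strategies that reach it). Under both
    terminal-alpha conventions these bounds keep every division
    probability in [0, 1] at every time.

    Returns
    -------
    (valid, reasons):
        ``valid`` is True iff all constraints hold; ``reasons`` lists a
        human-readable diagnostic for each violated constraint.
    """
    t0, tF = window
    reasons: list[str] = []
    if not 0.0 < strategy.alpha0 < 1.0:
        reasons.append(f"alpha0={strategy.alpha0} not in (0, 1)")
    if not strategy.alpha0 < strategy.alphaS <= 1.0:
        reasons.append(
            f"alphaS={strategy.alphaS} not in (alpha0={strategy.alpha0}, 1]"
        )
    if not 0.0 < strategy.betaF <= 1.0:
        reasons.append(f"betaF={strategy.betaF} not in (0, 1]")
    if not t0 < strategy.tS < tF:
        reasons.append(f"tS={strategy.tS} not inside the window ({t0}, {tF})")
    return (not reasons, reasons)
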