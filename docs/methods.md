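# Methods

## Model

The package describes cortical neurogenesis with two well-mixed
populations: progenitors P(t) (all premitotic progenitor types pooled —
neuroepithelial cells, apical/basal radial glia, intermediate progenitors)
and postmitotic neurons N(t). Progenitor divisions occur at rate
ρ(t) = ln 2 / T_C(t) per progenitor and fall into three modes: symmetric
proliferative (SymP), asymmetric neurogenic (AsymN, probability α(t)) and
symmetric neurogenic (SymN, probability β(t)). Bookkeeping over the three
modes gives

    dP/dt = ρ(t) P (1 − α(t) − 2β(t)),   P(t0) = P0,
    dN/dt = ρ(t) P (α(t) + 2β(t)),       N(t0) = 0.

The system is linear in the state, so the per-founder solution (P0 = 1,
written P̃, Ñ) carries all shape information and absolute runs are scalar
multiples of it. With constant α and β the system has the closed form

    P(t) = P0 e^{ρk(t−t0)},  k = 1 − α − 2β,
    N(t) = P0 (α+2β)/k (e^{ρk(t−t0)} − 1)     (k ≠ 0; linear in t at k = 0),

which separates extinction (k < 0), a constant pool (k = 0) and unbounded
growth (k > 0), and serves as the package's independent integration oracle.

Neuronal death and migration are not dynamic variables; they enter only as
scalar corrections when adult neuron counts are converted to a
neurogenic-output target (below). Progenitor death, subtype structure,
spatial organization and gliogenesis are out of scope.

## Division strategies

The division probabilities follow a two-step piecewise-linear *strategy*
(α0, αS, βF, tS): on [t0, tS], α rises linearly from α0 to αS and β = 0;
on [tS, tF], β rises linearly from 0 to βF while α falls linearly from αS
to a terminal value αF. Validity requires 0 < α0 < 1, α0 < αS ≤ 1,
0 < βF ≤ 1 and t0 < tS < tF (closed upper bounds are admitted because
fitted strategies reach them), which keeps all three probabilities in
[0, 1] throughout.

The terminal AsymN value αF is a genuine modeling freedom: the
qualitative picture only fixes that AsymN declines late. The package
default is αF = 0 (asymmetric divisions vanish by tF, leaving a residual
proliferative fraction 1 − βF for subsequent gliogenesis); the
alternative αF = 1 − βF ("complement", SymP vanishes at tF instead) and
arbitrary numeric αF ∈ [0, 1 − βF] are selectable everywhere via
`terminal_alpha`. The choice changes late-time dynamics: e.g. the human
constant-cycle strategy (βF = 0.5) gives a pool that plateaus at tF under
αF = 0 but contracts under the complement convention.

## Cell cycle

Two cell-cycle models supply ρ(t). *Constant*: the species-average T_C
(mouse 14.3 h; macaque 34.67 h; human uses the macaque value as a proxy —
no in-vivo human measurements exist). *Age-dependent*: T_C(t) interpolated
linearly through measured anchors (mouse E12: 10.2 h → E16: 18.4 h;
macaque E40: 23 h, E60: 54 h, E80: 27 h; human again borrows the macaque
anchors). Outside the anchor range the nearest segment is extrapolated
linearly by default, floored at 1 h; a "hold boundary value" rule is
available. The linear rule notably drives the macaque T_C to the floor at
E100 (the measured E60→E80 decline of 1.35 h/day reaches zero exactly
there), so late primate dynamics under the age-dependent model are
dominated by very fast cycling; this is the main reason age-dependent
founder estimates for primates should be read as order-of-magnitude. A
`scale` multiplier (e.g. 1.5× or 2× for hypothetical slower human cycles)
uniformly rescales T_C. The ln 2 convention is pinned by the doubling
property: with every division proliferative, P doubles once per T_C.

## Numerics

Integration is fixed-step classic Runge–Kutta (step 0.01 day by default)
on a uniform grid with every kink of the right-hand side — the strategy
switch tS and the cell-cycle anchor days — inserted exactly as grid
points, so the integrand is smooth within each step. Determinism across
platforms is preferred over adaptive stepping; the 0.5-day search lattice
and integer anchors are exact multiples of the step. Against the
closed-form constant-probability solution the integrator is accurate to
better than 1e−6 relative (tested on random tuples), and halving the step
moves final outputs by less than 1e−6 relative. Off-grid queries (e.g.
tM) interpolate linearly on the stored grid. The grid search integrates
all candidate strategies simultaneously (vectorized over candidates on a
shared grid containing every candidate's switch time), which is
numerically identical to per-candidate runs and roughly two orders of
magnitude faster.

## Strategy fitting and its identifiability

A species' strategy is fit by exhaustively scoring every lattice tuple
(α0, αS, βF in 0.1 steps; tS in 0.5-day steps inside the window) against
the layering constraint Ñ(tF) = Ñ(tM)/φ + ε, where φ is the deeper-layer
neuron fraction and tM the day deeper-layer production completes. Two
objective forms are provided: the default `eq4_absolute` scores |ε| in
per-founder neuron units; `fraction_error` scores the scale-free
|Ñ(tM)/Ñ(tF) − φ|. Ties break lexicographically on (tS, α0, αS, βF).

An important structural caveat, documented here deliberately: the
constraint is **one scalar condition on four parameters**, so its
solution set is (generically) a 3-dimensional manifold in strategy space.
On the default lattice, on the order of a hundred (mouse) to thousands
(primates) of tuples satisfy the constraint to within 1e−4 in the
deeper-layer fraction — far below any biologically meaningful
resolution. The argmin is therefore only weakly determined: tiny changes
in the objective form, the αF convention, or numerical error can move it
across the manifold. For this reason `fit_strategy` always returns the
full ranked table, the search should be read as characterizing the
solution *set*, and downstream founder inference defaults to the packaged
per-species **reference strategies** (the literature 4-tuples for each
cycle model, including the human 1.5×/2× cell-cycle variants) rather than
to a refit argmin. Selecting a unique tuple from the near-tie set would
require additional constraints (e.g. measured division-mode proportions
at specific ages) that are not part of this model.

## Sensitivity analysis

Around a reference strategy θ*, each coordinate is swept with the others
held fixed and scored by the normalized output deviation
S(θ) = |Ñ(tF; θ) − Ñ(tF; θ*)| / Ñ(tF; θ*), which is zero at θ*,
nonnegative, and independent of P0. Default sweeps use 9 points spanning
±20% of each parameter's admissible range ((0,1) for probabilities, the
neurogenesis window for tS) so the per-parameter maxima are comparable;
sweep points that violate the validity constraints are dropped and
reported. Around the mouse reference strategy the switch time tS
dominates the ranking (max S ≈ 0.65 vs ≤ 0.45 for the probability
parameters): *when* the switch to symmetric neurogenic divisions happens
matters more than the precise division-mode proportions.

## Founder-population inference

Adult neocortical neuron counts are converted to an end-of-neurogenesis
production target as N_target = N_adult × (1 − m) / (1 − d), with
immigrant interneuron fraction m (default 0.25) and post-neurogenesis
death fraction d (default 0.30): the locally produced survivors are the
non-immigrant share of adult neurons, inflated back through survival.
Both fractions are configurable, so alternative readings of the
corrections are directly testable.

Because the model is linear in P0, the point estimate
P0 = N_target / Ñ(tF) is exact. The rejection-ABC sampler is retained as
the general-purpose route: P0 is drawn log-uniformly from a prior
(default [1e2, 1e9] cells), the absolute output is computed for each
draw, and draws with |N(tF) − N_target| / N_target ≤ tolerance (default
0.01) are accepted; the sampler is reproducible from its seed and its
settings are recorded in the result. The linearity is exploited
computationally: each draw's output is evaluated as P0 · Ñ(tF) from a
single per-founder integration, which is exactly equal to integrating
per draw (verified to machine precision in the tests). The posterior
mean concentrates on the analytic estimate as the tolerance shrinks
(tested at tolerances 0.1, 0.01, 0.001).

With the reference strategies and baseline demographics, the constant
cell-cycle model gives P0 ≈ 1.95 × 10⁵ (mouse), 5.9 × 10⁵ (macaque) and
1.1 × 10⁵ (human): the human founder population comes out *below* both
mouse and macaque despite a ~10-fold larger neurogenic output, because
the long human window with a late switch amplifies each founder far
more. The ordering P0(human) < P0(mouse) < P0(macaque) holds for both
cycle models and is insensitive to the demographic corrections (which
rescale all species proportionally): it persists for death fractions up
to 0.8 and immigration up to 0.5. It can break under large uniform
human cell-cycle amplification (the 1.5×/2× variants), which is why
those sweeps are built in.

## Synthetic data and what the tests show

Unit and property tests use the packaged species, plus synthetic species
parameterizations (random but valid timing windows, layer fractions and
demographic constants) and a small toy species for fast search
bookkeeping. These synthetic inputs emulate the *structure* of real
parameterizations, not measured biology: passing tests demonstrate
correctness of the dynamics, search, and inference machinery, and
internal consistency of the packaged constants — not the empirical
adequacy of the two-population model itself, which pools heterogeneous
progenitor types and ignores space, death and stochasticity.

Problem sizes used by the default test and acceptance runs: grid searches
evaluate 6,750 (mouse), 53,550 (macaque) and 68,850 (human) candidate
strategies at the 0.01-day step; ABC uses 1e5 draws. Degenerate inputs
are handled explicitly: zero neuron output raises on fraction or founder
queries, empty/invalid search grids raise, ABC with an empty acceptance
set raises rather than returning an empty posterior, and extrapolated
cell-cycle lengths are floored at 1 h.

## Known limitations

* The deterministic continuum model has no demographic stochasticity;
  founder estimates are point-identified only through N(tF).
* The strategy argmin is not sharply identified (see above); treat
  fitted tuples as representatives of a solution set.
* Primate age-dependent dynamics depend strongly on the cell-cycle
  extrapolation rule beyond the last measured anchor (E80).
* Human cell-cycle and layering parameters are macaque proxies; the
  1.5×/2× variants bracket, but do not resolve, that uncertainty.
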