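"""ODE integration: closed-form oracle, linearity, convergence, shape."""

import numpy as np
import pytest

from corticogenesis import (
    Strategy,
    closed_form_constant,
    constant_cycle,
    deeper_layer_fraction,
    for_species,
    load_species,
    reference_strategy,
    simulate,
    simulate_batch,
    simulate_constant,
)
from corticogenesis.cell_cycle import LN2


class TestDegenerateRegimes:
    def test_pure_doubling_three_cycles(self):
        # alpha = beta = 0, TC = 24 h, three days: P = 2^3, no neurons
        traj = simulate_constant(0.0, 0.0, constant_cycle(24.0), (0.0, 3.0))
        assert traj.final_progenitors == pytest.approx(8.0, rel=1e-9)
        assert traj.final_neurons == pytest.approx(0.0, abs=1e-12)

    def test_all_asymmetric_keeps_pool_constant(self):
        # alpha = 1: every division renews the progenitor and adds a neuron
        rho = LN2 * 24 / 14.3
        traj = simulate_constant(1.0, 0.0, constant_cycle(14.3), (0.0, 5.0), P0=3.0)
        assert np.allclose(traj.P, 3.0, rtol=1e-12)
        assert traj.final_neurons == pytest.approx(3.0 * rho * 5.0, rel=1e-9)

    def test_closed_form_degenerate_k_branch(self):
        P, N = closed_form_constant(1.0, 0.0, 0.7, (0.0, 4.0), P0=2.0, t=4.0)
        assert P == pytest.approx(2.0)
        assert N == pytest.approx(2.0 * 0.7 * 4.0)

    def test_closed_form_pure_symmetric_consumption_limit(self):
        # alpha=0, beta=1: P decays, each progenitor yields 2 neurons in total
        P, N = closed_form_constant(0.0, 1.0, 1.3, (0.0, 60.0), P0=5.0, t=60.0)
        assert P == pytest.approx(5.0 * np.exp(-1.3 * 60.0))
        assert N == pytest.approx(10.0, rel=1e-6)


class TestOracleEquivalence:
    def test_rk4_matches_closed_form_on_random_constants(self):
        """Fixed-step RK4 agrees with the exact constant-probability
        solution to < 1e-6 relative error at every stored time."""
        rng = np.random.default_rng(20240917)
        for _ in range(100):
            alpha = rng.uniform(0.0, 1.0)
            beta = rng.uniform(0.0, 1.0 - alpha)
            rho = rng.uniform(0.1, 2.0)
            Tc_hours = LN2 * 24.0 / rho
            window = (0.0, rng.uniform(1.0, 5.0))
            traj = simulate_constant(alpha, beta, constant_cycle(Tc_hours), window)
            P_exact, N_exact = closed_form_constant(
                alpha, beta, rho, window, 1.0, traj.times
            )
            assert np.allclose(traj.P, P_exact, rtol=1e-6, atol=0)
            scale = max(N_exact[-1], 1e-12)
            assert np.max(np.abs(traj.N - N_exact)) / scale < 1e-6


class TestLinearityAndConvergence:
    def test_linearity_in_founder_population(self, mouse, mouse_cycle, mouse_reference):
        one = simulate(mouse_reference, mouse_cycle, mouse.window, P0=1.0)
        many = simulate(mouse_reference, mouse_cycle, mouse.window, P0=375000.0)
        assert np.allclose(many.P, 375000.0 * one.P, rtol=1e-12)
        assert np.allclose(many.N, 375000.0 * one.N, rtol=1e-12)

    def test_step_halving_converged(self, mouse, mouse_cycle, mouse_reference):
        coarse = simulate(mouse_reference, mouse_cycle, mouse.window, step=0.01)
        fine = simulate(mouse_reference, mouse_cycle, mouse.window, step=0.005)
        assert fine.final_progenitors == pytest.approx(
            coarse.final_progenitors, rel=1e-6
        )
        assert fine.final_neurons == pytest.approx(coarse.final_neurons, rel=1e-6)

    def test_batch_matches_single_runs(self, mouse, mouse_age_cycle):
        strategies = [
            Strategy(0.4, 0.5, 0.7, 14.0),
            Strategy(0.2, 0.7, 1.0, 16.0),
            Strategy(0.1, 0.9, 0.3, 12.5),
        ]
        P, N = simulate_batch(
            np.array([s.alpha0 for s in strategies]),
            np.array([s.alphaS for s in strategies]),
            np.array([s.betaF for s in strategies]),
            np.array([s.tS for s in strategies]),
            mouse_age_cycle,
            mouse.window,
            query_times=[mouse.tM, mouse.tF],
        )
        for j, s in enumerate(strategies):
            traj = simulate(s, mouse_age_cycle, mouse.window)
            assert N[0, j] == pytest.approx(traj.neurons_at(mouse.tM), rel=1e-9)
            assert N[1, j] == pytest.approx(traj.final_neurons, rel=1e-9)
            assert P[1, j] == pytest.approx(traj.final_progenitors, rel=1e-9)


class TestTrajectoryProperties:
    def test_initial_conditions_and_monotone_neurons(
        self, mouse, mouse_cycle, mouse_reference
    ):
        traj = simulate(mouse_reference, mouse_cycle, mouse.window, P0=7.0)
        assert traj.P[0] == 7.0
        assert traj.N[0] == 0.0
        assert np.all(np.diff(traj.N) >= 0)
        assert np.all(traj.P > 0)

    @pytest.mark.parametrize("name", ["mouse", "macaque"])
    def test_fitted_strategies_expand_then_shrink_the_pool(self, name):
        """The proliferative zone grows and then contracts, without
        depleting by the end of neurogenesis."""
        sp = load_species(name)
        traj = simulate(
            reference_strategy(name), for_species(name), sp.window
        )
        peak = np.argmax(traj.P)
        assert 0 < peak < len(traj.P) - 1
        assert traj.P[-1] < traj.P[peak]
        assert traj.final_progenitors > 0

    def test_human_pool_shrinks_under_complement_terminal_alpha(self):
        """With betaF = 0.5 and a vanishing terminal AsymN the human pool
        plateaus (net growth rate reaches exactly zero at tF); under the
        complement convention late AsymN persists and the pool contracts."""
        sp = load_species("human")
        strat = reference_strategy("human")
        plateau = simulate(strat, for_species("human"), sp.window)
        assert np.all(np.diff(plateau.P) >= 0)
        shrink = simulate(
            strat, for_species("human"), sp.window, terminal_alpha="complement"
        )
        assert shrink.final_progenitors < np.max(shrink.P)
        assert shrink.final_progenitors > 0

    def test_invalid_strategy_rejected(self, mouse, mouse_cycle):
        with pytest.raises(ValueError, match="invalid strategy"):
            simulate(Strategy(0.5, 0.4, 0.7, 14.0), mouse_cycle, mouse.window)

    def test_switch_time_lands_on_grid(self, mouse, mouse_cycle):
        traj = simulate(Strategy(0.4, 0.5, 0.7, 14.321), mouse_cycle, mouse.window)
        assert np.any(np.isclose(traj.times, 14.321))


class TestDeeperLayerFraction:
    def test_identity_at_final_time_raises(self, mouse, mouse_cycle, mouse_reference):
        traj = simulate(mouse_reference, mouse_cycle, mouse.window)
        with pytest.raises(ValueError):
            deeper_layer_fraction(traj, mouse.tF)  # tM must be interior

    def test_fraction_in_unit_interval_and_monotone(
        self, mouse, mouse_cycle, mouse_reference
    ):
        traj = simulate(mouse_reference, mouse_cycle, mouse.window)
        fracs = [deeper_layer_fraction(traj, tM) for tM in (13.0, 15.0, 17.0)]
        assert all(0 <= f <= 1 for f in fracs)
        assert fracs == sorted(fracs)

    def test_zero_output_is_an_error(self, mouse):
        traj = simulate_constant(0.0, 0.0, constant_cycle(14.3), mouse.window)
        with pytest.raises(ZeroDivisionError):
            deeper_layer_fraction(traj, 17.0)
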