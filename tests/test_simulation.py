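"""ODE compilation, piecewise-event integration, and trajectory I/O."""

import numpy as np
import pytest

from pathdyn import (
    FixtureSpec,
    Intervention,
    KineticExpression,
    Parameter,
    Reaction,
    ReactionNetwork,
    Regime,
    Species,
    compile_odes,
    integrated_signal,
    make_fixture,
    read_trajectory,
    simulate,
    write_trajectory,
)
from pathdyn.errors import IntegrityError, UnknownTargetError, ValidationError

from helpers import conserved_total, rk4_sample


def _ab_network(k=0.1):
    net = ReactionNetwork(id="ab")
    net.species = [Species("A", "A", 10.0), Species("B", "B", 0.0)]
    net.parameters = [Parameter("k", k)]
    net.reactions = [
        Reaction("r", [("A", 1.0)], [("B", 1.0)],
                 kinetic_law=KineticExpression("k*A"))
    ]
    return net.validate()


class TestCompileOdes:
    def test_mass_action_derivatives_and_velocity(self):
        sys = compile_odes(_ab_network(k=0.1))
        v = sys.velocities(0.0, np.array([10.0, 0.0]), np.array([0.1]))
        dy = sys.rhs(0.0, np.array([10.0, 0.0]), np.array([0.1]))
        assert v == pytest.approx([1.0])
        assert dy == pytest.approx([-1.0, 1.0])

    def test_second_order_stoichiometry(self):
        # 2A -> B with v = k*A^2: at k=0.5, A=2 the rate is 2, dA/dt=-4, dB/dt=+2
        net = ReactionNetwork(id="dimer")
        net.species = [Species("A", "A", 2.0), Species("B", "B", 0.0)]
        net.parameters = [Parameter("k", 0.5)]
        net.reactions = [
            Reaction("r", [("A", 2.0)], [("B", 1.0)],
                     kinetic_law=KineticExpression("k*A**2"))
        ]
        sys = compile_odes(net.validate())
        y, p = np.array([2.0, 0.0]), np.array([0.5])
        assert sys.velocities(0.0, y, p) == pytest.approx([2.0])
        assert sys.rhs(0.0, y, p) == pytest.approx([-4.0, 2.0])

    def test_zero_rate_constants_give_zero_derivatives(self):
        sys = compile_odes(_ab_network(k=0.0))
        dy = sys.rhs(0.0, np.array([10.0, 0.0]), np.array([0.0]))
        assert np.all(dy == 0.0)

    def test_boundary_species_held_constant(self):
        net = _ab_network()
        net.species[1] = Species("B", "B", 0.0, is_boundary=True)
        traj = simulate(net, t_end=5.0, n_points=11)
        assert np.all(traj.species_series("B") == 0.0)

    def test_unresolved_symbol_is_named_in_compile_error(self):
        net = _ab_network()
        net.reactions[0].kinetic_law = KineticExpression("k*A*mystery")
        with pytest.raises(IntegrityError, match="mystery"):
            compile_odes(net)


class TestSimulate:
    def test_decay_matches_closed_form(self, decay_fx):
        traj = simulate(decay_fx.network, t_end=10.0)
        expected = 10.0 * np.exp(-0.1 * traj.time_grid)
        rel = np.abs(traj.species_series("A") - expected) / expected
        assert rel.max() < 1e-6

    def test_grid_is_uniform_and_covers_0_to_t_end(self, decay_fx):
        traj = simulate(decay_fx.network, t_end=10.0, n_points=601)
        assert traj.time_grid[0] == 0.0 and traj.time_grid[-1] == 10.0
        assert np.allclose(np.diff(traj.time_grid), 10.0 / 600)
        assert traj.concentrations.shape == (2, 601)
        assert traj.velocities.shape == (1, 601)

    def test_mass_conservation_in_closed_networks(self, reversible_fx, receptor_fx):
        for fx in (reversible_fx, receptor_fx):
            traj = simulate(fx.network, t_end=10.0)
            for name, members in fx.properties["conserved_totals"].items():
                tot = conserved_total(traj, members)
                drift = np.abs(tot - tot[0]).max() / max(tot[0], 1e-12)
                assert drift < 1e-6, (fx.network.id, name)

    def test_dose_event_pre_identity_and_exact_jump(self, receptor_fx):
        """Before a t=5 dose the run is bit-identical to the untreated run;
        at t=5 the target jumps by exactly the dosage."""
        dose = Regime("Dosed", [Intervention("dose", "I", 30.0, 5.0)])
        base = simulate(receptor_fx.network, t_end=10.0, n_points=101)
        treated = simulate(receptor_fx.network, dose, t_end=10.0, n_points=101)
        pre = base.time_grid < 5.0
        assert np.array_equal(base.concentrations[:, pre],
                              treated.concentrations[:, pre])
        j = treated.grid_index(5.0)
        i_row = treated.species_ids.index("I")
        assert treated.concentrations[i_row, j] == base.concentrations[i_row, j] + 30.0

    def test_off_grid_intervention_splits_segment(self, decay_fx):
        dose = Regime("Dosed", [Intervention("set_concentration", "A", 20.0, 3.1415)])
        traj = simulate(decay_fx.network, dose, t_end=10.0, n_points=101)
        a = traj.species_series("A")
        j_after = int(np.searchsorted(traj.time_grid, 3.1415))
        expected = 20.0 * np.exp(-0.1 * (traj.time_grid[j_after] - 3.1415))
        assert a[j_after] == pytest.approx(expected, rel=1e-8)

    def test_grid_refinement_leaves_solution_unchanged(self, receptor_fx):
        coarse = simulate(receptor_fx.network, t_end=10.0, n_points=51)
        fine = simulate(receptor_fx.network, t_end=10.0, n_points=101)
        diff = np.abs(fine.concentrations[:, ::2] - coarse.concentrations).max()
        assert diff < 1e-7

    def test_rk4_oracle_agreement_on_small_fixtures(self):
        """Independent fixed-step RK4 confirms the adaptive solution."""
        for motif in ("decay", "reversible_pair", "linear_cascade"):
            fx = make_fixture(FixtureSpec(motif=motif))
            traj = simulate(fx.network, t_end=10.0, n_points=51)
            sys = compile_odes(fx.network)
            oracle = rk4_sample(sys, sys.parameter_values, 10.0, 1e-3,
                                traj.time_grid)
            scale = np.abs(oracle).max()
            assert np.abs(traj.concentrations - oracle).max() / scale < 1e-5, motif

    def test_parameter_interventions_change_dynamics(self, decay_fx):
        freeze = Regime("Freeze", [Intervention("scale_parameter", "k_decay", 0.0, 5.0)])
        traj = simulate(decay_fx.network, freeze, t_end=10.0, n_points=101)
        a = traj.species_series("A")
        j = traj.grid_index(5.0)
        assert np.allclose(a[j:], a[j])  # decay frozen from t=5 on
        assert a[j] < a[0]

    def test_invalid_arguments_rejected(self, decay_fx):
        with pytest.raises(ValidationError):
            simulate(decay_fx.network, t_end=0.0)
        with pytest.raises(ValidationError):
            simulate(decay_fx.network, t_end=10.0, n_points=1)


class TestIntegratedSignal:
    def test_constant_and_zero_signals(self, reversible_fx):
        net = reversible_fx.network
        zero = Regime("Zero", [Intervention("scale_parameter", "k_f", 0.0),
                               Intervention("scale_parameter", "k_r", 0.0)])
        traj = simulate(net, zero, t_end=10.0, n_points=11)
        assert integrated_signal(traj, "A", (0.0, 10.0)) == pytest.approx(80.0)
        b0 = traj.species_series("B")[0]
        assert integrated_signal(traj, "B") == pytest.approx(10 * b0)

    def test_exponential_closed_form(self, decay_fx):
        traj = simulate(decay_fx.network, t_end=10.0, n_points=601)
        val = integrated_signal(traj, "A", (0.0, 10.0))
        assert val == pytest.approx(100.0 * (1 - np.exp(-1.0)), rel=1e-4)

    def test_unknown_species_and_bad_window(self, decay_fx):
        traj = simulate(decay_fx.network, t_end=10.0, n_points=11)
        with pytest.raises(UnknownTargetError):
            integrated_signal(traj, "GHOST")
        with pytest.raises(ValidationError):
            integrated_signal(traj, "A", (0.0, 99.0))


def test_trajectory_csv_round_trip(tmp_path, receptor_fx, receptor_suite):
    traj = simulate(receptor_fx.network, receptor_suite[1], t_end=10.0, n_points=61)
    write_trajectory(traj, tmp_path)
    reread = read_trajectory(tmp_path)
    assert reread.species_ids == traj.species_ids
    assert reread.reaction_ids == traj.reaction_ids
    assert reread.regime_label == traj.regime_label
    assert np.allclose(reread.concentrations, traj.concentrations,
                       rtol=1e-10, atol=1e-12)
    assert np.allclose(reread.velocities, traj.velocities, rtol=1e-10, atol=1e-12)
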