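"""Single- and multi-population right-hand sides, equilibria, integration."""
import numpy as np
import pytest

import neuromass as nm
from neuromass.fixed_points import single_fixed_points, classify_fixed_point


class TestSingleRHS:
    def test_rate_derivative_at_origin(self):
        p = nm.NeuralMassParams(tau_m=20.0, delta=1.0, eta_bar=0.0)
        dr, dv = nm.single_rhs(0.0, 0.0, p)
        assert dr == pytest.approx(1.0 / (400.0 * np.pi), rel=1e-12)
        assert dv == 0.0

    def test_rate_derivative_linear_in_delta(self):
        p1 = nm.NeuralMassParams(delta=1.0, eta_bar=-3.0)
        p2 = nm.NeuralMassParams(delta=2.0, eta_bar=-3.0)
        dr1, _ = nm.single_rhs(0.0, 0.5, p1)
        dr2, _ = nm.single_rhs(0.0, 0.5, p2)
        assert dr2 == pytest.approx(2.0 * dr1, rel=1e-12)

    @pytest.mark.parametrize("eta,J", [(-6.0, 20.0), (-50.0, 0.0), (4.0, 0.0)])
    def test_vanishes_at_fixed_points(self, eta, J):
        p = nm.NeuralMassParams(eta_bar=eta)
        for fp in single_fixed_points(eta, J_self=J):
            dr, dv = nm.single_rhs(fp.r_star, fp.v_star, p, J_self=J)
            assert max(abs(dr), abs(dv)) < 1e-10

    def test_rejects_nonfinite_state(self):
        p = nm.NeuralMassParams()
        with pytest.raises(ValueError):
            nm.single_rhs(np.nan, 0.0, p)


class TestNetworkRHS:
    def test_decoupled_equals_single(self):
        n = 4
        J = np.diag(np.full(n, 20.0))
        p = nm.NeuralMassParams(eta_bar=-6.0)
        state = nm.NetworkState(np.full(n, 0.03), np.full(n, -0.5))
        dr, dv = nm.network_rhs(state, p, J)
        dr1, dv1 = nm.single_rhs(0.03, -0.5, p, J_self=20.0)
        assert np.allclose(dr, dr1) and np.allclose(dv, dv1)

    def test_coupling_current_vanishes_at_zero_rates(self):
        J = np.array([[20.0, 5.0], [5.0, 20.0]])
        p = nm.NeuralMassParams(eta_bar=-6.0)
        s = nm.NetworkState(np.zeros(2), np.array([-1.0, -2.0]))
        _, dv = nm.network_rhs(s, p, J)
        _, dv0 = nm.network_rhs(s, p, np.diag([20.0, 20.0]))
        assert np.allclose(dv, dv0)

    def test_two_node_coupling_contribution(self):
        # tau_m * J_12 * r_2 = 20 * 5 * 0.05 = 5 inside the voltage bracket
        p = nm.NeuralMassParams(tau_m=20.0, eta_bar=0.0)
        s = nm.NetworkState(np.array([0.0, 0.05]), np.zeros(2))
        Jc = np.array([[0.0, 5.0], [0.0, 0.0]])
        _, dv = nm.network_rhs(s, p, Jc)
        _, dv0 = nm.network_rhs(s, p, np.zeros((2, 2)))
        assert (dv[0] - dv0[0]) * p.tau_m == pytest.approx(5.0, rel=1e-12)

    def test_dimension_mismatch_raises(self):
        p = nm.NeuralMassParams()
        s = nm.NetworkState(np.zeros(3), np.zeros(3))
        with pytest.raises(ValueError):
            nm.network_rhs(s, p, np.zeros((2, 2)))


class TestIntegrate:
    def test_relaxes_to_la_root(self):
        p = nm.NeuralMassParams(eta_bar=-50.0)
        st = nm.relax(p, np.zeros((1, 1)), nm.NetworkState.zeros(1), 2000.0)
        fp = single_fixed_points(-50.0)[0]
        assert abs(st.r[0] - fp.r_star) < 1e-6
        assert abs(st.v[0] - fp.v_star) < 1e-6

    def test_dt_convergence(self):
        p = nm.NeuralMassParams(eta_bar=-50.0)
        s1 = nm.relax(p, np.zeros((1, 1)), nm.NetworkState.zeros(1), 500.0,
                      dt=0.01)
        s2 = nm.relax(p, np.zeros((1, 1)), nm.NetworkState.zeros(1), 500.0,
                      dt=0.005)
        assert abs(s1.r[0] - s2.r[0]) < 1e-8
        assert abs(s1.v[0] - s2.v[0]) < 1e-8

    def test_zero_amplitude_stimulus_is_identity(self):
        p = nm.NeuralMassParams(eta_bar=-9.0)
        J = np.diag([20.0, 20.0])
        stim = nm.StimulusProtocol(targets=(0,), amplitude=0.0, t_on=100.0)
        t1 = nm.integrate(p, J, nm.NetworkState.zeros(2), 800.0,
                          stimulus=stim)
        t2 = nm.integrate(p, J, nm.NetworkState.zeros(2), 800.0)
        assert np.array_equal(t1.r, t2.r) and np.array_equal(t1.v, t2.v)

    def test_divergence_raises_with_time(self):
        p = nm.NeuralMassParams(eta_bar=0.0)
        s0 = nm.NetworkState(np.zeros(1), np.full(1, 1e8))
        with pytest.raises(nm.IntegrationError, match="t ="):
            nm.integrate(p, np.zeros((1, 1)), s0, 100.0)

    def test_rate_positivity_preserved(self):
        # rate stays positive along the trajectory (dr/dt > 0 at r = 0)
        p = nm.NeuralMassParams(eta_bar=-9.0)
        J = np.array([[20.0, 3.0], [3.0, 20.0]])
        stim = nm.StimulusProtocol(targets=(0,), amplitude=10.0, t_on=500.0)
        traj = nm.integrate(p, J, nm.NetworkState.zeros(2), 3000.0,
                            stimulus=stim)
        assert np.all(traj.r[1:] > 0)  # dr/dt > 0 lifts r off zero at once


class TestFixedPoints:
    def test_small_delta_limit_matches_single_neuron_rate(self):
        # Delta -> 0, J = 0, eta > 0: r* -> sqrt(eta)/(pi tau), v* -> 0
        fps = single_fixed_points(4.0, delta=1e-9, tau_m=20.0, J_self=0.0)
        assert len(fps) == 1
        assert fps[0].r_star == pytest.approx(2.0 / (np.pi * 20.0), rel=1e-4)
        assert abs(fps[0].v_star) < 1e-4

    def test_bistable_window_root_structure(self):
        fps = single_fixed_points(-6.0, J_self=20.0)
        assert len(fps) == 3
        assert [f.stability for f in fps] == [
            "stable_node", "saddle", "stable_focus",
        ]
        assert fps[0].r_star < fps[1].r_star < fps[2].r_star

    def test_roots_sorted_and_consistent(self):
        for eta in (-12.0, -8.0, -4.0, 0.0):
            fps = single_fixed_points(eta, J_self=20.0)
            rs = [f.r_star for f in fps]
            assert rs == sorted(rs)
            assert 1 <= len(fps) <= 3

    def test_classify_matches_labels(self):
        # deep-LA equilibrium with recurrent excitation: a stable node
        fps = single_fixed_points(-50.0, J_self=20.0)
        assert classify_fixed_point(fps[0], J_self=20.0) == "stable_node"
        ha = single_fixed_points(-6.0, J_self=20.0)[2]
        assert classify_fixed_point(ha, J_self=20.0) == "stable_focus"
        assert any(abs(ev.imag) > 0 for ev in ha.eigenvalues)

    def test_classify_rejects_non_equilibrium(self):
        fp = nm.FixedPoint(0.05, -0.5, (0j, 0j), "stable_node")
        with pytest.raises(ValueError):
            classify_fixed_point(fp, J_self=20.0, eta_bar=-6.0)

    def test_damped_oscillation_onto_focus(self):
        # approach to the HA focus crosses its terminal voltage repeatedly
        fp = single_fixed_points(-5.0, J_self=20.0)[2]
        p = nm.NeuralMassParams(eta_bar=-5.0)
        s0 = nm.NetworkState(np.array([fp.r_star * 1.3]),
                             np.array([fp.v_star]))
        traj = nm.integrate(p, np.array([[20.0]]), s0, 1500.0)
        crossings = np.sum(np.diff(np.sign(traj.v[:, 0] - traj.v[-1, 0])) != 0)
        assert crossings >= 3


class TestPhaseDiagram:
    def test_no_bistability_without_recurrent_excitation(self):
        labels = nm.single_phase_diagram(np.linspace(-12, 4, 17), [0.0])
        assert "bistable" not in labels

    def test_deep_negative_eta_always_la(self):
        labels = nm.single_phase_diagram([-50.0], np.linspace(0, 20, 9))
        assert set(labels.ravel()) == {"LA_only"}

    def test_three_contiguous_regions_at_strong_coupling(self):
        etas = np.linspace(-14, 0, 57)
        labels = nm.single_phase_diagram(etas, [20.0])[0]
        core = [l for l in labels if l != "boundary"]
        assert set(core) == {"LA_only", "bistable", "HA_focus_only"}
        # one saddle-node pair: transitions LA -> bistable -> HA, no return
        collapsed = [core[0]]
        for l in core[1:]:
            if l != collapsed[-1]:
                collapsed.append(l)
        assert collapsed == ["LA_only", "bistable", "HA_focus_only"]


class TestLorentzianSampling:
    def test_three_point_closed_form(self):
        assert nm.sample_lorentzian(0.0, 1.0, 3) == pytest.approx(
            [-1.0, 0.0, 1.0], abs=1e-12
        )

    def test_median_is_center_for_odd_n(self):
        s = nm.sample_lorentzian(-7.3, 2.0, 101)
        assert np.median(s) == pytest.approx(-7.3, abs=1e-12)

    def test_random_scheme_reproducible(self):
        a = nm.sample_lorentzian(0.0, 1.0, 50, scheme="random", seed=3)
        b = nm.sample_lorentzian(0.0, 1.0, 50, scheme="random", seed=3)
        assert np.array_equal(a, b)
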