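"""Unit and property tests for the electrostatic MEMS network core."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from memsctrnn import mems
from memsctrnn.mems import (
    MEMSParams,
    NetworkState,
    NetworkWeights,
    PowerModel,
    StabilityError,
    VoltageDivergenceError,
    mems_step,
    network_power,
    node_voltages,
    release_voltage,
    scaled_time_constant,
    simulate_network,
    static_pullin_voltage,
    time_constant,
)


def make_weights(w_rec, theta, w_in=None, w_out=None):
    n = len(theta)
    return NetworkWeights(
        w_rec=np.asarray(w_rec, dtype=float),
        w_in=np.zeros((n, 1)) if w_in is None else np.asarray(w_in, dtype=float),
        theta=np.asarray(theta, dtype=float),
        w_out=np.zeros((2, n)) if w_out is None else np.asarray(w_out, dtype=float),
    )


class TestNodeVoltages:
    def test_nothing_fired_gives_bias_voltages(self):
        w = make_weights(np.ones((3, 3)), [1.0, -2.0, 0.5])
        assert np.allclose(node_voltages(w, np.zeros(3)), w.theta)

    def test_single_fired_substitution(self):
        w = make_weights([[0.0, 1.0], [0.0, 0.0]], [0.0, 2.0])
        assert np.allclose(node_voltages(w, np.array([0.0, 1.0])), [2.0, 2.0])

    def test_matches_dense_linear_solve_on_fired_subsystem(self, rng):
        # independent oracle: eliminate un-fired nodes by hand, solve the
        # reduced fixed point, back-substitute
        for _ in range(20):
            n = int(rng.integers(2, 6))
            w = make_weights(rng.normal(scale=0.3, size=(n, n)), rng.normal(size=n))
            fired = (rng.random(n) < 0.5).astype(float)
            idx = np.flatnonzero(fired)
            sub = np.eye(len(idx)) - w.w_rec[np.ix_(idx, idx)]
            v_fired = np.linalg.solve(sub, w.theta[idx])
            expected = w.theta.copy()
            expected += w.w_rec[:, idx] @ v_fired
            expected[idx] = v_fired
            assert np.allclose(node_voltages(w, fired), expected)

    def test_divergent_recursion_raises(self):
        w = make_weights([[1.0]], [1.0])  # (I - W) singular once fired
        with pytest.raises(VoltageDivergenceError):
            node_voltages(w, np.ones(1))

    def test_wrong_length_rejected(self):
        w = make_weights(np.zeros((2, 2)), [0.0, 0.0])
        with pytest.raises(ValueError):
            node_voltages(w, np.zeros(3))


class TestMemsStep:
    def test_force_free_relaxation_is_exponential(self, params, single_neuron):
        z0 = 0.5 * params.d
        state = NetworkState(z=np.array([z0]), fired=np.zeros(1), V=np.zeros(1))
        dt = params.tau / 20
        max_rel = 0.0
        for _ in range(60):  # 3 tau
            state = mems_step(state, params, single_neuron, np.zeros(1), dt)
            exact = z0 * np.exp(-state.t / params.tau)
            max_rel = max(max_rel, abs(state.z[0] - exact) / exact)
        assert max_rel <= 2 * dt / params.tau

    def test_subcritical_voltage_settles_at_smallest_cubic_root(self, params, single_neuron):
        # oracle: smallest root of z (d - z)^2 = eps A V^2 / (2 k)
        V = 0.8 * static_pullin_voltage(params)
        rhs = params.force_coeff * V**2
        z_root = brentq(lambda z: z * (params.d - z) ** 2 - rhs, 0, params.d / 3)
        assert z_root < params.d / 3
        single_neuron.theta[0] = V
        state = NetworkState.initial(single_neuron)
        dt = params.tau / 10
        for _ in range(200):  # 20 tau
            state = mems_step(state, params, single_neuron, np.zeros(1), dt)
        assert state.z[0] == pytest.approx(z_root, rel=0.02)

    def test_displacement_always_inside_travel_bounds(self, params, single_neuron, rng):
        single_neuron.theta[0] = 1.2 * static_pullin_voltage(params)
        state = NetworkState.initial(single_neuron)
        dt = params.tau / 4
        for _ in range(200):
            state = mems_step(state, params, single_neuron, rng.normal(size=1), dt)
            assert 0.0 <= state.z[0] <= params.z_stop
            assert state.fired[0] == (state.z[0] >= params.z_fire)

    def test_too_large_dt_suggests_substepping(self, params, single_neuron):
        state = NetworkState.initial(single_neuron)
        with pytest.raises(StabilityError, match="sub-steps"):
            mems_step(state, params, single_neuron, np.zeros(1), dt=3 * params.tau)

    def test_nonpositive_dt_rejected(self, params, single_neuron):
        state = NetworkState.initial(single_neuron)
        with pytest.raises(ValueError):
            mems_step(state, params, single_neuron, np.zeros(1), dt=0.0)


def quasi_static_sweep(params, voltages, holds=40):
    """Simulated firing trace along a voltage schedule (quasi-static)."""
    w = make_weights(np.zeros((1, 1)), [0.0])
    state = NetworkState.initial(w)
    dt = params.tau / 4
    trace = np.zeros(len(voltages))
    for i, v in enumerate(voltages):
        w.theta[0] = v
        for _ in range(holds):
            state = mems_step(state, params, w, np.zeros(1), dt)
        trace[i] = state.fired[0]
    return trace


def equilibrium_tracking_oracle(params, voltages):
    """Brute-force continuation of the static balance z (d-z)^2 = c V^2.

    Tracks the equilibrium branch nearest the previous displacement and
    reports the first voltage with no reachable stable equilibrium on the
    way up (pull-in) and the first voltage where the latched branch
    vanishes on the way down (release).
    """
    z = 0.0
    pullin = release = None
    latched = False
    for v in voltages:
        rhs = params.force_coeff * v**2
        # stable branch exists below z = d/3
        f = lambda zz: zz * (params.d - zz) ** 2 - rhs
        if not latched:
            if f(params.d / 3) < 0:  # no equilibrium below the fold
                latched = True
                if pullin is None:
                    pullin = v
            else:
                z = brentq(f, 0, params.d / 3)
        else:
            # latched at the stopper; release when the electrostatic force
            # at the stopper falls below the spring restoring force
            if params.force_coeff * v**2 / (params.d - params.z_stop) ** 2 < params.z_stop:
                latched = False
                release = v
                z = brentq(f, 0, params.d / 3)
    return pullin, release


class TestHysteresis:
    def test_pullin_exceeds_release_and_matches_oracle(self, params):
        v_pi = static_pullin_voltage(params)
        up = np.linspace(0, 1.2 * v_pi, 300)
        down = up[::-1]
        trace = quasi_static_sweep(params, np.concatenate([up, down]))
        sim_pullin = up[trace[:300] > 0.5][0]
        sim_release = down[trace[300:] < 0.5][0]
        assert sim_pullin > sim_release  # hysteresis loop
        oracle_pullin, oracle_release = equilibrium_tracking_oracle(
            params, np.concatenate([up, down])
        )
        assert sim_pullin == pytest.approx(oracle_pullin, rel=0.01)
        assert sim_release == pytest.approx(oracle_release, rel=0.01)


class TestStaticPullin:
    def test_gap_scaling_law(self, params):
        import dataclasses

        doubled = dataclasses.replace(params, d=2 * params.d)
        assert static_pullin_voltage(doubled) == pytest.approx(
            2**1.5 * static_pullin_voltage(params)
        )

    def test_area_scaling_law(self, params):
        import dataclasses

        quad = dataclasses.replace(params, A=4 * params.A)
        assert static_pullin_voltage(quad) == pytest.approx(
            0.5 * static_pullin_voltage(params)
        )

    def test_is_largest_voltage_with_stable_equilibrium(self, params):
        # brute-force V sweep: classify existence of a root below d/3
        v_pi = static_pullin_voltage(params)
        voltages = np.linspace(0.01, 1.5 * v_pi, 400)
        has_stable = np.array(
            [v * 0 + (lambda rhs: rhs <= 4 * params.d**3 / 27)(params.force_coeff * v**2)
             for v in voltages],
            dtype=bool,
        )
        boundary = voltages[has_stable][-1]
        assert boundary == pytest.approx(v_pi, rel=0.01)

    def test_release_below_pullin(self, params):
        assert release_voltage(params) < static_pullin_voltage(params)


class TestSimulateNetwork:
    def test_zero_network_never_fires_scores_are_biases(self, params):
        w = make_weights(np.zeros((2, 2)), [0.0, 0.0], w_in=np.zeros((2, 3)))
        w.b_out = np.array([0.3, -0.7])
        traj, scores = simulate_network(np.zeros((3, 10)), params, w)
        assert not traj["fired"].any()
        assert np.allclose(scores, w.b_out)

    def test_subcritical_bias_never_fires_supercritical_fires_quickly(self, params):
        v_pi = static_pullin_voltage(params)
        w = make_weights(np.zeros((1, 1)), [0.95 * v_pi])
        traj, _ = simulate_network(np.zeros((1, 30)), params, w)
        assert not traj["fired"].any()
        w.theta[0] = 1.05 * v_pi
        # 10 tau = 17 ms < one 20 ms sample interval
        traj, _ = simulate_network(np.zeros((1, 1)), params, w, sample_dt=10 * params.tau)
        assert traj["fired"][-1, 0] == 1.0

    def test_self_convergence_under_substep_refinement(self, params, rng):
        w = make_weights(
            rng.uniform(-0.3, 0.3, size=(4, 4)),
            3.0 + rng.uniform(-0.3, 0.3, size=4),
            w_in=np.vstack([rng.uniform(-0.5, 0.5, size=(2, 2)), np.zeros((2, 2))]),
        )
        window = rng.normal(scale=2.0, size=(2, 15))
        traj1, _ = simulate_network(window, params, w, substeps=16)
        traj2, _ = simulate_network(window, params, w, substeps=32)
        scale = params.d
        assert np.max(np.abs(traj1["z"][-1] - traj2["z"][-1])) / scale < 0.05

    def test_deterministic_given_identical_arguments(self, params, rng):
        w = make_weights(
            rng.uniform(-0.3, 0.3, size=(3, 3)),
            3.0 + rng.uniform(-0.3, 0.3, size=3),
            w_in=rng.uniform(-0.5, 0.5, size=(3, 1)),
            w_out=rng.uniform(-1, 1, size=(2, 3)),
        )
        window = rng.normal(size=(1, 20))
        t1, s1 = simulate_network(window, params, w)
        t2, s2 = simulate_network(window, params, w)
        assert np.array_equal(s1, s2)
        assert np.array_equal(t1["z"], t2["z"])
        assert np.array_equal(t1["fired"], t2["fired"])


class TestTimeConstants:
    def test_direct_substitution(self):
        assert time_constant(1.0, 1000.0) == pytest.approx(0.002)
        assert time_constant(0.0, 500.0) == 0.0

    def test_scaling_omega_n_by_p_scales_tau_inversely(self):
        base = time_constant(0.85, 1000.0)
        for P in (0.25, 2.0, 10.0):
            assert time_constant(0.85, 1000.0 * P) == pytest.approx(base / P)

    def test_scaled_time_constant_values(self):
        assert scaled_time_constant(0.0017, 0.25) == pytest.approx(0.0068)
        assert scaled_time_constant(0.0017, 1.0) == pytest.approx(0.0017)
        assert scaled_time_constant(0.0017, 10.0) == pytest.approx(0.00017)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            time_constant(1.0, 0.0)
        with pytest.raises(ValueError):
            scaled_time_constant(0.0017, 0.0)


class TestPowerModel:
    def test_reference_operating_point(self):
        model = PowerModel()
        assert network_power(model, 1) == pytest.approx(6.25e-10)  # 0.625 nW/neuron
        # totals are exactly linear in the neuron count
        assert network_power(model, 100) == pytest.approx(100 * 6.25e-10)

    def test_zero_voltage_means_zero_power(self):
        model = PowerModel(V_op=0.0)
        for n in (0, 1, 57):
            assert network_power(model, n) == 0.0

    @settings(deadline=None, derandomize=True)
    @given(
        n=st.integers(min_value=0, max_value=10_000),
        scale=st.floats(min_value=0.1, max_value=10.0),
    )
    def test_linear_in_count_quadratic_in_voltage(self, n, scale):
        base = PowerModel()
        scaled = PowerModel(V_op=base.V_op * scale)
        assert network_power(base, n) == pytest.approx(n * network_power(base, 1))
        assert network_power(scaled, 1) == pytest.approx(
            scale**2 * network_power(base, 1)
        )

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            network_power(PowerModel(), -1)


class TestValidation:
    def test_params_invariants(self):
        with pytest.raises(ValueError):
            MEMSParams(d=-1.0)
        with pytest.raises(ValueError):
            MEMSParams(fire_frac=0.99, contact_frac=0.95)
        with pytest.raises(ValueError):
            MEMSParams(zeta=0.0)  # tau must stay positive

    def test_weight_shape_checks(self):
        with pytest.raises(ValueError):
            NetworkWeights(np.zeros((2, 3)), np.zeros((2, 1)), np.zeros(2), np.zeros((2, 2)))
        with pytest.raises(ValueError):
            NetworkWeights(
                np.full((2, 2), np.nan), np.zeros((2, 1)), np.zeros(2), np.zeros((2, 2))
            )
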