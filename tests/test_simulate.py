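"""Threshold-fire-reset dynamics, motor readout and the virtual arena."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import wormnet as wn
from conftest import random_connectome, scalar_step_oracle


def make_pair(weight):
    """Two neurons where A receives `weight` when B fires."""
    return wn.connectome_from_edges(
        [wn.Edge(pre="B", post="A", kind="chemical", weight=weight)]
    )


class TestStepNetwork:
    def test_subthreshold_quiescence_is_a_fixed_point(self, two_neuron_connectome):
        state = wn.NetworkState(values=np.array([1.0, 2.0]))
        nxt = wn.step_network(state, two_neuron_connectome, h=30.0, external=np.zeros(2))
        assert np.array_equal(nxt.values, state.values)

    def test_excitatory_fire_and_reset(self):
        conn = make_pair(5.0)
        nxt = wn.step_network(
            wn.NetworkState(values=np.array([2.0, 4.0])), conn, h=3.0, external=np.zeros(2)
        )
        assert nxt.values.tolist() == [7.0, 0.0]

    def test_inhibitory_weight_drives_state_negative(self):
        conn = make_pair(-5.0)
        nxt = wn.step_network(
            wn.NetworkState(values=np.array([2.0, 31.0])), conn, h=30.0, external=np.zeros(2)
        )
        assert nxt.values.tolist() == [-3.0, 0.0]

    def test_exactly_at_threshold_does_not_fire(self):
        conn = make_pair(5.0)
        nxt = wn.step_network(
            wn.NetworkState(values=np.array([0.0, 3.0])), conn, h=3.0, external=np.zeros(2)
        )
        assert nxt.values.tolist() == [0.0, 3.0]

    def test_dimension_mismatch_rejected(self, two_neuron_connectome):
        with pytest.raises(ValueError):
            wn.step_network(
                wn.NetworkState(values=np.zeros(3)),
                two_neuron_connectome,
                h=30.0,
                external=np.zeros(3),
            )

    def test_non_finite_state_rejected(self, two_neuron_connectome):
        with pytest.raises(ValueError):
            wn.step_network(
                wn.NetworkState(values=np.array([np.nan, 0.0])),
                two_neuron_connectome,
                h=30.0,
                external=np.zeros(2),
            )


class TestRunSimulation:
    def test_unstimulated_edgeless_network_stays_silent(self):
        conn = wn.Connectome(
            neurons=[wn.Neuron.from_name("A"), wn.Neuron.from_name("B")],
            weight_matrix=np.zeros((2, 2)),
        )
        trace = wn.run_simulation(conn, wn.SimConfig(duration=20, threshold=30.0))
        assert np.all(trace.states == 0)
        assert trace.states.shape == (21, 2)

    def test_unknown_protocol_neuron_rejected_before_stepping(self, planted_small):
        _, conn, _, _ = planted_small
        proto = wn.StimulationProtocol(
            schedule=[(0, frozenset({"NOPE"}), 1.0)], duration=1
        )
        with pytest.raises(ValueError, match="NOPE"):
            wn.run_simulation(conn, wn.SimConfig(duration=10, threshold=30.0), proto)

    def test_deterministic_under_fixed_seed(self, planted_small):
        _, conn, proto, _ = planted_small
        cfg = wn.SimConfig(duration=256, threshold=30.0, seed=5, init="random")
        a = wn.run_simulation(conn, cfg, proto)
        b = wn.run_simulation(conn, cfg, proto)
        assert np.array_equal(a.states, b.states)

    def test_reset_to_zero_after_firing(self):
        rng = np.random.default_rng(0)
        conn = random_connectome(rng)
        cfg = wn.SimConfig(duration=50, threshold=5.0, seed=1, init="random")
        trace = wn.run_simulation(conn, cfg)
        for name in trace.names:
            j = trace.names.index(name)
            for t in trace.firing_times(name):
                if t < trace.duration:
                    assert trace.states[t + 1, j] == 0.0

    def test_nonneg_weights_monotone_until_first_firing(self):
        conn = wn.connectome_from_edges(
            [
                wn.Edge("A", "B", "chemical", 2.0),
                wn.Edge("B", "A", "chemical", 3.0),
            ]
        )
        cfg = wn.SimConfig(
            duration=40, threshold=10.0, initial_values=np.array([9.0, 11.0])
        )
        trace = wn.run_simulation(conn, cfg)
        for j in range(2):
            col = trace.states[:, j]
            fires = np.nonzero(col > 10.0)[0]
            upto = fires[0] if fires.size else len(col) - 1
            assert np.all(np.diff(col[: upto + 1]) >= 0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_vectorized_step_matches_scalar_oracle(self, seed):
        rng = np.random.default_rng(seed)
        conn = random_connectome(rng)
        n = conn.n_neurons
        h = float(rng.integers(3, 31))
        values = rng.integers(-2 * int(h), 2 * int(h) + 1, size=n).astype(float)
        external = (rng.integers(0, 6, size=n) * (rng.random(n) < 0.5)).astype(float)
        nxt = wn.step_network(wn.NetworkState(values=values.copy()), conn, h, external)
        expect = scalar_step_oracle(values, conn.weight_matrix, h, external)
        np.testing.assert_array_equal(nxt.values, expect)


class TestMotorAndActions:
    def test_no_fired_motor_neurons_gives_zeros(self):
        assert wn.motor_readout(set(), {"A": (1.0, 2.0)}) == (0.0, 0.0)

    def test_signed_sum(self):
        motor_map = {"A": (3.0, 0.0), "B": (-1.0, 0.0)}
        left, right = wn.motor_readout({"A", "B"}, motor_map)
        assert left == 2.0 and right == 0.0

    def test_mirror_symmetry(self):
        motor_map = {"A": (3.0, 3.0), "B": (-1.0, -1.0)}
        left, right = wn.motor_readout({"A", "B"}, motor_map)
        assert left == right

    @pytest.mark.parametrize(
        "lr,expect",
        [
            ((5.0, 3.0), "forward"),
            ((-2.0, -7.0), "backward"),
            ((0.0, 0.0), "idle"),
            ((-1.0, 2.0), "turn_left"),
            ((2.0, -1.0), "turn_right"),
            ((0.0, 3.0), "turn_left"),
            ((2.0, -2.0), "turn_right"),  # mixed-sign tie
        ],
    )
    def test_action_rule(self, lr, expect):
        assert wn.classify_action(*lr) == expect


def always_forward_setup():
    """A/B fire on alternating steps so the robot moves forward every step;
    C is the avoidance sensory neuron."""
    conn = wn.Connectome(
        neurons=[wn.Neuron.from_name(n) for n in ["A", "B", "C"]],
        weight_matrix=np.zeros((3, 3)),
    )
    cfg = wn.SimConfig(
        duration=30,
        threshold=30.0,
        food_drive=31.0,
        initial_values=np.array([31.0, 0.0, 0.0]),
    )
    motor_map = {"A": (1.0, 1.0), "B": (1.0, 1.0)}
    return conn, cfg, motor_map


class TestArena:
    def test_empty_arena_never_stimulates(self):
        conn, cfg, motor_map = always_forward_setup()
        arena = wn.Arena(
            bounds=(0.0, 0.0, 10_000.0, 10_000.0),
            start_pose=(5000.0, 5000.0, 0.0),
            speed=5.0,
        )
        trace, log = wn.simulate_arena_run(
            conn, cfg, arena, avoidance_neurons={"C"}, food_neurons={"A", "B"},
            motor_map=motor_map,
        )
        c = trace.names.index("C")
        assert np.all(trace.states[:, c] == 0.0)

    def test_first_avoidance_stimulation_step(self):
        # wall 100 cm ahead, 5 cm/step, 30 cm trigger: first stimulation at
        # step 14, i.e. the avoidance neuron state first becomes nonzero at
        # row 15 of the trace
        conn, cfg, motor_map = always_forward_setup()
        arena = wn.Arena(
            bounds=(0.0, 0.0, 100.0, 2000.0),
            start_pose=(0.0, 1000.0, 0.0),
            speed=5.0,
        )
        trace, log = wn.simulate_arena_run(
            conn, cfg, arena, avoidance_neurons={"C"}, food_neurons={"A", "B"},
            motor_map=motor_map,
        )
        c = trace.names.index("C")
        nonzero = np.nonzero(trace.states[:, c] != 0.0)[0]
        assert nonzero[0] == 15
        assert all(a == "forward" for _, a, _, _ in log.events[:14])

    def test_log_steps_within_duration(self):
        conn, cfg, motor_map = always_forward_setup()
        arena = wn.Arena(bounds=(0.0, 0.0, 400.0, 400.0), start_pose=(200.0, 200.0, 45.0))
        trace, log = wn.simulate_arena_run(
            conn, cfg, arena, avoidance_neurons={"C"}, motor_map=motor_map
        )
        steps = [e[0] for e in log.events]
        assert min(steps) >= 0 and max(steps) <= cfg.duration

    def test_pose_clipped_at_bounds_logs_collision(self, caplog):
        conn, cfg, motor_map = always_forward_setup()
        arena = wn.Arena(bounds=(0.0, 0.0, 20.0, 2000.0), start_pose=(0.0, 1000.0, 0.0), speed=50.0)
        with caplog.at_level("INFO", logger="wormnet"):
            wn.simulate_arena_run(
                conn, cfg, arena, avoidance_neurons={"C"}, food_neurons={"A", "B"},
                motor_map=motor_map,
            )
        assert "collision" in caplog.text

    def test_initial_pose_outside_bounds_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            wn.Arena(bounds=(0.0, 0.0, 10.0, 10.0), start_pose=(50.0, 5.0, 0.0))

    def test_circle_obstacle_detected_by_sensor(self):
        arena = wn.Arena(
            bounds=(0.0, 0.0, 1000.0, 1000.0),
            circles=[(500.0, 100.0, 10.0)],
            start_pose=(100.0, 100.0, 0.0),
        )
        d = wn.sensor_distance(arena, arena.start_pose)
        assert d == pytest.approx(390.0)
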