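import itertools

import numpy as np
import pytest

from animats.markov_brain import (
    ContractError,
    HMGate,
    MarkovBrain,
    SystemState,
    gate_output_distribution,
    step,
    step_bits,
    to_wiring,
    transition_matrix,
)


def identity_gate(src, dst):
    """Deterministic copy gate src -> dst at extreme weights."""
    return HMGate((src,), (dst,), np.array([[255, 0], [0, 255]]))


class TestGateOutputDistribution:
    def test_uniform_row_gives_uniform_patterns(self):
        gate = HMGate((0, 1), (2, 3), np.full((4, 4), 7))
        dist = gate_output_distribution(gate, [0, 1])
        assert np.allclose(dist, 0.25)

    def test_first_input_is_most_significant_bit(self):
        # '100' selects row 4: make row 4 unique and check it is used
        table = np.ones((8, 2), dtype=int)
        table[4] = [255, 0]
        gate = HMGate((0, 1, 2), (3,), table)
        dist = gate_output_distribution(gate, [1, 0, 0])
        assert dist[0] == pytest.approx(256 / 257)

    def test_clamping_rule_adds_one_to_every_weight(self):
        gate = HMGate((0,), (1, 2), np.array([[255, 1, 1, 1], [0, 0, 0, 0]]))
        dist = gate_output_distribution(gate, [0])
        assert np.allclose(dist, np.array([256, 2, 2, 2]) / 262)
        # all-zero weight row clamps to uniform, never to an invalid vector
        assert np.allclose(gate_output_distribution(gate, [1]), 0.25)

    def test_wrong_input_length_rejected(self):
        gate = HMGate((0, 1), (2,), np.ones((4, 2)))
        with pytest.raises(ContractError):
            gate_output_distribution(gate, [0])

    def test_distribution_normalized_for_random_gates(self, rng):
        for _ in range(20):
            m = int(rng.integers(1, 5))
            n = int(rng.integers(1, 4))
            gate = HMGate(
                tuple(range(m)), tuple(range(m, m + n)),
                rng.integers(0, 256, size=(2**m, 2**n)),
            )
            bits = rng.integers(0, 2, size=m)
            assert gate_output_distribution(gate, bits).sum() == pytest.approx(1.0)


class TestStep:
    def test_zero_gate_brain_resets_non_sensor_bits(self, rng):
        brain = MarkovBrain(gates=[])
        state = SystemState(bits=np.ones(12, dtype=np.uint8))
        out = step(brain, state, rng)
        assert np.all(out.bits[6:] == 0)
        assert np.all(out.bits[:6] == 1)  # sensors belong to the environment

    def test_auto_feedback_maintains_memory(self, rng):
        brain = MarkovBrain(gates=[identity_gate(9, 9)])
        bits = np.zeros(12, dtype=np.uint8)
        bits[9] = 1
        state = SystemState(bits=bits)
        for _ in range(50):
            state = step(brain, state, rng)
        assert state.bits[9] == 1

    def test_or_combination_of_conflicting_writes(self, rng):
        writes_one = HMGate((6,), (10,), np.array([[0, 255], [0, 255]]))
        writes_zero = HMGate((7,), (10,), np.array([[255, 0], [255, 0]]))
        brain = MarkovBrain(gates=[writes_one, writes_zero])
        out = step(brain, SystemState.zeros(), rng)
        assert out.bits[10] == 1

    def test_step_result_independent_of_gate_order(self):
        g1 = HMGate((6,), (10,), np.array([[0, 255], [0, 255]]))
        g2 = HMGate((7,), (10, 11), np.array([[255, 0, 0, 0]] * 2))
        bits = np.zeros(12, dtype=np.uint8)
        u = np.array([0.3, 0.7])
        a = step_bits(MarkovBrain(gates=[g1, g2]), bits, u)
        b = step_bits(MarkovBrain(gates=[g2, g1]), bits, u[::-1])
        assert np.array_equal(a, b)

    def test_deterministic_under_fixed_seed(self):
        gate = HMGate((6, 7), (8, 9), np.arange(16).reshape(4, 4))
        brain = MarkovBrain(gates=[gate])
        bits = np.zeros(12, dtype=np.uint8)
        s1 = step(brain, SystemState(bits=bits.copy()), np.random.default_rng(9))
        s2 = step(brain, SystemState(bits=bits.copy()), np.random.default_rng(9))
        assert np.array_equal(s1.bits, s2.bits)

    def test_connection_limit_enforced(self):
        gates = [identity_gate(6, 7) for _ in range(4)]
        with pytest.raises(ContractError):
            MarkovBrain(gates=gates)


class TestTransitionMatrix:
    def test_gate_free_brain_maps_everything_to_zero(self):
        brain = MarkovBrain(gates=[])
        tm = transition_matrix(brain, [6, 7])
        assert np.allclose(tm[:, 0], 1.0)

    def test_rows_sum_to_one(self, rng):
        gate = HMGate((6, 7), (7, 8), rng.integers(0, 256, size=(4, 4)))
        brain = MarkovBrain(gates=[gate])
        tm = transition_matrix(brain, [6, 7, 8])
        assert np.allclose(tm.sum(axis=1), 1.0, atol=1e-12)

    def test_matches_brute_force_enumeration(self, rng):
        """Exact matrix equals direct enumeration over all gate output combos."""
        gates = [
            HMGate((6,), (7, 8), rng.integers(0, 256, size=(2, 4))),
            HMGate((7, 8), (6,), rng.integers(0, 256, size=(4, 2))),
        ]
        brain = MarkovBrain(gates=gates)
        free = (6, 7, 8)
        tm = transition_matrix(brain, free)
        pos = {v: j for j, v in enumerate(free)}
        expected = np.zeros_like(tm)
        for s in range(8):
            bits = {v: (s >> pos[v]) & 1 for v in free}
            patterns = []
            for g in gates:
                row = 0
                for v in g.input_ids:
                    row = (row << 1) | bits[v]
                probs = (g.table[row] + 1) / (g.table[row] + 1).sum()
                patterns.append(list(enumerate(probs)))
            for combo in itertools.product(*patterns):
                p = np.prod([pr for _, pr in combo])
                out = 0
                for (col, _), g in zip(combo, gates):
                    for k, v in enumerate(g.output_ids):
                        if (col >> (g.n_outputs - 1 - k)) & 1:
                            out |= 1 << pos[v]
                expected[s, out] += p
        assert np.allclose(tm, expected, atol=1e-12)

    def test_agrees_with_sampled_steps(self, rng):
        gate = HMGate((6, 7), (6, 7), rng.integers(0, 256, size=(4, 4)))
        brain = MarkovBrain(gates=[gate])
        tm = transition_matrix(brain, [6, 7])
        n = 40_000
        start = np.zeros(12, dtype=np.uint8)
        start[6] = 1
        s_idx = 1  # bit order: 6 -> bit0, 7 -> bit1
        counts = np.zeros(4)
        for _ in range(n):
            out = step_bits(brain, start, rng.random(1))
            counts[int(out[6]) | (int(out[7]) << 1)] += 1
        freq = counts / n
        se = np.sqrt(tm[s_idx] * (1 - tm[s_idx]) / n)
        assert np.all(np.abs(freq - tm[s_idx]) <= 3 * se + 1e-9)

    def test_size_guard(self):
        with pytest.raises(ContractError):
            transition_matrix(MarkovBrain(gates=[], n_vars=20, sensor_ids=(),
                                          internal_ids=tuple(range(20)), motor_ids=()),
                              list(range(17)))


class TestWiring:
    def test_dual_graph_edges_of_single_gate(self):
        gate = HMGate((1, 2, 3), (3, 4), np.ones((8, 4)))
        wiring = to_wiring(MarkovBrain(gates=[gate]))
        assert set(wiring.edges()) == {(1, 3), (1, 4), (2, 3), (2, 4), (3, 3), (3, 4)}

    def test_empty_brain_has_no_edges(self):
        assert to_wiring(MarkovBrain(gates=[])).number_of_edges() == 0

    def test_dot_export_lists_nodes_and_edges(self):
        from animats.markov_brain import to_dot

        gate = HMGate((0,), (10,), np.ones((2, 2)))
        dot = to_dot(MarkovBrain(gates=[gate]))
        assert dot.startswith("digraph")
        assert "n0 -> n10;" in dot
        assert "shape=triangle" in dot and "shape=trapezium" in dot

    def test_edge_set_invariant_under_gate_permutation(self, rng):
        g1 = HMGate((0, 6), (7,), rng.integers(0, 256, (4, 2)))
        g2 = HMGate((7,), (10, 11), rng.integers(0, 256, (2, 4)))
        e1 = set(to_wiring(MarkovBrain(gates=[g1, g2])).edges())
        e2 = set(to_wiring(MarkovBrain(gates=[g2, g1])).edges())
        assert e1 == e2
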