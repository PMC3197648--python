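import numpy as np
import pytest

from animats.markov_brain import ContractError, HMGate, MarkovBrain, transition_matrix
from animats.infotheory import (
    PairDistribution,
    Partition,
    atomic_measures,
    bell_number,
    effective_information,
    ei_max_entropy,
    enumerate_partitions,
    entropy,
    estimate_pairs,
    find_mip,
    main_complex,
    multi_information,
    predictive_information,
    synergistic_information,
    total_information,
)
from conftest import random_pair_distribution


def naive_mip(pd):
    """Stored-list exhaustive MIP search recomputing every EI from scratch."""
    best_key, best_part, best_ei = None, None, None
    for part in enumerate_partitions(pd.n_nodes):
        relabeled = Partition(
            parts=tuple(tuple(pd.nodes[i] for i in p) for p in part.parts)
        )
        ei = effective_information(pd, relabeled)
        minsize = min(len(p) for p in relabeled.parts)
        key = (ei / ((relabeled.k - 1) * minsize), ei)
        if best_key is None or key < best_key:
            best_key, best_part, best_ei = key, relabeled, ei
    return best_part, best_ei


class TestPairDistribution:
    def test_one_trajectory_counts_t_pairs(self):
        states = np.zeros((11, 12), dtype=np.uint8)
        pd = PairDistribution.from_state_arrays([states], nodes=range(12))
        assert pd.total == 10

    def test_pairs_never_cross_trajectory_boundaries(self):
        a = np.zeros((5, 2), dtype=np.uint8)
        b = np.ones((5, 2), dtype=np.uint8)
        pd = PairDistribution.from_state_arrays([a, b], nodes=[0, 1])
        assert pd.total == 8
        # no (0,0) -> (1,1) transition was counted
        cross = (pd.xt == 0) & (pd.xt1 == 3)
        assert pd.weights[cross].sum() == 0

    def test_marginal_consistency(self, rng):
        pd = random_pair_distribution(rng, 3)
        m01 = pd.marginal([0, 1])
        m0_direct = pd.marginal([0])
        m0_nested = m01.marginal([0])
        assert m0_direct.entropy_joint() == pytest.approx(m0_nested.entropy_joint())
        assert m0_direct.total == pytest.approx(pd.total)

    def test_time_marginal_matches_state_histogram(self, rng):
        states = rng.integers(0, 2, size=(10_001, 3)).astype(np.uint8)
        pd = PairDistribution.from_state_arrays([states], nodes=range(3))
        packed = states[:-1, 0] | (states[:-1, 1] << 1) | (states[:-1, 2] << 2)
        hist = np.bincount(packed, minlength=8)
        for s in range(8):
            assert pd.weights[pd.xt == s].sum() == hist[s]


class TestEntropy:
    def test_uniform_and_point_mass(self):
        assert entropy([1, 1, 1, 1]) == pytest.approx(2.0)
        assert entropy([5, 0, 0]) == pytest.approx(0.0)

    def test_additive_for_independent_variables(self, rng):
        pa = rng.random(4)
        pb = rng.random(8)
        joint = np.outer(pa, pb).ravel()
        assert entropy(joint) == pytest.approx(entropy(pa) + entropy(pb), abs=1e-12)


class TestPredictiveInformation:
    def test_constant_motors_give_zero(self):
        states = np.zeros((100, 12), dtype=np.uint8)
        states[:, 0] = np.arange(100) % 2
        pd = estimate_pairs([states], nodes=range(12))
        assert predictive_information(pd, range(6), (10, 11)) == pytest.approx(0.0)

    def test_motor_copying_uniform_sensor_gives_one_bit(self, rng):
        T = 2000
        sensor = rng.integers(0, 2, size=T + 1).astype(np.uint8)
        states = np.zeros((T + 1, 12), dtype=np.uint8)
        states[:, 0] = sensor
        states[1:, 10] = sensor[:-1]  # motor copies the sensor one step later
        pd = estimate_pairs([states], nodes=range(12))
        assert predictive_information(pd, range(6), (10, 11)) == pytest.approx(
            1.0, abs=0.01
        )

    def test_matches_double_sum_oracle(self, rng):
        """Brute-force evaluation of the mutual-information sum."""
        pd = random_pair_distribution(rng, 4)
        value = predictive_information(pd, [0, 1], [2, 3])
        # oracle: dense joint of (sensors at t, motors at t+1)
        joint = np.zeros((4, 4))
        for s, s1, w in zip(pd.xt, pd.xt1, pd.weights):
            joint[s & 3, (s1 >> 2) & 3] += w
        joint /= joint.sum()
        pa, pb = joint.sum(1), joint.sum(0)
        oracle = sum(
            joint[a, b] * np.log2(joint[a, b] / (pa[a] * pb[b]))
            for a in range(4) for b in range(4) if joint[a, b] > 0
        )
        assert value == pytest.approx(oracle, abs=1e-12)


class TestTotalAndMultiInformation:
    def test_iid_resampled_states_process_nothing(self, rng):
        states = rng.integers(0, 2, size=(20_000, 2)).astype(np.uint8)
        pd = PairDistribution.from_state_arrays([states], nodes=range(2))
        assert total_information(pd) < 0.002

    def test_deterministic_permutation_processes_n_bits(self):
        # x -> x+1 mod 8 on uniform states
        joint = np.zeros((8, 8))
        for s in range(8):
            joint[s, (s + 1) % 8] = 1 / 8
        pd = PairDistribution.from_joint(joint)
        assert total_information(pd) == pytest.approx(3.0)

    def test_total_information_identity(self, rng):
        pd = random_pair_distribution(rng, 3)
        expected = pd.entropy_t() + pd.entropy_t1() - pd.entropy_joint()
        assert total_information(pd) == pytest.approx(expected, abs=1e-12)

    def test_multi_information_cases(self):
        # independent bits
        joint = np.full((4, 4), 1 / 16)
        assert multi_information(PairDistribution.from_joint(joint)) == pytest.approx(0.0)
        # two perfectly correlated bits
        joint = np.zeros((4, 4))
        joint[0, :] = 1 / 8
        joint[3, :] = 1 / 8
        assert multi_information(PairDistribution.from_joint(joint)) == pytest.approx(1.0)
        # three-bit even-parity uniform distribution
        joint = np.zeros((8, 8))
        for s in range(8):
            if bin(s).count("1") % 2 == 0:
                joint[s, :] = 1 / 32
        assert multi_information(PairDistribution.from_joint(joint)) == pytest.approx(1.0)


class TestAtomicMeasures:
    def test_independent_nodes_have_no_synergy(self, rng):
        pa = random_pair_distribution(rng, 1)
        pb = random_pair_distribution(rng, 1)
        joint = np.zeros((4, 4))
        for i, (s, s1, w) in enumerate(zip(pa.xt, pa.xt1, pa.weights)):
            for j, (t, t1, u) in enumerate(zip(pb.xt, pb.xt1, pb.weights)):
                joint[s | (t << 1), s1 | (t1 << 1)] += w * u
        pd = PairDistribution.from_joint(joint)
        am = atomic_measures(pd)
        assert am.i_syn == pytest.approx(0.0, abs=1e-9)
        assert am.phi_atomic == pytest.approx(multi_information(pd), abs=1e-9)

    def test_xor_closed_form(self, xor_pair_distribution):
        am = atomic_measures(xor_pair_distribution)
        assert am.phi_atomic == pytest.approx(1.0, abs=1e-9)
        assert am.i_syn == pytest.approx(1.0, abs=1e-9)
        assert multi_information(xor_pair_distribution) == pytest.approx(0.0, abs=1e-9)

    def test_decomposition_identity_on_random_tables(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 6))
            pd = random_pair_distribution(rng, n)
            am = atomic_measures(pd)
            assert am.phi_atomic == pytest.approx(
                am.i_syn + multi_information(pd), abs=1e-9
            )


class TestEffectiveInformation:
    def test_zero_across_independent_parts(self, rng):
        w1 = rng.random((4, 4))
        w2 = rng.random((2, 2))
        joint = np.zeros((8, 8))
        for s in range(8):
            for s1 in range(8):
                joint[s, s1] = w1[s & 3, s1 & 3] * w2[s >> 2, s1 >> 2]
        pd = PairDistribution.from_joint(joint)
        ei = effective_information(pd, Partition(parts=((0, 1), (2,))))
        assert ei == pytest.approx(0.0, abs=1e-9)

    def test_atomic_partition_equals_phi_atomic(self, rng):
        pd = random_pair_distribution(rng, 4)
        ei = effective_information(pd, Partition.atomic(range(4)))
        assert ei == pytest.approx(atomic_measures(pd).phi_atomic, abs=1e-12)

    def test_nonnegative_and_matches_recomputation(self, rng):
        for _ in range(20):
            pd = random_pair_distribution(rng, 4)
            for part in enumerate_partitions(4):
                ei = effective_information(pd, part)
                assert ei >= -1e-9
                # naive recomputation from first principles
                naive = -pd.h_t_given_t1()
                for p in part.parts:
                    naive += pd.marginal(p).h_t_given_t1()
                assert ei == pytest.approx(naive, abs=1e-12)

    def test_invalid_partition_rejected(self, rng):
        pd = random_pair_distribution(rng, 3)
        with pytest.raises(ContractError):
            effective_information(pd, Partition(parts=((0, 1),)))


class TestPartitionEnumeration:
    def test_bell_numbers(self):
        assert bell_number(1) == 1
        assert bell_number(3) == 5
        assert bell_number(7) == 877
        assert bell_number(12) == 4_213_597

    def test_iterator_counts_match_bell(self):
        for n in range(1, 9):
            assert sum(1 for _ in enumerate_partitions(n, min_parts=1)) == bell_number(n)
            assert sum(1 for _ in enumerate_partitions(n)) == bell_number(n) - 1

    def test_three_node_partitions_explicit(self):
        parts = {p.parts for p in enumerate_partitions(3)}
        assert parts == {
            ((0,), (1,), (2,)),
            ((0,), (1, 2)),
            ((0, 1), (2,)),
            ((0, 2), (1,)),
        }

    def test_partitions_are_unique(self):
        seen = [p.parts for p in enumerate_partitions(5, min_parts=1)]
        assert len(seen) == len(set(seen)) == bell_number(5)


class TestFindMip:
    def test_independent_subsystems_split_with_zero_phi(self, rng):
        w1 = rng.random((4, 4))
        w2 = rng.random((4, 4))
        joint = np.zeros((16, 16))
        for s in range(16):
            for s1 in range(16):
                joint[s, s1] = w1[s & 3, s1 & 3] * w2[s >> 2, s1 >> 2]
        res = find_mip(PairDistribution.from_joint(joint))
        assert res.phi == pytest.approx(0.0, abs=1e-9)
        assert set(res.mip.parts) == {(0, 1), (2, 3)}

    def test_disconnected_noise_node_zeroes_phi(self, rng):
        w1 = rng.random((8, 8))
        joint = np.zeros((16, 16))
        for s in range(16):
            for s1 in range(16):
                joint[s, s1] = w1[s & 7, s1 & 7] * 0.25
        res = find_mip(PairDistribution.from_joint(joint))
        assert res.phi == pytest.approx(0.0, abs=1e-9)

    def test_cached_search_matches_stored_list_oracle(self, rng):
        for _ in range(10):
            n = int(rng.integers(4, 6))
            pd = random_pair_distribution(rng, n, sparsity=3.0)
            res = find_mip(pd)
            part, ei = naive_mip(pd)
            assert res.phi == pytest.approx(ei, abs=1e-10)
            assert res.mip.parts == part.parts
            assert res.n_candidates == bell_number(n) - 1

    def test_node_limit_guard(self, rng):
        pd = random_pair_distribution(rng, 3)
        with pytest.raises(ContractError):
            find_mip(pd, node_limit=2)


class TestMainComplex:
    def test_independent_nodes_give_zero(self, rng):
        ps = [rng.random(2) for _ in range(3)]
        joint = np.zeros((8, 8))
        for s in range(8):
            for s1 in range(8):
                p = 1.0
                for j in range(3):
                    p *= ps[j][(s >> j) & 1] / ps[j].sum()
                joint[s, s1] = p / 8
        res = main_complex(PairDistribution.from_joint(joint))
        assert res.phi == pytest.approx(0.0, abs=1e-9)

    def test_main_complex_at_least_full_system_phi(self, rng):
        pd = random_pair_distribution(rng, 4)
        res = main_complex(pd)
        assert res.phi >= find_mip(pd).phi - 1e-12

    def test_coupled_pair_beats_noise_nodes(self, rng):
        # X1(t+1) copies X0(t); nodes 2, 3 are i.i.d. noise
        joint = np.zeros((16, 16))
        for s in range(16):
            for s1 in range(16):
                p = 1 / 16  # p(s) uniform
                p *= 0.5 if True else 0  # y0 uniform
                p *= 1.0 if ((s1 >> 1) & 1) == (s & 1) else 0.0
                p *= 0.25  # noise at t+1
                p *= 0.5   # y0
                joint[s, s1] = p
        res = main_complex(PairDistribution.from_joint(joint))
        assert res.nodes == (0, 1)
        assert res.phi == pytest.approx(1.0, abs=1e-9)
        # subset table covers every subset of size >= 2
        assert len(res.subset_phi) == 2**4 - 4 - 1


class TestEiMaxEntropy:
    def test_forms_agree_under_uniform_input(self, rng):
        for _ in range(20):
            tm = rng.dirichlet(np.ones(8), size=8)
            for part in enumerate_partitions(3):
                c = ei_max_entropy(tm, part, form="conditional")
                s = ei_max_entropy(tm, part, form="synergy")
                assert c == pytest.approx(s, abs=1e-9)

    def test_identity_dynamics_bipartition_zero(self):
        tm = np.eye(4)
        assert ei_max_entropy(tm, Partition(parts=((0,), (1,)))) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_factorizing_dynamics_zero(self, rng):
        t1 = rng.dirichlet(np.ones(2), size=2)
        t2 = rng.dirichlet(np.ones(2), size=2)
        tm = np.kron(t2, t1)  # bit 0 = fast factor: check both orders
        part = Partition(parts=((0,), (1,)))
        assert ei_max_entropy(tm, part) == pytest.approx(0.0, abs=1e-9)

    def test_brain_transition_matrix_roundtrip(self, rng):
        """EI forms also agree on matrices produced by real brains."""
        gate = HMGate((6, 7), (7, 8), rng.integers(0, 256, (4, 4)))
        brain = MarkovBrain(gates=[gate])
        tm = transition_matrix(brain, [6, 7, 8])
        for part in enumerate_partitions(3):
            c = ei_max_entropy(tm, part, form="conditional")
            s = ei_max_entropy(tm, part, form="synergy")
            assert c == pytest.approx(s, abs=1e-9)


class TestReductionProperty:
    def test_sensor_motor_markov_system_reduces_to_predictive_info(self, rng):
        """With only sensor and response nodes, I_total equals I_pred."""
        for _ in range(20):
            p_s = rng.dirichlet(np.ones(4))      # i.i.d. sensor pair (2 bits)
            t_m = rng.dirichlet(np.ones(4), 4)   # p(motors' | sensors)
            p_m = p_s @ t_m                      # stationary motor marginal
            joint = np.zeros((16, 16))
            for s in range(4):
                for m in range(4):
                    for s1 in range(4):
                        for m1 in range(4):
                            joint[s | (m << 2), s1 | (m1 << 2)] = (
                                p_s[s] * p_m[m] * p_s[s1] * t_m[s, m1]
                            )
            pd = PairDistribution.from_joint(joint)
            i_total = total_information(pd)
            i_pred = predictive_information(pd, [0, 1], [2, 3])
            assert i_total == pytest.approx(i_pred, abs=1e-9)
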