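import numpy as np
import pytest

from animats.maze_world import Maze, generate_maze
from animats.infotheory import PairDistribution


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def maze(rng):
    return generate_maze(rng)


@pytest.fixture
def tiny_maze():
    """Hand-crafted 5-wide maze with all doors in column 2."""
    walls = [(3 * (k + 1), 2) for k in range(26)]
    return Maze(width=5, walls=walls, period=3 * 26 + 3)


def random_pair_distribution(rng, n_nodes, sparsity=1.0):
    """Random dense joint over (x_t, x_{t+1}) for n binary nodes."""
    w = rng.random((2**n_nodes, 2**n_nodes)) ** sparsity
    return PairDistribution.from_joint(w)


@pytest.fixture
def xor_pair_distribution():
    """3-node system with C(t+1) = A(t) XOR B(t); A, B uniform i.i.d.

    Closed form: I_total = I_syn = Phi_atomic = 1 bit, I_multi = 0.
    """
    joint = np.zeros((8, 8))
    for s in range(8):
        a, b = s & 1, (s >> 1) & 1
        for s1 in range(8):
            if ((s1 >> 2) & 1) == (a ^ b):
                joint[s, s1] += 1 / 32  # p(s)=1/8, A',B' uniform (1/4)
    return PairDistribution.from_joint(joint)
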