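"""Information processing and integration measures on empirical pair
distributions of consecutive system states.

All entropies are plug-in (maximum-likelihood) estimates in bits with the
0*log(0)=0 convention.  The substrate is a :class:`PairDistribution`: the
empirical joint of (X_t, X_{t+1}) over a node subset, stored sparsely as
unique observed pairs with (possibly fractional) weights so that analytic
distributions and empirical counts go through the same code path.

Measures:

* predictive information  I(sensors_t ; motors_{t+1})
* total processed information  I(X_t ; X_{t+1})
* multi-information  sum_i H(X_i) - H(X)
* synergistic atomic information  I_syn = I_total - sum_i I(X_i,t ; X_i,t+1)
* atomic integration  Phi_atomic = sum_i H(X_i,t|X_i,t+1) - H(X_t|X_{t+1}),
  which decomposes exactly as Phi_atomic = I_syn + I_multi
* effective information of a partition P = {M_1..M_K}:
  EI(P) = sum_k H(M_k,t | M_k,t+1) - H(X_t | X_{t+1})
* Phi: EI at the Minimum Information Partition, the minimizer of
  EI(P) / ((K-1) * min_k Hmax(M_k)) over all partitions with K >= 2, where
  Hmax of a part of binary nodes is its node count
* the main complex: the node subset with the largest Phi over all subsets.

The MIP search enumerates set partitions as restricted-growth strings with
constant memory; with the per-subset conditional-entropy cache each
partition costs a table-lookup sum, which keeps the full 12-node search
(~4.2 million partitions) tractable.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .markov_brain import ContractError
from ._kernels import mip_kernel

DEFAULT_NODE_LIMIT = 16


# --------------------------------------------------------------------------
# pair distributions
# --------------------------------------------------------------------------

def _plugin_entropy(weights: np.ndarray) -> float:
    """Base-2 plug-in entropy of non-negative weights (any normalization)."""
    w = weights[weights > 0]
    total = w.sum()
    p = w / total
    return float(-(p * np.log2(p)).sum())


def _aggregate(keys: np.ndarray, weights: np.ndarray):
    uniq, inv = np.unique(keys, return_inverse=True)
    return uniq, np.bincount(inv, weights=weights)


@dataclass
class PairDistribution:
    """Empirical joint of consecutive states restricted to a node subset.

    ``nodes`` is an ordered tuple of variable ids; bit ``j`` (least
    significant first) of the packed keys corresponds to ``nodes[j]``.
    ``xt``/``xt1`` hold the unique observed (state, next state) pairs and
    ``weights`` their counts.
    """

    nodes: tuple[int, ...]
    xt: np.ndarray
    xt1: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.nodes = tuple(int(v) for v in self.nodes)
        self.xt = np.asarray(self.xt, dtype=np.int64)
        self.xt1 = np.asarray(self.xt1, dtype=np.int64)
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if not (self.xt.size == self.xt1.size == self.weights.size):
            raise ContractError("xt, xt1 and weights must have equal length")
        if self.weights.size == 0 or self.weights.sum() <= 0:
            raise ContractError("pair distribution has no mass")

    # --- constructors -----------------------------------------------------
    @classmethod
    def from_state_arrays(cls, state_arrays, nodes) -> "PairDistribution":
        """Count consecutive pairs within each (T+1, n_vars) bit array.

        Pairs are never counted across array boundaries; the sample count is
        the total number of transitions.
        """
        nodes = tuple(int(v) for v in nodes)
        if not state_arrays:
            raise ContractError("no state arrays supplied")
        keys_t, keys_t1 = [], []
        shift = np.array([1 << j for j in range(len(nodes))], dtype=np.int64)
        for arr in state_arrays:
            arr = np.asarray(arr)
            packed = (arr[:, list(nodes)].astype(np.int64) * shift).sum(axis=1)
            keys_t.append(packed[:-1])
            keys_t1.append(packed[1:])
        kt = np.concatenate(keys_t)
        kt1 = np.concatenate(keys_t1)
        combined = kt * (1 << len(nodes)) + kt1
        uniq, w = _aggregate(combined, np.ones_like(kt, dtype=np.float64))
        return cls(
            nodes=nodes,
            xt=uniq >> len(nodes),
            xt1=uniq & ((1 << len(nodes)) - 1),
            weights=w,
        )

    @classmethod
    def from_trajectories(cls, trajectories, nodes) -> "PairDistribution":
        return cls.from_state_arrays([t.states for t in trajectories], nodes)

    @classmethod
    def from_joint(cls, joint: np.ndarray, nodes=None) -> "PairDistribution":
        """Dense (2^n, 2^n) joint table of (x_t, x_{t+1}) weights."""
        joint = np.asarray(joint, dtype=np.float64)
        n = int(np.log2(joint.shape[0]))
        if joint.shape != (2**n, 2**n):
            raise ContractError("joint must be (2^n, 2^n)")
        if nodes is None:
            nodes = tuple(range(n))
        s, s1 = np.nonzero(joint > 0)
        return cls(nodes=tuple(nodes), xt=s, xt1=s1, weights=joint[s, s1])

    @classmethod
    def from_transition_matrix(
        cls, tm: np.ndarray, input_dist: np.ndarray | None = None, nodes=None
    ) -> "PairDistribution":
        """Pair distribution of one step of ``tm`` from ``input_dist`` over X_t.

        With ``input_dist=None`` the input is uniform (maximum entropy), the
        convention used for the subscript-0 effective-information variant.
        """
        tm = np.asarray(tm, dtype=np.float64)
        n_states = tm.shape[0]
        if input_dist is None:
            input_dist = np.full(n_states, 1.0 / n_states)
        joint = tm * np.asarray(input_dist, dtype=np.float64)[:, None]
        return cls.from_joint(joint, nodes=nodes)

    # --- basic quantities --------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def total(self) -> float:
        return float(self.weights.sum())

    def marginal(self, sub_nodes) -> "PairDistribution":
        """Restriction to a subset of nodes (marginal-consistent)."""
        sub = tuple(int(v) for v in sub_nodes)
        pos = []
        for v in sub:
            if v not in self.nodes:
                raise ContractError(f"node {v} not in distribution")
            pos.append(self.nodes.index(v))
        mask_t = np.zeros_like(self.xt)
        mask_t1 = np.zeros_like(self.xt1)
        for j, p in enumerate(pos):
            mask_t |= ((self.xt >> p) & 1) << j
            mask_t1 |= ((self.xt1 >> p) & 1) << j
        combined = mask_t * (1 << len(sub)) + mask_t1
        uniq, w = _aggregate(combined, self.weights)
        return PairDistribution(
            nodes=sub,
            xt=uniq >> len(sub),
            xt1=uniq & ((1 << len(sub)) - 1),
            weights=w,
        )

    def entropy_t(self) -> float:
        _, w = _aggregate(self.xt, self.weights)
        return _plugin_entropy(w)

    def entropy_t1(self) -> float:
        _, w = _aggregate(self.xt1, self.weights)
        return _plugin_entropy(w)

    def entropy_joint(self) -> float:
        return _plugin_entropy(self.weights)

    def h_t_given_t1(self) -> float:
        """H(X_t | X_{t+1})."""
        return self.entropy_joint() - self.entropy_t1()

    def mutual_information(self) -> float:
        """I(X_t ; X_{t+1})."""
        return self.entropy_t() + self.entropy_t1() - self.entropy_joint()

    def cross_information(self, nodes_t, nodes_t1) -> float:
        """I(A_t ; B_{t+1}) for node subsets A (at t) and B (at t+1)."""
        pos_a = [self.nodes.index(int(v)) for v in nodes_t]
        pos_b = [self.nodes.index(int(v)) for v in nodes_t1]
        a = np.zeros_like(self.xt)
        b = np.zeros_like(self.xt1)
        for j, p in enumerate(pos_a):
            a |= ((self.xt >> p) & 1) << j
        for j, p in enumerate(pos_b):
            b |= ((self.xt1 >> p) & 1) << j
        _, wa = _aggregate(a, self.weights)
        _, wb = _aggregate(b, self.weights)
        _, wab = _aggregate(a * (1 << len(pos_b)) + b, self.weights)
        return _plugin_entropy(wa) + _plugin_entropy(wb) - _plugin_entropy(wab)


def estimate_pairs(trajectories, nodes) -> PairDistribution:
    """Empirical pair distribution from trajectories or raw state arrays."""
    arrays = [t.states if hasattr(t, "states") else t for t in trajectories]
    return PairDistribution.from_state_arrays(arrays, nodes)


def entropy(weights) -> float:
    """Plug-in entropy (bits) of a weight/probability vector."""
    return _plugin_entropy(np.asarray(weights, dtype=np.float64))


def conditional_entropy(joint: np.ndarray) -> float:
    """H(A | B) from a dense joint table with A on axis 0, B on axis 1."""
    joint = np.asarray(joint, dtype=np.float64)
    return _plugin_entropy(joint.ravel()) - _plugin_entropy(joint.sum(axis=0))


# --------------------------------------------------------------------------
# partitions
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Partition:
    """Disjoint, covering node-set partition; parts sorted canonically."""

    parts: tuple[tuple[int, ...], ...]

    def __post_init__(self) -> None:
        parts = tuple(tuple(sorted(int(v) for v in p)) for p in self.parts)
        parts = tuple(sorted(parts))
        object.__setattr__(self, "parts", parts)
        seen: set[int] = set()
        for p in parts:
            if not p:
                raise ContractError("empty part in partition")
            if seen & set(p):
                raise ContractError("overlapping parts in partition")
            seen |= set(p)

    @property
    def k(self) -> int:
        return len(self.parts)

    @property
    def nodes(self) -> tuple[int, ...]:
        return tuple(sorted(v for p in self.parts for v in p))

    @classmethod
    def atomic(cls, nodes) -> "Partition":
        return cls(parts=tuple((int(v),) for v in nodes))

    @classmethod
    def from_rgs(cls, rgs, nodes) -> "Partition":
        nodes = tuple(nodes)
        groups: dict[int, list[int]] = {}
        for v, g in zip(nodes, rgs):
            groups.setdefault(int(g), []).append(v)
        return cls(parts=tuple(tuple(p) for p in groups.values()))


def bell_number(n: int) -> int:
    """Number of set partitions of n elements (Bell triangle recurrence)."""
    if n < 0:
        raise ValueError("n must be >= 0")
    row = [1]
    for _ in range(n):
        new_row = [row[-1]]
        for x in row:
            new_row.append(new_row[-1] + x)
        row = new_row
    return row[0]


def enumerate_partitions(n: int, min_parts: int = 2):
    """Iterate set partitions of ``range(n)`` via restricted-growth strings.

    Yields each partition exactly once in lexicographic RGS order using
    constant memory.  With the default ``min_parts=2`` the single-part
    partition is excluded (it is not a MIP candidate), so the iterator
    yields ``bell_number(n) - 1`` partitions; ``min_parts=1`` yields all
    ``bell_number(n)``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    a = [0] * n
    while True:
        k = max(a) + 1
        if k >= min_parts:
            yield Partition.from_rgs(a, range(n))
        j = n - 1
        advanced = False
        while j > 0:
            if a[j] <= max(a[:j]):
                a[j] += 1
                for i in range(j + 1, n):
                    a[i] = 0
                advanced = True
                break
            j -= 1
        if not advanced:
            return


# --------------------------------------------------------------------------
# measures
# --------------------------------------------------------------------------

def predictive_information(
    pairs: PairDistribution, sensor_nodes, motor_nodes, lag: int = 1
) -> float:
    """Shared information between sensors and motors one step later.

    ``lag=1`` (default) pairs sensors at t with motors at t+1; ``lag=0``
    evaluates the instantaneous alternative.
    """
    if lag == 1:
        return pairs.cross_information(sensor_nodes, motor_nodes)
    if lag == 0:
        return _cross_information_same_time(pairs, sensor_nodes, motor_nodes)
    raise ValueError("lag must be 0 or 1")


def _cross_information_same_time(pairs: PairDistribution, nodes_a, nodes_b) -> float:
    pos_a = [pairs.nodes.index(int(v)) for v in nodes_a]
    pos_b = [pairs.nodes.index(int(v)) for v in nodes_b]
    a = np.zeros_like(pairs.xt)
    b = np.zeros_like(pairs.xt)
    for j, p in enumerate(pos_a):
        a |= ((pairs.xt >> p) & 1) << j
    for j, p in enumerate(pos_b):
        b |= ((pairs.xt >> p) & 1) << j
    _, wa = _aggregate(a, pairs.weights)
    _, wb = _aggregate(b, pairs.weights)
    _, wab = _aggregate(a * (1 << len(pos_b)) + b, pairs.weights)
    return _plugin_entropy(wa) + _plugin_entropy(wb) - _plugin_entropy(wab)


def total_information(pairs: PairDistribution) -> float:
    """I(X_t ; X_{t+1}) of the full recorded system."""
    return pairs.mutual_information()


def multi_information(pairs: PairDistribution, time: str = "t") -> float:
    """sum_i H(X_i) - H(X) at a single time slice."""
    if time == "t":
        keys, h_joint = pairs.xt, None
    elif time == "t1":
        keys, h_joint = pairs.xt1, None
    else:
        raise ValueError("time must be 't' or 't1'")
    _, w = _aggregate(keys, pairs.weights)
    h_joint = _plugin_entropy(w)
    h_sum = 0.0
    for j in range(pairs.n_nodes):
        _, wj = _aggregate((keys >> j) & 1, pairs.weights)
        h_sum += _plugin_entropy(wj)
    return h_sum - h_joint


@dataclass
class AtomicMeasures:
    i_per_node: list[float]
    i_total: float
    i_syn: float
    phi_atomic: float


def atomic_measures(pairs: PairDistribution) -> AtomicMeasures:
    """Node-wise processed information, synergy and atomic integration."""
    i_total = total_information(pairs)
    i_nodes = []
    h_cond_sum = 0.0
    for v in pairs.nodes:
        m = pairs.marginal([v])
        i_nodes.append(m.mutual_information())
        h_cond_sum += m.h_t_given_t1()
    i_syn = i_total - sum(i_nodes)
    phi_atomic = h_cond_sum - pairs.h_t_given_t1()
    return AtomicMeasures(
        i_per_node=i_nodes, i_total=i_total, i_syn=i_syn, phi_atomic=phi_atomic
    )


def effective_information(pairs: PairDistribution, partition: Partition) -> float:
    """EI(P) = sum_k H(M_k,t | M_k,t+1) - H(X_t | X_{t+1})."""
    if partition.nodes != tuple(sorted(pairs.nodes)):
        raise ContractError("partition does not cover the distribution's nodes")
    total = -pairs.h_t_given_t1()
    for part in partition.parts:
        total += pairs.marginal(part).h_t_given_t1()
    return total


def synergistic_information(pairs: PairDistribution, partition: Partition) -> float:
    """SI(P) = I(X_t;X_{t+1}) - sum_k I(M_k,t;M_k,t+1)."""
    if partition.nodes != tuple(sorted(pairs.nodes)):
        raise ContractError("partition does not cover the distribution's nodes")
    total = pairs.mutual_information()
    for part in partition.parts:
        total -= pairs.marginal(part).mutual_information()
    return total


# --------------------------------------------------------------------------
# MIP search and main complex
# --------------------------------------------------------------------------

@dataclass
class PhiResult:
    phi: float
    mip: Partition
    ei_at_mip: float
    normalized_ei_at_mip: float
    n_candidates: int


def _subset_conditional_entropies(pairs: PairDistribution) -> np.ndarray:
    """H(M_S,t | M_S,t+1) for every non-empty subset mask S of the nodes."""
    n = pairs.n_nodes
    hcond = np.zeros(1 << n)
    for mask in range(1, 1 << n):
        sub = [pairs.nodes[j] for j in range(n) if (mask >> j) & 1]
        hcond[mask] = pairs.marginal(sub).h_t_given_t1()
    return hcond


def find_mip(
    pairs: PairDistribution,
    node_limit: int = DEFAULT_NODE_LIMIT,
    _hcond: np.ndarray | None = None,
    _positions: np.ndarray | None = None,
) -> PhiResult:
    """Exhaustive Minimum Information Partition search.

    Minimizes EI(P)/N(P) with N(P) = (K-1) * min_k |M_k| over all
    partitions with K >= 2 parts; Phi is the unnormalized EI at the
    minimizer.  Ties break toward smaller unnormalized EI, then the
    lexicographically smallest restricted-growth string.
    """
    n = pairs.n_nodes
    if n > node_limit:
        raise ContractError(
            f"{n} nodes exceeds the search limit {node_limit}; restrict the "
            "node set or raise node_limit"
        )
    if n < 2:
        raise ContractError("MIP search needs at least 2 nodes")
    if _hcond is None:
        _hcond = _subset_conditional_entropies(pairs)
        _positions = np.arange(n, dtype=np.int64)
    sizes = np.array([bin(m).count("1") for m in range(_hcond.size)], dtype=np.int64)
    full_mask = 0
    for p in _positions:
        full_mask |= 1 << int(p)
    rgs, ei, norm, count = mip_kernel(_positions, _hcond, sizes, full_mask)
    node_order = [pairs.nodes[int(p)] for p in _positions] if len(_positions) == n else list(pairs.nodes)
    mip = Partition.from_rgs(rgs, node_order)
    return PhiResult(
        phi=float(ei), mip=mip, ei_at_mip=float(ei),
        normalized_ei_at_mip=float(norm), n_candidates=int(count),
    )


@dataclass
class MainComplexResult:
    nodes: tuple[int, ...]
    phi: float
    subset_phi: dict[tuple[int, ...], float]
    proper_complexes: list[tuple[int, ...]]


def main_complex(
    pairs: PairDistribution, node_limit: int = DEFAULT_NODE_LIMIT
) -> MainComplexResult:
    """Phi over every node subset; the main complex is the argmax.

    Ties prefer the smaller subset, then lexicographic order.  Subsets whose
    Phi exceeds that of every strict superset are flagged as proper
    complexes.
    """
    n = pairs.n_nodes
    if n > node_limit:
        raise ContractError(f"{n} nodes exceeds the limit {node_limit}")
    hcond = _subset_conditional_entropies(pairs)
    sizes = np.array([bin(m).count("1") for m in range(1 << n)], dtype=np.int64)
    subset_phi: dict[tuple[int, ...], float] = {}
    for size in range(2, n + 1):
        for combo in combinations(range(n), size):
            positions = np.array(combo, dtype=np.int64)
            full_mask = 0
            for p in combo:
                full_mask |= 1 << p
            _rgs, ei, _norm, _cnt = mip_kernel(positions, hcond, sizes, full_mask)
            subset = tuple(pairs.nodes[p] for p in combo)
            subset_phi[subset] = float(ei)
    best = max(
        subset_phi.items(), key=lambda kv: (kv[1], -len(kv[0]), tuple(-x for x in kv[0]))
    )
    proper = []
    for subset, phi in subset_phi.items():
        sset = set(subset)
        if all(
            phi > other_phi
            for other, other_phi in subset_phi.items()
            if sset < set(other)
        ):
            proper.append(subset)
    return MainComplexResult(
        nodes=best[0], phi=best[1], subset_phi=subset_phi, proper_complexes=sorted(proper)
    )


# --------------------------------------------------------------------------
# maximum-entropy effective information
# --------------------------------------------------------------------------

def ei_max_entropy(
    transition: np.ndarray, partition: Partition, form: str = "conditional"
) -> float:
    """One-step EI with the input distribution forced uniform.

    ``form="conditional"`` evaluates the conditional-entropy expression;
    ``form="synergy"`` the synergistic-information expression.  With a
    uniform X_t the two agree.
    """
    pairs = PairDistribution.from_transition_matrix(transition)
    if form == "conditional":
        return effective_information(pairs, partition)
    if form == "synergy":
        return synergistic_information(pairs, partition)
    raise ValueError("form must be 'conditional' or 'synergy'")


# --------------------------------------------------------------------------
# per-brain summaries
# --------------------------------------------------------------------------

@dataclass
class InfoSummary:
    i_pred: float
    i_total: float
    i_multi: float
    i_syn: float
    phi_atomic: float
    phi: float | None = None
    phi_mc: float | None = None
    mc_nodes: tuple[int, ...] | None = None

    def as_dict(self) -> dict:
        return {
            "I_pred": self.i_pred,
            "I_total": self.i_total,
            "I_multi": self.i_multi,
            "I_syn": self.i_syn,
            "Phi_atomic": self.phi_atomic,
            "Phi": self.phi,
            "Phi_MC": self.phi_mc,
            "mc_nodes": "" if self.mc_nodes is None else ";".join(map(str, self.mc_nodes)),
        }


def summarize_pairs(
    pairs: PairDistribution,
    sensor_nodes,
    motor_nodes,
    compute_phi: bool = True,
    compute_main_complex: bool = True,
    node_limit: int = DEFAULT_NODE_LIMIT,
) -> InfoSummary:
    """All scalar measures from one full-system pair distribution."""
    atoms = atomic_measures(pairs)
    summary = InfoSummary(
        i_pred=predictive_information(pairs, sensor_nodes, motor_nodes),
        i_total=atoms.i_total,
        i_multi=multi_information(pairs),
        i_syn=atoms.i_syn,
        phi_atomic=atoms.phi_atomic,
    )
    if compute_phi:
        summary.phi = find_mip(pairs, node_limit=node_limit).phi
    if compute_main_complex:
        mc = main_complex(pairs, node_limit=node_limit)
        summary.phi_mc = mc.phi
        summary.mc_nodes = mc.nodes
    return summary
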