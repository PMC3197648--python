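"""Networks of Hidden Markov Gates (HMGs) over binary variables.

A Markov brain is a set of probabilistic logic gates updating a fixed vector
of binary variables synchronously.  The default animat layout has 12
variables: six sensors (0-5), four internal nodes (6-9) and two motors
(10, 11).  Each gate reads 1-4 variables, interprets their bits as a row
index into a weight table, and samples one of its 2^n_outputs output
patterns with probability proportional to the (clamped) row weights.  The
new value of every variable is the OR of all values written into it this
step; non-sensor variables nobody wrote to reset to 0.

Weights are unsigned bytes.  The clamping rule

    p_j = (w_j + 1) / sum_k (w_k + 1)

makes every controller minimally stochastic: no transition ever has
probability exactly 0 or 1, even for weight rows drawn from {0, 255}.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import networkx as nx

SENSOR_IDS = (0, 1, 2, 3, 4, 5)
INTERNAL_IDS = (6, 7, 8, 9)
MOTOR_IDS = (10, 11)
N_VARS = 12

MAX_INPUTS = 4
MAX_OUTPUTS = 3
MAX_CONNECTIONS = 3  # per-variable limit on both readers and writers


class ContractError(ValueError):
    """A caller violated an operation precondition."""


@dataclass
class HMGate:
    """One probabilistic logic gate.

    ``input_ids``/``output_ids`` are ordered: the *first* listed variable is
    the most significant bit of the row/column index.
    """

    input_ids: tuple[int, ...]
    output_ids: tuple[int, ...]
    table: np.ndarray  # (2^n_inputs, 2^n_outputs) integer weights in [0, 255]

    def __post_init__(self) -> None:
        self.input_ids = tuple(int(i) for i in self.input_ids)
        self.output_ids = tuple(int(i) for i in self.output_ids)
        if not 1 <= len(self.input_ids) <= MAX_INPUTS:
            raise ContractError(f"gate must have 1..{MAX_INPUTS} inputs")
        if not 1 <= len(self.output_ids) <= MAX_OUTPUTS:
            raise ContractError(f"gate must have 1..{MAX_OUTPUTS} outputs")
        self.table = np.asarray(self.table, dtype=np.int64)
        expected = (2 ** len(self.input_ids), 2 ** len(self.output_ids))
        if self.table.shape != expected:
            raise ContractError(
                f"table shape {self.table.shape} != {expected} for "
                f"{len(self.input_ids)} inputs / {len(self.output_ids)} outputs"
            )
        if self.table.min() < 0 or self.table.max() > 255:
            raise ContractError("table weights must lie in [0, 255]")

    @property
    def n_inputs(self) -> int:
        return len(self.input_ids)

    @property
    def n_outputs(self) -> int:
        return len(self.output_ids)

    def probabilities(self) -> np.ndarray:
        """Row-stochastic matrix after the +1 clamp."""
        w = self.table + 1
        return w / w.sum(axis=1, keepdims=True)


def gate_output_distribution(gate: HMGate, input_bits) -> np.ndarray:
    """Probability vector over the gate's 2^n_outputs output patterns.

    ``input_bits`` must have one bit per gate input; the first input is the
    most significant bit of the row index (input '100' on a three-input gate
    selects row 4).
    """
    bits = np.asarray(input_bits).astype(np.int64).ravel()
    if bits.size != gate.n_inputs:
        raise ContractError(
            f"expected {gate.n_inputs} input bits, got {bits.size}"
        )
    row = 0
    for b in bits:
        row = (row << 1) | (int(b) & 1)
    return gate.probabilities()[row]


@dataclass
class SystemState:
    """Joint state of all brain variables at one time step."""

    bits: np.ndarray
    t: int = 0

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=np.uint8)
        if np.any(self.bits > 1):
            raise ContractError("state bits must be 0/1")

    @classmethod
    def zeros(cls, n_vars: int = N_VARS, t: int = 0) -> "SystemState":
        return cls(bits=np.zeros(n_vars, dtype=np.uint8), t=t)


@dataclass
class MarkovBrain:
    """A network of HMGates over ``n_vars`` binary variables.

    ``read_clamp``/``write_clamp`` support knock-out analyses: a read clamp
    fixes the value every gate sees when reading a variable; a write clamp
    overrides the stored value after OR-combination.  Both default to empty.
    """

    gates: list[HMGate] = field(default_factory=list)
    n_vars: int = N_VARS
    sensor_ids: tuple[int, ...] = SENSOR_IDS
    internal_ids: tuple[int, ...] = INTERNAL_IDS
    motor_ids: tuple[int, ...] = MOTOR_IDS
    read_clamp: dict[int, int] = field(default_factory=dict)
    write_clamp: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for g in self.gates:
            for v in g.input_ids + g.output_ids:
                if not 0 <= v < self.n_vars:
                    raise ContractError(f"gate variable {v} >= n_vars={self.n_vars}")
        reads = self.read_counts
        writes = self.write_counts
        if reads.size and reads.max(initial=0) > MAX_CONNECTIONS:
            raise ContractError("a variable has more than 3 read connections")
        if writes.size and writes.max(initial=0) > MAX_CONNECTIONS:
            raise ContractError("a variable has more than 3 write connections")

    @property
    def read_counts(self) -> np.ndarray:
        counts = np.zeros(self.n_vars, dtype=np.int64)
        for g in self.gates:
            for v in g.input_ids:
                counts[v] += 1
        return counts

    @property
    def write_counts(self) -> np.ndarray:
        counts = np.zeros(self.n_vars, dtype=np.int64)
        for g in self.gates:
            for v in g.output_ids:
                counts[v] += 1
        return counts

    @property
    def sensor_mask(self) -> np.ndarray:
        mask = np.zeros(self.n_vars, dtype=bool)
        mask[list(self.sensor_ids)] = True
        return mask

    def copy(self) -> "MarkovBrain":
        return MarkovBrain(
            gates=[HMGate(g.input_ids, g.output_ids, g.table.copy()) for g in self.gates],
            n_vars=self.n_vars,
            sensor_ids=self.sensor_ids,
            internal_ids=self.internal_ids,
            motor_ids=self.motor_ids,
            read_clamp=dict(self.read_clamp),
            write_clamp=dict(self.write_clamp),
        )


def _read_bits(brain: MarkovBrain, bits: np.ndarray, ids: tuple[int, ...]) -> list[int]:
    out = []
    for v in ids:
        if v in brain.read_clamp:
            out.append(brain.read_clamp[v])
        else:
            out.append(int(bits[v]))
    return out


def step_bits(
    brain: MarkovBrain,
    bits: np.ndarray,
    uniforms: np.ndarray,
    gate_rows: np.ndarray | None = None,
) -> np.ndarray:
    """One synchronous update consuming one uniform variate per gate.

    ``uniforms`` must hold ``len(brain.gates)`` numbers in [0, 1).  If
    ``gate_rows`` is given, the selected row index per gate is recorded into
    it (used by the knock-out input-usage histogram).
    """
    new = np.zeros(brain.n_vars, dtype=np.uint8)
    for gi, gate in enumerate(brain.gates):
        in_bits = _read_bits(brain, bits, gate.input_ids)
        row = 0
        for b in in_bits:
            row = (row << 1) | (b & 1)
        if gate_rows is not None:
            gate_rows[gi] = row
        weights = gate.table[row] + 1
        cum = np.cumsum(weights)
        r = uniforms[gi] * cum[-1]
        col = int(np.searchsorted(cum, r, side="right"))
        # write the column's bits (first output = MSB), OR-combined
        for k, v in enumerate(gate.output_ids):
            bit = (col >> (gate.n_outputs - 1 - k)) & 1
            if bit:
                new[v] = 1
    # sensors are the environment's: keep their previous value, writes to
    # them have no lasting effect
    for v in brain.sensor_ids:
        new[v] = bits[v]
    for v, val in brain.write_clamp.items():
        if v not in brain.sensor_ids:
            new[v] = val
    return new


def step(brain: MarkovBrain, state: SystemState, rng: np.random.Generator) -> SystemState:
    """Advance the brain one time step (sensor bits are left untouched)."""
    if state.bits.size != brain.n_vars:
        raise ContractError("state size does not match brain.n_vars")
    uniforms = rng.random(len(brain.gates))
    return SystemState(bits=step_bits(brain, state.bits, uniforms), t=state.t + 1)


def transition_matrix(brain: MarkovBrain, free_vars) -> np.ndarray:
    """Exact one-step stochastic matrix over the joint states of ``free_vars``.

    State index bit j corresponds to ``sorted(free_vars)[j]`` (least
    significant bit first).  Variables outside ``free_vars`` are held at 0.
    Gate stochasticity is marginalized exactly; sensor variables inside the
    subset keep their value (the environment owns them).
    """
    free = tuple(sorted(int(v) for v in free_vars))
    f = len(free)
    if f > 16:
        raise ContractError(f"free_vars has {f} variables; limit is 16")
    pos = {v: j for j, v in enumerate(free)}
    n_states = 2**f
    sensor_set = set(brain.sensor_ids)
    tm = np.zeros((n_states, n_states))
    for s in range(n_states):
        bits = np.zeros(brain.n_vars, dtype=np.uint8)
        for v, j in pos.items():
            bits[v] = (s >> j) & 1
        # base: unwritten non-sensors go to 0, sensors keep their value
        base = 0
        for v in free:
            if v in sensor_set:
                base |= int(bits[v]) << pos[v]
        dist = np.zeros(n_states)
        dist[base] = 1.0
        for gate in brain.gates:
            in_bits = _read_bits(brain, bits, gate.input_ids)
            row = 0
            for b in in_bits:
                row = (row << 1) | (b & 1)
            probs = (gate.table[row] + 1) / (gate.table[row] + 1).sum()
            new_dist = np.zeros(n_states)
            for col, p in enumerate(probs):
                wmask = 0
                for k, v in enumerate(gate.output_ids):
                    bit = (col >> (gate.n_outputs - 1 - k)) & 1
                    if bit and v in pos and v not in sensor_set:
                        wmask |= 1 << pos[v]
                if wmask == 0:
                    new_dist += p * dist
                else:
                    for cur in np.nonzero(dist)[0]:
                        new_dist[cur | wmask] += p * dist[cur]
            dist = new_dist
        # write clamps override
        force1 = 0
        force0 = 0
        for v, val in brain.write_clamp.items():
            if v in pos and v not in sensor_set:
                if val:
                    force1 |= 1 << pos[v]
                else:
                    force0 |= 1 << pos[v]
        if force1 or force0:
            clamped = np.zeros(n_states)
            for cur in np.nonzero(dist)[0]:
                clamped[(cur | force1) & ~force0] += dist[cur]
            dist = clamped
        tm[s] = dist
    return tm


def to_wiring(brain: MarkovBrain) -> nx.MultiDiGraph:
    """Variable-level causal graph: edge u->v iff a gate reads u and writes v."""
    g = nx.MultiDiGraph()
    for v in range(brain.n_vars):
        if v in brain.sensor_ids:
            kind = "sensor"
        elif v in brain.motor_ids:
            kind = "motor"
        else:
            kind = "internal"
        g.add_node(v, kind=kind)
    for gi, gate in enumerate(brain.gates):
        for u in gate.input_ids:
            for v in gate.output_ids:
                g.add_edge(u, v, gate=gi)
    return g


_DOT_SHAPE = {"sensor": "triangle", "internal": "circle", "motor": "trapezium"}
_DOT_COLOR = {"sensor": "red", "internal": "gray", "motor": "lightblue"}


def to_dot(brain: MarkovBrain) -> str:
    """Graphviz DOT export of the wiring (one edge per distinct u->v link)."""
    wiring = to_wiring(brain)
    lines = ["digraph animat {"]
    for v, data in sorted(wiring.nodes(data=True)):
        kind = data["kind"]
        lines.append(
            f'  n{v} [label="{v}", shape={_DOT_SHAPE[kind]}, '
            f'style=filled, fillcolor={_DOT_COLOR[kind]}];'
        )
    for u, v in sorted(set(wiring.edges())):
        lines.append(f"  n{u} -> n{v};")
    lines.append("}")
    return "\n".join(lines)
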