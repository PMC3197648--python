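"""Pure-Python twin of the compiled world loop.

Consumes the identical uniform stream as ``_kernels.run_kernel`` (one
variate per gate per step, in gate order) so the two paths can be asserted
bit-for-bit equal.  Also used by the knock-out screen when the per-gate
input-usage histogram is requested.
"""

from __future__ import annotations

import numpy as np

from .markov_brain import MarkovBrain, step_bits
from .maze_world import Maze, Trajectory, sense, act


def run_animat_reference(
    brain: MarkovBrain,
    maze: Maze,
    T: int,
    uniforms: np.ndarray,
    collect_gate_rows: bool = False,
):
    """Simulate T steps; returns a Trajectory (and optionally per-step gate rows)."""
    n_gates = max(len(brain.gates), 1)
    positions = np.zeros((T + 1, 2), dtype=np.int64)
    states = np.zeros((T + 1, brain.n_vars), dtype=np.uint8)
    gate_rows = np.zeros((T, len(brain.gates)), dtype=np.int64) if collect_gate_rows else None
    pos = maze.start
    state = np.zeros(brain.n_vars, dtype=np.uint8)
    state[:6] = sense(maze, pos)
    positions[0] = pos
    states[0] = state
    doors = 0
    for t in range(T):
        rows_out = gate_rows[t] if collect_gate_rows else None
        new = step_bits(
            brain, state, uniforms[t * len(brain.gates):(t + 1) * len(brain.gates)]
            if brain.gates else uniforms[:0],
            gate_rows=rows_out,
        )
        new_pos = act(maze, pos, (new[10], new[11]))
        if new_pos[0] == pos[0] + 1 and pos[0] % maze.period == maze.last_wall_row:
            doors += 1
        pos = new_pos
        new[:6] = sense(maze, pos)
        state = new
        positions[t + 1] = pos
        states[t + 1] = state
    traj = Trajectory(positions=positions, states=states, doors_passed=doors, T=T, maze=maze)
    if collect_gate_rows:
        return traj, gate_rows
    return traj
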