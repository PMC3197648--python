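"""Maze fitness, selection fitness, and control fitness.

Raw maze fitness combines full traversals with time-averaged progress::

    f = c * d_max + (1/T) * sum_{t=1..T} (d_max - d_t)

where ``d_t`` is the shortest-path distance from the animat's position at
step ``t`` to the last doorway of the maze, ``d_max`` the maximum such
distance over cells, and ``c`` the number of times the animat passed the
last doorway.  A final-state variant ``f = c*d_max + (d_max - d_T)`` is
available through ``mode="final"``.

The maximum attainable fitness ``f_max`` is what a deterministic walker
with full maze knowledge scores: it always steps along a shortest path to
the last doorway and keeps going period after period.

Selection fitness is the geometric mean of replicate ratios ``f/f_max``
(one total failure zeroes it); control fitness is the arithmetic mean over
ten unseen mazes, which a single failure cannot zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .markov_brain import ContractError, MarkovBrain
from .maze_world import DEFAULT_T, Maze, Trajectory, generate_maze, run_animat

N_CONTROL_MAZES = 10
DEFAULT_REPS = 10


@dataclass
class FitnessResult:
    f: float
    f_max: float
    ratio: float
    replicates: list[float]


def maze_fitness(trajectory: Trajectory, maze: Maze, mode: str = "per_step") -> float:
    """Evaluate the raw fitness of a recorded trajectory on its maze."""
    if trajectory.maze is not None and trajectory.maze is not maze:
        raise ContractError("trajectory was not produced on this maze")
    rows = trajectory.positions[1:, 0] % maze.period
    cols = trajectory.positions[1:, 1]
    d = maze.dist[rows, cols]
    if np.any(d < 0):
        raise ContractError("trajectory visits unreachable cells of this maze")
    c = trajectory.doors_passed
    if mode == "per_step":
        return float(c * maze.d_max + np.mean(maze.d_max - d))
    if mode == "final":
        return float(c * maze.d_max + (maze.d_max - d[-1]))
    raise ValueError(f"unknown fitness mode {mode!r}")


def optimal_walker_trajectory(maze: Maze, T: int = DEFAULT_T) -> Trajectory:
    """Deterministic shortest-path walker used to define f_max."""
    pos = maze.start
    positions = np.zeros((T + 1, 2), dtype=np.int64)
    positions[0] = pos
    doors = 0
    for t in range(T):
        row, col = pos
        d = maze.dist[row % maze.period, col]
        if d == 0:
            nxt = (row + 1, col)  # pass through the last doorway
        else:
            nxt = None
            for cand in ((row + 1, col), (row, col - 1), (row, col + 1)):
                if (
                    maze.standable(*cand)
                    and maze.dist[cand[0] % maze.period, cand[1]] == d - 1
                ):
                    nxt = cand
                    break
            if nxt is None:  # cannot happen on BFS-consistent distance fields
                nxt = pos
        if nxt[0] == row + 1 and row % maze.period == maze.last_wall_row:
            doors += 1
        pos = nxt
        positions[t + 1] = pos
    states = np.zeros((T + 1, 12), dtype=np.uint8)
    return Trajectory(positions=positions, states=states, doors_passed=doors, T=T, maze=maze)


def max_fitness(maze: Maze, T: int = DEFAULT_T, mode: str = "per_step") -> float:
    key = (T, mode)
    if key not in maze._fmax_cache:
        traj = optimal_walker_trajectory(maze, T)
        maze._fmax_cache[key] = maze_fitness(traj, maze, mode=mode)
    return maze._fmax_cache[key]


def fitness_ratio(trajectory: Trajectory, maze: Maze, mode: str = "per_step") -> float:
    return maze_fitness(trajectory, maze, mode=mode) / max_fitness(maze, trajectory.T, mode)


def selection_fitness(
    brain: MarkovBrain,
    maze: Maze,
    reps: int = DEFAULT_REPS,
    T: int = DEFAULT_T,
    rng: np.random.Generator | None = None,
    mode: str = "per_step",
) -> FitnessResult:
    """Geometric mean of ``reps`` stochastic evaluations of f/f_max."""
    if reps < 1:
        raise ContractError("reps must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    fmax = max_fitness(maze, T, mode)
    ratios = []
    for _ in range(reps):
        traj = run_animat(brain, maze, T=T, rng=rng)
        ratios.append(maze_fitness(traj, maze, mode=mode) / fmax)
    ratios_arr = np.asarray(ratios)
    pi = 0.0 if np.any(ratios_arr == 0) else float(np.exp(np.mean(np.log(ratios_arr))))
    return FitnessResult(
        f=float(np.mean(ratios_arr) * fmax), f_max=fmax, ratio=pi, replicates=ratios
    )


def control_fitness(
    brain: MarkovBrain,
    control_mazes: list[Maze],
    reps: int = DEFAULT_REPS,
    T: int = DEFAULT_T,
    rng: np.random.Generator | None = None,
    mode: str = "per_step",
) -> float:
    """Arithmetic mean of f/f_max over unseen mazes and replicates."""
    if rng is None:
        rng = np.random.default_rng()
    per_maze = []
    for maze in control_mazes:
        fmax = max_fitness(maze, T, mode)
        vals = [
            maze_fitness(run_animat(brain, maze, T=T, rng=rng), maze, mode=mode) / fmax
            for _ in range(reps)
        ]
        per_maze.append(np.mean(vals))
    return float(np.mean(per_maze))


def control_maze_set(
    rng: np.random.Generator, n: int = N_CONTROL_MAZES, **maze_params
) -> list[Maze]:
    return [generate_maze(rng, **maze_params) for _ in range(n)]
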