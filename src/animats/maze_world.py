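"""Periodic wall-and-door mazes and the embodied animat loop.

The world is a two-dimensional grid corridor of fixed width whose lateral
boundaries are walls.  Vertical walls (full rows with a single open door
cell) appear at random spacings; after the last wall the maze wraps, so the
environment is unbounded in the direction of travel.  Each door carries a
beacon bit that reads 1 iff the *next* door lies strictly to the right of
the current one; the bit is visible only while standing in the door.

The animat faces increasing row and cannot turn.  Its six sensors report:
front, left-front and right-front obstacles (bits 0-2), the door beacon
(bit 3), and lateral contact left/right (bits 4-5).  Its two motors move it
right (only bit 10), left (only bit 11), forward (both) or not at all;
moves into walls or the boundary leave it in place.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .markov_brain import MarkovBrain
from . import _kernels

DEFAULT_WIDTH = 16
DEFAULT_N_WALLS = 26
DEFAULT_SPACING = (3, 6)
DEFAULT_T = 1000


class MazeConfigError(ValueError):
    pass


@dataclass
class Maze:
    """Periodic corridor maze.

    ``walls`` lists (row, door_column) in increasing row order; ``period``
    is the number of rows before the maze repeats; ``dist[r, c]`` is the
    shortest-path distance (under legal animat moves) from cell (r, c) to
    the door of the last wall, and ``d_max`` its maximum over cells.
    """

    width: int
    walls: list[tuple[int, int]]
    period: int
    beacon_dirs: np.ndarray = field(init=False)
    dist: np.ndarray = field(init=False)
    d_max: int = field(init=False)
    start: tuple[int, int] = field(init=False)
    _fmax_cache: dict = field(init=False, default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.width < 3:
            raise MazeConfigError("corridor width must be >= 3")
        if len(self.walls) < 1:
            raise MazeConfigError("maze needs at least one wall")
        rows = [r for r, _ in self.walls]
        if rows != sorted(rows) or len(set(rows)) != len(rows):
            raise MazeConfigError("wall rows must be strictly increasing")
        if rows[-1] >= self.period:
            raise MazeConfigError("last wall must lie inside the period")
        for _, door in self.walls:
            if not 0 <= door < self.width:
                raise MazeConfigError("door column outside corridor")
        # beacon: 1 iff the next door (cyclically) is strictly to the right
        doors = [d for _, d in self.walls]
        nxt = doors[1:] + doors[:1]
        self.beacon_dirs = np.array(
            [1 if n > d else 0 for d, n in zip(doors, nxt)], dtype=np.uint8
        )
        self._wall_row = {r: d for r, d in self.walls}
        self.dist = self._bfs_distances()
        self.d_max = int(self.dist[self.dist >= 0].max())
        self.start = (0, self.width // 2)

    # --- geometry ---------------------------------------------------------
    @property
    def last_wall_row(self) -> int:
        return self.walls[-1][0]

    def is_wall_row(self, row: int) -> bool:
        return (row % self.period) in self._wall_row

    def door_col(self, row: int) -> int | None:
        return self._wall_row.get(row % self.period)

    def standable(self, row: int, col: int) -> bool:
        """Can the animat occupy (row, col)?  Row is taken modulo the period."""
        if not 0 <= col < self.width:
            return False
        r = row % self.period
        door = self._wall_row.get(r)
        return door is None or col == door

    def _bfs_distances(self) -> np.ndarray:
        """Distance-to-last-door via reverse BFS over legal moves."""
        dist = np.full((self.period, self.width), -1, dtype=np.int64)
        target = (self.last_wall_row, self._wall_row[self.last_wall_row])
        dist[target] = 0
        queue = [target]
        while queue:
            nxt = []
            for (r, c) in queue:
                d = dist[r, c]
                # predecessors: cells whose single move reaches (r, c)
                for (pr, pc) in (
                    (r, c - 1),            # moved right
                    (r, c + 1),            # moved left
                    ((r - 1) % self.period, c),  # moved forward
                ):
                    if self.standable(pr, pc) and dist[pr % self.period, pc] < 0:
                        dist[pr % self.period, pc] = d + 1
                        nxt.append((pr % self.period, pc))
            queue = nxt
        return dist

    # --- serialization ----------------------------------------------------
    def dumps(self) -> str:
        lines = [f"#animat-maze v1 width={self.width} period={self.period}"]
        lines += [f"{r}:{d}" for r, d in self.walls]
        return "\n".join(lines) + "\n"

    @classmethod
    def loads(cls, text: str) -> "Maze":
        lines = [ln for ln in text.strip().splitlines() if ln]
        head = lines[0].split()
        if not lines[0].startswith("#animat-maze v1"):
            raise MazeConfigError("not an animat-maze v1 file")
        width = int(head[2].split("=")[1])
        period = int(head[3].split("=")[1])
        walls = [tuple(int(x) for x in ln.split(":")) for ln in lines[1:]]
        return cls(width=width, walls=walls, period=period)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.dumps())

    @classmethod
    def load(cls, path: str | Path) -> "Maze":
        return cls.loads(Path(path).read_text())


def generate_maze(
    rng: np.random.Generator,
    width: int = DEFAULT_WIDTH,
    n_walls: int = DEFAULT_N_WALLS,
    spacing: tuple[int, int] = DEFAULT_SPACING,
) -> Maze:
    """Random maze: doors uniform in column, wall spacing uniform in ``spacing``."""
    if n_walls < DEFAULT_N_WALLS:
        raise MazeConfigError(f"maze must have at least {DEFAULT_N_WALLS} walls")
    lo, hi = spacing
    if lo < 1 or hi < lo:
        raise MazeConfigError("invalid wall spacing range")
    gaps = rng.integers(lo, hi + 1, size=n_walls + 1)
    rows = np.cumsum(gaps[:-1])
    period = int(rows[-1] + gaps[-1])
    doors = rng.integers(0, width, size=n_walls)
    walls = [(int(r), int(d)) for r, d in zip(rows, doors)]
    return Maze(width=width, walls=walls, period=period)


@dataclass
class Trajectory:
    """Recorded run: absolute positions, full 12-bit states, door passages."""

    positions: np.ndarray  # (T+1, 2) absolute (row, col)
    states: np.ndarray     # (T+1, n_vars) uint8
    doors_passed: int
    T: int
    maze: Maze | None = None

    def to_csv(self, path: str | Path) -> None:
        n = self.states.shape[1]
        header = "t,row,col," + ",".join(f"bit{i}" for i in range(n))
        rows = np.column_stack(
            [np.arange(self.T + 1), self.positions, self.states]
        )
        np.savetxt(path, rows, fmt="%d", delimiter=",", header=header, comments="")


def sense(maze: Maze, position: tuple[int, int]) -> np.ndarray:
    """Six sensor bits for an animat standing at ``position`` (absolute row)."""
    row, col = position
    bits = np.zeros(6, dtype=np.uint8)
    bits[0] = not maze.standable(row + 1, col)
    bits[1] = not maze.standable(row + 1, col - 1)
    bits[2] = not maze.standable(row + 1, col + 1)
    door = maze.door_col(row)
    if door is not None and col == door:
        widx = [r for r, _ in maze.walls].index(row % maze.period)
        bits[3] = maze.beacon_dirs[widx]
    bits[4] = not maze.standable(row, col - 1)
    bits[5] = not maze.standable(row, col + 1)
    return bits


def act(maze: Maze, position: tuple[int, int], motor_bits) -> tuple[int, int]:
    """Apply one move; blocked moves leave the position unchanged."""
    row, col = position
    b10, b11 = int(motor_bits[0]), int(motor_bits[1])
    if b10 and b11:
        tr, tc = row + 1, col
    elif b10:
        tr, tc = row, col + 1
    elif b11:
        tr, tc = row, col - 1
    else:
        return (row, col)
    if maze.standable(tr, tc):
        return (tr, tc)
    return (row, col)


def run_animat(
    brain: MarkovBrain,
    maze: Maze,
    T: int = DEFAULT_T,
    rng: np.random.Generator | None = None,
    record: bool = True,
) -> Trajectory:
    """Simulate ``T`` world steps from an all-zero initial brain state.

    Per step: sensors are written into the state, the brain updates, the
    motor bits of the *new* state are applied as a move, and the new
    position's sensors overwrite the sensor bits.  Uses the compiled kernel;
    ``animats.reference.run_animat_reference`` is the pure-Python twin.
    """
    if rng is None:
        rng = np.random.default_rng()
    arrays = _kernels.brain_arrays(brain)
    maze_arr = _kernels.maze_arrays(maze)
    uniforms = rng.random(T * max(len(brain.gates), 1))
    positions, states, doors, dist_sum = _kernels.run_kernel(
        *arrays, *maze_arr, maze.start[0], maze.start[1], T, uniforms
    )
    return Trajectory(
        positions=positions,
        states=states,
        doors_passed=int(doors),
        T=T,
        maze=maze,
    )
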