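"""Genetic-algorithm driver with elitism, roulette-wheel selection and
line-of-descent reconstruction.

Each generation the whole population is scored with the selection fitness
on the current maze, the top three genomes (the elite) are copied over
unmutated unless a fresh re-test scores zero, and the remaining slots are
filled by fitness-proportional sampling (no parent may place more than ten
roulette offspring) followed by mutation.  A fresh selection maze replaces
the old one every ``maze_refresh`` generations.  Reproduction is asexual,
so the genealogy is a forest of single-parent edges and the final
population coalesces backwards onto a single line of descent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import Genome, MutationRates, decode, mutate, random_genome
from .fitness import max_fitness, selection_fitness
from .maze_world import generate_maze


@dataclass
class EvolutionConfig:
    pop_size: int = 300
    generations: int = 50_000
    elite: int = 3
    offspring_cap: int = 10
    genome_length: int = 3000
    target_gates: int = 12
    selection_reps: int = 10
    selection_T: int = 1000
    maze_refresh: int = 100
    checkpoint_every: int = 500
    lod_final_offset: int = 1000
    maze_width: int = 16
    maze_walls: int = 26
    maze_spacing: tuple[int, int] = (3, 6)
    fitness_mode: str = "per_step"
    rates: MutationRates = field(default_factory=MutationRates)

    def as_dict(self) -> dict:
        d = asdict(self)
        d["maze_spacing"] = list(self.maze_spacing)
        return d


def demo_profile(**overrides) -> EvolutionConfig:
    """Desk-scale profile: small population, short runs, light evaluation."""
    cfg = EvolutionConfig(
        pop_size=100,
        generations=2000,
        selection_reps=5,
        selection_T=500,
        checkpoint_every=500,
        lod_final_offset=200,
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


@dataclass
class RunRecord:
    config: EvolutionConfig
    fitness_log: pd.DataFrame          # generation, best_pi, mean_pi
    genealogy: list[np.ndarray]        # per generation: parent index of member i
    snapshots: dict[int, list[Genome]]  # checkpoint generation -> population
    final_population: list[Genome]
    final_fitness: np.ndarray
    initial_fitness: np.ndarray | None = None

    @property
    def checkpoint_gens(self) -> list[int]:
        return sorted(self.snapshots)


def _ratio_from_arrays(barr, n_gates, maze, marr, fmax, cfg, rng) -> float:
    from . import _kernels

    uniforms = rng.random(cfg.selection_reps * cfg.selection_T * max(n_gates, 1))
    stats = _kernels.fitness_kernel(
        *barr, *marr, maze.start[0], maze.start[1],
        cfg.selection_T, cfg.selection_reps, uniforms,
    )
    if cfg.fitness_mode == "per_step":
        f = stats[:, 0] * maze.d_max + stats[:, 1] / cfg.selection_T
    else:
        f = stats[:, 0] * maze.d_max + stats[:, 2]
    ratios = f / fmax
    if np.any(ratios == 0):
        return 0.0
    return float(np.exp(np.mean(np.log(ratios))))


def _selection_ratio_fast(genome: Genome, maze, cfg, rng) -> float:
    """Geometric-mean selection fitness via the no-recording kernel."""
    from . import _kernels
    from .fitness import max_fitness

    fmax = max_fitness(maze, cfg.selection_T, cfg.fitness_mode)
    barr = _kernels.decode_arrays(genome.loci)
    marr = _kernels.maze_arrays(maze)
    return _ratio_from_arrays(barr, barr[1].shape[0], maze, marr, fmax, cfg, rng)


def _evaluate_population(genomes, maze, cfg, rng):
    """Score the whole population with one batched kernel call."""
    from . import _kernels
    from .fitness import max_fitness

    fmax = max_fitness(maze, cfg.selection_T, cfg.fitness_mode)
    marr = _kernels.maze_arrays(maze)
    n = len(genomes)
    parts = [_kernels.decode_arrays(g.loci) for g in genomes]
    gate_count = np.array([p[1].shape[0] for p in parts], dtype=np.int64)
    gate_start = np.concatenate([[0], np.cumsum(gate_count)[:-1]])
    cum_sizes = np.array([p[3].size for p in parts], dtype=np.int64)
    cum_start = np.concatenate([[0], np.cumsum(cum_sizes)[:-1]])
    g_in = np.ascontiguousarray(np.concatenate([p[1] for p in parts]))
    offs = np.concatenate([p[2] for p in parts])
    cum = np.concatenate([p[3] for p in parts])
    g_wmask = np.ascontiguousarray(np.concatenate([p[4] for p in parts]))
    sensor_mask = parts[0][9]
    seeds = rng.integers(1, 2**63, size=n, dtype=np.uint64)
    stats = _kernels.population_fitness_kernel(
        gate_start, gate_count, cum_start,
        g_in, offs, cum, g_wmask, sensor_mask,
        *marr, maze.start[0], maze.start[1],
        cfg.selection_T, cfg.selection_reps, seeds,
    )
    if cfg.fitness_mode == "per_step":
        f = stats[:, :, 0] * maze.d_max + stats[:, :, 1] / cfg.selection_T
    else:
        f = stats[:, :, 0] * maze.d_max + stats[:, :, 2]
    ratios = f / fmax
    scores = np.where(
        (ratios == 0).any(axis=1), 0.0, np.exp(np.log(np.maximum(ratios, 1e-300)).mean(axis=1))
    )
    return scores


def _roulette_parents(scores, n_offspring, cap, rng):
    """Fitness-proportional parent draws with a per-parent offspring cap."""
    weights = np.asarray(scores, dtype=np.float64).copy()
    if weights.sum() <= 0:
        weights = np.ones_like(weights)
    counts = np.zeros(len(weights), dtype=np.int64)
    parents = np.zeros(n_offspring, dtype=np.int64)
    probs = weights / weights.sum()
    for j in range(n_offspring):
        p = int(rng.choice(len(weights), p=probs))
        parents[j] = p
        counts[p] += 1
        if counts[p] >= cap:
            weights[p] = 0.0
            if weights.sum() <= 0:
                weights = np.where(counts >= cap, 0.0, 1.0)
                if weights.sum() <= 0:  # every member capped: reopen all
                    weights = np.ones_like(weights)
            probs = weights / weights.sum()
    return parents


def next_generation(genomes, scores, maze, cfg: EvolutionConfig, rng):
    """One generational turnover; returns (new genomes, parent indices)."""
    pop = len(genomes)
    order = np.argsort(-scores, kind="stable")
    elite_idx = []
    for i in order[: cfg.elite]:
        retest = _selection_ratio_fast(genomes[i], maze, cfg, rng)
        if retest > 0:
            elite_idx.append(int(i))
    n_offspring = pop - len(elite_idx)
    parents = _roulette_parents(scores, n_offspring, cfg.offspring_cap, rng)
    new_genomes: list[Genome] = []
    parent_of = np.zeros(pop, dtype=np.int64)
    for slot, i in enumerate(elite_idx):
        new_genomes.append(genomes[i].copy())
        parent_of[slot] = i
    for slot, p in enumerate(parents, start=len(elite_idx)):
        new_genomes.append(mutate(genomes[p], cfg.rates, rng))
        parent_of[slot] = p
    return new_genomes, parent_of


def evolve(cfg: EvolutionConfig, seed: int, progress: bool = False) -> RunRecord:
    """Run one evolution experiment; deterministic under a fixed seed."""
    rng = np.random.default_rng(seed)
    genomes = [random_genome(rng, cfg.target_gates, cfg.genome_length) for _ in range(cfg.pop_size)]
    maze = generate_maze(rng, cfg.maze_width, cfg.maze_walls, cfg.maze_spacing)
    genealogy: list[np.ndarray] = []
    snapshots: dict[int, list[Genome]] = {}
    log_rows = []
    scores = _evaluate_population(genomes, maze, cfg, rng)
    initial_scores = scores.copy()
    for gen in range(cfg.generations):
        if gen % cfg.checkpoint_every == 0:
            snapshots[gen] = [g.copy() for g in genomes]
        log_rows.append(
            {"generation": gen, "best_pi": float(scores.max()), "mean_pi": float(scores.mean())}
        )
        genomes, parent_of = next_generation(genomes, scores, maze, cfg, rng)
        genealogy.append(parent_of)
        if (gen + 1) % cfg.maze_refresh == 0:
            maze = generate_maze(rng, cfg.maze_width, cfg.maze_walls, cfg.maze_spacing)
        scores = _evaluate_population(genomes, maze, cfg, rng)
        if progress and (gen + 1) % 100 == 0:
            print(f"gen {gen + 1}: best_pi={scores.max():.3f}")
    snapshots[cfg.generations] = [g.copy() for g in genomes]
    log_rows.append(
        {
            "generation": cfg.generations,
            "best_pi": float(scores.max()),
            "mean_pi": float(scores.mean()),
        }
    )
    return RunRecord(
        config=cfg,
        fitness_log=pd.DataFrame(log_rows),
        genealogy=genealogy,
        snapshots=snapshots,
        final_population=genomes,
        final_fitness=scores,
        initial_fitness=initial_scores,
    )


@dataclass
class LOD:
    """Line of descent: member index per generation, and coalescence info."""

    indices: np.ndarray          # (generations+1,) index of the LOD member
    coalesced_from: int          # earliest generation where all lines agree

    def genome_at(self, record: RunRecord, generation: int) -> Genome:
        if generation not in record.snapshots:
            raise KeyError(
                f"no snapshot at generation {generation}; available: "
                f"{sorted(record.snapshots)}"
            )
        return record.snapshots[generation][int(self.indices[generation])]


def line_of_descent(
    genealogy: list[np.ndarray],
    final_scores: np.ndarray | None = None,
) -> LOD:
    """Backtrace every final member to the founders; report the fused line.

    The representative line follows the fittest final member (first index on
    ties).  ``coalesced_from`` is the earliest generation at which all final
    members share the same ancestor; in pathological short runs it may equal
    the number of generations.
    """
    n_gens = len(genealogy)
    pop = genealogy[0].size if n_gens else 0
    if n_gens == 0:
        raise ValueError("empty genealogy")
    rep = int(np.argmax(final_scores)) if final_scores is not None else 0
    # trace all members backwards, generation by generation
    current = np.arange(pop)
    indices_all = np.zeros((n_gens + 1, pop), dtype=np.int64)
    indices_all[n_gens] = current
    for g in range(n_gens - 1, -1, -1):
        current = genealogy[g][current]
        indices_all[g] = current
    coalesced_from = n_gens + 1  # sentinel: not coalesced anywhere
    for g in range(n_gens + 1):
        if np.all(indices_all[g] == indices_all[g, 0]):
            coalesced_from = g
        else:
            break
    rep_line = np.zeros(n_gens + 1, dtype=np.int64)
    rep_line[n_gens] = rep
    cur = rep
    for g in range(n_gens - 1, -1, -1):
        cur = int(genealogy[g][cur])
        rep_line[g] = cur
    return LOD(indices=rep_line, coalesced_from=coalesced_from)


def lod_final_generation(record: RunRecord, lod: LOD) -> int:
    """The configured 'final' LOD generation, clipped to the coalesced range.

    Default convention: ``generations - lod_final_offset`` (at full scale,
    generation 49,000 of 50,000).  If the lineage has not coalesced by then, the
    latest checkpointed generation at or before coalescence is returned
    with a warning.
    """
    import warnings

    cfg = record.config
    requested = max(cfg.generations - cfg.lod_final_offset, 0)
    # snap to an available snapshot
    gens = [g for g in record.checkpoint_gens if g <= requested]
    target = gens[-1] if gens else record.checkpoint_gens[0]
    if target < lod.coalesced_from:
        safe = [g for g in record.checkpoint_gens if g >= lod.coalesced_from]
        warnings.warn(
            f"lineage not coalesced at generation {target}; "
            f"using generation {safe[0] if safe else target}"
        )
        if safe:
            target = safe[0]
    return target


def save_genealogy(genealogy: list[np.ndarray], path: str | Path) -> None:
    """Append-style text log: one `generation index parent` triple per line."""
    with Path(path).open("w") as fh:
        for gen, parents in enumerate(genealogy):
            for idx, parent in enumerate(parents):
                fh.write(f"{gen + 1} {idx} {int(parent)}\n")


def load_genealogy(path: str | Path) -> list[np.ndarray]:
    rows = np.loadtxt(path, dtype=np.int64, ndmin=2)
    gens = []
    for g in np.unique(rows[:, 0]):
        sub = rows[rows[:, 0] == g]
        parents = np.zeros(sub.shape[0], dtype=np.int64)
        parents[sub[:, 1]] = sub[:, 2]
        gens.append(parents)
    return gens
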