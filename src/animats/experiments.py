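"""Multi-run experiments: LOD measures, correlation tables, statistics.

The central analysis is a rank correlation across independent evolution
runs between each information measure — evaluated for the line-of-descent
genome at the configured final generation — and that genome's fitness,
mirroring the question "which complexity proxy predicts adaptation?".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome import Genome, decode
from .fitness import control_fitness, control_maze_set, selection_fitness
from .maze_world import run_animat
from .infotheory import InfoSummary, estimate_pairs, summarize_pairs
from .evolution import (
    EvolutionConfig,
    RunRecord,
    evolve,
    line_of_descent,
    lod_final_generation,
)

MEASURE_COLUMNS = ["I_pred", "I_total", "I_multi", "I_syn", "Phi_atomic", "Phi", "Phi_MC"]
LOD_CSV_COLUMNS = (
    ["generation", "fitness", "control_fitness"] + MEASURE_COLUMNS + ["mc_nodes"]
)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with average-rank ties; p via t-approximation."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def fisher_r_to_z(r1: float, r2: float, n: int) -> tuple[float, float]:
    """Compare two correlations measured on the same n samples.

    z = (atanh r1 - atanh r2) / sqrt(2/(n-3)), two-sided normal p-value.
    """
    if not (abs(r1) < 1 and abs(r2) < 1):
        raise ValueError("correlations must lie strictly inside (-1, 1)")
    if n <= 3:
        raise ValueError("need n > 3")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(2.0 / (n - 3))
    p = 2 * stats.norm.sf(abs(z))
    return float(z), float(p)


def measure_brain(
    brain,
    mazes,
    reps: int = 10,
    T: int = 1000,
    rng: np.random.Generator | None = None,
    compute_phi: bool = True,
    compute_main_complex: bool = True,
    fitness_mode: str = "per_step",
) -> tuple[InfoSummary, float]:
    """Run the measurement protocol: trajectories on control mazes, then all
    information measures from the pooled pair distribution.

    Returns (InfoSummary, control fitness) computed from the same sample.
    """
    if rng is None:
        rng = np.random.default_rng()
    trajectories = []
    from .fitness import max_fitness, maze_fitness

    ratios = []
    for maze in mazes:
        fmax = max_fitness(maze, T, fitness_mode)
        maze_ratios = []
        for _ in range(reps):
            traj = run_animat(brain, maze, T=T, rng=rng)
            trajectories.append(traj)
            maze_ratios.append(maze_fitness(traj, maze, mode=fitness_mode) / fmax)
        ratios.append(np.mean(maze_ratios))
    pairs = estimate_pairs(trajectories, nodes=range(brain.n_vars))
    summary = summarize_pairs(
        pairs,
        sensor_nodes=brain.sensor_ids,
        motor_nodes=brain.motor_ids,
        compute_phi=compute_phi,
        compute_main_complex=compute_main_complex,
    )
    return summary, float(np.mean(ratios))


@dataclass
class RunSummary:
    run_id: int
    final_generation: int
    fitness: float
    control_fitness: float
    measures: InfoSummary

    def as_row(self) -> dict:
        row = {
            "run_id": self.run_id,
            "final_generation": self.final_generation,
            "fitness": self.fitness,
            "control_fitness": self.control_fitness,
        }
        row.update(self.measures.as_dict())
        return row


def summarize_run(
    record: RunRecord,
    run_id: int,
    seed: int,
    reps: int = 10,
    T: int = 1000,
    n_control_mazes: int = 10,
    compute_phi: bool = False,
    compute_main_complex: bool = False,
) -> RunSummary:
    """Measure the LOD genome at the configured final generation."""
    lod = line_of_descent(record.genealogy, record.final_fitness)
    gen = lod_final_generation(record, lod)
    genome = lod.genome_at(record, gen)
    brain = decode(genome)
    rng = np.random.default_rng(seed)
    mazes = control_maze_set(
        rng,
        n=n_control_mazes,
        width=record.config.maze_width,
        n_walls=record.config.maze_walls,
        spacing=record.config.maze_spacing,
    )
    summary, cf = measure_brain(
        brain, mazes, reps=reps, T=T, rng=rng,
        compute_phi=compute_phi, compute_main_complex=compute_main_complex,
        fitness_mode=record.config.fitness_mode,
    )
    sel = selection_fitness(
        brain, mazes[0], reps=reps, T=T, rng=rng, mode=record.config.fitness_mode
    )
    return RunSummary(
        run_id=run_id,
        final_generation=gen,
        fitness=sel.ratio,
        control_fitness=cf,
        measures=summary,
    )


def correlation_table(summaries: list[RunSummary]) -> pd.DataFrame:
    """Spearman rho and p of every measure against final fitness across runs."""
    if len(summaries) < 3:
        raise ValueError("need at least 3 runs")
    df = pd.DataFrame([s.as_row() for s in summaries])
    rows = []
    for col in MEASURE_COLUMNS:
        if df[col].isna().any():
            rows.append({"measure": col, "rho": np.nan, "p": np.nan})
            continue
        rho, p = spearman(df[col].to_numpy(), df["control_fitness"].to_numpy())
        rows.append({"measure": col, "rho": rho, "p": p})
    return pd.DataFrame(rows)


def lod_measures(
    record: RunRecord,
    seed: int,
    reps: int = 10,
    T: int = 1000,
    n_control_mazes: int = 10,
    compute_phi: bool = False,
    compute_main_complex: bool = False,
) -> pd.DataFrame:
    """Measure every checkpointed LOD genome; schema matches lod_measures.csv."""
    lod = line_of_descent(record.genealogy, record.final_fitness)
    rng = np.random.default_rng(seed)
    mazes = control_maze_set(
        rng,
        n=n_control_mazes,
        width=record.config.maze_width,
        n_walls=record.config.maze_walls,
        spacing=record.config.maze_spacing,
    )
    rows = []
    for gen in record.checkpoint_gens:
        genome = lod.genome_at(record, gen)
        brain = decode(genome)
        summary, cf = measure_brain(
            brain, mazes, reps=reps, T=T, rng=rng,
            compute_phi=compute_phi, compute_main_complex=compute_main_complex,
            fitness_mode=record.config.fitness_mode,
        )
        sel = selection_fitness(
            brain, mazes[0], reps=reps, T=T, rng=rng, mode=record.config.fitness_mode
        )
        row = {"generation": gen, "fitness": sel.ratio, "control_fitness": cf}
        row.update(summary.as_dict())
        rows.append(row)
    return pd.DataFrame(rows)[LOD_CSV_COLUMNS]


def run_experiment(
    n_runs: int,
    cfg: EvolutionConfig,
    seed: int,
    measure_reps: int = 10,
    measure_T: int = 1000,
    compute_phi: bool = False,
    compute_main_complex: bool = False,
) -> tuple[list[RunSummary], list[RunRecord]]:
    """Evolve ``n_runs`` independent populations and summarize each."""
    summaries = []
    records = []
    for run_id in range(n_runs):
        record = evolve(cfg, seed=seed + 1000 * run_id)
        records.append(record)
        summaries.append(
            summarize_run(
                record,
                run_id=run_id,
                seed=seed + 1000 * run_id + 1,
                reps=measure_reps,
                T=measure_T,
                compute_phi=compute_phi,
                compute_main_complex=compute_main_complex,
            )
        )
    return summaries, records
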