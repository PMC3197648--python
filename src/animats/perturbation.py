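"""Knock-out analyses: clamp variables, delete gates, replace table entries.

All perturbations operate on decoded brains (never on genome files) and are
evaluated with common random numbers — the same control-maze set and the
same random seeds for baseline and every variant — so that the fitness
delta of a behaviorally neutral perturbation is exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .markov_brain import ContractError, MarkovBrain
from .maze_world import Maze
from .fitness import control_fitness
from .reference import run_animat_reference

READ_MODES = ("read0", "read1")
WRITE_MODES = ("write0", "write1")


def knockout_variable(brain: MarkovBrain, var: int, mode: str) -> MarkovBrain:
    """Clamp what gates read from ``var`` or what gets stored into it."""
    if not 0 <= var < brain.n_vars:
        raise ContractError(f"variable {var} out of range")
    variant = brain.copy()
    value = 1 if mode.endswith("1") else 0
    if mode in READ_MODES:
        variant.read_clamp[var] = value
    elif mode in WRITE_MODES:
        variant.write_clamp[var] = value
    else:
        raise ValueError(f"unknown knockout mode {mode!r}")
    return variant


def knockout_gate(brain: MarkovBrain, gate_index: int) -> MarkovBrain:
    """Delete one gate from the controller."""
    if not 0 <= gate_index < len(brain.gates):
        raise ContractError(f"gate index {gate_index} out of range")
    variant = brain.copy()
    del variant.gates[gate_index]
    return variant


def knockout_table_entry(
    brain: MarkovBrain, gate_index: int, row: int, col: int, value: int
) -> MarkovBrain:
    """Replace a single pre-clamp weight by 0 or 255."""
    if value not in (0, 255):
        raise ContractError("knockout value must be 0 or 255")
    variant = brain.copy()
    gate = variant.gates[gate_index]
    if not (0 <= row < gate.table.shape[0] and 0 <= col < gate.table.shape[1]):
        raise ContractError("table entry out of range")
    gate.table[row, col] = value
    return variant


@dataclass
class KnockoutReport:
    baseline: float
    table: pd.DataFrame  # perturbation, target, value, fitness, delta
    gate_input_usage: dict[int, np.ndarray] = field(default_factory=dict)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _paired_control_fitness(brain, mazes, seeds, reps, T, mode) -> float:
    vals = []
    for seed in seeds:
        vals.append(
            control_fitness(
                brain, mazes, reps=reps, T=T,
                rng=np.random.default_rng(seed), mode=mode,
            )
        )
    return float(np.mean(vals))


def knockout_screen(
    brain: MarkovBrain,
    control_mazes: list[Maze],
    seeds=(0,),
    reps: int = 10,
    T: int = 1000,
    mode: str = "per_step",
    include_table_entries: bool = True,
) -> KnockoutReport:
    """Run every variable, gate (and optionally table-entry) knock-out.

    Each variant is evaluated with the identical maze set and seed list as
    the baseline; the report also tallies how often each gate saw each of
    its input patterns during the baseline runs.
    """
    baseline = _paired_control_fitness(brain, control_mazes, seeds, reps, T, mode)
    rows = []
    for var in range(brain.n_vars):
        for komode in READ_MODES + WRITE_MODES:
            variant = knockout_variable(brain, var, komode)
            fit = _paired_control_fitness(variant, control_mazes, seeds, reps, T, mode)
            rows.append(("variable", f"{var}:{komode}", "", fit, fit - baseline))
    for gi in range(len(brain.gates)):
        variant = knockout_gate(brain, gi)
        fit = _paired_control_fitness(variant, control_mazes, seeds, reps, T, mode)
        rows.append(("gate", str(gi), "", fit, fit - baseline))
    if include_table_entries:
        for gi, gate in enumerate(brain.gates):
            for r in range(gate.table.shape[0]):
                for c in range(gate.table.shape[1]):
                    for value in (0, 255):
                        variant = knockout_table_entry(brain, gi, r, c, value)
                        fit = _paired_control_fitness(
                            variant, control_mazes, seeds, reps, T, mode
                        )
                        rows.append(
                            ("table", f"{gi}:{r}:{c}", str(value), fit, fit - baseline)
                        )
    table = pd.DataFrame(
        rows, columns=["perturbation", "target", "value", "fitness", "delta"]
    ).sort_values("delta", kind="stable", ignore_index=True)

    # per-gate input-pattern usage histogram from the baseline runs
    usage = {
        gi: np.zeros(2 ** g.n_inputs, dtype=np.int64) for gi, g in enumerate(brain.gates)
    }
    for seed in seeds:
        rng = np.random.default_rng(seed)
        for maze in control_mazes:
            uniforms = rng.random(T * max(len(brain.gates), 1))
            _traj, gate_rows = run_animat_reference(
                brain, maze, T, uniforms, collect_gate_rows=True
            )
            for gi in usage:
                counts = np.bincount(gate_rows[:, gi], minlength=usage[gi].size)
                usage[gi] += counts
    return KnockoutReport(baseline=baseline, table=table, gate_input_usage=usage)
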