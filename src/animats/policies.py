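"""Hand-coded controllers expressed as minimally stochastic Markov brains.

The beacon-memorizing policy is the best simple strategy for the
wall-and-door maze: run forward until blocked, remember the last door
beacon in internal bit 9, sweep toward the remembered side along the wall,
and step through the opening.  Lateral boundary contact corrects a wrong
(or corrupted) memory bit, so the policy recovers from the stochastic
slips that the +1 weight clamp makes unavoidable.

All gate tables use only the extreme weights 0 and 255, so each intended
transition fires with probability 256/257 per gate per step.
"""

from __future__ import annotations

import numpy as np

from .markov_brain import HMGate, MarkovBrain


def _one_output_table(truth: list[int]) -> np.ndarray:
    """Weight table for a 1-output gate from a row -> bit truth vector."""
    table = np.zeros((len(truth), 2), dtype=np.int64)
    for row, bit in enumerate(truth):
        table[row, 1 if bit else 0] = 255
    return table


def beacon_policy_brain() -> MarkovBrain:
    """Three-gate implementation of the beacon-memorizing navigation policy.

    Memory gate (bits 3,4,5,9 -> 9): in a door (both lateral contacts set)
    store the beacon; at the left boundary force 1 (door must be right), at
    the right boundary force 0; otherwise hold.  Motor gates (bits 0,4,5,9
    -> 10 and 11): move forward while the front is clear, otherwise sweep
    right iff the memory says right (boundary contact overrides).
    """
    mem_truth = []
    for row in range(16):
        b3 = (row >> 3) & 1
        b4 = (row >> 2) & 1
        b5 = (row >> 1) & 1
        m = row & 1
        if b4 and b5:
            mem_truth.append(b3)
        elif b4:
            mem_truth.append(1)
        elif b5:
            mem_truth.append(0)
        else:
            mem_truth.append(m)
    right_truth = []
    left_truth = []
    for row in range(16):
        b0 = (row >> 3) & 1
        b4 = (row >> 2) & 1
        b5 = (row >> 1) & 1
        m = row & 1
        if not b0:
            right_truth.append(1)
            left_truth.append(1)
        else:
            right_truth.append(1 if (b4 or (m and not b5)) else 0)
            left_truth.append(1 if (b5 or (not m and not b4)) else 0)
    gates = [
        HMGate((3, 4, 5, 9), (9,), _one_output_table(mem_truth)),
        HMGate((0, 4, 5, 9), (10,), _one_output_table(right_truth)),
        HMGate((0, 4, 5, 9), (11,), _one_output_table(left_truth)),
    ]
    return MarkovBrain(gates=gates)
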