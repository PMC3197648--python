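"""Circular byte genomes encoding Markov brains, and their mutation operators.

Gene layout (versioned: ``animat-genome v1``)::

    42 213 | a_in a_out | i0 i1 i2 i3 | o0 o1 o2 | table bytes ...

``42 213`` is the start codon.  The number of inputs is ``1 + a_in % 4``,
the number of outputs ``1 + a_out % 3``.  Four input-id bytes and three
output-id bytes are always present; only the first m (n) are used, each
taken modulo the number of brain variables.  The table occupies
``2^m * 2^n`` bytes, row-major, read circularly past the genome end if
necessary.

Decoding scans the sequence once from position 0; a start codon that falls
inside an already-decoded gene's extent is non-coding.  When a read or write
would exceed a variable's limit of three connections the connection is
rerouted to the nearest available variable (smallest circular index
distance, ties to the lower index); if no variable has spare capacity the
connection is dropped, and a gate left without inputs or outputs is
discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .markov_brain import (
    HMGate,
    MarkovBrain,
    MAX_CONNECTIONS,
    MAX_INPUTS,
    MAX_OUTPUTS,
    N_VARS,
)

START_CODON = (42, 213)
HEADER_LEN = 2 + 2 + MAX_INPUTS + MAX_OUTPUTS  # codon, arities, id fields
DEFAULT_LENGTH = 3000
DEFAULT_TARGET_GATES = 12


@dataclass
class Genome:
    """Circular sequence of byte loci plus lineage provenance."""

    loci: np.ndarray
    parent_id: int | None = None
    generation: int = 0

    def __post_init__(self) -> None:
        self.loci = np.asarray(self.loci, dtype=np.uint8)
        if self.loci.size < 1:
            raise ValueError("genome must contain at least one locus")

    def __len__(self) -> int:
        return int(self.loci.size)

    def copy(self) -> "Genome":
        return replace(self, loci=self.loci.copy())


@dataclass
class MutationRates:
    """Per-locus and per-gene mutation probabilities.

    With ``normalize=True`` all rates are rescaled each call so the expected
    number of changed loci per genome per generation is one (gene-level
    events are weighted by the loci they touch).
    """

    copy: float = 0.0005
    delete: float = 0.0005
    insert: float = 0.0005
    replace: float = 0.005
    perturb: float = 0.005
    perturb_range: int = 8
    gene_duplicate: float = 0.0005
    gene_delete: float = 0.0005
    gene_insert: float = 0.0005
    normalize: bool = True

    def __post_init__(self) -> None:
        for name in (
            "copy", "delete", "insert", "replace", "perturb",
            "gene_duplicate", "gene_delete", "gene_insert",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"rate {name} must be >= 0")


def _circular_distance(a: int, b: int, n: int) -> int:
    d = abs(a - b) % n
    return min(d, n - d)


def _nearest_available(requested: int, counts: np.ndarray, n_vars: int) -> int | None:
    """Variable closest to ``requested`` with spare capacity (ties: lower index)."""
    if counts[requested] < MAX_CONNECTIONS:
        return requested
    best = None
    best_key = None
    for v in range(n_vars):
        if counts[v] >= MAX_CONNECTIONS:
            continue
        key = (_circular_distance(requested, v, n_vars), v)
        if best_key is None or key < best_key:
            best, best_key = v, key
    return best


def find_gene_starts(loci: np.ndarray, n_vars: int = N_VARS) -> list[int]:
    """Start positions of decoded genes under the sequential, non-overlapping scan."""
    starts = []
    for start, _, _, _ in _scan_genes(loci):
        starts.append(start)
    return starts


def _scan_genes(loci: np.ndarray):
    """Yield (start, n_inputs, n_outputs, gene_length) for each coding gene."""
    L = loci.size
    hits = (loci[:-1] == START_CODON[0]) & (loci[1:] == START_CODON[1])
    candidates = list(np.nonzero(hits)[0])
    if L > 1 and loci[-1] == START_CODON[0] and loci[0] == START_CODON[1]:
        candidates.append(L - 1)
    floor = 0
    for i in candidates:
        i = int(i)
        if i < floor:
            continue
        m = 1 + int(loci[(i + 2) % L]) % MAX_INPUTS
        n = 1 + int(loci[(i + 3) % L]) % MAX_OUTPUTS
        length = HEADER_LEN + (2**m) * (2**n)
        yield i, m, n, length
        floor = i + length


def decode(genome: Genome, n_vars: int = N_VARS) -> MarkovBrain:
    """Translate a genome into a Markov brain (pure and deterministic)."""
    loci = genome.loci
    L = loci.size
    gates: list[HMGate] = []
    read_counts = np.zeros(n_vars, dtype=np.int64)
    write_counts = np.zeros(n_vars, dtype=np.int64)
    for start, m, n, _length in _scan_genes(loci):
        at = lambda k: int(loci[(start + k) % L])  # noqa: E731
        requested_in = [at(4 + j) % n_vars for j in range(m)]
        requested_out = [at(4 + MAX_INPUTS + j) % n_vars for j in range(n)]
        resolved_in = []
        tentative_reads = read_counts.copy()
        for v in requested_in:
            target = _nearest_available(v, tentative_reads, n_vars)
            if target is not None:
                tentative_reads[target] += 1
                resolved_in.append(target)
        resolved_out = []
        tentative_writes = write_counts.copy()
        for v in requested_out:
            target = _nearest_available(v, tentative_writes, n_vars)
            if target is not None:
                tentative_writes[target] += 1
                resolved_out.append(target)
        if not resolved_in or not resolved_out:
            continue  # connection capacity exhausted: gene is non-functional
        read_counts = tentative_reads
        write_counts = tentative_writes
        m_eff, n_eff = len(resolved_in), len(resolved_out)
        n_table = (2**m_eff) * (2**n_eff)
        idx = (start + HEADER_LEN + np.arange(n_table)) % L
        table = loci[idx].astype(np.int64).reshape(2**m_eff, 2**n_eff)
        gates.append(HMGate(tuple(resolved_in), tuple(resolved_out), table))
    return MarkovBrain(gates=gates, n_vars=n_vars)


def encode(brain: MarkovBrain, pad_to: int | None = None,
           rng: np.random.Generator | None = None) -> Genome:
    """Emit a genome whose decode reproduces ``brain``'s gate structure.

    Genes are written contiguously from position 0; optional random padding
    (scrubbed of accidental start codons) extends the genome to ``pad_to``.
    """
    parts: list[int] = []
    for gate in brain.gates:
        m, n = gate.n_inputs, gate.n_outputs
        parts += list(START_CODON)
        parts += [m - 1, n - 1]
        parts += list(gate.input_ids) + [0] * (MAX_INPUTS - m)
        parts += list(gate.output_ids) + [0] * (MAX_OUTPUTS - n)
        parts += [int(w) for w in gate.table.ravel()]
    if pad_to is not None and pad_to > len(parts):
        if rng is None:
            rng = np.random.default_rng(0)
        pad = rng.integers(0, 256, size=pad_to - len(parts)).tolist()
        parts = _scrub_codons(parts + pad, n_coding=len(parts))
    if not parts:
        parts = [0]
    return Genome(loci=np.array(parts, dtype=np.uint8))


def _scrub_codons(seq: list[int], n_coding: int) -> list[int]:
    """Remove accidental start codons from the non-coding tail of ``seq``."""
    L = len(seq)
    for i in range(max(n_coding - 1, 0), L):
        j = (i + 1) % L
        if seq[i] == START_CODON[0] and seq[j] == START_CODON[1] and j >= n_coding:
            seq[j] = START_CODON[1] + 1
    return seq


def _random_gene(rng: np.random.Generator, read_counts: np.ndarray,
                 write_counts: np.ndarray, n_vars: int,
                 max_in: int = MAX_INPUTS, max_out: int = MAX_OUTPUTS) -> list[int] | None:
    """Random gene bytes whose connections respect spare capacity, or None."""
    if max_in < 1 or max_out < 1:
        return None
    m = int(rng.integers(1, max_in + 1))
    n = int(rng.integers(1, max_out + 1))
    ins, outs = [], []
    for _ in range(m):
        v = _nearest_available(int(rng.integers(0, n_vars)), read_counts, n_vars)
        if v is not None:
            read_counts[v] += 1
            ins.append(v)
    for _ in range(n):
        v = _nearest_available(int(rng.integers(0, n_vars)), write_counts, n_vars)
        if v is not None:
            write_counts[v] += 1
            outs.append(v)
    if not ins or not outs:
        return None
    m_eff, n_eff = len(ins), len(outs)
    gene = list(START_CODON) + [m_eff - 1, n_eff - 1]
    gene += ins + [0] * (MAX_INPUTS - m_eff)
    gene += outs + [0] * (MAX_OUTPUTS - n_eff)
    gene += rng.integers(0, 256, size=(2**m_eff) * (2**n_eff)).tolist()
    return gene


def random_genome(
    rng: np.random.Generator,
    target_gates: int = DEFAULT_TARGET_GATES,
    length: int = DEFAULT_LENGTH,
    n_vars: int = N_VARS,
) -> Genome:
    """Random ancestral genome decoding to ``target_gates`` gates.

    Genes with random arities, connections and tables are scattered through
    the sequence with random non-coding spacers; spacers are scrubbed of
    accidental start codons so the decoded gate count equals the target
    (up to connection-capacity exhaustion for very large targets).
    """
    if target_gates < 0:
        raise ValueError("target_gates must be >= 0")
    read_counts = np.zeros(n_vars, dtype=np.int64)
    write_counts = np.zeros(n_vars, dtype=np.int64)
    genes: list[list[int]] = []
    for k in range(target_gates):
        # budget the connection slots so every remaining gene keeps >= 1
        # read and >= 1 write: the decoded gate count then equals the target
        remaining = target_gates - k - 1
        max_in = min(MAX_INPUTS, n_vars * MAX_CONNECTIONS - int(read_counts.sum()) - remaining)
        max_out = min(MAX_OUTPUTS, n_vars * MAX_CONNECTIONS - int(write_counts.sum()) - remaining)
        gene = _random_gene(rng, read_counts, write_counts, n_vars, max_in, max_out)
        if gene is not None:
            genes.append(gene)
    coding = sum(len(g) for g in genes)
    n_spacer = max(length - coding, len(genes) + 1)
    # split the non-coding budget into len(genes)+1 random spacers
    cuts = np.sort(rng.integers(0, n_spacer + 1, size=max(len(genes), 0)))
    seq: list[int] = []
    prev = 0
    spacer_bytes = rng.integers(0, 256, size=n_spacer).tolist()
    for k, gene in enumerate(genes):
        cut = int(cuts[k]) if k < len(cuts) else n_spacer
        seq += _clean_spacer(spacer_bytes[prev:cut])
        prev = cut
        seq += gene
    seq += _clean_spacer(spacer_bytes[prev:])
    if not seq:
        seq = _clean_spacer(rng.integers(0, 256, size=length).tolist())
    return Genome(loci=np.array(seq, dtype=np.uint8))


def _clean_spacer(bytes_: list[int]) -> list[int]:
    """Replace the second byte of any in-spacer start codon."""
    out = list(bytes_)
    for i in range(len(out) - 1):
        if out[i] == START_CODON[0] and out[i + 1] == START_CODON[1]:
            out[i + 1] = START_CODON[1] + 1
    # avoid forming a codon with whatever byte follows the spacer (genes
    # start with 42, so a trailing 42 is safe; a trailing 42 before a 213
    # spacer continuation was handled above)
    return out


def expressed_fraction(genome: Genome, n_vars: int = N_VARS) -> float:
    """Fraction of loci consumed by genes that decode into connected gates."""
    total = 0
    for _start, m, n, length in _scan_genes(genome.loci):
        total += min(length, genome.loci.size)
    return total / genome.loci.size


def _gene_segments(loci: np.ndarray) -> list[tuple[int, int]]:
    """(start, length) spans of coding genes, clipped to the sequence end."""
    return [(s, min(ln, loci.size - s)) for s, _m, _n, ln in _scan_genes(loci)]


def mutate(genome: Genome, rates: MutationRates, rng: np.random.Generator,
           n_vars: int = N_VARS, return_report: bool = False):
    """Apply the per-locus and per-gene operator mix to a copy of ``genome``.

    Gene-level operators act on the coding segments of the *input* genome;
    per-locus operators then act on the intermediate sequence.  Values pushed
    outside [0, 255] by the +/- perturbation are clipped.  A genome that
    would shrink to zero loci retains a single random locus.
    """
    from ._kernels import gene_segments_kernel

    loci = genome.loci.copy()
    seg_starts, seg_lengths = gene_segments_kernel(loci)
    n_genes = len(seg_starts)
    mean_gene_len = (
        float(seg_lengths.sum() / n_genes) if n_genes else float(HEADER_LEN + 8)
    )

    locus_rates = {
        "copy": rates.copy,
        "delete": rates.delete,
        "insert": rates.insert,
        "replace": rates.replace,
        "perturb": rates.perturb,
    }
    gene_rates = {
        "gene_duplicate": rates.gene_duplicate,
        "gene_delete": rates.gene_delete,
        "gene_insert": rates.gene_insert,
    }
    scale = 1.0
    if rates.normalize:
        expected = loci.size * sum(locus_rates.values())
        expected += n_genes * mean_gene_len * (rates.gene_duplicate + rates.gene_delete)
        expected += max(n_genes, 1) * mean_gene_len * rates.gene_insert
        if expected > 0:
            scale = 1.0 / expected

    work = loci.astype(np.int64)
    changed = 0

    # --- gene-level structural events (highest position first) ---
    events: list[tuple[int, str, np.ndarray | None]] = []
    if n_genes:
        draws = rng.random(2 * n_genes)
        for k in range(n_genes):
            start, ln = int(seg_starts[k]), int(seg_lengths[k])
            if draws[2 * k] < rates.gene_duplicate * scale:
                events.append((start, "dup", work[start:start + ln].copy()))
            if draws[2 * k + 1] < rates.gene_delete * scale:
                events.append((start, "del", np.arange(start, start + ln)))
    if rng.random() < rates.gene_insert * scale * max(n_genes, 1):
        gene = _random_gene(
            rng, np.zeros(n_vars, dtype=np.int64), np.zeros(n_vars, dtype=np.int64), n_vars
        )
        if gene is not None:
            pos = int(rng.integers(0, work.size + 1))
            events.append((pos, "ins_gene", np.array(gene, dtype=np.int64)))
    for pos, kind, payload in sorted(events, key=lambda e: -e[0]):
        if kind == "dup":
            work = np.insert(work, pos, payload)
            changed += payload.size
        elif kind == "del":
            keep = payload[payload < work.size]
            work = np.delete(work, keep)
            changed += keep.size
        else:
            work = np.insert(work, min(pos, work.size), payload)
            changed += payload.size

    # --- per-locus point events ---
    L = work.size
    if L > 0:
        probs = np.minimum(
            np.array([
                locus_rates["replace"], locus_rates["perturb"],
                locus_rates["copy"], locus_rates["insert"], locus_rates["delete"],
            ]) * scale,
            1.0,
        )
        n_repl, n_pert, n_copy, n_ins, n_del = rng.binomial(L, probs)
        if n_repl:
            idx = rng.integers(0, L, size=n_repl)
            vals = rng.integers(0, 256, size=n_repl)
            changed += int(np.sum(work[idx] != vals))
            work[idx] = vals
        if n_pert:
            idx = rng.integers(0, L, size=n_pert)
            mag = rng.integers(1, rates.perturb_range + 1, size=n_pert)
            sign = rng.choice([-1, 1], size=n_pert)
            vals = np.clip(work[idx] + sign * mag, 0, 255)
            changed += int(np.sum(work[idx] != vals))
            work[idx] = vals
        for _ in range(n_copy):
            pos = int(rng.integers(0, work.size))
            work = np.insert(work, pos, work[pos])
            changed += 1
        for _ in range(n_ins):
            pos = int(rng.integers(0, work.size + 1))
            work = np.insert(work, pos, int(rng.integers(0, 256)))
            changed += 1
        for _ in range(n_del):
            if work.size == 0:
                break
            pos = int(rng.integers(0, work.size))
            work = np.delete(work, pos)
            changed += 1

    if work.size == 0:
        work = rng.integers(0, 256, size=1)
        changed += 1
    out = Genome(
        loci=work.astype(np.uint8),
        parent_id=genome.parent_id,
        generation=genome.generation,
    )
    if return_report:
        return out, changed
    return out


# --- plain-text genome files ------------------------------------------------

def save_genome(genome: Genome, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"#animat-genome v1 length={len(genome)}\n")
        fh.write(",".join(str(int(x)) for x in genome.loci))
        fh.write("\n")


def load_genome(path: str | Path) -> Genome:
    path = Path(path)
    with path.open() as fh:
        header = fh.readline()
        if not header.startswith("#animat-genome v1"):
            raise ValueError(f"{path} is not an animat-genome v1 file")
        loci = np.array([int(x) for x in fh.readline().strip().split(",")], dtype=np.uint8)
    return Genome(loci=loci)
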