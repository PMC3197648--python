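"""numba-compiled inner loops: genome decoding, animat stepping, MIP search.

Everything here is a performance twin of pure-Python code elsewhere in the
package (``genome.decode`` for the decoder, ``animats.reference`` for the
world loop, the naive search in the test-suite for the MIP): the compiled
and interpreted paths consume the same random streams and are asserted
equal in the tests.

States travel through the kernels as int64 bit masks (bit v = variable v);
gate tables are flattened into per-row cumulative probability vectors after
the +1 weight clamp.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .markov_brain import MarkovBrain

_MAX_GATES = 36  # every gate needs >=1 read and >=1 write; 12 vars * 3 slots


def _clamp_masks(brain: MarkovBrain):
    rc_mask = rc_vals = wc_mask = wc_vals = 0
    sensor_set = set(brain.sensor_ids)
    for v, val in brain.read_clamp.items():
        rc_mask |= 1 << v
        if val:
            rc_vals |= 1 << v
    for v, val in brain.write_clamp.items():
        if v in sensor_set:
            continue  # sensor writes are overwritten by the environment
        wc_mask |= 1 << v
        if val:
            wc_vals |= 1 << v
    sensor_mask = 0
    for v in brain.sensor_ids:
        sensor_mask |= 1 << v
    return rc_mask, rc_vals, wc_mask, wc_vals, sensor_mask


def brain_arrays(brain: MarkovBrain):
    """Flatten a brain into the padded array form the kernels consume.

    Inputs are right-aligned in a fixed 4-slot field; unused leading slots
    read bit 63 (always 0), so the row index is unchanged.  Every table row
    is padded to 8 cumulative-probability entries (pad value 2.0), which
    lets the kernels sample columns with fixed-bound, branch-free loops.
    """
    n_gates = len(brain.gates)
    g_in = np.full((n_gates, 4), 63, dtype=np.int64)
    g_wmask = np.zeros((n_gates, 8), dtype=np.int64)
    offs = np.zeros(n_gates, dtype=np.int64)
    cum = np.full(16 * 8 * max(n_gates, 1), 2.0)
    off = 0
    for gi, gate in enumerate(brain.gates):
        nin = gate.n_inputs
        g_in[gi, 4 - nin:] = gate.input_ids
        ncol = 2 ** gate.n_outputs
        for col in range(ncol):
            mask = 0
            for k, v in enumerate(gate.output_ids):
                if (col >> (gate.n_outputs - 1 - k)) & 1:
                    mask |= 1 << v
            g_wmask[gi, col] = mask
        offs[gi] = off
        w = (gate.table + 1).astype(np.float64)
        cumrows = np.cumsum(w, axis=1)
        cumrows /= cumrows[:, -1:]
        for r in range(cumrows.shape[0]):
            cum[off + 8 * r: off + 8 * r + ncol] = cumrows[r]
        off += 8 * cumrows.shape[0]
    cum = cum[:off]
    rc_mask, rc_vals, wc_mask, wc_vals, sensor_mask = _clamp_masks(brain)
    return (
        np.int64(brain.n_vars), g_in, offs, cum, g_wmask,
        np.int64(rc_mask), np.int64(rc_vals), np.int64(wc_mask),
        np.int64(wc_vals), np.int64(sensor_mask),
    )


@njit(cache=True)
def _nearest_free(requested, counts, n_vars):
    if counts[requested] < 3:
        return requested
    best = -1
    best_d = 1 << 30
    for v in range(n_vars):
        if counts[v] >= 3:
            continue
        d = requested - v if requested >= v else v - requested
        if n_vars - d < d:
            d = n_vars - d
        if d < best_d or (d == best_d and v < best):
            best = v
            best_d = d
    return best


@njit(cache=True)
def decode_kernel(loci, n_vars):
    """Genome -> flat gate arrays, mirroring ``genome.decode`` exactly."""
    L = loci.size
    read_counts = np.zeros(n_vars, dtype=np.int64)
    write_counts = np.zeros(n_vars, dtype=np.int64)
    g_in = np.full((_MAX_GATES, 4), 63, dtype=np.int64)
    g_wmask = np.zeros((_MAX_GATES, 8), dtype=np.int64)
    offs = np.zeros(_MAX_GATES, dtype=np.int64)
    cum = np.full(_MAX_GATES * 128, 2.0, dtype=np.float64)
    n_gates = 0
    off = 0
    i = 0
    while i < L:
        if loci[i] == 42 and loci[(i + 1) % L] == 213:
            m = 1 + int(loci[(i + 2) % L]) % 4
            n = 1 + int(loci[(i + 3) % L]) % 3
            length = 11 + (1 << m) * (1 << n)
            tmp_reads = read_counts.copy()
            tmp_writes = write_counts.copy()
            nin = 0
            in_buf = np.zeros(4, dtype=np.int64)
            for k in range(m):
                v = int(loci[(i + 4 + k) % L]) % n_vars
                t = _nearest_free(v, tmp_reads, n_vars)
                if t >= 0:
                    tmp_reads[t] += 1
                    in_buf[nin] = t
                    nin += 1
            nout = 0
            out_buf = np.zeros(3, dtype=np.int64)
            for k in range(n):
                v = int(loci[(i + 8 + k) % L]) % n_vars
                t = _nearest_free(v, tmp_writes, n_vars)
                if t >= 0:
                    tmp_writes[t] += 1
                    out_buf[nout] = t
                    nout += 1
            if nin > 0 and nout > 0 and n_gates < _MAX_GATES:
                read_counts = tmp_reads
                write_counts = tmp_writes
                for k in range(nin):
                    g_in[n_gates, 4 - nin + k] = in_buf[k]
                ncol = 1 << nout
                for col in range(ncol):
                    mask = 0
                    for k in range(nout):
                        if (col >> (nout - 1 - k)) & 1:
                            mask |= 1 << out_buf[k]
                    g_wmask[n_gates, col] = mask
                offs[n_gates] = off
                rows = 1 << nin
                for r in range(rows):
                    s = 0.0
                    for c in range(ncol):
                        w = float(loci[(i + 11 + r * ncol + c) % L]) + 1.0
                        s += w
                        cum[off + 8 * r + c] = s
                    for c in range(ncol):
                        cum[off + 8 * r + c] /= s
                off += 8 * rows
                n_gates += 1
            i += length
        else:
            i += 1
    return n_gates, g_in, g_wmask, offs, cum, off


@njit(cache=True)
def gene_segments_kernel(loci):
    """(start, length) spans of coding genes under the sequential scan,
    lengths clipped at the sequence end; twin of ``genome._scan_genes``."""
    L = loci.size
    starts = np.empty(L // 15 + 1, dtype=np.int64)
    lengths = np.empty(L // 15 + 1, dtype=np.int64)
    n = 0
    i = 0
    while i < L:
        if loci[i] == 42 and loci[(i + 1) % L] == 213:
            m = 1 + int(loci[(i + 2) % L]) % 4
            nn = 1 + int(loci[(i + 3) % L]) % 3
            length = 11 + (1 << m) * (1 << nn)
            starts[n] = i
            lengths[n] = min(length, L - i)
            n += 1
            i += length
        else:
            i += 1
    return starts[:n], lengths[:n]


def decode_arrays(loci: np.ndarray, n_vars: int = 12, sensor_ids=(0, 1, 2, 3, 4, 5)):
    """Kernel-ready arrays straight from a genome (fast path for evolution)."""
    ng, g_in, g_wmask, offs, cum, used = decode_kernel(
        np.ascontiguousarray(loci, dtype=np.uint8), n_vars
    )
    sensor_mask = 0
    for v in sensor_ids:
        sensor_mask |= 1 << v
    return (
        np.int64(n_vars), g_in[:ng], offs[:ng], cum[:used], g_wmask[:ng],
        np.int64(0), np.int64(0), np.int64(0), np.int64(0),
        np.int64(sensor_mask),
    )


def maze_arrays(maze):
    wall_door = np.full(maze.period, -1, dtype=np.int64)
    beacon = np.zeros(maze.period, dtype=np.int64)
    for (r, d), b in zip(maze.walls, maze.beacon_dirs):
        wall_door[r] = d
        beacon[r] = b
    return (
        wall_door, beacon, maze.dist.astype(np.int64),
        np.int64(maze.width), np.int64(maze.period),
        np.int64(maze.last_wall_row), np.int64(maze.d_max),
    )


@njit(cache=True, inline="always")
def _blocked(wall_door, width, period, row, col):
    if col < 0 or col >= width:
        return True
    door = wall_door[row % period]
    return door >= 0 and col != door


@njit(cache=True, inline="always")
def _sense_from_doors(dc, d1, bc, width, col):
    """Sensor bits from the door columns of the current (dc) and next (d1)
    rows and the current row's beacon bit; -1 marks a wall-free row."""
    bits = 0
    if d1 >= 0 and col != d1:
        bits |= 1
    if col - 1 < 0 or (d1 >= 0 and col - 1 != d1):
        bits |= 2
    if col + 1 >= width or (d1 >= 0 and col + 1 != d1):
        bits |= 4
    if dc >= 0 and col == dc and bc == 1:
        bits |= 8
    if col - 1 < 0 or (dc >= 0 and col - 1 != dc):
        bits |= 16
    if col + 1 >= width or (dc >= 0 and col + 1 != dc):
        bits |= 32
    return bits


@njit(cache=True, inline="always")
def _sense_mask(wall_door, beacon, width, period, row, col):
    prow = row % period
    prow1 = prow + 1
    if prow1 == period:
        prow1 = 0
    return _sense_from_doors(
        wall_door[prow], wall_door[prow1], beacon[prow], width, col
    )


@njit(cache=True, inline="always")
def _brain_step(
    state, g_in, offs, cum, g_wmask,
    rc_mask, rc_vals, wc_mask, wc_vals, sensor_mask, uniforms, u,
):
    """One synchronous update; returns the new state (sensors copied over)."""
    rstate = (state & ~rc_mask) | rc_vals
    wmask = 0
    for g in range(g_in.shape[0]):
        ridx = 0
        for k in range(4):  # leading dummy inputs read bit 63 (always 0)
            ridx = (ridx << 1) | ((rstate >> g_in[g, k]) & 1)
        base = offs[g] + ridx * 8
        r = uniforms[u]
        u += 1
        col = 0
        for c in range(7):  # branch-free scan of the padded cumulative row
            col += np.int64(r >= cum[base + c])
        wmask |= g_wmask[g, col]
    new = wmask & ~sensor_mask
    new = (new & ~wc_mask) | wc_vals
    new |= state & sensor_mask
    return new, u


@njit(cache=True)
def run_kernel(
    n_vars, g_in, offs, cum, g_wmask,
    rc_mask, rc_vals, wc_mask, wc_vals, sensor_mask,
    wall_door, beacon, dist, width, period, last_wall_row, d_max,
    start_row, start_col, T, uniforms,
):
    positions = np.zeros((T + 1, 2), dtype=np.int64)
    states = np.zeros((T + 1, n_vars), dtype=np.uint8)
    row, col = start_row, start_col
    state = _sense_mask(wall_door, beacon, width, period, row, col)
    positions[0, 0] = row
    positions[0, 1] = col
    for v in range(n_vars):
        states[0, v] = (state >> v) & 1
    doors = 0
    dist_sum = 0.0
    u = 0
    for t in range(T):
        new, u = _brain_step(
            state, g_in, offs, cum, g_wmask,
            rc_mask, rc_vals, wc_mask, wc_vals, sensor_mask, uniforms, u,
        )
        b10 = (new >> 10) & 1
        b11 = (new >> 11) & 1
        if b10 == 1 and b11 == 1:
            if not _blocked(wall_door, width, period, row + 1, col):
                if row % period == last_wall_row:
                    doors += 1
                row += 1
        elif b10 == 1:
            if not _blocked(wall_door, width, period, row, col + 1):
                col += 1
        elif b11 == 1:
            if not _blocked(wall_door, width, period, row, col - 1):
                col -= 1
        new = (new & ~np.int64(63)) | _sense_mask(
            wall_door, beacon, width, period, row, col
        )
        state = new
        positions[t + 1, 0] = row
        positions[t + 1, 1] = col
        for v in range(n_vars):
            states[t + 1, v] = (state >> v) & 1
        dist_sum += d_max - dist[row % period, col]
    return positions, states, doors, dist_sum


@njit(cache=True)
def fitness_kernel(
    n_vars, g_in, offs, cum, g_wmask,
    rc_mask, rc_vals, wc_mask, wc_vals, sensor_mask,
    wall_door, beacon, dist, width, period, last_wall_row, d_max,
    start_row, start_col, T, reps, uniforms,
):
    """Replicated no-recording world loop; per replicate returns
    (doors, sum of per-step distance gains, final gain)."""
    out = np.zeros((reps, 3))
    u = 0
    for rep in range(reps):
        col = start_col
        prow = start_row % period
        prow1 = prow + 1 if prow + 1 < period else 0
        state = _sense_from_doors(
            wall_door[prow], wall_door[prow1], beacon[prow], width, col
        )
        doors = 0
        dist_sum = 0.0
        d_last = 0.0
        for t in range(T):
            new, u = _brain_step(
                state, g_in, offs, cum, g_wmask,
                rc_mask, rc_vals, wc_mask, wc_vals, sensor_mask, uniforms, u,
            )
            b10 = (new >> 10) & 1
            b11 = (new >> 11) & 1
            d1 = wall_door[prow1]
            dc = wall_door[prow]
            if b10 == 1 and b11 == 1:
                if d1 < 0 or col == d1:
                    if prow == last_wall_row:
                        doors += 1
                    prow = prow1
                    prow1 = prow + 1 if prow + 1 < period else 0
            elif b10 == 1:
                if col + 1 < width and (dc < 0 or col + 1 == dc):
                    col += 1
            elif b11 == 1:
                if col - 1 >= 0 and (dc < 0 or col - 1 == dc):
                    col -= 1
            state = (new & ~np.int64(63)) | _sense_from_doors(
                wall_door[prow], wall_door[prow1], beacon[prow], width, col
            )
            d_last = d_max - dist[prow, col]
            dist_sum += d_last
        out[rep, 0] = doors
        out[rep, 1] = dist_sum
        out[rep, 2] = d_last
    return out


@njit(cache=True, inline="always")
def _xorshift_next(s):
    """xorshift64* step; returns (new state, uniform in [0, 1))."""
    s ^= s >> 12
    s ^= (s << 25) & np.uint64(0xFFFFFFFFFFFFFFFF)
    s ^= s >> 27
    x = (s * np.uint64(2685821657736338717)) >> np.uint64(11)
    return s, np.float64(x) * (1.0 / 9007199254740992.0)


@njit(cache=True)
def population_fitness_kernel(
    member_gate_start, member_gate_count, member_cum_start,
    g_in, offs, cum, g_wmask, sensor_mask,
    wall_door, beacon, dist, width, period, last_wall_row, d_max,
    start_row, start_col, T, reps, seeds,
):
    """``fitness_kernel`` over a whole population in one call.

    Gate arrays of all members are concatenated; ``offs`` is member-local
    and shifted by ``member_cum_start``.  No clamps (evolution never uses
    them).  All replicates of a member advance in lock-step within the time
    loop (they are independent walkers, which lets their serial
    sample-update chains overlap); each replicate has its own xorshift64*
    stream derived from the member seed.
    """
    n_members = member_gate_start.shape[0]
    out = np.zeros((n_members, reps, 3))
    state = np.empty(reps, dtype=np.int64)
    prow = np.empty(reps, dtype=np.int64)
    prow1 = np.empty(reps, dtype=np.int64)
    col = np.empty(reps, dtype=np.int64)
    doors = np.empty(reps, dtype=np.int64)
    dist_sum = np.empty(reps, dtype=np.float64)
    d_last = np.empty(reps, dtype=np.float64)
    rng_states = np.empty(reps, dtype=np.uint64)
    p0 = start_row % period
    p1 = p0 + 1 if p0 + 1 < period else 0
    sense0 = _sense_from_doors(wall_door[p0], wall_door[p1], beacon[p0], width, start_col)
    for mi in range(n_members):
        gs = member_gate_start[mi]
        ge = gs + member_gate_count[mi]
        cs = member_cum_start[mi]
        for rep in range(reps):
            # splitmix64 of (member seed, rep) -> per-replicate stream
            z = seeds[mi] + np.uint64(0x9E3779B97F4A7C15) * np.uint64(rep + 1)
            z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
            z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
            rng_states[rep] = (z ^ (z >> np.uint64(31))) | np.uint64(1)
            state[rep] = sense0
            prow[rep] = p0
            prow1[rep] = p1
            col[rep] = start_col
            doors[rep] = 0
            dist_sum[rep] = 0.0
            d_last[rep] = 0.0
        for t in range(T):
            for rep in range(reps):
                st = state[rep]
                rs = rng_states[rep]
                wmask = 0
                for g in range(gs, ge):
                    ridx = 0
                    for k in range(4):
                        ridx = (ridx << 1) | ((st >> g_in[g, k]) & 1)
                    base = cs + offs[g] + ridx * 8
                    rs, r = _xorshift_next(rs)
                    colx = 0
                    for c in range(7):  # branch-free column selection
                        colx += np.int64(r >= cum[base + c])
                    wmask |= g_wmask[g, colx]
                rng_states[rep] = rs
                new = (wmask & ~sensor_mask) | (st & sensor_mask)
                b10 = (new >> 10) & 1
                b11 = (new >> 11) & 1
                cl = col[rep]
                pr = prow[rep]
                pr1 = prow1[rep]
                d1 = wall_door[pr1]
                dc = wall_door[pr]
                if b10 == 1 and b11 == 1:
                    if d1 < 0 or cl == d1:
                        if pr == last_wall_row:
                            doors[rep] += 1
                        pr = pr1
                        pr1 = pr + 1 if pr + 1 < period else 0
                elif b10 == 1:
                    if cl + 1 < width and (dc < 0 or cl + 1 == dc):
                        cl += 1
                elif b11 == 1:
                    if cl - 1 >= 0 and (dc < 0 or cl - 1 == dc):
                        cl -= 1
                state[rep] = (new & ~np.int64(63)) | _sense_from_doors(
                    wall_door[pr], wall_door[pr1], beacon[pr], width, cl
                )
                col[rep] = cl
                prow[rep] = pr
                prow1[rep] = pr1
                dl = d_max - dist[pr, cl]
                d_last[rep] = dl
                dist_sum[rep] += dl
        for rep in range(reps):
            out[mi, rep, 0] = doors[rep]
            out[mi, rep, 1] = dist_sum[rep]
            out[mi, rep, 2] = d_last[rep]
    return out


@njit(cache=True)
def mip_kernel(positions, hcond, sizes, full_mask):
    """Exhaustive MIP search over restricted-growth strings.

    ``positions`` holds the global bit index of each node in the searched
    subset; ``hcond[m]`` is H(M_S(t) | M_S(t+1)) for the node set with global
    bit mask ``m``; ``sizes[m]`` its node count.  Returns the lexicographically
    first minimizer of EI/((K-1)*min_part_size), ties broken by smaller
    unnormalized EI.
    """
    k = positions.shape[0]
    a = np.zeros(k, dtype=np.int64)
    best_rgs = np.zeros(k, dtype=np.int64)
    best_norm = np.inf
    best_ei = np.inf
    h_full = hcond[full_mask]
    count = 0
    masks = np.zeros(k, dtype=np.int64)
    while True:
        kparts = 0
        for i in range(k):
            if a[i] + 1 > kparts:
                kparts = a[i] + 1
        if kparts >= 2:
            count += 1
            for p in range(kparts):
                masks[p] = 0
            for i in range(k):
                masks[a[i]] |= 1 << positions[i]
            ei = -h_full
            min_size = k
            for p in range(kparts):
                ei += hcond[masks[p]]
                if sizes[masks[p]] < min_size:
                    min_size = sizes[masks[p]]
            norm = ei / ((kparts - 1) * min_size)
            if norm < best_norm or (norm == best_norm and ei < best_ei):
                best_norm = norm
                best_ei = ei
                for i in range(k):
                    best_rgs[i] = a[i]
        # lexicographic successor of the restricted-growth string
        j = k - 1
        advanced = False
        while j > 0:
            prefix_max = 0
            for i in range(j):
                if a[i] > prefix_max:
                    prefix_max = a[i]
            if a[j] <= prefix_max:
                a[j] += 1
                for i in range(j + 1, k):
                    a[i] = 0
                advanced = True
                break
            j -= 1
        if not advanced:
            break
    return best_rgs, best_ei, best_norm, count
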