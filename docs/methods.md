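# Methods

This note documents the model, the estimation choices, the defaults and
their rationale, and what the test suite does and does not establish.

## Controllers: Hidden Markov Gates

A controller is a synchronous network over `n_vars = 12` binary variables
(sensors 0–5, internal 6–9, motors 10–11).  Each Hidden Markov Gate reads
1–4 variables, treats their bits as a row index (first listed input = most
significant bit), and samples one of its 2^n_outputs column patterns with
probability proportional to the row's weights.  Per variable at most three
gates may read and at most three may write; writes are OR-combined and
non-sensor variables with no writer reset to 0, so persistent memory must
be built explicitly from auto-feedback.  Sensor variables belong to the
environment: gates may write to them, but the values are overwritten before
the next update, so such writes are inert.

**Weight clamping.**  Table weights are bytes; probabilities are
`p_j = (w_j + 1)/Σ(w_k + 1)`.  This Laplace-style clamp is the simplest
rule that (a) keeps every transition strictly inside (0, 1) — controllers
are minimally stochastic by construction — and (b) keeps weight-0 entries
meaningful for knock-out analyses that overwrite alleles with 0 or 255.
With one output, an extreme row (255 vs 0) fires as intended with
probability 256/257 ≈ 0.9961 per step.  If a different published clamp for
this architecture surfaces, `HMGate.probabilities` is the single place to
change.

**Exact transition matrices** (`transition_matrix`) marginalize gate
stochasticity by dynamic programming over joint next-state distributions.
Cost grows as 2^(2f) in the number of free variables f; the guard is 16,
practical use is f ≤ 8.  They back the maximum-entropy effective
information variant and the Monte-Carlo cross-checks.

## Genome encoding

Genomes are circular byte strings.  A gene is `42 213 | a_in a_out |
4 input-id bytes | 3 output-id bytes | 2^m·2^n table bytes`; arities are
`1 + a_in mod 4` and `1 + a_out mod 3`, ids are taken modulo 12, and table
bytes may wrap past the genome end.  Scanning is sequential and
non-overlapping: a start codon inside an already-decoded gene is
non-coding.  (The alternative — letting genes overlap — was rejected
because it makes the written-gene round-trip ambiguous whenever a table
happens to contain the codon.)  Connections that would exceed a variable's
three-reader/three-writer budget are rerouted to the nearest available
variable by circular index distance, ties to the lower index; when nothing
is available the connection is dropped, and a gate stripped of all inputs
or all outputs is discarded.

Random ancestral genomes are 3,000 loci long and seed exactly the target
number of genes (default 12) by budgeting connection slots during
construction and scrubbing accidental codons from the non-coding spacers.

**Mutation.**  Per-locus operators (copy, delete, insert, replace, perturb
±8 with clipping to [0, 255]) and per-gene operators (duplicate, delete,
insert a random gene) run at the declared default rates, then all rates
are rescaled so the *expected number of changed loci per genome per call
is one* — the normalization is the binding constraint; the individual
rates only set the operator mix.  Gene-level events are weighted by the
loci they touch.  A genome that would shrink to nothing retains a single
random locus.

## World, task, fitness

The maze is a 16-cell-wide corridor with walls every 3–6 rows (uniform),
26 walls per period, one uniformly placed door per wall, and periodic
wrap-around.  These geometry defaults are declared, not reconstructions:
they were chosen once so that exploiting the beacon is worth a clear
fitness margin over wall-following.  The beacon bit is 1 iff the next
door's column is strictly larger, readable only on the door cell.

Distances `d(cell)` to the last doorway are breadth-first-search distances
under the legal move set (left, right, forward only — the animat cannot
turn or back up).  Raw fitness uses the per-step form

    f = c·d_max + (1/T) Σ_{t=1..T} (d_max − d_t),

which uses each of the four symbols once and rewards both sustained
progress and completed traversals; the final-state alternative
`f = c·d_max + (d_max − d_T)` sits behind `mode="final"`.  `f_max` is
*computed*, not assumed: a deterministic walker with full maze knowledge
follows BFS shortest paths for the same T and is scored by the same
formula.  Because every legal move changes d by at most one, no policy can
beat it, so ratios are guaranteed in [0, 1].

Selection fitness is the geometric mean of `reps` ratio replicates (one
total failure zeroes it); control fitness is the arithmetic mean over ten
never-seen mazes, where a single failure cannot zero the result.

## Genetic algorithm

Population 300 (default), elite 3 copied unmutated unless a fresh re-test
scores zero, remaining slots by fitness-proportional roulette with a
ten-offspring cap per parent, all offspring mutated, selection maze
regenerated every 100 generations.  All-zero-fitness populations fall back
to uniform parent choice.  The genealogy stores one parent index per
member per generation; the line of descent is the backtrace from the
fittest final member, and the coalescence generation is checked rather
than assumed (short runs may not have coalesced; the API then warns and
returns the earliest coalesced checkpoint).  The "final" LOD generation
defaults to 1,000 generations before the end, mirroring the
49,000-of-50,000 convention at full scale.

## Information measures

All entropies are plug-in (maximum-likelihood) estimates in base 2 with
0·log 0 = 0 and **no bias correction** — at 12 nodes and ~10^5 samples the
plug-in bias is real; measured values are comparable across controllers
sampled identically, which is all the correlation analyses need, but they
are not unbiased estimates of the underlying process quantities.
Empirical pair distributions are stored sparsely (unique observed
(x_t, x_{t+1}) pairs with weights), so analytic joints and trajectory
counts share one code path, and marginalization is exact bit-masking.
Pairs are never counted across trajectory boundaries.  All recorded steps
are used (burn-in 0 by default; configurable).

The MIP search minimizes `EI(P)/((K−1)·min_k H_max(M_k))` over all
partitions with K ≥ 2 (the single-part partition has an undefined
normalization and trivially zero EI, so it is excluded), where `H_max` of
a part is its node count, i.e. normalization uses maximum, not realized,
entropy.  Φ is the *unnormalized* EI at the minimizer.  Ties break toward
smaller unnormalized EI, then the lexicographically smallest
restricted-growth string; enumeration is in lexicographic RGS order with
constant memory.  The per-subset cache `H(M_S,t|M_S,t+1)` for all 2^n
subsets turns each partition into a table-lookup sum; the same cache
serves every subset's search in the main-complex scan, which makes the
full 12-node Φ (~4.2 M partitions, ~1 s) and the all-subset Φ table
(~28 M partition evaluations, ~6 s) routine.  The main complex is the
Φ-argmax over subsets (ties: smaller subset, then lexicographic); subsets
whose Φ exceeds every strict superset are flagged as proper complexes.

Predictive information pairs sensors at t with motors at t+1 ("the future
and the present"); the instantaneous alternative is available via
`lag=0`.  The maximum-entropy EI variant feeds a uniform X_t through an
exact transition matrix; under that input the conditional-entropy form and
the synergy form agree identically, which the tests exploit as a
dual-formula oracle.

**Random streams.**  The recording world loop and the single-brain fitness
loop consume one externally supplied uniform variate per gate per step, so
the compiled kernels can be asserted bit-identical to the pure-Python
reference.  The batched population evaluator used inside the GA instead
draws from per-replicate xorshift64* streams seeded (via splitmix64) from
one generator-drawn seed per member: this keeps evaluation deterministic
under the run seed while avoiding the cost of materializing ~10^7 uniforms
per generation.

## Hand-coded benchmark controller

`beacon_policy_brain()` implements the best simple strategy in three
gates at extreme weights: a memory gate (door beacon → internal bit 9,
held by auto-feedback, corrected at lateral boundaries) and two motor
gates (forward while the front is clear, else sweep toward the remembered
side).  Its control fitness lands a few percent below the optimum because
each gate misfires with probability 1/257 per step — the clamped analogue
of a hand-written optimal controller, and the package's benchmark target
(≈ 93 % of maximal control fitness, seed-to-seed spread of a few
percentage points).

## Problem sizes used by the tests

The full-scale study configuration (64 runs × 50,000 generations ×
population 300, selection at 10 × 1,000 steps) is expressible but is a
cluster-scale computation; it is documented here and not exercised by the
suite.  The suite's evolution experiment uses the package's demo profile —
8 runs × 2,000 generations × population 100, selection at 5 replicates ×
500 steps — while *measurements* (control fitness, information measures)
always use the full protocol of 10 mazes × 10 repetitions × 1,000 steps.
(A lighter selection protocol was tried first and rejected: with fewer,
shorter replicates the selection-fitness estimate is so noisy that
roulette selection barely responds within 2,000 generations.)
At this scale evolution reliably improves control fitness but does not
reach beacon-exploiting navigation; the Φ_atomic–fitness correlation is
therefore tested only for sign, not magnitude.  Passing tests show the
machinery is correct and the qualitative effect present at desk scale;
they do not reproduce full-scale correlation coefficients.

## Known limitations

* Plug-in entropies are biased upward for undersampled subsets (no
  Miller–Madow or jackknife correction).
* The exact transition-matrix path scales as 4^f and is only practical to
  ~8 free variables; empirical estimation is the intended route at 12.
* Knock-out deltas for *gate deletions* are paired by seed but not
  stream-aligned (removing a gate shifts random-number consumption), so
  they are zero-mean noisy rather than exactly zero for neutral deletions;
  variable and table-entry knock-outs are exactly paired.
* The maze geometry parameters are declared defaults; behavior under very
  narrow corridors or widely spaced walls is untested.
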