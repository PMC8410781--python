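# Methods

## Model and scope

`boolck` works with deterministic synchronous Boolean networks: `n` named
nodes, one Boolean update function per node, all nodes updated
simultaneously.  Update functions are stored as truth tables over each
node's *essential* inputs (inputs whose value can change the output),
obtained by probing the parsed expression's table; expressions with more
than 20 syntactic inputs skip the probe and keep syntactic dependencies,
flagged on the node.  States are integers, little-endian: node 0 is the
least-significant bit.  This convention is used in every serialization and
makes test vectors bit-exact.

Asynchronous and probabilistic update schemes are out of scope, as is
SBML-qual parsing.  Constants `0`/`1` are allowed in rules; a node with a
constant rule is *not* an input node (an input node's rule must be the
identity on itself, checked semantically, not syntactically).

## Attractor search

*Exhaustive* (default, `n ≤ 22`): the full successor table is built with
vectorized numpy gathers, then every state is visited exactly once by
memoized trajectory walking; basin sizes are exact and sum to `2^n`.  The
transition matrix is never materialized beyond this 1-D successor array.

*Sampled*: `N_S` initial states drawn uniformly **with replacement** from a
seeded generator; each trajectory runs until a state repeats (at most `2^n`
steps, no cutoff parameter).  Basin counts are sampled counts.  The exact
initial-state sample is retained so that pinned re-tests can reuse *the
same* states, projected onto the unpinned nodes; sampled CK statements are
therefore exact relative to the sampled attractor set.

*Modular*: strongly connected components of the essential dependency graph
form a DAG of modules (networkx condensation).  Modules are solved in
topological order; for each consistent combination of upstream attractors
the module's conditional dynamics are solved by brute force over the
product system (context phase × module state).  Combining upstream
attractors uses a single `combine` primitive over partial attractors: every
relative phase shift is tried over the combined period `lcm(ℓ₁, ℓ₂)`,
shifts disagreeing on shared ancestor nodes are dropped, and equivalent
merges are deduplicated — for disjoint node sets this reduces exactly to
the `gcd(ℓ₁, ℓ₂)` phase-class count.  Basins are not computed in this mode.

Attractor identity is the *set* of cycle states: cycles are canonically
rotated to start at the minimal integer state, so equality is phase-free.
A fixed point is a length-1 cycle.  Repellors are fixed points with basin
size exactly 1 (exhaustive mode only).

## Witness sets and distinguishing nodes

Minimal witness search is a minimum hitting-set problem over the per-pair
difference sets.  The exact solver enumerates candidate subsets of the
*union* of difference sets (coordinates outside it cannot help) by
increasing size, ties broken lexicographically on the sorted coordinate
tuple, so reported witnesses are deterministic.  For `n ≤ 62` candidates
are evaluated in vectorized int64 batches with identical enumeration order.
The subset-test budget defaults to 10⁷; on exhaustion a greedy
(largest-uncovered-first) hitting set is returned flagged `upper_bound`.
Means over families refuse budget-limited members unless explicitly told
to accept an upper-bound mean.

Cyclic attractors add two rules: a coordinate where the *other* attractor
is non-constant always distinguishes, and a cyclic *target* may only use
its own constant coordinates.  When both members are cycles the rules are
applied simultaneously (their conjunction); no published example exercises
this interaction, so it is a documented convention of this package.  Two
distinct cycles can share an identical constant profile — no static
pinning separates them, and their witnesses are reported `nonexistent`
(attractor-derived families tolerate such profile duplicates; plain vector
families must be pairwise distinct).

## Control kernel search

For a target attractor the search enumerates candidate sets that (a)
contain all input nodes, (b) lie within the target's constant nodes, and
(c) are distinguishing with respect to every other attractor, ordered by
size then lexicographically.  Each candidate is pinned to the target's
values and the pinned network's attractors recomputed; success is exactly
one attractor equal to the target's restriction.  Cyclic targets are first
screened by pinning *all* their constant nodes — if more than one attractor
survives, the cycle has no static CK.  Static pinning only; dynamic pinning
is deliberately not implemented.  A budget (default 10⁶) caps
pinned-dynamics evaluations; on exhaustion the iterative bound is returned
with status `bound_only`.  An optional flag enumerates all minimal CKs
(off by default for cost).

The iterative bound pins inputs in round zero, then repeatedly pins a
minimal distinguishing set of the restricted target against all currently
remaining attractors, choosing among minimal sets (up to 200 alternatives)
the one creating the fewest *new* attractors — new means canonical cycles
absent from the pre-pinning set restricted to the surviving coordinates —
with lexicographic tie-breaks.  Lower bound `m + |w¹|`, upper bound
`m + Σ|wⁱ|`, round cap 50.

The first-order approximation computes `w¹` directly from the original
attractor set: input pinning never creates attractors, so the input-pinned
network's attractors are exactly the originals sharing the target's input
configuration.  Input entropy `μ = −Σ (r_j/r) log₂(r_j/r)` over the
distribution of attractor counts `r_j` across input configurations yields
the bound chain `⟨|w¹|⟩ ≤ x log₂ x + x log₂ r` (with
`x = 1 − (2^m − 1)/r`) and `⟨|CK¹|⟩ ≤ log₂ r + (m − μ) ≤ 2 log₂ r`.

Union CKs take the union of the per-attractor kernels found, with no
cross-attractor minimization.  Per-module CK nodes are searched within a
module against a fixed upstream context and assembled along the DAG;
global minimality of the assembly is an empirical property checked against
direct search in the test suite, not assumed.

## Ensembles and constructions

*p–K networks*: each node reads `K` distinct uniformly chosen nodes
(self-input permitted, the classic Kauffman convention); each truth-table
output bit is 1 independently with probability `p_on`.  Degenerate
(constant) functions are not excluded.

*Threshold networks*: directed Erdős–Rényi dependency graph, each ordered
pair present with probability `d/(n−1)` — so `d` is the expected
**in**-degree (the generator records the raw signed adjacency in
`net.meta`).  Each edge is inhibitory (−1) with probability `p_I`.  The
update compares the signed input sum to the threshold, keeping the current
state on a tie; ties make every zero-in-degree node an input node.  Zero
mode sets all thresholds to 0 (the all-OFF state is then always fixed);
balanced mode sets `τ_i` to half the summed signed in-edges, compared
exactly as `2s_i` vs the integer sum (no floating point).

*Projective plane*: points and lines of the order-`p` plane (prime `p`,
trial-division primality; prime powers out of scope) are projective classes
of nonzero GF(p) triples, incidence = zero dot product; the four incidence
axioms are verified at construction.  The witness family is the `q`
incidence rows followed by the `q` identity rows (`r = 2q`,
`q = p² + p + 1`).  Every line needs 2 pins and every point `p + 2`, mean
`(p+4)/2`; the package validates the closed form exhaustively at `p = 2, 3`
and uses it for the prime scan (first exceedance of `log₂ 2q` at `p = 17`)
and the real-valued crossing scan (first integer `r ≥ 6` with
`(p+4)/2 > log₂ r` at `r = 369`).

*Random maps*: each of the `2^{n′}` states receives an independent uniform
successor; self-maps are counted per replicate.  The expectation is exactly
1 for any `n′`, which is the heuristic behind small attractor counts after
input pinning.

*Random vector families* draw `r` distinct tuples uniformly without
replacement (witness sets require distinctness).

## Problem sizes used by the test suite

The property batteries run at sizes a single desk CPU clears in minutes,
chosen once: modular-vs-exhaustive equivalence on 100 random networks at
`n ≤ 12`; CK postcondition, Propositions 1–2 and bound sandwich on 100
networks at `n ≤ 10`; the brute-force minimality oracle on 40 networks at
`n = 8`; witness-solver oracle equivalence on 300 random families
(`n ≤ 10`, `r ≤ 16`); the random-family scaling experiment at
`n ∈ {8, 12, 16}`, `r ∈ {2, 4, 8, 16, 32, 64}`, 50 replicates per cell;
and the ensemble first-order study at `n ∈ {10, 15}` with 10 seeds per
parameter cell, skipping networks with `r > 100` (exact witness search on
very attractor-rich networks is the NP-hard core and dominates runtime).
The synthetic generators emulate the standard random ensembles, not
curated biological models: they lack the strong modularity, long chains and
canalizing logic of inferred regulatory networks, so passing tests
demonstrates algorithmic correctness and the ensemble-level inequalities,
not biological coverage.

## Known limitations

* Exhaustive mode is capped near `n ≈ 22` by the successor table; modular
  mode helps only as far as the largest module, and sampled mode trades
  exactness for reach.
* Witness/CK searches are exponential in the minimal set size by nature;
  budgets convert worst cases into flagged bounds rather than silent
  failures.
* The per-module CK assembly and the `⟨|w¹|⟩ ≤ log₂ r_j` inequality are
  empirical regularities, tested and reported, not theorems; violations
  surface as test failures or flagged summary columns rather than being
  suppressed.
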