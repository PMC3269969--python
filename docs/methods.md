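# Methods

## Problem and notation

Input: n DNA sequences (length m each, though only length ≥ ℓ is required),
a motif length ℓ and a mismatch budget d.  An ℓ-mer M is an (ℓ, d)-motif if
every sequence contains a window within Hamming distance d of M
(d̄_H(M, S) ≤ d); the quorum variant requires only q of the n sequences to
contain such a window.  The search is exact: the reported set is provably
M_{ℓ,d}(S), for every input and every tuning choice.

## The neighborhood tree

B_d(x) is enumerated by a rooted tree whose nodes are pairs (t, p): t an
ℓ-mer, p ∈ [0, ℓ] the rightmost changed position (1-based; 0 at the root),
with t equal to x everywhere right of p.  A child flips exactly one
position strictly right of its parent's p to a non-x symbol, so the
positions changed along a root path are strictly increasing: each member of
B_d(x) is produced exactly once (its changed positions, flipped left to
right), and a node's depth equals its distance from x.  Children are
ordered by flip position, then alphabet order, making traversals
deterministic.  Nodes are generated lazily during an explicit-stack DFS; the
tree is never materialized (the complexity argument needs traversal, not
storage, and an explicit stack avoids recursion limits at ℓ up to 23).

## The feasibility prune

At a node (t, p), the subtree (node included) contains an element of
B_d(x) ∩ B_d(y) ∩ B_d(z) iff some suffix w of length ℓ − p satisfies
d_H(·₁, t₁) + d_H(·₂, w) ≤ d for each of x, y, z (prefix/suffix split at p).
Classifying each suffix column of (x₂, y₂, z₂) into the five match patterns
aaa/aab/aba/baa/abc reduces this to a 10-variable integer program whose
input is only the 8-tuple (n₁..n₅, R₁, R₂, R₃), with
R_i = ℓ − p − d + d_H(·₁, t₁) clamped below at zero.

The decision procedure saturates N₁ₐ = n₁ (it serves all three coverage
constraints and competes with nothing), enumerates the three two-way splits
with the complement always given to the sibling variable (extra coverage is
free), and then checks that the residual deficits sum to at most n₅ — the
three type-5 variables are disjoint across constraints, so their minimal
total is exactly the deficit sum.  This is exact (verified against full
allocation enumeration) and O(ℓ³) per key; keys are memoized in a lazy map
rather than a fully materialized (ℓ+1)⁵(d+1)³ table, since only reachable
keys are ever needed (the full table reaches hundreds of MB at ℓ = 23).
One process-wide cache serves all calls; it can be saved/loaded as JSON.

For alphabets of size ≥ 4 the reduction is exact in both directions: every
feasible allocation is realizable by an actual witness string (a type-5
column needs a 4th symbol for "match none").  For binary alphabets the test
is a relaxation — infeasible still implies no witness, so pruning remains
safe and output remains exact; only the node-count accounting weakens.
Tests cover both regimes.

## Traversal and node accounting

The DFS evaluates a child's feasibility key at generation time (its prefix
distances are O(1) updates from the parent via precomputed mismatch prefix
sums) and only pushes feasible children; the root is always visited and its
own key gates its expansion.  A node is emitted when all three total
distances are ≤ d; emission is checked before expansion, and nodes at depth
d are never expanded.  `visited_nodes` therefore counts the non-pruned
nodes — the tree whose leaves, for DNA, are guaranteed intersection
elements.

Node-count bound: since the explored tree is exactly the ancestors-or-self
of the intersection elements, its size is at most 1 + Σ(element depths)
≤ 1 + d·|B_d(x,y,z)|.  When x itself is in the intersection (the root is an
element) the bound tightens to d·|B| for d ≥ 1, because the root's path is
free: 1 + d·(|B|−1) ≤ d·|B|.  The tighter bound is the one usually quoted;
note it is *not* true for arbitrary triples — e.g. x = AAAA, y = z = CCAA,
d = 1 explores 3 nodes for 2 elements — and is vacuous for d = 0 or empty
intersections (where exactly the root is visited).  The tests assert
1 + d·|B| on arbitrary random triples and d·|B| on triples with y, z within
distance d of x, the regime the search driver actually reaches after
triangle screening.

## Search drivers

Full quorum (`pms5_find`): for each distinct window x of s₁ (duplicates
processed once), the remaining sequences are paired consecutively (last one
duplicated if odd); for each pair the candidate pool is the union of
B_d(x, y, z) over the pair's window combinations, and pools are intersected
across pairs.  When the running pool drops below `threshold` (default 5000,
CLI-configurable; any positive value is correct — published practice uses
5000–10000) the loop breaks and survivors are verified against the
not-yet-consumed sequences.  A window pair (y, z) is skipped when any of
d(x,y), d(x,z), d(y,z) exceeds 2d — by the triangle inequality the
intersection is then empty — using numpy distance matrices computed once
per sequence pair.  This screen is what makes the driver fast on planted
instances: for random windows at the challenging parameter ratios, almost
all window combinations die here.

Quorum (`qpms_find`): every index triple i < j < k is visited.  Per triple
the candidate pool is computed, by default, through the identity
∪_{x,y,z} B_d(x, y, z) = M({s_i}) ∩ M({s_j}) ∩ M({s_k}) with the
per-sequence motif sets M({s}) = ∪_windows B_d(x) built once per call —
output-identical to running FULLPRUNE per window triple but far cheaper in
Python at desk scales.  The literal per-window-triple strategy
(`strategy="triples"`, with triangle screening) is retained and
cross-checked for equality in the tests.  Candidates are quorum-checked
with a global memo; q < 3 (too few sequences to anchor a triple) falls back
to the union of all per-sequence motif sets as the candidate space.
Results deduplicate across triples; q = n reproduces the full search
through an entirely different code path, which the tests exploit.

Reported motifs carry the leftmost best-match offset and distance per
sequence and the score Σ_i d̄_H(M, s_i); output is sorted
lexicographically, so runs are byte-identical.

## Instance statistics

With p_{ℓ,d} = Σ_{i≤d} C(ℓ,i)(3/4)^i(1/4)^{ℓ−i}: the expected common
neighborhood of three random ℓ-mers is 4^ℓ·p³ (equivalently N(ℓ,d)³/4^{2ℓ},
an identity the tests assert to 1e-12 relative); the chance that a random
ℓ-mer matches somewhere in a random length-m sequence is
Q = 1 − (1−P)^{m−ℓ+1} (window independence is assumed, the standard
approximation); the probability of matching ≥ q of n sequences is the
binomial upper tail R, summed exactly (no normal approximation; integer
combinatorics, float powers); and the expected number of chance motifs is
4^ℓ·R.  An instance is *challenging* when d is the smallest budget making
this expectation ≥ 1.  Note the exponent in Q must be the window count
m − ℓ + 1; the literature sometimes misprints its sign.

Known discrepancies with published reference values, verified by exact
rational arithmetic (`fractions.Fraction`) during development:

* Reference chance-motif tables for n=20, m=600, q=10 carry ~0.03–0.3%
  error in their 4th significant digit, consistent with a single-precision
  original computation; comparisons are made at 3 significant figures.
* Three to four rows of that table — (9,1), (9,2), (11,1), (17,4) — do not
  recompute under any formula variant tried; (9,2)'s printed 1.599 is
  reproduced almost exactly by the full-quorum (q = n) computation,
  suggesting a quorum mix-up in the original.  These rows are documented
  and excluded from numeric comparisons.
* The conventional full-quorum challenging ladder continues
  (17,6), (19,7), (21,8), (23,9), but the definition's own arithmetic gives
  expected counts 0.884, 0.177, 0.025, 0.0027 there — below 1 — so
  `challenging_d` returns d = 7, 8, 9, 10 for ℓ ≥ 17.  The conventional
  labels follow the d = (ℓ−5)/2 pattern rather than the formula; this
  package implements the formula, and the corresponding acceptance test is
  deliberately left failing for the divergent entries rather than papering
  over the contradiction.

## Benchmark generator

The generator emulates the field's standard planted (FM) benchmark:
i.i.d. uniform background of n sequences × length m (defaults 20 × 600), a
uniform random motif, and per sequence one occurrence mutated in exactly d
distinct uniformly-chosen positions (each to a uniformly-chosen *different*
base), written at a uniform offset, overwriting the background so lengths
stay m.  A relaxed mode mutates to arbitrary bases, giving distance ≤ d —
both conventions appear in the literature.  One RNG stream
(`numpy.random.default_rng(seed)`) with a documented draw order — motif;
then per sequence: background, offset, positions, substitutions — makes
instances reproducible byte-for-byte.  The exact-d contract is asserted on
every generated instance.

What the generator does *not* emulate: real promoter background (biased
composition, repeats, correlated windows), multiple sites per sequence,
decoy motifs, or reverse-complement occurrences.  Passing the planted
recovery tests therefore demonstrates algorithmic completeness on the
standard benchmark model, not performance on genomic data.

## Problem sizes in the test suite

Exactness is established by oracle equivalence at desk scale — 50 seeded
instances with n ∈ [4,8], m ∈ [15,40], ℓ ∈ [4,9], d ∈ [0,2] for both
drivers, 200 random triples with ℓ ≤ 8, d ≤ 3 for FULLPRUNE — a regime
where brute-force filtering of the full candidate space is itself feasible,
plus degenerate identities (|B_d(x,x,x)| = N(ℓ,d) at ℓ ∈ {9,11}) and a
reduced-length planted run (n=20, m=100, ℓ=11, d=2).  Since the algorithm's
output is input-independent of every tuning knob (threshold, cache state,
strategy), correctness at these scales transfers to larger ones; the
historical multi-hour challenging-instance runs at m = 600, ℓ ≥ 17 are a
performance claim, not a correctness claim, and are not reproduced here.

## Known limitations

* Single strand only: no reverse-complement matching.
* The three-way intersection is the fixed basic step; a k-way
  generalization is a natural extension point but is not implemented.
* Pure-Python traversal: asymptotics match the design but constants are
  far from the original C implementation's; the package targets
  correctness, instrumentation and desk-scale experimentation.
* Sequences containing non-ACGT symbols are rejected by default; an opt-in
  mode drops the affected windows, which silently reduces the number of
  candidate occurrences per sequence.
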