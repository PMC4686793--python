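# Methods

## Decomposition grammars and the outside transform

A grammar here is a decomposition scheme: nonterminals name classes of
partial objects, terminals name atomic pieces of the input, and a
production lists one way the left-hand object splits into parts. Objects
carry a *boundary* — the part shared with their complement relative to the
full input (nothing for alignment prefixes, the last position for HMM
prefixes, the closing base pair for an RNA helix, the endpoints for a
partial path). Declaring boundaries per symbol (rather than per
production) is a design choice; it is what makes the complement of an
object well defined independently of how it was derived, at the price of
not being able to give one symbol different boundary semantics in
different rules.

The outside grammar is derived rule by rule: `A → α B β` contributes
`B* → α A* β` for each nonterminal `B` on the right, `S → A` becomes
`A* → S*`, and `A → ε` becomes `ε* → A*`. Derived rules inherit the
attribute slot of their generating rule, so the inside and outside
grammars have isomorphic signatures and share one evaluation algebra. The
transform requires a *normalized* grammar (start rules have a single
nonterminal right-hand side; terminal-only rules are exactly `lhs → ε`);
`derive_outside` rejects non-normalized input by default and can
auto-normalize by introducing fresh start/stop routing rules. Production
order is canonicalized lexicographically wherever grammars are compared.

The covering axioms behind the decompositions (parts cover the object,
interiors are disjoint, interiors are isotone) are statements about index
semantics, not syntax; they are exercised by the engines' oracle tests on
small inputs rather than checked statically on grammars.

`enumerate_parses` is the brute-force oracle: exhaustive recursive
enumeration of derivations over ordered string tapes (1 or 2), memoised
per (symbol, spans), with a limit guard. Set-structured inputs are served
by a dedicated oracle (`enumerate_hamiltonian_paths`) because punctuated
sets carry boundary state that the generic string parser has no use for.

## HMM engine

Two states, `+` (CpG island) and `−` (background), each with a first-order
dinucleotide table `a_s[prev, next]` (rows sum to 1, validated at 1e-9)
and per-step leave probabilities `q_pm` (leave `+`) and `q_mp` (leave
`−`). A step from origin state `s` to destination `s'` at position `i`
weighs `(stay-or-switch factor of s) × a_s[x[i−1], x[i]]` — both the
switch probability and the dinucleotide table belong to the **origin**
state. Position 1 has no predecessor; it is scored with a per-state
initial emission weight, by default the column marginal of `a_s`, and the
chain may start in either state (start weights (1, 1), matching
`f±[0] = 1`). Because a state is paired with the transition *into* its
position, time reversal maps the state chain with a one-position shift;
the reversibility tests account for this.

Posteriors are the per-position product `f±[i]·b±[i]` normalised by
`f₊b₊ + f₋b₋` (which equals the sequence likelihood at every position), so
they are proper probabilities; the raw unnormalised product is exposed
separately. For sequences longer than 64 the tables are rescaled per
position with the log-scale tracked, so likelihoods are returned in log
space without underflow; the scale cancels inside posterior ratios.

## Alignment engine

All recursions are written over a semiring (choice, combination):
max/plus or min/plus for optimisation, sum/product with unit weights for
counting, sum/product with Boltzmann weights `exp(score/RT)` (RT = 1 by
default) for partition functions. Default scores: match +1, mismatch −1,
gap open −2, gap extension −1.

Inside tables are prefix-indexed; `M/D/I[i][j]` classify prefix alignments
by their last column. The empty alignment is pinned to the match class
(`D` and `I` start at the semiring zero): this makes every alignment have
exactly one parse — the first column of every gap run is an opening — which
is what makes counting correct (13 alignments of two length-2 strings, the
central Delannoy number) and partition functions unambiguous. The
symmetric rule set with stop rules on all three states is kept in the
grammar module for the symbolic golden tests, with the ambiguity
documented there.

The outside tables are the mechanically derived gap-*closing* variant: the
(n, m) corner seeds all three `*` states (any class may end a global
alignment), and e.g. the weight of "open a deletion after a match"
attaches to the outside rule extending `M*` by that same column. The
numeric loops implement exactly the rule set `derive_outside` produces
from the engine grammar — asserted in the tests. Match posteriors are
`M[i][j]·M*[i][j]/Z`. Optimisation ties break deterministically
(M over D over I, leftmost split) so a single backtrace is reproducible.

## RNA engine

The toy secondary-structure model: every structure is a non-crossing set
of canonical pairs (gc, cg, au, ua, gu, ug), energy `E_pair = 1` per pair
and `E_unpaired = 0` per unpaired base, Boltzmann weights `exp(−E/RT)`.
The nearest-neighbour loop model is deliberately out of scope. The
decomposition is the unambiguous leftmost one (`U → cU | BU | ε`,
`B → cUc'`), so parse counting equals structure counting (verified against
the enumeration oracle, not assumed). `min_hairpin` defaults to 0 to match
the bare grammar; 3 is the physically realistic setting and is a
documented deviation when used.

`B[i][j]` carries its closing pair as a boundary shared with the outside
context `B*[i][j]`; the pair's Boltzmann factor is assigned to the inside
`B` rule only, so `B·B*/Z` counts it exactly once and is directly the pair
probability. In the outside split rule `B*[i][j] = Σ_k U*[i][k]·U[j+1][k]`
the sum starts at `k = j` (empty right interval), which the consistency
tests require. Per-position completeness — unpaired probability plus the
pair-probability row summing to 1 — is the inside/outside consistency
check used throughout.

## Set DP

Punctuated-set tables are dense arrays indexed `[mask, i, j]` (directed
endpoint convention), filled in increasing mask order by splitting one
endpoint off; `O(n² 2ⁿ)` states. Paths are undirected: symmetric input
matrices are required for ensembles (asymmetric ones are rejected with the
offending cell named; Held–Karp accepts them), and directed totals are
halved where appropriate. Held–Karp anchors tours at vertex 0 and breaks
ties towards the smallest vertex index.

Partition tables are kept in **log space** throughout (logsumexp
reductions), so very small temperatures — where every path weight
underflows linearly — remain exact; posteriors are formed as
`exp(log term − log Z)`, which is safe because every term is bounded by
Z. Ensemble parameters: `α = 1/(R·T)` with `R = (n−1)·d̄`, `d̄` the mean
over distinct unordered off-diagonal distances; `R` is overridable.
Adjacency marginals sum, over all complementary splits, the weight of
paths crossing a given edge; conditional adjacencies (fixed endpoint pair)
are computed on demand the same way. The outside tables (complement sets
sharing one boundary vertex) are filled by their own recursion and, for
symmetric inputs, coincide with the inside tables by path reversal — kept
as an implementation cross-check. Edges can be forbidden by setting their
distance to infinity, which prunes subsets no path can traverse.

Default size caps: 24 vertices for Held–Karp, 16 for ensemble tables
(memory is the binding constraint: the dense table is `n² 2ⁿ` doubles).
Tests and the acceptance script run at n ≤ 12, where everything completes
in seconds; those sizes were chosen because exhaustive oracles
(permutation and structure enumeration) stay cheap there.

## Gene-cluster pipeline

Distances between aligned amino-acid sequences: Hamming (count of
differing residues) or the BLOSUM45 transform
`d_ab = s(a,a) + s(b,b) − 2·s(a,b)` with `s` the summed BLOSUM45 score
(the standard published half-bit matrix, taken from Biopython's
substitution-matrix collection). Columns containing gaps or unknown
residues are dropped per sequence pair by default (self-scores are summed
over the same column set, keeping the diagonal exactly zero and the
transform nonnegative); a strict mode errors instead. Both metrics are
reported side by side by the CLI when requested, since either is a
defensible choice for diverged homeodomains.

The analysis sets `R = (n−1)·d̄` once, computes the optimal path (min
algebra) and the ensemble posteriors at each requested temperature, and
serialises the full report to JSON losslessly.

The synthetic generator emulates serial duplication: genes are placed on a
line with seeded positive increments drawn uniformly from (2, 8) —
homeodomain-scale Hamming distances between neighbouring paralogs, small
enough that a 60-column sequence realisation does not saturate for a
dozen genes — and `d[i,j] = |t_i − t_j|`. A line metric satisfies the
Robinson condition `d_ik ≥ max(d_ij, d_jk)` (i < j < k) exactly, so at
zero noise the shortest Hamiltonian path provably follows the gene order;
Gaussian symmetric noise (clipped at zero) degrades it gradually. The
optional sequence mode mutates the rounded number of distinct positions
per step, so adjacent Hamming distances match the matrix exactly and
longer spans only approximately (positions get re-mutated). What the
generator does **not** emulate: rate variation across lineages, saturating
substitution processes, gene loss, or rearrangements — so passing tests
demonstrate correctness of the machinery and recoverability under the
duplication-distance model, not performance on real, noisy clusters.
Analysis of a real cluster requires user-supplied aligned homeodomain
sequences in genomic order; `reference_endpoint_comparison` then tabulates
computed endpoint probabilities against externally published values.

## Numerical conventions

* Coordinates in all files and reports are 1-based inclusive; internal
  arrays are 0-based; the boundary is crossed only in I/O.
* Floats are written at 6 significant digits; tests compare by tolerance,
  never by string equality.
* Row-stochasticity and symmetry validations use 1e-9; oracle-equality
  tests assert 1e-10 to 1e-12 (the computations are exact up to float
  rounding); ensemble normalisation checks use 1e-9.
* Every stochastic routine takes an explicit seed; CLI runs echo their
  configuration and record seeds in their summaries.

## Known limitations

* Grammar products, multi-tape (>2) alignment, multi-context-free
  grammars/pseudoknots and tree data structures are out of scope.
* The generic parse enumerator handles ordered string tapes only.
* The RNA model is the toy energy model; no Turner parameters.
* Ensemble set DP is exact and therefore exponential; it is meant for
  gene-cluster-sized inputs (n ≲ 16), not general TSP workloads.
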