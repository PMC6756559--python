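# Methods

## Scope and objects

`btcnet` works with **binary tree-child (BTC) phylogenetic networks**: rooted
directed acyclic graphs, leaf-labeled by a taxon set (canonically
`[n] = {1..n}`), in which every node has degree pair (indegree, outdegree)
in {(1,0), (0,2), (1,2), (2,1)} and every non-leaf node has at least one
child of indegree ≤ 1 (a *tree node*). Nodes of degree (2,1) are *hybrid
nodes* and model reticulate events; the tree-child condition says every
ancestral lineage keeps at least one line of pure vertical descent. The
trivial network is a single node of degree (0,0), simultaneously root and
leaf; admitting it as a degenerate case is what lets every network reduce
all the way down. With `n` leaves, `t` tree nodes and `h` hybrid nodes,
`t − h = 2n − 1` and `h ≤ n − 1`; these identities are asserted throughout
the test suite.

Nodes are opaque integers assigned in creation order, and every iteration
order in the package derives from them, so all outputs are byte-reproducible
across runs and platforms. Path counts (mu-vectors) and all counting
arithmetic use exact Python integers: correctness over speed.

## Reduction

For a leaf `ℓ`, the *TH-path* `TH(ℓ)` is the unique maximal path of tree
nodes `u_1 .. u_r = ℓ` whose off-path children `v_i` are pairwise distinct
hybrid nodes. Extension of the path upward stops when the head's parent is
hybrid (the leaf has *type H*), is a tree node with two tree children, or
already feeds one of the attached hybrids (*type T*); in a valid network
the head never reaches the root. The reduction `R(N, ℓ)` deletes the
extended path (`TH(ℓ)` plus, for type H, the hybrid parent above it) and
eliminates the elementary nodes this creates — which are exactly the `v_i`
and the parents `w_j` of the path head, a fact the implementation asserts
rather than assumes. When the residual root is elementary, heir promotion
is applied repeatedly until the root is not; the fixpoint is well defined.

The *recovering data* of a reduction is `(S1, S2)`: the multiset of heirs
of the `w_j` (one node for T, two for H — equal exactly when the two `w`
nodes were joined by an arc) and the tuple of heirs of the `v_i` in path
order. `S1` is kept as a sorted tuple acting as a multiset, since the
repeated-heir case is semantically distinct from a single anchor.

`reduce_to_trivial` removes the highest label first (`n, n−1, …, 2`), so
generation, which adds `2, 3, …, n`, is its exact inverse. Because node
ids are not stable across reconstruction, recovering data is serialized
with nodes referenced by their mu-vectors; this is unambiguous because a
BTC network has no nontrivial automorphism, and the only mu-collision — a
hybrid node with its single child — is resolved by the fact that recovering
data only ever names tree nodes.

## Augmentation and feasibility

A pair `(S1, S2)` of tree nodes is *feasible* when (1) the `S2` members are
pairwise distinct and siblings only if one of them is in `S1`; (2) any `S2`
member with a hybrid parent or hybrid sibling is in `S1`; (3) no `S1` node
is a proper descendant of an `S2` node; and (4) `|S1| = 1` (T) or
`|S1| = 2` with `S1 ∩ S2 = ∅` (H). "Proper descendant" excludes the node
itself, which is what permits the T-anchor to appear in `S2`. The
augmentation splits the anchors first and then the `S2` nodes in order, so
the two coincidence cases (T-anchor inside `S2`; repeated H-anchor) fall
out of plain split composition. T-augmentations add `|S2|` hybrid nodes,
H-augmentations `|S2| + 1`.

Feasible pairs are enumerated depth-first with incremental pruning of
conditions 1–3, in a fixed documented order (T before H, `|S2|` ascending,
then lexicographic by node id, then anchors ascending). Termination needs
no external cap: any feasible tuple's prefix is feasible, so the first
empty length ends the scan.

## Generation, random networks, estimation

Every BTC network over `[n]` arises from the trivial network by a unique
chain of augmentations adding leaves `2..n`, so depth-first expansion over
feasible pairs generates `BTC_n` exhaustively with no isomorphism
filtering. Networks are copied on augmentation and streamed; memory is
O(depth × network size). Default problem sizes: the test suite generates
up to n = 5 (496,710 networks, a few seconds) and the key-uniqueness check
materializes canonical keys up to n = 4; n = 6 (101,833,875) runs with the
same code but is an hours-scale job and is not part of any default run.

`random_network(n, seed)` draws one feasible pair uniformly at each step
from a dedicated `random.Random(seed)` stream. This reaches every network
with positive probability but is **not** uniform over `BTC_n` — ancestors
differ in how many feasible pairs they expose — and no test treats it as
uniform; it serves as a seeded source of structurally diverse instances.
`estimate_next_count(n, m, seed)` materializes `BTC_n`, samples `m`
networks uniformly with replacement, and scales the mean offspring count
(= feasible-pair count) by `|BTC_n|`; `m ≥ |BTC_n|` clamps to the exact
exhaustive sum. The stopping rule is deliberately explicit (a sample size)
rather than an auto-stabilization criterion.

## Canonical form

The mu-vector of a node is the length-`n` integer vector of path counts to
each leaf, computed in reverse topological order. The canonical key of a
network is (sorted labels, sorted multiset of node mu-vectors, sorted
multiset of arc mu-pairs). The node multiset alone already characterizes
tree-child networks up to isomorphism; the arc pairs are included as
belt-and-braces, and the combination is validated empirically against
brute-force leaf-label-preserving digraph isomorphism (networkx VF2) on
all 66 networks of `BTC_3` and on the distinctness of all 4,059 keys of
`BTC_4`, rather than re-derived formally here.

## Counting and the upper bound

The closed forms count pairs satisfying the feasibility conditions *minus*
the descent condition (3), which depends on the topology; dropping it only
adds pairs, so the recursion
`B(n,h) = Σ_{h'} B(n−1,h')·F_T(n−1,h',h−h') + Σ_{h'} B(n−1,h')·F_H(n−1,h',h−h'−1)`
with `B(1,0) = 1` upper-bounds the exact census. The factorial-ratio
formulas are implemented as falling-factorial products in which any
non-positive factor zeroes its term, and `p(·,·,k)` is 1 at `k = 0` and 0
for `k < 0`. These degenerate-argument conventions are not forced by the
algebra; they were fixed once and are adjudicated by two independent
checks: the closed forms equal a brute-force pair census (condition 3
disabled) exactly on concrete networks with `(n,h)` in
{(1,0), (2,1), (3,0), (3,1), (4,1)}, and the bound totals for `n ≤ 10`
reproduce the published reference column digit for digit. The division in
`F_H,2` happens after multiplying two consecutive integers, keeping all
arithmetic integral. No closed-form asymptotics for the bound are
attempted.

## Sequence placement

A *sequenced network* maps every tree node to a fixed-length string over a
finite alphabet; hybrid nodes carry none (their sequence lives at the
single tree child). An evolution model supplies `P_S(s, s')` (descent with
modification) and `P_H(s1, s2, s')` (hybridization), plus a strategy for
maximizing kernel products over candidate sequences. The bundled toy model
uses Jukes–Cantor-style point mutation, `P_S = μ^d (1−(q−1)μ)^{L−d}` with
`d` the Hamming distance and `q` the alphabet size (`0 < μ < 1/q`), and
models hybridization as plain half-sequence recombination, each of the two
splices having probability 1/2 (`L` even). Its maximizer is exhaustive
over `Σ^L` in lexicographic order, so sequence ties resolve to the
lexicographically smallest; anchor ties resolve to the smallest node id;
and the T-attachment wins exact ties with H.

The heuristic scores a T-attachment at `t` by
`π(t) = max_σ φ_t(σ)·P_S(σ, s(t))·P_S(σ, s_ℓ)`, with `φ_t` the probability
of a sequence arising at `t` from above (1 at the root), and an
H-attachment at an unordered pair analogously with `P_H` coupling the two
inferred sequences. **Anchor candidates are the tree nodes with an
incoming arc.** The score prices the subdivision of the arc entering the
anchor; the root has no such arc, and with `φ_root ≡ 1` it would
spuriously dominate every comparison (its score has one kernel fewer).
Only on the trivial network, which has no arc at all, is the single node
itself the anchor. After attachment, hybridizations `y_1, y_2, …` are
accepted greedily: at each round every tree node keeping the pair feasible
is scored, candidates whose gain `κ` over the hybridization-free
explanation is negative are dropped (`κ = 0` is kept: removal is strictly
"negative"), and the best survivor is accepted. Candidates whose parent is
a hybrid node are skipped with a warning — the score needs the parent's
own sequence, which a hybrid node does not have, and no adapted formula is
defined; the case is only reachable through an anchor that is itself
hybrid-adjacent. Maximization is greedy per step, not joint across
rounds, and no global optimality is claimed.

### The worked example fixture

The tests and README use a sequenced 3-taxon tree
`(alpha,(beta,gamma))` with leaf sequences AAAC, BBCC, BBBB over
`Σ = {A,B,C}` and new sequence AACC. The internal assignment —
root = AAAB, inner node = BBBB — is a synthetic reconstruction: it is the
assignment under which the example's documented analytic scores hold
exactly, namely `π(alpha) = μ²(1−2μ)^10` with inferred sequence AAAC
(unique optimum), best H-pair {alpha, beta} with inferred sequences
(AAAB, BBCC) and `π = μ³(1−2μ)^13/2`, accepted hybridization `y_1 = beta`
with inferred sequence AACC and gain `(1−2μ)^7 μ/2 − μ³(1−2μ)^5`, and no
second hybridization. The critical rate at which that gain vanishes is
the root of `(1−2μ)^7 μ/2 = μ³(1−2μ)^5` in `(0, 1/3)`, in closed form
`μ* = 1/(2+√2) ≈ 0.29289`.

## What the generated data does and does not show

All test inputs are generated by the package itself (exhaustive levels,
seeded random networks, the worked example); nothing is estimated from
empirical alignments. Passing tests therefore establish the combinatorial
contracts — validity, unicity, round-trip identity, exact counts and
bounds — on the full spaces up to the sizes stated, but say nothing about
statistical performance of the placement heuristic on real sequence data:
the toy model's recombination kernel is far cruder than any realistic
model, sequence length 4 makes exhaustive maximization trivial, and the
non-uniform random generator over-represents networks whose ancestors
expose few feasible pairs.

## Known limitations

* Non-binary networks, outdegree > 2, and unrooted networks are out of
  scope, as are mu-distances beyond equality testing.
* Uniform sampling from `BTC_n` is not provided (the stepwise-uniform
  scheme is provably non-uniform, and no uniform sampler is known for this
  construction).
* Exhaustive generation at n = 7 and the full-scale n = 8 offspring
  estimate are out of reach of the default configuration by design;
  the estimator is exercised at small n where its exact target is known.
* The eNewick dialect is the common one (child subtree at the first
  occurrence of each `#H` tag); other dialects exist, and the lossless
  interchange format is the edge list.
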