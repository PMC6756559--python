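# btcnet

Binary tree-child (BTC) phylogenetic networks: exhaustive unique
generation, leaf reduction/augmentation, counting bounds, and placement of
a new sequence into a sequenced network.

Phylogenetic networks generalize phylogenetic trees with *hybrid nodes*
(indegree 2) that model reticulate evolution — hybridization,
recombination, lateral gene transfer. The binary **tree-child** class
restricts every non-leaf node to have at least one child reached by plain
vertical descent, which keeps the networks biologically interpretable and
computationally tractable. `btcnet` is for people who need to work with
the *space* of these networks: enumerate it exactly, sample from it,
bound its size, or extend an inferred network with a new taxon.

## What it implements

* **Reduction** `R(N, ℓ)`: removes a leaf together with its maximal
  *TH-path* (a path of tree nodes whose off-path children are distinct
  hybrid nodes) and returns a BTC network over `X \ {ℓ}` plus the
  *recovering data* `(S1, S2)` — the minimal information needed to invert
  the operation. Iterating reduces any BTC network to the trivial
  single-node network.
* **Augmentation** `R⁻¹(N, ℓ; S1, S2)`: the inverse operations (type T
  anchored at one tree node, type H at a multiset of two) defined for
  *feasible pairs*. Distinct feasible pairs give non-isomorphic networks,
  and every network over `[n]` arises from the trivial network by a unique
  augmentation chain adding leaves `2, …, n`.
* **Generation**: depth-first expansion over feasible pairs enumerates
  `BTC_n` exhaustively, each network exactly once, with no isomorphism
  filtering — `|BTC_n|` = 1, 3, 66, 4 059, 496 710, … for n = 1, 2, 3, 4, 5.
  Also: seeded random generation (uniform feasible-pair choice per step;
  not uniform over `BTC_n`) and a sampling estimator of `|BTC_{n+1}|`.
* **Counting bound**: closed-form pair counts `F_T(n, h, k)`,
  `F_H(n, h, k)` (feasibility minus the topology-dependent descent
  condition) feed the exact-integer recursion
  `B(n,h) ≤ Σ_{h'} B(n−1,h')·F_T + Σ_{h'} B(n−1,h')·F_H`, whose totals
  upper-bound `|BTC_n|`.
* **Isomorphism oracle**: mu-vectors (per-node path counts to each leaf);
  the sorted multisets of node and arc mu-vectors form a canonical key on
  this class.
* **Placement**: given a network whose tree nodes carry aligned sequences
  and a new sequence `s_ℓ`, a greedy heuristic picks the best T- or
  H-attachment by maximizing `π(t) = max_σ φ_t(σ)·P_S(σ, s(t))·P_S(σ, s_ℓ)`
  (and its H analogue), then accepts hybridizations while their gain `κ`
  over the hybridization-free explanation is non-negative. A toy
  Jukes–Cantor + half-sequence-recombination model is bundled; kernels are
  pluggable.

See `docs/methods.md` for definitions, conventions and limitations.

## Worked example

Count and census a level, and bound the next ones:

```
$ btcnet count -n 3
66
$ btcnet generate -n 3 --by-hybrids
0	3
1	21
2	42
total	66
$ btcnet bound -n 4
total	7442
```

Of the 66 BTC networks on 3 leaves, 3 are the hybrid-free trees, 21 have
one hybrid node, 42 have two; the recursion bounds the 4 059 networks of
`BTC_4` by 7 442. Estimate `|BTC_4|` by sampling offspring counts of 40
random networks in `BTC_3` (truth: 4 059):

```
$ btcnet estimate -n 3 --samples 40 --seed 1
estimate	4430.2
stderr	547.4
```

Reduce a cherry: the recovering data names nodes by their mu-vectors.

```
$ echo "(1,2);" > cherry.nwk
$ btcnet reduce --leaf 2 cherry.nwk
1;
{"kind": "T", "S1": [[1]], "S2": []}
```

Place a new sequence AACC (taxon `delta`) into a sequenced 3-taxon tree
under the toy model with mutation rate μ = 0.1:

```
$ printf '(alpha,(beta,gamma)m)r;\n' > net.nwk
$ printf '>r\nAAAB\n>m\nBBBB\n>alpha\nAAAC\n>beta\nBBCC\n>gamma\nBBBB\n' > seqs.fa
$ btcnet place --network net.nwk --sequences seqs.fa \
    --label delta --new-seq AACC --mu 0.1 --trace trace.json
((gamma,(beta)#H1),(alpha,(delta,#H1)));
```

The heuristic attaches `delta` next to `alpha` (inferred ancestral
sequence AAAC, score `π = μ²(1−2μ)¹⁰ ≈ 1.07×10⁻³`, beating the best
hybrid attachment `μ³(1−2μ)¹³/2`) and accepts one hybridization: `beta`
is re-explained as a recombinant of the new AACC lineage with its old
parent, which is more likely than two independent mutation paths whenever
μ < 1/(2+√2) ≈ 0.2929. The output eNewick shows the new leaf `delta` and
the hybrid `#H1` feeding `beta`; `trace.json` records every candidate
score.

The same operations are available as a library (`btcnet.generate_all`,
`btcnet.reduce`, `btcnet.augment`, `btcnet.place_sequence`, …), which is
the better interface for sweeps.

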