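"""Leaf reduction of BTC networks.

Removing a leaf from a tree-child network naively can leave the tree-child
class.  The reduction implemented here removes, together with the leaf
``l``, the maximal *TH-path* hanging over it — the unique maximal path of
tree nodes ending at ``l`` whose off-path children are pairwise distinct
hybrid nodes — plus, when the path is headed by a hybrid node, that hybrid
parent.  After deleting this set and eliminating the elementary nodes the
deletion creates, the result is again a BTC network with one leaf less.

Each reduction also emits its *recovering data* ``(S1, S2)``: the multiset
of heirs of the deleted ``w`` nodes and the tuple of heirs of the deleted
hybrid ``v`` nodes.  Together with the removed label this is exactly the
information the augmentation operations need to invert the reduction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Optional

from .network import (
    PhyloNetwork,
    eliminate_elementary,
    heir_of,
    mu_vectors,
    validate,
)

__all__ = [
    "THPath",
    "RecoveringData",
    "ReductionStep",
    "compute_th_path",
    "reduce",
    "reduce_to_trivial",
    "replay",
    "resolve_mu_ref",
    "recovering_data_to_jsonable",
    "recovering_data_from_jsonable",
]


@dataclass
class THPath:
    """The TH-path of a leaf with all its attached nodes resolved.

    ``path`` is ``u_1 .. u_r`` with ``u_r`` the leaf; ``kind`` is ``"T"``
    when the parent of ``u_1`` is a tree node and ``"H"`` when it is hybrid,
    in which case ``u0`` is that hybrid parent.  For ``i in [r-1]``:
    ``v[i]`` is the hybrid child of ``u_i``, ``x[i]`` the other parent of
    ``v[i]``, ``y[i]`` its single child.  ``w`` lists the parent(s) of the
    head of the extended path (one for T, two for H), ``t[j]`` the child of
    ``w[j]`` other than the head, and ``z[j]`` its parent when it exists.
    """

    leaf: int
    path: list[int]
    kind: str  # "T" | "H"
    u0: Optional[int]
    v: list[int]
    x: list[int]
    y: list[int]
    w: list[int]
    t: list[int]
    z: list[Optional[int]]

    @property
    def r(self) -> int:
        return len(self.path)

    @property
    def extended_path(self) -> list[int]:
        """TH-bar: the TH-path, preceded by the hybrid parent for kind H."""
        return self.path if self.u0 is None else [self.u0] + self.path


@dataclass(frozen=True)
class RecoveringData:
    """The feasible pair emitted by a reduction.

    ``s1`` is a sorted tuple acting as a multiset (length 1 for T, 2 for H;
    the two entries coincide exactly when the two ``w`` nodes were linked by
    an arc).  ``s2`` is the tuple of heirs of the ``v`` nodes in path
    order.  All node ids refer to the *reduced* network.
    """

    kind: str  # "T" | "H"
    s1: tuple[int, ...]
    s2: tuple[int, ...]


def compute_th_path(net: PhyloNetwork, leaf: int) -> THPath:
    """The unique maximal TH-path ending at ``leaf``.

    Starting from the trivial path formed by the leaf alone, the path is
    extended by prepending the parent of its head while that parent is a
    tree node whose other child is a hybrid node not already attached to
    the path.  Extension stops when the head's parent is hybrid (the leaf
    is then of kind H), is a tree node with two tree children, or is the
    other parent of one of the already-attached hybrids (kind T).
    """
    if net.num_nodes == 1:
        raise ValueError("the trivial network has no TH-path")
    if not net.is_leaf(leaf):
        raise ValueError(f"node {leaf} is not a leaf")

    path = [leaf]
    vs: list[int] = []
    while True:
        head = path[0]
        parents = net.parents(head)
        if not parents:
            # Impossible in a valid BTC network (the head of a TH-path is
            # never the root); reaching here means the input is broken.
            raise ValueError("TH-path head reached the root; network is not BTC")
        p = parents[0]
        if net.is_hybrid(p):
            kind = "H"
            break
        other = [c for c in net.children(p) if c != head]
        c = other[0]
        if net.is_tree_node(c) or c in vs:
            kind = "T"
            break
        path.insert(0, p)
        vs.insert(0, c)

    head = path[0]
    parent_of_head = net.parents(head)[0]
    if kind == "H":
        u0 = parent_of_head
        w = sorted(net.parents(u0))
        anchor = u0
    else:
        u0 = None
        w = [parent_of_head]
        anchor = head

    x = [next(p for p in net.parents(v) if p != u) for u, v in zip(path, vs)]
    y = [net.children(v)[0] for v in vs]
    t = [next(c for c in net.children(wj) if c != anchor) for wj in w]
    z = [net.parents(wj)[0] if net.parents(wj) else None for wj in w]
    return THPath(
        leaf=leaf, path=path, kind=kind, u0=u0, v=vs, x=x, y=y, w=w, t=t, z=z
    )


def reduce(
    net: PhyloNetwork, leaf_label: Hashable
) -> tuple[PhyloNetwork, RecoveringData]:
    """Reduce ``net`` with respect to the leaf carrying ``leaf_label``.

    Deletes the extended TH-path of the leaf, records the heirs of the
    elementary nodes this creates (the recovering data), then eliminates
    all elementary paths.  The result is a valid BTC network over the
    original taxa minus ``leaf_label``; surviving nodes keep their ids.
    """
    if net.num_nodes == 1:
        raise ValueError("cannot reduce the trivial network")
    leaf = net.node_with_label(leaf_label)
    th = compute_th_path(net, leaf)

    work = net.copy()
    for u in th.extended_path:
        work.remove_node(u)

    elem = {u for u in work.nodes if work.is_elementary(u)}
    expected = set(th.v) | set(th.w)
    if elem != expected:
        raise AssertionError(
            f"elementary nodes after deletion {elem} != v+w nodes {expected}"
        )

    s2 = tuple(heir_of(work, v) for v in th.v)
    s1 = tuple(sorted(heir_of(work, wj) for wj in th.w))

    reduced = eliminate_elementary(work)

    # Node-count bookkeeping: the reduction removes |TH-bar|+1 tree nodes
    # and turns |TH-bar|-1 hybrids into (eliminated) elementary nodes.
    k = len(th.extended_path)
    if reduced.num_tree() != net.num_tree() - k - 1:
        raise AssertionError("tree-node count after reduction is off")
    if reduced.num_hybrid() != net.num_hybrid() - k + 1:
        raise AssertionError("hybrid-node count after reduction is off")

    return reduced, RecoveringData(kind=th.kind, s1=s1, s2=s2)


@dataclass(frozen=True)
class ReductionStep:
    """One step of a full reduction, with nodes referenced by mu-vector.

    Node ids are not stable across serialization or reconstruction, but
    mu-vectors are (a BTC network has no nontrivial automorphism), so the
    recovering data is stored as mu-vectors of the reduced network's nodes.
    """

    label: Hashable
    kind: str
    s1_mu: tuple[tuple[int, ...], ...]
    s2_mu: tuple[tuple[int, ...], ...]


def _mu_refs(net: PhyloNetwork, nodes: tuple[int, ...]) -> tuple[tuple[int, ...], ...]:
    mu = mu_vectors(net)
    return tuple(mu[u] for u in nodes)


def resolve_mu_ref(net: PhyloNetwork, ref: tuple[int, ...]) -> int:
    """The tree node of ``net`` whose mu-vector equals ``ref``.

    A hybrid node shares its mu-vector with its single child, so among the
    matches the tree node is taken (recovering data only names tree nodes).
    """
    mu = mu_vectors(net)
    hits = [u for u, vec in mu.items() if vec == tuple(ref) and net.is_tree_node(u)]
    if len(hits) != 1:
        raise ValueError(f"mu-vector {ref} does not name a unique tree node")
    return hits[0]


def reduce_to_trivial(net: PhyloNetwork) -> list[ReductionStep]:
    """Reduce a network over ``[n]`` to the trivial network, leaf by leaf.

    Leaves are removed in the order ``n, n-1, ..., 2`` so that the
    generation procedure (which adds ``2, 3, ..., n``) is its exact
    inverse.  The returned steps are in reduction order; replaying them
    reversed through the augmentation operations reconstructs a network
    isomorphic to the input.
    """
    labels = net.label_set()
    n = len(labels)
    if labels != list(range(1, n + 1)):
        raise ValueError(f"labels must be exactly 1..n, got {labels}")
    steps: list[ReductionStep] = []
    current = net
    for lab in range(n, 1, -1):
        current, data = reduce(current, lab)
        steps.append(
            ReductionStep(
                label=lab,
                kind=data.kind,
                s1_mu=_mu_refs(current, data.s1),
                s2_mu=_mu_refs(current, data.s2),
            )
        )
    return steps


def replay(steps: list[ReductionStep]) -> PhyloNetwork:
    """Reconstruct a network from the steps of :func:`reduce_to_trivial`.

    Starting from the trivial network, the steps are applied in reverse
    through the augmentation operations, resolving each mu-vector reference
    against the network built so far.  The result is isomorphic to the
    network the steps were computed from.
    """
    from .augmentation import augment

    current = PhyloNetwork.trivial(1)
    for step in reversed(steps):
        s1 = tuple(sorted(resolve_mu_ref(current, m) for m in step.s1_mu))
        s2 = tuple(resolve_mu_ref(current, m) for m in step.s2_mu)
        current = augment(current, step.label, s1, s2)
    return current


def recovering_data_to_jsonable(net: PhyloNetwork, data: RecoveringData) -> dict:
    """Serialize recovering data against its network, nodes as mu-vectors."""
    mu = mu_vectors(net)
    return {
        "kind": data.kind,
        "S1": [list(mu[u]) for u in data.s1],
        "S2": [list(mu[u]) for u in data.s2],
    }


def recovering_data_from_jsonable(net: PhyloNetwork, obj: dict) -> RecoveringData:
    s1 = tuple(sorted(resolve_mu_ref(net, tuple(v)) for v in obj["S1"]))
    s2 = tuple(resolve_mu_ref(net, tuple(v)) for v in obj["S2"])
    return RecoveringData(kind=obj["kind"], s1=s1, s2=s2)
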