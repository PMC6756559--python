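"""Binary tree-child (BTC) phylogenetic networks.

A BTC network is a rooted, binary, leaf-labeled directed acyclic graph in
which every node is either a *tree node* (indegree at most 1) or a *hybrid
node* (indegree 2, outdegree 1), and every non-leaf node has at least one
child that is a tree node.  Hybrid nodes model reticulate events
(hybridization, recombination, lateral transfer); the tree-child condition
says that every ancestral lineage leaves at least one descendant line of
pure vertical descent.

This module provides the network container itself, validity diagnostics,
the two elementary rewriting primitives (node splitting and elimination of
elementary paths) on which the reduction/augmentation calculus is built,
and the mu-vector canonical form used as the isomorphism oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Iterable, Iterator

import networkx as nx

__all__ = [
    "PhyloNetwork",
    "ValidationReport",
    "validate",
    "split_node",
    "eliminate_elementary",
    "mu_representation",
    "isomorphic",
]

#: Degree pairs (indegree, outdegree) admitted in a binary phylogenetic
#: network: leaf, root, internal tree node, hybrid node.
ALLOWED_DEGREES = {(1, 0), (0, 2), (1, 2), (2, 1)}

#: Degree pairs of elementary nodes (only transiently present, between a
#: split and the elimination that undoes it).
ELEMENTARY_DEGREES = {(1, 1), (0, 1)}


def _label_sort_key(label: Hashable):
    # Integer labels sort numerically, anything else after them as strings;
    # keeps mixed taxon sets orderable without surprising collisions.
    if isinstance(label, int):
        return (0, label, "")
    return (1, 0, str(label))


class PhyloNetwork:
    """Rooted leaf-labeled DAG with creation-order integer node ids.

    Node identifiers are opaque integers assigned in creation order; all
    iteration orders derive from them, so every computation on a network is
    byte-reproducible across runs and platforms.

    The container is deliberately permissive: it stores any DAG-ish
    structure, and :func:`validate` diagnoses whether it is a BTC network.
    The trivial network is a single node of degree (0, 0) that is
    simultaneously the root and a labeled leaf.
    """

    __slots__ = ("_children", "_parents", "_labels", "_next_id")

    def __init__(self) -> None:
        self._children: dict[int, list[int]] = {}
        self._parents: dict[int, list[int]] = {}
        self._labels: dict[int, Hashable] = {}
        self._next_id: int = 0

    # -- construction -------------------------------------------------

    @classmethod
    def trivial(cls, label: Hashable = 1) -> "PhyloNetwork":
        """The trivial BTC network: a single node carrying ``label``."""
        net = cls()
        u = net.add_node()
        net.set_label(u, label)
        return net

    @classmethod
    def from_arcs(
        cls,
        arcs: Iterable[tuple[int, int]],
        labels: dict[int, Hashable],
    ) -> "PhyloNetwork":
        """Build a network from explicit arcs and a leaf-label map.

        Node ids are taken as given; ``_next_id`` resumes above the largest.
        """
        net = cls()
        arcs = list(arcs)
        nodes = sorted({u for a in arcs for u in a} | set(labels))
        for u in nodes:
            net._children[u] = []
            net._parents[u] = []
        net._next_id = (max(nodes) + 1) if nodes else 0
        for u, v in arcs:
            net.add_arc(u, v)
        for u, lab in labels.items():
            net.set_label(u, lab)
        return net

    def copy(self) -> "PhyloNetwork":
        net = PhyloNetwork()
        net._children = {u: list(cs) for u, cs in self._children.items()}
        net._parents = {u: list(ps) for u, ps in self._parents.items()}
        net._labels = dict(self._labels)
        net._next_id = self._next_id
        return net

    # -- mutation -----------------------------------------------------

    def add_node(self) -> int:
        u = self._next_id
        self._next_id += 1
        self._children[u] = []
        self._parents[u] = []
        return u

    def add_arc(self, u: int, v: int) -> None:
        self._children[u].append(v)
        self._parents[v].append(u)

    def remove_arc(self, u: int, v: int) -> None:
        self._children[u].remove(v)
        self._parents[v].remove(u)

    def remove_node(self, u: int) -> None:
        for v in list(self._children[u]):
            self.remove_arc(u, v)
        for p in list(self._parents[u]):
            self.remove_arc(p, u)
        del self._children[u]
        del self._parents[u]
        self._labels.pop(u, None)

    def set_label(self, u: int, label: Hashable) -> None:
        self._labels[u] = label

    def split(self, u: int) -> int:
        """Split ``u``: insert a new node above it, inheriting its in-arcs.

        The new node :math:`\\tilde u` gets the arc :math:`(\\tilde u, u)`,
        and every former arc :math:`(v, u)` becomes :math:`(v, \\tilde u)`.
        If ``u`` is a tree node the new node is elementary and its
        elimination recovers the original network.
        """
        if u not in self._children:
            raise KeyError(f"node {u} not in network")
        w = self.add_node()
        for p in list(self._parents[u]):
            self.remove_arc(p, u)
            self.add_arc(p, w)
        self.add_arc(w, u)
        return w

    # -- inspection ---------------------------------------------------

    @property
    def nodes(self) -> list[int]:
        return sorted(self._children)

    @property
    def num_nodes(self) -> int:
        return len(self._children)

    def arcs(self) -> Iterator[tuple[int, int]]:
        for u in sorted(self._children):
            for v in self._children[u]:
                yield (u, v)

    def children(self, u: int) -> list[int]:
        return self._children[u]

    def parents(self, u: int) -> list[int]:
        return self._parents[u]

    def indegree(self, u: int) -> int:
        return len(self._parents[u])

    def outdegree(self, u: int) -> int:
        return len(self._children[u])

    def degree_pair(self, u: int) -> tuple[int, int]:
        return (len(self._parents[u]), len(self._children[u]))

    def is_leaf(self, u: int) -> bool:
        return not self._children[u]

    def is_tree_node(self, u: int) -> bool:
        """Leaves, internal tree nodes and the root; also the trivial node."""
        return len(self._parents[u]) <= 1

    def is_hybrid(self, u: int) -> bool:
        return len(self._parents[u]) == 2

    def is_elementary(self, u: int) -> bool:
        return self.degree_pair(u) in ELEMENTARY_DEGREES

    def root(self) -> int:
        roots = [u for u in self._children if not self._parents[u]]
        if len(roots) != 1:
            raise ValueError(f"network has {len(roots)} roots")
        return roots[0]

    def leaves(self) -> list[int]:
        return [u for u in sorted(self._children) if not self._children[u]]

    @property
    def labels(self) -> dict[int, Hashable]:
        return self._labels

    def label_set(self) -> list[Hashable]:
        return sorted(self._labels.values(), key=_label_sort_key)

    def node_with_label(self, label: Hashable) -> int:
        for u, lab in self._labels.items():
            if lab == label:
                return u
        raise KeyError(f"no leaf labeled {label!r}")

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    def num_hybrid(self) -> int:
        return sum(1 for u in self._parents.values() if len(u) == 2)

    def num_tree(self) -> int:
        return sum(1 for u in self._parents.values() if len(u) <= 1)

    def descendants(self, u: int) -> set[int]:
        """Proper descendants of ``u`` (reachable by a path of length >= 1)."""
        seen: set[int] = set()
        stack = list(self._children[u])
        while stack:
            v = stack.pop()
            if v not in seen:
                seen.add(v)
                stack.extend(self._children[v])
        return seen

    def to_networkx(self) -> nx.DiGraph:
        """Bridge to networkx for DAG algorithms and external tooling."""
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.arcs())
        for u, lab in self._labels.items():
            g.nodes[u]["label"] = lab
        return g

    def __repr__(self) -> str:
        return (
            f"<PhyloNetwork n={self.n_leaves} nodes={self.num_nodes} "
            f"h={self.num_hybrid()}>"
        )


@dataclass
class ValidationReport:
    """Outcome of :func:`validate`: per-rule diagnoses, not an exception."""

    violations: list[tuple[str, list[int]]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def add(self, rule: str, nodes: Iterable[int] = ()) -> None:
        self.violations.append((rule, sorted(nodes)))

    def rules(self) -> set[str]:
        return {rule for rule, _ in self.violations}


def validate(net: PhyloNetwork) -> ValidationReport:
    """Diagnose whether ``net`` is a valid BTC network.

    Checks, each reported separately: acyclicity, single root, the binary
    degree table, the tree-child condition, and that the leaf labeling is a
    bijection.  The trivial one-node network is valid.
    """
    report = ValidationReport()
    if net.num_nodes == 0:
        report.add("empty")
        return report

    if not nx.is_directed_acyclic_graph(net.to_networkx()):
        report.add("acyclic")

    roots = [u for u in net.nodes if net.indegree(u) == 0]
    if len(roots) != 1:
        report.add("single-root", roots)

    if net.num_nodes == 1:
        u = net.nodes[0]
        if net.degree_pair(u) != (0, 0):
            report.add("degree", [u])
    else:
        bad = [u for u in net.nodes if net.degree_pair(u) not in ALLOWED_DEGREES]
        if bad:
            report.add("degree", bad)

    bad_tc = [
        u
        for u in net.nodes
        if net.children(u) and not any(net.is_tree_node(c) for c in net.children(u))
    ]
    if bad_tc:
        report.add("tree-child", bad_tc)

    leaves = set(net.leaves())
    labeled = set(net.labels)
    if leaves != labeled or len(set(net.labels.values())) != len(net.labels):
        report.add("labels", leaves ^ labeled)

    return report


def split_node(net: PhyloNetwork, u: int) -> tuple[PhyloNetwork, int]:
    """Return a copy of ``net`` with node ``u`` split, and the new node id."""
    out = net.copy()
    w = out.split(u)
    return out, w


def _elementary_chain(net: PhyloNetwork, e: int) -> list[int]:
    """The maximal elementary path through elementary node ``e``."""
    chain = [e]
    while True:
        ps = net.parents(chain[0])
        if ps and net.is_elementary(ps[0]):
            chain.insert(0, ps[0])
        else:
            break
    while True:
        c = net.children(chain[-1])[0]
        if net.is_elementary(c):
            chain.append(c)
        else:
            break
    return chain


def heir_of(net: PhyloNetwork, e: int) -> int:
    """The heir of elementary node ``e``: the first non-elementary node
    reached by descending through its single-child chain."""
    v = net.children(e)[0]
    while net.is_elementary(v):
        v = net.children(v)[0]
    return v


def eliminate_elementary(net: PhyloNetwork) -> PhyloNetwork:
    """Eliminate every maximal elementary path of ``net`` (a copy is returned).

    Each path is deleted and replaced by an arc from its grantor (the
    non-elementary parent above, when it exists) to its heir (the
    non-elementary child below).  When a path has no grantor — the root of
    the graph was elementary — its heir is promoted to root; promotions are
    iterated until no elementary node remains.
    """
    out = net.copy()
    for u in out.nodes:
        d = out.degree_pair(u)
        if d not in ALLOWED_DEGREES and d not in ELEMENTARY_DEGREES and d != (0, 0):
            raise ValueError(f"node {u} has degree {d}, outside the admissible table")
    while True:
        elem = [u for u in out.nodes if out.is_elementary(u)]
        if not elem:
            return out
        done: set[int] = set()
        for e in elem:
            if e in done:
                continue
            chain = _elementary_chain(out, e)
            done.update(chain)
            grantor = out.parents(chain[0])[0] if out.parents(chain[0]) else None
            heir = out.children(chain[-1])[0]
            for u in chain:
                out.remove_node(u)
            if grantor is not None:
                out.add_arc(grantor, heir)


def mu_vectors(net: PhyloNetwork) -> dict[int, tuple[int, ...]]:
    """Per-node mu-vectors: entry *i* counts the distinct directed paths
    from the node to the leaf with the *i*-th smallest label.

    Path counts are exact Python integers; they can exceed 64 bits on
    heavily reticulate networks.
    """
    labels = net.label_set()
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    order = list(nx.topological_sort(net.to_networkx()))
    mu: dict[int, tuple[int, ...]] = {}
    for u in reversed(order):
        if net.is_leaf(u):
            vec = [0] * n
            vec[index[net.labels[u]]] = 1
        else:
            vec = [0] * n
            for c in net.children(u):
                cv = mu[c]
                for i in range(n):
                    vec[i] += cv[i]
        mu[u] = tuple(vec)
    return mu


def mu_representation(net: PhyloNetwork):
    """Canonical, order-independent key of a BTC network.

    The key is the triple (sorted labels, sorted multiset of node
    mu-vectors, sorted multiset of arc mu-pairs).  On tree-child networks
    equal keys hold exactly for isomorphic networks: the node multiset is
    already injective on this class, and the arc pairs are included as
    belt-and-braces against degenerate collisions (the combination is
    cross-checked against brute-force digraph isomorphism in the tests).
    """
    report = validate(net)
    if not report.ok:
        raise ValueError(f"invalid network: {report.violations}")
    mu = mu_vectors(net)
    nodes_key = tuple(sorted(mu.values()))
    arcs_key = tuple(sorted((mu[u], mu[v]) for u, v in net.arcs()))
    labels_key = tuple(str(lab) for lab in net.label_set())
    return (labels_key, nodes_key, arcs_key)


def isomorphic(n1: PhyloNetwork, n2: PhyloNetwork) -> bool:
    """Leaf-label-preserving isomorphism test via the canonical form."""
    if n1.label_set() != n2.label_set():
        return False
    return mu_representation(n1) == mu_representation(n2)
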