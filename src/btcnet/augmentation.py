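"""Augmentation operations: the inverses of the leaf reductions.

An augmentation inserts a new labeled leaf into a BTC network, guided by a
*feasible pair* ``(S1, S2)`` of tree nodes.  ``S2 = (y_1, .., y_{r-1})``
names the nodes that acquire a new hybrid parent fed by the lineage of the
new leaf; ``S1`` names the node(s) whose incoming arc is subdivided to
anchor that lineage — one node for a T-augmentation (the new leaf descends
from a speciation) and a multiset of two for an H-augmentation (the new
leaf descends from a reticulate event).  Every feasible pair produces a
valid BTC network with one leaf more, distinct pairs produce
non-isomorphic networks, and every network arises this way from exactly
one (parent network, pair) — which is what makes exhaustive generation
without isomorphism filtering possible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Iterable, Iterator, Optional, Sequence

from .network import PhyloNetwork

__all__ = [
    "FeasibilityResult",
    "check_feasible",
    "augment",
    "augment_with_detail",
    "AugmentationDetail",
    "enumerate_feasible_pairs",
]


@dataclass
class FeasibilityResult:
    """Outcome of :func:`check_feasible`: a kind, or the violated conditions."""

    kind: Optional[str]  # "T" | "H" | None
    violations: list[str] = field(default_factory=list)

    def __bool__(self) -> bool:
        return self.kind is not None


def _siblings(net: PhyloNetwork, u: int) -> list[int]:
    out = []
    for p in net.parents(u):
        out.extend(c for c in net.children(p) if c != u)
    return out


def _hybrid_adjacent(net: PhyloNetwork, u: int) -> bool:
    """True when ``u`` has a hybrid parent or a hybrid sibling."""
    ps = net.parents(u)
    if ps and net.is_hybrid(ps[0]):
        return True
    return any(net.is_hybrid(s) for s in _siblings(net, u))


def check_feasible(
    net: PhyloNetwork, s1: Sequence[int], s2: Sequence[int]
) -> FeasibilityResult:
    """Check the feasibility conditions for the pair ``(s1, s2)``.

    All members must be tree nodes of ``net``.  The conditions are:

    1. the ``y_i`` are pairwise distinct, and two of them may be siblings
       only if one of them belongs to ``S1``;
    2. a ``y_i`` that is the child of a hybrid node or has a hybrid sibling
       must belong to ``S1``;
    3. no node of ``S1`` is a proper descendant of a node of ``S2``;
    4. ``|S1| = 1`` (T) or ``|S1| = 2`` with ``S1`` disjoint from ``S2`` (H).

    "Proper descendant" means reachable by a directed path of length at
    least one; a node is not a proper descendant of itself, which is what
    permits the single T-anchor to appear in ``S2``.
    """
    s1 = tuple(s1)
    s2 = tuple(s2)
    for u in s1 + s2:
        if u not in net._children:
            raise KeyError(f"node {u} not in network")
    violations: list[str] = []
    if not all(net.is_tree_node(u) for u in s1 + s2):
        violations.append("members must be tree nodes")

    s1_set = set(s1)
    for i in range(len(s2)):
        for j in range(i + 1, len(s2)):
            yi, yj = s2[i], s2[j]
            if yi == yj:
                violations.append(f"condition 1: repeated node {yi} in S2")
            elif yj in _siblings(net, yi) and yi not in s1_set and yj not in s1_set:
                violations.append(f"condition 1: siblings {yi},{yj} outside S1")
    for yi in s2:
        if _hybrid_adjacent(net, yi) and yi not in s1_set:
            violations.append(f"condition 2: hybrid-adjacent node {yi} outside S1")
    for y in set(s2):
        desc = net.descendants(y)
        for tau in s1:
            if tau in desc:
                violations.append(f"condition 3: {tau} descends from {y}")

    if len(s1) == 1:
        kind = "T"
    elif len(s1) == 2:
        kind = "H"
        if s1_set & set(s2):
            violations.append("condition 4H: S1 and S2 not disjoint")
    else:
        kind = None
        violations.append(f"condition 4: |S1| = {len(s1)} not in {{1, 2}}")

    return FeasibilityResult(kind=None if violations else kind, violations=violations)


@dataclass
class AugmentationDetail:
    """Ids of the nodes created by an augmentation, for callers that need
    to decorate them (the placement heuristic attaches sequences)."""

    w: list[int]  # split nodes above the S1 anchors (1 for T, 2 for H)
    u0: Optional[int]  # the new hybrid head (H only)
    us: list[int]  # the new path u_1 .. u_r; us[-1] is the new leaf
    vs: list[int]  # the new hybrid parents of the S2 nodes, in order


def augment_with_detail(
    net: PhyloNetwork,
    label: Hashable,
    s1: Sequence[int],
    s2: Sequence[int],
    *,
    check: bool = True,
) -> tuple[PhyloNetwork, AugmentationDetail]:
    """Apply the augmentation for ``(s1, s2)``, returning the new network
    (the input is not modified) and the ids of the created nodes.

    Splits are performed in a fixed order — the ``S1`` anchors first, then
    ``y_1 .. y_{r-1}`` — so that the coincidence cases fall out correctly:
    a T-anchor equal to some ``y_i`` yields the arc ``(w_1, v_i)``, and a
    repeated H-anchor yields ``w_1`` as parent of ``w_2``.
    """
    if label in net.labels.values():
        raise ValueError(f"label {label!r} already present")
    if check:
        result = check_feasible(net, s1, s2)
        if not result:
            raise ValueError(f"infeasible pair: {result.violations}")

    s1 = tuple(sorted(s1))
    s2 = tuple(s2)
    out = net.copy()
    r = len(s2) + 1

    ws = [out.split(tau) for tau in s1]
    u0 = None
    if len(s1) == 2:
        u0 = out.add_node()
        for w in ws:
            out.add_arc(w, u0)

    us = [out.add_node() for _ in range(r)]
    out.add_arc(u0 if u0 is not None else ws[0], us[0])
    for a, b in zip(us, us[1:]):
        out.add_arc(a, b)

    vs = []
    for i, y in enumerate(s2):
        v = out.split(y)
        out.add_arc(us[i], v)
        vs.append(v)

    out.set_label(us[-1], label)
    return out, AugmentationDetail(w=ws, u0=u0, us=us, vs=vs)


def augment(
    net: PhyloNetwork,
    label: Hashable,
    s1: Sequence[int],
    s2: Sequence[int],
    *,
    check: bool = True,
) -> PhyloNetwork:
    """The augmented network ``R^{-1}(net, label; s1, s2)``.

    Dispatches on ``|s1|``: one anchor applies the T-augmentation, two the
    H-augmentation.  The result is a valid BTC network over the input taxa
    plus ``label``, with ``h + r - 1`` (T) or ``h + r`` (H) hybrid nodes
    where ``r - 1 = |s2|``.
    """
    out, _ = augment_with_detail(net, label, s1, s2, check=check)
    return out


def enumerate_feasible_pairs(
    net: PhyloNetwork,
) -> Iterator[tuple[tuple[int, ...], tuple[int, ...]]]:
    """All feasible pairs of ``net``, each exactly once, in a fixed order.

    Order: T-pairs before H-pairs; within a kind, ``|S2|`` ascending; within
    a length, ``S2`` tuples lexicographic by node id and then ``S1``
    ascending.  The search is depth-first with incremental pruning of
    conditions 1–3, so the enumeration terminates as soon as no tuple of a
    given length can be extended.
    """
    tnodes = [u for u in net.nodes if net.is_tree_node(u)]
    marked = {u for u in tnodes if _hybrid_adjacent(net, u)}
    sibs = {u: set(_siblings(net, u)) for u in tnodes}
    desc = {u: net.descendants(u) for u in tnodes}

    # ---- T-pairs: S1 = {tau1}; at most one member of S2 may need the
    # "excuse" of membership in S1, and then tau1 is pinned to it.
    def t_tuples(k: int, start_ys: list[int], required: Optional[frozenset]):
        if len(start_ys) == k:
            if required is None:
                pool: Iterable[int] = tnodes
            else:
                pool = sorted(required)
            ys = tuple(start_ys)
            for tau in pool:
                if all(tau not in desc[y] for y in ys):
                    yield ((tau,), ys)
            return
        used = set(start_ys)
        for y in tnodes:
            if y in used:
                continue
            req = required
            if y in marked:
                req = frozenset([y]) if req is None else req & {y}
                if not req:
                    continue
            clash = sibs[y] & used
            ok = True
            for z in clash:
                pair = frozenset([y, z])
                req = pair if req is None else req & pair
                if not req:
                    ok = False
                    break
            if not ok:
                continue
            start_ys.append(y)
            yield from t_tuples(k, start_ys, req)
            start_ys.pop()

    k = 0
    while True:
        found = False
        for pair in t_tuples(k, [], None):
            found = True
            yield pair
        if not found:
            break
        k += 1

    # ---- H-pairs: S1 is a multiset of two anchors disjoint from S2, so no
    # excuses are possible: S2 draws only from clean, pairwise non-sibling
    # nodes.
    clean = [u for u in tnodes if u not in marked]

    def h_tuples(k: int, start_ys: list[int]):
        if len(start_ys) == k:
            ys = tuple(start_ys)
            used = set(ys)
            blocked = set().union(*(desc[y] for y in ys)) if ys else set()
            pool = [t for t in tnodes if t not in used and t not in blocked]
            for a_idx, a in enumerate(pool):
                for b in pool[a_idx:]:
                    yield ((a, b), ys)
            return
        used = set(start_ys)
        for y in clean:
            if y in used or sibs[y] & used:
                continue
            start_ys.append(y)
            yield from h_tuples(k, start_ys)
            start_ys.pop()

    k = 0
    while True:
        found = False
        for pair in h_tuples(k, []):
            found = True
            yield pair
        if not found:
            break
        k += 1
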