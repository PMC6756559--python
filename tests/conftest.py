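"""Shared fixtures: small reference networks, generated levels, and the
brute-force isomorphism oracle used to validate the mu-vector canonical
form."""

from __future__ import annotations

import pytest
from networkx.algorithms import isomorphism as nxiso

from btcnet import PhyloNetwork, augment, generate_all
from btcnet.placement import SequencedNetwork


def brute_force_isomorphic(n1: PhyloNetwork, n2: PhyloNetwork) -> bool:
    """Leaf-label-preserving digraph isomorphism by exhaustive search
    (networkx VF2); independent of the mu-vector canonical form."""
    g1, g2 = n1.to_networkx(), n2.to_networkx()
    nm = nxiso.categorical_node_match("label", None)
    return nxiso.DiGraphMatcher(g1, g2, node_match=nm).is_isomorphic()


@pytest.fixture
def trivial() -> PhyloNetwork:
    return PhyloNetwork.trivial(1)


@pytest.fixture
def cherry() -> PhyloNetwork:
    """The rooted cherry on {1, 2}."""
    return augment(PhyloNetwork.trivial(1), 2, (0,), ())


@pytest.fixture
def btc2_hybrid() -> PhyloNetwork:
    """The BTC network over {1, 2} whose leaf 2 hangs below a hybrid node."""
    return augment(PhyloNetwork.trivial(1), 2, (0, 0), ())


@pytest.fixture
def four_taxon_network() -> PhyloNetwork:
    """A 4-taxon BTC network with one hybrid node: root u with children
    v, w; v -> leaf 1 and hybrid x; w -> x and y; x -> leaf 2; y -> leaves
    3, 4."""
    u, v, w, x, y = 0, 1, 2, 3, 4
    arcs = [
        (u, v), (u, w),
        (v, 5), (v, x),
        (w, x), (w, y),
        (x, 6),
        (y, 7), (y, 8),
    ]
    return PhyloNetwork.from_arcs(arcs, {5: 1, 6: 2, 7: 3, 8: 4})


@pytest.fixture(scope="session")
def btc3() -> list[PhyloNetwork]:
    return list(generate_all(3))


@pytest.fixture(scope="session")
def btc4() -> list[PhyloNetwork]:
    return list(generate_all(4))


@pytest.fixture
def example_sequenced_network() -> tuple[SequencedNetwork, dict[str, int]]:
    """A sequenced 3-taxon tree for the worked placement example.

    Topology (alpha,(beta,gamma)) with leaf sequences alpha=AAAC,
    beta=BBCC, gamma=BBBB over the alphabet {A,B,C}.  The internal
    assignment (root=AAAB, inner node=BBBB) is a synthetic reconstruction
    chosen so the documented analytic scores of the placement heuristic
    hold exactly; see docs/methods.md.
    """
    net = PhyloNetwork()
    root, alpha, m, beta, gamma = (net.add_node() for _ in range(5))
    net.add_arc(root, alpha)
    net.add_arc(root, m)
    net.add_arc(m, beta)
    net.add_arc(m, gamma)
    net.set_label(alpha, "alpha")
    net.set_label(beta, "beta")
    net.set_label(gamma, "gamma")
    seqs = {root: "AAAB", m: "BBBB", alpha: "AAAC", beta: "BBCC", gamma: "BBBB"}
    names = {"root": root, "m": m, "alpha": alpha, "beta": beta, "gamma": gamma}
    return SequencedNetwork(net, seqs), names
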