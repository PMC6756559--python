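"""The toy evolution model and the greedy placement heuristic.

The worked example places the sequence AACC (taxon delta) into the
sequenced 3-taxon tree (alpha:AAAC, (beta:BBCC, gamma:BBBB)); its expected
scores below are the analytic values of the heuristic's objective under
the toy model, derived by hand from the kernel definitions.
"""

import itertools

import pytest

from btcnet import PhyloNetwork, augment, isomorphic, validate
from btcnet.placement import (
    SequencedNetwork,
    extend_with_hybridizations,
    phi,
    place_sequence,
    select_attachment,
    toy_model,
)

MU = 0.1


class TestToyModel:
    def test_speciation_kernel_is_hamming_based(self):
        model = toy_model(MU)
        assert model.p_s("AAAC", "AAAC") == pytest.approx((1 - 2 * MU) ** 4)
        assert model.p_s("AAAC", "AACC") == pytest.approx(MU * (1 - 2 * MU) ** 3)
        assert model.p_s("AAAA", "BBBB") == pytest.approx(MU**4)

    def test_hybridization_kernel_is_half_split(self):
        model = toy_model(MU)
        assert model.p_h("AABB", "CCDD", "AADD") == 0.5
        assert model.p_h("AABB", "CCDD", "CCBB") == 0.5
        assert model.p_h("AABB", "CCDD", "ABCD") == 0.0

    def test_hybridization_kernel_sums_to_one_when_recombinants_differ(self):
        model = toy_model(MU)
        s1, s2 = "AABB", "BBAA"
        total = sum(
            model.p_h(s1, s2, "".join(s)) for s in itertools.product("AB", repeat=4)
        )
        assert total == 1.0

    def test_mu_range_enforced(self):
        with pytest.raises(ValueError):
            toy_model(1 / 3)
        with pytest.raises(ValueError):
            toy_model(0.0)

    def test_odd_length_rejected(self):
        with pytest.raises(ValueError):
            toy_model(MU, length=5)

    def test_argmax_breaks_ties_lexicographically(self):
        model = toy_model(MU, length=2)
        sigma, val = model.argmax(lambda s: 1.0)
        assert sigma == "AA" and val == 1.0


class TestPhi:
    def test_root_is_constant_one(self, example_sequenced_network):
        snet, names = example_sequenced_network
        assert phi(snet, names["root"], "CCCC", toy_model(MU)) == 1.0

    def test_tree_parent_uses_speciation_kernel(self, example_sequenced_network):
        snet, names = example_sequenced_network
        model = toy_model(MU)
        # parent of alpha carries AAAB, one mismatch from AAAC
        assert phi(snet, names["alpha"], "AAAC", model) == pytest.approx(
            MU * (1 - 2 * MU) ** 3
        )

    def test_hybrid_parent_uses_recombination_kernel(self):
        net = augment(PhyloNetwork.trivial(1), 2, (0, 0), ())
        root = net.root()
        inner = next(c for c in net.children(root) if not net.is_leaf(c))
        leaf2 = net.node_with_label(2)
        snet = SequencedNetwork(net, {root: "AABB", inner: "CCDD", 0: "CCDD", leaf2: "AADD"})
        model = toy_model(MU, alphabet="ABCD")
        assert phi(snet, leaf2, "AADD", model) == 0.5
        assert phi(snet, leaf2, "ABCD", model) == 0.0


class TestSelectAttachment:
    def test_example_attachment_is_t_at_alpha(self, example_sequenced_network):
        snet, names = example_sequenced_network
        trace = select_attachment(snet, "AACC", toy_model(MU))
        assert trace.kind == "T"
        assert trace.s1 == (names["alpha"],)
        assert trace.sigmas == ("AAAC",)
        assert trace.pi_t == pytest.approx(MU**2 * (1 - 2 * MU) ** 10)

    def test_example_h_score_and_pair(self, example_sequenced_network):
        snet, names = example_sequenced_network
        trace = select_attachment(snet, "AACC", toy_model(MU))
        assert trace.pi_h == pytest.approx(MU**3 * (1 - 2 * MU) ** 13 / 2)
        best_pair = max(trace.h_scores, key=lambda p: trace.h_scores[p][2])
        assert set(best_pair) == {names["alpha"], names["beta"]}
        assert trace.h_scores[best_pair][:2] == ("AAAB", "BBCC")

    def test_t_beats_h_for_all_admissible_mu(self, example_sequenced_network):
        snet, _ = example_sequenced_network
        for mu in (0.05, 0.15, 0.25, 0.32):
            trace = select_attachment(snet, "AACC", toy_model(mu))
            assert trace.kind == "T"

    def test_single_node_network_attaches_at_root(self):
        net = PhyloNetwork.trivial("a")
        snet = SequencedNetwork(net, {0: "AABB"})
        model = toy_model(MU)
        trace = select_attachment(snet, "AABB", model)
        assert trace.kind == "T" and trace.s1 == (0,)
        assert trace.sigmas == ("AABB",)
        assert trace.pi == pytest.approx(model.p_s("AABB", "AABB") ** 2)


class TestExtension:
    def test_example_accepts_beta_then_stops(self, example_sequenced_network):
        snet, names = example_sequenced_network
        model = toy_model(MU)
        trace = select_attachment(snet, "AACC", model)
        trace = extend_with_hybridizations(snet, trace, "AACC", model)
        assert [y for y, _, _ in trace.accepted] == [names["beta"]]
        y, sigma, kappa = trace.accepted[0]
        assert sigma == "AACC"
        expected_kappa = (1 - 2 * MU) ** 7 * MU / 2 - MU**3 * (1 - 2 * MU) ** 5
        assert kappa == pytest.approx(expected_kappa)
        assert len(trace.rounds) == 2 and not trace.rounds[-1]

    def test_accepted_candidates_have_nonnegative_gain(self, example_sequenced_network):
        snet, _ = example_sequenced_network
        model = toy_model(MU)
        trace = select_attachment(snet, "AACC", model)
        trace = extend_with_hybridizations(snet, trace, "AACC", model)
        assert all(kappa >= 0 for _, _, kappa in trace.accepted)


class TestPlaceSequence:
    def test_example_end_to_end(self, example_sequenced_network):
        snet, names = example_sequenced_network
        out, trace = place_sequence(snet, "delta", "AACC", toy_model(MU))
        assert validate(out.network).ok
        assert out.network.n_leaves == 4
        reference = augment(
            snet.network, "delta", (names["alpha"],), (names["beta"],)
        )
        assert isomorphic(out.network, reference)
        # the new hybrid is fed by a node carrying the inferred AACC
        hybrid = next(u for u in out.network.nodes if out.network.is_hybrid(u))
        feeder_seqs = {out.sequences.get(p) for p in out.network.parents(hybrid)}
        assert "AACC" in feeder_seqs
        # pre-existing tree nodes keep their sequences
        for node, seq in snet.sequences.items():
            assert out.sequences[node] == seq

    def test_trivial_network_grows_to_cherry(self):
        snet = SequencedNetwork(PhyloNetwork.trivial(1), {0: "ABAB"})
        out, trace = place_sequence(snet, 2, "AABB", toy_model(MU))
        assert trace.kind == "T"
        assert out.network.n_leaves == 2 and out.network.num_hybrid() == 0
        assert validate(out.network).ok

    def test_identical_sequence_placed_without_hybridization(self):
        """Placing a copy of an existing leaf sequence into a 2-leaf tree:
        brute force over all anchors and sequences says plain T-descent
        wins, so no hybridization should be accepted."""
        net = augment(PhyloNetwork.trivial(1), 2, (0,), ())
        root = net.root()
        snet = SequencedNetwork(net, {root: "AAAA", 0: "AAAA", net.node_with_label(2): "BBBB"})
        model = toy_model(MU)
        out, trace = place_sequence(snet, 3, "AAAA", model)
        assert trace.kind == "T"
        assert not trace.accepted
        assert out.network.num_hybrid() == 0
        # independent check of the winning T-score by exhaustive search
        best = max(
            model.p_s(snet.sequences[root], s) * model.p_s(s, "AAAA") ** 2
            for s in map("".join, itertools.product("ABC", repeat=4))
        )
        assert trace.pi == pytest.approx(best)

    def test_duplicate_label_rejected(self, example_sequenced_network):
        snet, _ = example_sequenced_network
        with pytest.raises(ValueError):
            place_sequence(snet, "alpha", "AACC", toy_model(MU))
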