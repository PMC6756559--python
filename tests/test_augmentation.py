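"""Feasibility conditions, the two augmentation operations, and the
deterministic enumeration of feasible pairs."""

import itertools

import pytest

from btcnet import (
    PhyloNetwork,
    augment,
    check_feasible,
    enumerate_feasible_pairs,
    isomorphic,
    mu_representation,
    reduce,
    validate,
)


class TestCheckFeasible:
    def test_trivial_singleton_is_t_feasible(self, trivial):
        assert check_feasible(trivial, (0,), ()).kind == "T"

    def test_trivial_doubled_anchor_is_h_feasible(self, trivial):
        assert check_feasible(trivial, (0, 0), ()).kind == "H"

    def test_4h_disjointness(self, trivial):
        result = check_feasible(trivial, (0, 0), (0,))
        assert result.kind is None
        assert any("4H" in v for v in result.violations)

    def test_tau_in_s2_allowed_for_t(self, trivial):
        assert check_feasible(trivial, (0,), (0,)).kind == "T"

    def test_descent_condition(self, cherry):
        root, leaf1 = cherry.root(), cherry.node_with_label(1)
        result = check_feasible(cherry, (leaf1,), (root,))
        assert result.kind is None
        assert any("condition 3" in v for v in result.violations)

    def test_hybrid_adjacent_node_needs_excuse(self, btc2_hybrid):
        # leaf 1 is sibling of the hybrid node: usable in S2 only as tau_1
        leaf1 = btc2_hybrid.node_with_label(1)
        assert check_feasible(btc2_hybrid, (leaf1,), (leaf1,)).kind == "T"
        root = btc2_hybrid.root()
        bad = check_feasible(btc2_hybrid, (root,), (leaf1,))
        assert any("condition 2" in v for v in bad.violations)

    def test_hybrid_member_rejected(self, btc2_hybrid):
        hybrid = next(u for u in btc2_hybrid.nodes if btc2_hybrid.is_hybrid(u))
        result = check_feasible(btc2_hybrid, (hybrid,), ())
        assert result.kind is None

    def test_unknown_node_raises(self, trivial):
        with pytest.raises(KeyError):
            check_feasible(trivial, (42,), ())


class TestAugment:
    def test_t_augmentation_of_trivial_gives_cherry(self, trivial, cherry):
        assert isomorphic(augment(trivial, 2, (0,), ()), cherry)

    def test_h_augmentation_of_trivial(self, trivial):
        net = augment(trivial, 2, (0, 0), ())
        assert validate(net).ok
        assert net.num_hybrid() == 1
        hybrid = next(u for u in net.nodes if net.is_hybrid(u))
        child = net.children(hybrid)[0]
        assert net.labels.get(child) == 2

    def test_three_pairs_give_all_of_btc2(self, trivial):
        nets = [augment(trivial, 2, s1, s2) for s1, s2 in enumerate_feasible_pairs(trivial)]
        assert len(nets) == 3
        keys = {mu_representation(net) for net in nets}
        assert len(keys) == 3

    def test_infeasible_pair_raises(self, trivial):
        with pytest.raises(ValueError):
            augment(trivial, 2, (0, 0), (0,))

    def test_duplicate_label_raises(self, cherry):
        with pytest.raises(ValueError):
            augment(cherry, 2, (cherry.root(),), ())

    def test_hybrid_count_deltas_match_operation_kind(self, btc3):
        """T-augmentations add |S2| hybrids, H-augmentations |S2| + 1."""
        for net in btc3[::9]:
            h = net.num_hybrid()
            for s1, s2 in enumerate_feasible_pairs(net):
                child = augment(net, 4, s1, s2)
                expected = h + len(s2) + (1 if len(s1) == 2 else 0)
                assert child.num_hybrid() == expected

    def test_augment_then_reduce_recovers_input_pair(self, btc3):
        for net in btc3[::13]:
            key = mu_representation(net)
            for s1, s2 in itertools.islice(enumerate_feasible_pairs(net), 12):
                child = augment(net, 4, s1, s2)
                back, data = reduce(child, 4)
                assert mu_representation(back) == key
                assert data.s1 == tuple(sorted(s1)) and data.s2 == s2


class TestEnumerateFeasiblePairs:
    def test_trivial_pairs_exact(self, trivial):
        assert list(enumerate_feasible_pairs(trivial)) == [
            ((0,), ()),
            ((0,), (0,)),
            ((0, 0), ()),
        ]

    def test_matches_brute_force_on_small_networks(
        self, trivial, cherry, btc2_hybrid, four_taxon_network
    ):
        """The pruned enumeration equals a naive scan over all (S1, S2)
        combinations checked one by one with check_feasible."""
        for net in (trivial, cherry, btc2_hybrid, four_taxon_network):
            tnodes = [u for u in net.nodes if net.is_tree_node(u)]
            kmax = min(len(tnodes), 3)  # keeps the naive scan affordable
            brute = set()
            for k in range(0, kmax + 1):
                for s2 in itertools.permutations(tnodes, k):
                    for tau in tnodes:
                        if check_feasible(net, (tau,), s2).kind == "T":
                            brute.add(((tau,), s2))
                    for pair in itertools.combinations_with_replacement(tnodes, 2):
                        if check_feasible(net, pair, s2).kind == "H":
                            brute.add((pair, s2))
            enumerated = list(enumerate_feasible_pairs(net))
            assert len(enumerated) == len(set(enumerated))
            assert {p for p in enumerated if len(p[1]) <= kmax} == brute

    def test_offspring_of_cherry_all_distinct(self, cherry, btc3):
        """Distinct feasible pairs give non-isomorphic offspring, and the
        two BTC_2 networks' offspring tile all 66 networks of BTC_3."""
        pairs = list(enumerate_feasible_pairs(cherry))
        keys = [mu_representation(augment(cherry, 3, s1, s2)) for s1, s2 in pairs]
        assert len(set(keys)) == len(pairs)
        all_keys = {mu_representation(net) for net in btc3}
        assert set(keys) <= all_keys

    def test_enumeration_is_deterministic(self, four_taxon_network):
        first = list(enumerate_feasible_pairs(four_taxon_network))
        second = list(enumerate_feasible_pairs(four_taxon_network))
        assert first == second
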