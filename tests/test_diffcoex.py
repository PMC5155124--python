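"""Differential coexpression scoring: subnetworks, DCGN-S, stars, DCGN-I."""

import itertools
import math

import numpy as np
import pytest

from dcgn import (
    dcgn_i,
    dcgn_s,
    extract_subnetwork,
    max_least_step_prob,
    score_all,
    star_transform,
)

from conftest import (
    ball_and_edges_oracle,
    enumerate_min_hop_walk_prob,
    net_from_edges,
    random_network,
)


def path_graph():
    return net_from_edges(
        {("A", "B"): 0.5, ("B", "C"): 0.5, ("C", "D"): 0.5}, list("ABCD")
    )


class TestExtractSubnetwork:
    def test_path_graph_balls(self):
        net = path_graph()
        sub1 = extract_subnetwork(net, "A", 1)
        assert sub1.node_set == {"A", "B"}
        assert sub1.edge_set == {("A", "B")}
        sub2 = extract_subnetwork(net, "A", 2)
        assert sub2.node_set == {"A", "B", "C"}
        assert sub2.edge_set == {("A", "B"), ("B", "C")}

    def test_isolated_center(self):
        net = net_from_edges({("A", "B"): 0.5}, list("ABC"))
        sub = extract_subnetwork(net, "C", 2)
        assert sub.node_set == {"C"}
        assert sub.edge_set == frozenset()

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_matches_matrix_power_oracle(self, rng, k):
        for _ in range(10):
            net = random_network(rng, 15, density=0.2)
            center = net.gene_ids[int(rng.integers(15))]
            sub = extract_subnetwork(net, center, k)
            nodes, edges = ball_and_edges_oracle(net, center, k)
            assert sub.node_set == nodes
            assert set(sub.edge_set) == edges

    def test_missing_gene_raises(self):
        with pytest.raises(KeyError):
            extract_subnetwork(path_graph(), "Z", 1)


class TestDcgnS:
    def test_identical_networks_score_zero(self):
        net = path_graph()
        assert dcgn_s(net, net, "B", 1) == 0.0

    def test_disjoint_edge_sets_score_one(self):
        a = net_from_edges({("A", "B"): 0.5}, list("ABC"))
        b = net_from_edges({("A", "C"): 0.5}, list("ABC"))
        assert dcgn_s(a, b, "A", 1) == 1.0

    def test_hand_computed_partial_overlap(self):
        # around B at k=1: edge sets {AB, BC, BD} vs {AB, BE}; Jaccard 1/4
        a = net_from_edges(
            {("A", "B"): 0.5, ("B", "C"): 0.5, ("B", "D"): 0.5}, list("ABCDE")
        )
        b = net_from_edges({("A", "B"): 0.5, ("B", "E"): 0.5}, list("ABCDE"))
        assert dcgn_s(a, b, "B", 1) == pytest.approx(0.75)

    def test_isolated_in_both_scores_zero(self):
        a = net_from_edges({("A", "B"): 0.5}, list("ABC"))
        b = net_from_edges({("A", "B"): 0.7}, list("ABC"))
        assert dcgn_s(a, b, "C", 1) == 0.0

    def test_symmetric_and_bounded(self, rng):
        for _ in range(10):
            a = random_network(rng, 10, 0.3)
            b = random_network(rng, 10, 0.3)
            for g in a.gene_ids:
                d_ab = dcgn_s(a, b, g, 2)
                assert 0.0 <= d_ab <= 1.0
                assert d_ab == dcgn_s(b, a, g, 2)

    def test_missing_gene_raises(self):
        a = net_from_edges({("A", "B"): 0.5}, list("AB"))
        b = net_from_edges({("A", "B"): 0.5}, list("ABC"))
        with pytest.raises(KeyError):
            dcgn_s(a, b, "C", 1)


class TestMaxLeastStepProb:
    def test_direct_neighbor_is_transition_probability(self):
        net = net_from_edges({("A", "B"): 0.2, ("A", "C"): 0.3}, list("ABC"))
        sub = extract_subnetwork(net, "A", 1)
        assert max_least_step_prob(sub, "B") == pytest.approx(0.4)
        assert max_least_step_prob(sub, "C") == pytest.approx(0.6)

    def test_two_competing_two_step_walks(self):
        # walks i-u-j (0.2 * 0.5) and i-v-j (0.3 * 0.3): maximum is 0.10
        net = net_from_edges(
            {
                ("i", "u"): 0.2,
                ("i", "v"): 0.3,
                ("i", "x"): 0.5,  # pads i's row so M[i,u]=0.2, M[i,v]=0.3
                ("u", "j"): 0.2,
                ("v", "j"): 0.9 / 7,
            },
            genes=["i", "u", "v", "x", "j"],
        )
        sub = extract_subnetwork(net, "i", 2)
        assert max_least_step_prob(sub, "j") == pytest.approx(0.10)

    def test_matches_exhaustive_walk_enumeration(self, rng):
        hits = 0
        for _ in range(20):
            net = random_network(rng, 10, density=0.25)
            for center in net.gene_ids:
                sub = extract_subnetwork(net, center, 2)
                for target in sorted(sub.node_set - {center}):
                    expected = enumerate_min_hop_walk_prob(
                        net, sub.node_set, center, target
                    )
                    assert max_least_step_prob(sub, target) == pytest.approx(expected)
                    hits += 1
        assert hits > 50

    def test_center_as_target_rejected(self):
        sub = extract_subnetwork(path_graph(), "A", 1)
        with pytest.raises(ValueError):
            max_least_step_prob(sub, "A")


class TestStarTransform:
    def test_single_partner_carries_no_information(self):
        net = net_from_edges({("A", "B"): 0.5}, list("AB"))
        star = star_transform(extract_subnetwork(net, "A", 1))
        assert star.partner_probs == {"B": 1.0}
        assert star.partner_info == {"B": 0.0}

    def test_uniform_two_partner_star(self):
        net = net_from_edges({("A", "B"): 0.3, ("A", "C"): 0.3}, list("ABC"))
        star = star_transform(extract_subnetwork(net, "A", 1))
        assert star.norm_probs["B"] == pytest.approx(0.5)
        assert star.partner_probs["B"] == pytest.approx(0.5)
        for j in "BC":
            assert star.partner_info[j] == pytest.approx(math.log(2) / 2)

    def test_inversion_of_skewed_probabilities(self):
        # raw transition probs {0.8, 0.2} invert to {0.2, 0.8}
        net = net_from_edges({("A", "B"): 0.8, ("A", "C"): 0.2}, list("ABC"))
        star = star_transform(extract_subnetwork(net, "A", 1))
        assert star.norm_probs["B"] == pytest.approx(0.8)
        assert star.partner_probs["B"] == pytest.approx(0.2)
        assert star.partner_probs["C"] == pytest.approx(0.8)
        assert star.partner_info["B"] == pytest.approx(-math.log(0.2) * 0.2)
        assert star.partner_info["C"] == pytest.approx(-math.log(0.8) * 0.8)

    def test_isolated_center_yields_empty_star(self):
        net = net_from_edges({("A", "B"): 0.5}, list("ABC"))
        star = star_transform(extract_subnetwork(net, "C", 1))
        assert star.partner_probs == {} and star.partner_info == {}

    def test_probability_sums_and_order_reversal(self, rng):
        # both probability maps sum to 1; stronger raw prob => weaker q
        for _ in range(10):
            net = random_network(rng, 12, density=0.4)
            g = net.gene_ids[int(rng.integers(12))]
            star = star_transform(extract_subnetwork(net, g, 2))
            if len(star.partner_probs) < 2:
                continue
            assert sum(star.norm_probs.values()) == pytest.approx(1.0)
            assert sum(star.partner_probs.values()) == pytest.approx(1.0)
            assert all(0.0 <= i <= 1 / math.e + 1e-12
                       for i in star.partner_info.values())
            for u, v in itertools.combinations(star.norm_probs, 2):
                if star.norm_probs[u] > star.norm_probs[v]:
                    assert star.partner_probs[u] < star.partner_probs[v]


class TestDcgnI:
    def test_identical_node_sets_score_zero(self):
        # same neighbourhood membership, different weights: information
        # variation is about membership change only
        a = net_from_edges({("A", "B"): 0.5, ("A", "C"): 0.2}, list("ABC"))
        b = net_from_edges({("A", "B"): 0.9, ("A", "C"): 0.7}, list("ABC"))
        assert dcgn_i(a, b, "A", 1) == 0.0

    def test_hub_collapse_of_uniform_star_gives_log_degree(self):
        for d in (2, 5, 9):
            genes = ["hub"] + [f"n{i}" for i in range(d)]
            a = net_from_edges({("hub", f"n{i}"): 0.4 for i in range(d)}, genes)
            b = net_from_edges({}, genes)
            assert dcgn_i(a, b, "hub", 1) == pytest.approx(math.log(d))
            assert dcgn_i(b, a, "hub", 1) == pytest.approx(math.log(d))

    def test_matches_brute_force_symmetric_difference(self, rng):
        # independent route: enumerate walks, redo the star arithmetic inline
        for _ in range(5):
            a = random_network(rng, 20, 0.15, label="a")
            b = random_network(rng, 20, 0.15, label="b")
            for g in a.gene_ids:
                expected = 0.0
                sub_nodes = {}
                for net in (a, b):
                    nodes, _ = ball_and_edges_oracle(net, g, 1)
                    sub_nodes[net.phase_label] = nodes
                for net, own, other in ((a, "a", "b"), (b, "b", "a")):
                    nodes = sub_nodes[own]
                    partners = sorted(nodes - {g})
                    if not partners:
                        continue
                    raw = np.array([
                        enumerate_min_hop_walk_prob(net, nodes, g, j)
                        for j in partners
                    ])
                    p = raw / raw.sum()
                    q = (1 / p) / (1 / p).sum()
                    info = dict(zip(partners, -np.log(q) * q))
                    for j in nodes - sub_nodes[other] - {g}:
                        expected += info[j]
                assert dcgn_i(a, b, g, 1) == pytest.approx(expected)

    def test_symmetric_and_nonnegative(self, rng):
        a = random_network(rng, 12, 0.3)
        b = random_network(rng, 12, 0.3)
        for g in a.gene_ids:
            v = dcgn_i(a, b, g, 2)
            assert v >= 0.0
            assert v == pytest.approx(dcgn_i(b, a, g, 2))

    def test_information_grows_with_collapsed_degree(self):
        # uniform-star hub collapse: I = ln D is non-decreasing in D
        values = []
        for d in range(2, 12):
            genes = ["hub"] + [f"n{i}" for i in range(d)]
            a = net_from_edges({("hub", f"n{i}"): 0.4 for i in range(d)}, genes)
            b = net_from_edges({}, genes)
            values.append(dcgn_i(a, b, "hub", 1))
        assert all(x <= y for x, y in zip(values, values[1:]))


class TestScoreAll:
    def test_pair_count_and_elementwise_agreement(self, rng):
        nets = [random_network(rng, 8, 0.3, label=f"p{i}") for i in range(3)]
        tables = score_all(nets, "S", 1)
        assert len(tables) == 3
        pairs = {t.phase_pair for t in tables}
        assert pairs == {("p0", "p1"), ("p0", "p2"), ("p1", "p2")}
        for t in tables:
            ia = [n.phase_label for n in nets].index(t.phase_pair[0])
            ib = [n.phase_label for n in nets].index(t.phase_pair[1])
            for g, v in zip(t.gene_ids, t.values):
                assert v == pytest.approx(dcgn_s(nets[ia], nets[ib], g, 1))

    def test_duplicate_network_scores_all_zero(self, rng):
        net = random_network(rng, 8, 0.3, label="x")
        for metric in ("S", "I"):
            tables = score_all([net, net], metric, 1)
            assert len(tables) == 1
            assert np.all(tables[0].values == 0.0)

    def test_mismatched_universe_rejected(self, rng):
        a = random_network(rng, 8, 0.3)
        b = random_network(rng, 9, 0.3)
        with pytest.raises(ValueError, match="universe"):
            score_all([a, b], "S", 1)
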