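"""Signed nodal strength and asymmetric signed modularity."""

import networkx as nx
import numpy as np
import pytest

from signet import (
    ConnectivityMatrix,
    brute_force_max_modularity,
    detect_communities_signed,
    modularity_given_partition,
    nodal_strength_signed,
    planted_partition_matrix,
)
from tests.conftest import random_signed_matrix


def cm_from(weights):
    weights = np.asarray(weights, dtype=float)
    return ConnectivityMatrix(weights, tuple(f"N{i}" for i in range(len(weights))))


def direct_q_star(cm, labels):
    """Independent direct-summation oracle for the signed modularity formula."""
    w = cm.weights
    w_pos, w_neg = np.maximum(w, 0), np.maximum(-w, 0)
    out = {}
    for sign, wp in (("pos", w_pos), ("neg", w_neg)):
        s = wp.sum(axis=1)
        v = s.sum()
        q = 0.0
        if v > 0:
            for i in range(len(w)):
                for j in range(len(w)):
                    if labels[i] == labels[j]:
                        q += (wp[i, j] - s[i] * s[j] / v) / v
        out[sign] = (q, v)
    q_pos, v_pos = out["pos"]
    q_neg, v_neg = out["neg"]
    total = v_pos + v_neg
    return q_pos - (v_neg / total) * q_neg if total else 0.0


class TestNodalStrength:
    def test_empty_graph_all_zero(self):
        ns = nodal_strength_signed(cm_from(np.zeros((4, 4))))
        assert (ns.s_pos == 0).all() and (ns.s_neg == 0).all()

    def test_worked_four_node_example(self):
        w = np.zeros((4, 4))
        pairs = {(0, 1): 0.5, (0, 2): -0.2, (1, 2): 0.3, (1, 3): -0.1, (2, 3): 0.4}
        for (i, j), v in pairs.items():
            w[i, j] = w[j, i] = v
        ns = nodal_strength_signed(cm_from(w))
        np.testing.assert_allclose(ns.s_pos, [0.5, 0.8, 0.7, 0.4])
        np.testing.assert_allclose(ns.s_neg, [0.2, 0.1, 0.2, 0.1])
        np.testing.assert_allclose(ns.s_total, [0.7, 0.9, 0.9, 0.5])

    def test_matches_brute_force_edge_summation(self, rng):
        for _ in range(20):
            cm = random_signed_matrix(8, rng)
            ns = nodal_strength_signed(cm)
            for i in range(8):
                s_pos = sum(max(cm.weights[i, j], 0) for j in range(8))
                s_neg = sum(max(-cm.weights[i, j], 0) for j in range(8))
                assert ns.s_pos[i] == pytest.approx(s_pos, abs=1e-12)
                assert ns.s_neg[i] == pytest.approx(s_neg, abs=1e-12)

    def test_positive_only_total_equals_positive(self, rng):
        w = np.abs(rng.uniform(0, 1, (5, 5)))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        ns = nodal_strength_signed(cm_from(w))
        assert (ns.s_neg == 0).all()
        np.testing.assert_array_equal(ns.s_total, ns.s_pos)

    def test_difference_mode(self, rng):
        cm = random_signed_matrix(6, rng)
        ns = nodal_strength_signed(cm, total_mode="difference")
        np.testing.assert_allclose(ns.s_total, cm.weights.sum(axis=1), atol=1e-12)

    def test_strength_mass_conservation(self, rng):
        cm = random_signed_matrix(7, rng)
        ns = nodal_strength_signed(cm)
        pos_mass = np.maximum(cm.weights, 0).sum() / 2
        neg_mass = np.maximum(-cm.weights, 0).sum() / 2
        assert ns.s_pos.sum() == pytest.approx(2 * pos_mass, abs=1e-10)
        assert ns.s_neg.sum() == pytest.approx(2 * neg_mass, abs=1e-10)


class TestModularityGivenPartition:
    def test_single_module_partition_is_zero(self, rng):
        cm = random_signed_matrix(6, rng)
        res = modularity_given_partition(cm, {lab: 1 for lab in cm.roi_labels})
        assert res.q_star == pytest.approx(0.0, abs=1e-12)
        assert res.q_pos == pytest.approx(0.0, abs=1e-12)
        assert res.q_neg == pytest.approx(0.0, abs=1e-12)

    def test_positive_only_q_star_equals_q_pos(self, rng):
        w = np.abs(rng.uniform(0, 1, (6, 6)))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        cm = cm_from(w)
        part = {lab: 1 + i % 2 for i, lab in enumerate(cm.roi_labels)}
        res = modularity_given_partition(cm, part)
        assert res.v_neg == 0
        assert res.q_star == pytest.approx(res.q_pos, abs=1e-15)

    def test_two_cliques_with_bridge_matches_direct_summation(self):
        w = np.zeros((6, 6))
        for grp in ([0, 1, 2], [3, 4, 5]):
            for i in grp:
                for j in grp:
                    if i != j:
                        w[i, j] = 1.0
        w[2, 3] = w[3, 2] = 0.1
        cm = cm_from(w)
        labels = [1, 1, 1, 2, 2, 2]
        res = modularity_given_partition(cm, dict(zip(cm.roi_labels, labels)))
        assert res.q_star == pytest.approx(direct_q_star(cm, labels), abs=1e-12)
        assert res.q_pos == pytest.approx(res.q_star, abs=1e-15)  # no negatives

    def test_matches_direct_summation_on_random_signed(self, rng):
        for _ in range(10):
            cm = random_signed_matrix(7, rng)
            labels = rng.integers(1, 4, 7)
            res = modularity_given_partition(cm, dict(zip(cm.roi_labels, labels)))
            assert res.q_star == pytest.approx(direct_q_star(cm, labels), abs=1e-12)

    def test_invariant_to_module_relabeling_and_node_order(self, rng):
        cm = random_signed_matrix(8, rng)
        labels = rng.integers(1, 4, 8)
        res1 = modularity_given_partition(cm, dict(zip(cm.roi_labels, labels)))
        relabeled = {lab: 10 - m for lab, m in zip(cm.roi_labels, labels)}
        res2 = modularity_given_partition(cm, relabeled)
        assert res1.q_star == pytest.approx(res2.q_star, abs=1e-12)
        perm = rng.permutation(8)
        cm_perm = ConnectivityMatrix(
            cm.weights[np.ix_(perm, perm)], tuple(cm.roi_labels[i] for i in perm)
        )
        res3 = modularity_given_partition(
            cm_perm, dict(zip(cm.roi_labels, labels))
        )
        assert res1.q_star == pytest.approx(res3.q_star, abs=1e-12)

    def test_positive_graph_agrees_with_newman_modularity(self, rng):
        """Cross-check against networkx's classic weighted modularity."""
        w = np.abs(rng.uniform(0.1, 1, (8, 8)))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        cm = cm_from(w)
        labels = rng.integers(0, 3, 8)
        g = nx.from_numpy_array(w)
        communities = [
            {i for i in range(8) if labels[i] == m} for m in range(3)
        ]
        communities = [c for c in communities if c]
        expected = nx.community.modularity(g, communities, weight="weight")
        res = modularity_given_partition(cm, dict(zip(cm.roi_labels, labels + 1)))
        assert res.q_star == pytest.approx(expected, abs=1e-10)

    def test_missing_node_rejected(self, rng):
        cm = random_signed_matrix(4, rng)
        with pytest.raises(ValueError, match="missing"):
            modularity_given_partition(cm, {"N0": 1})


class TestBruteForce:
    def test_two_nodes_positive_edge_single_module(self):
        res = brute_force_max_modularity(cm_from([[0, 0.5], [0.5, 0]]))
        assert res.n_modules == 1
        assert res.q_star == pytest.approx(0.0, abs=1e-15)

    def test_two_nodes_negative_edge_split(self):
        # hand enumeration with the diagonal-inclusive null (the convention
        # that makes the single-module partition exactly zero):
        #   single module: Q* = 0
        #   two singletons: Q- = 2*(0 - 0.25)/1 = -0.5, Q* = -1*(-0.5) = +0.5
        # so the maximizer separates the negatively-linked nodes
        res = brute_force_max_modularity(cm_from([[0, -0.5], [-0.5, 0]]))
        assert res.n_modules == 2
        assert res.q_star == pytest.approx(0.5, abs=1e-15)

    def test_six_node_planted_partition_recovered(self):
        assignment = {f"R{i}": 1 if i < 3 else 2 for i in range(6)}
        cm = planted_partition_matrix(6, assignment, 0.8, -0.2)
        res = brute_force_max_modularity(cm)
        groups = {}
        for lab, m in res.partition.items():
            groups.setdefault(m, set()).add(lab)
        assert set(map(frozenset, groups.values())) == {
            frozenset({"R0", "R1", "R2"}),
            frozenset({"R3", "R4", "R5"}),
        }

    def test_refuses_large_graphs(self, rng):
        cm = random_signed_matrix(11, rng)
        with pytest.raises(ValueError, match="10"):
            brute_force_max_modularity(cm)


class TestDetectCommunities:
    def test_recovers_planted_two_clique_split(self):
        w = np.full((8, 8), -0.2)
        for grp in (range(4), range(4, 8)):
            for i in grp:
                for j in grp:
                    w[i, j] = 0.8
        np.fill_diagonal(w, 0)
        cm = cm_from(w)
        res = detect_communities_signed(cm, n_restarts=20, seed=0)
        oracle = brute_force_max_modularity(cm)
        assert res.q_star == pytest.approx(oracle.q_star, abs=1e-12)
        labels = [res.partition[f"N{i}"] for i in range(8)]
        assert len(set(labels[:4])) == 1 and len(set(labels[4:])) == 1
        assert labels[0] != labels[4]

    def test_deterministic_given_seed(self, rng):
        cm = random_signed_matrix(10, rng)
        r1 = detect_communities_signed(cm, n_restarts=10, seed=42)
        r2 = detect_communities_signed(cm, n_restarts=10, seed=42)
        assert r1.partition == r2.partition
        assert r1.q_star == r2.q_star

    def test_never_below_trivial_partition(self, rng):
        for _ in range(10):
            cm = random_signed_matrix(6, rng)
            res = detect_communities_signed(cm, n_restarts=5, seed=0)
            assert res.q_star >= 0.0

    def test_more_restarts_never_worse(self, rng):
        cm = random_signed_matrix(9, rng)
        q5 = detect_communities_signed(cm, n_restarts=5, seed=7).q_star
        q50 = detect_communities_signed(cm, n_restarts=50, seed=7).q_star
        assert q50 >= q5 - 1e-15
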