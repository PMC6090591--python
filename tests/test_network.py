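import itertools

import numpy as np
import pytest
from scipy.stats import chi2_contingency

from phasecycle.clustering import MCV
from phasecycle.network import (
    build_complete_network,
    compare_direction_proportions,
    conserved_network,
    edge_direction_classes,
    jaccard,
    null_distribution,
)


def _random_partition(genes, n_clusters, rng):
    labels = rng.integers(0, n_clusters, len(genes))
    labels[:n_clusters] = np.arange(n_clusters)
    out = {}
    for k in range(n_clusters):
        out[k] = {g for g, l in zip(genes, labels) if l == k}
    return {k: v for k, v in out.items() if v}


class TestJaccard:
    def test_identical_nonempty(self):
        assert jaccard({"a", "b"}, {"a", "b"}) == 1.0

    def test_disjoint(self):
        assert jaccard({"a"}, {"b"}) == 0.0

    def test_forced_arithmetic(self):
        assert jaccard({"a", "b", "c"}, {"b", "c", "d"}) == 0.5

    def test_both_empty(self):
        assert jaccard(set(), set()) == 0.0


class TestCompleteNetwork:
    def test_direct_enumeration(self):
        a = {"a1": {"g1", "g2"}, "a2": {"g3"}}
        b = {"b1": {"g1"}, "b2": {"g2", "g3"}}
        net = build_complete_network(a, b)
        edges = {(e.a, e.b): e.weight for e in net.edges}
        assert edges == {("a1", "b1"): 1, ("a1", "b2"): 1, ("a2", "b2"): 1}

    def test_identical_clusterings_form_perfect_matching(self):
        part = {k: {f"g{k}_{i}" for i in range(5)} for k in range(4)}
        net = build_complete_network(part, dict(part))
        assert len(net.edges) == 4
        assert all(e.weight == 5 and e.jaccard == 1.0 for e in net.edges)

    def test_edge_weights_conserve_universe(self):
        """Every gene sits on exactly one edge: weights sum to |universe|."""
        rng = np.random.default_rng(17)
        genes = [f"g{i}" for i in range(200)]
        for _ in range(100):
            pa = _random_partition(genes, int(rng.integers(2, 12)), rng)
            pb = _random_partition(genes, int(rng.integers(2, 12)), rng)
            net = build_complete_network(pa, pb)
            assert net.total_edge_weight() == 200
            assert all(e.a in pa and e.b in pb for e in net.edges)

    def test_disjoint_universes_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            build_complete_network({"a": {"g1"}}, {"b": {"g2"}})


class TestNullDistribution:
    def test_exhaustive_enumeration_toy_case(self):
        """Two clusters of 2 in a 4-gene universe: the null Jaccard support
        is computable by enumerating all cluster reassignments."""
        genes = ["g1", "g2", "g3", "g4"]
        support = []
        fixed = [{"g1", "g2"}, {"g3", "g4"}]
        for combo in itertools.combinations(genes, 2):
            b1 = set(combo)
            b2 = set(genes) - b1
            for a in fixed:
                for b in (b1, b2):
                    support.append(jaccard(a, b))
        support = np.array(support)
        expected_probs = {v: (support == v).mean() for v in np.unique(support)}

        null = null_distribution([2, 2], [2, 2], genes, n_replicates=10000, seed=3)
        for v, p in expected_probs.items():
            assert (np.isclose(null.scores, v).mean()
                    == pytest.approx(p, abs=0.02))

    def test_seed_reproducibility(self):
        genes = [f"g{i}" for i in range(30)]
        a = null_distribution([10, 10, 10], [15, 15], genes, 200, seed=5)
        b = null_distribution([10, 10, 10], [15, 15], genes, 200, seed=5)
        assert a.threshold == b.threshold
        np.testing.assert_array_equal(a.scores, b.scores)

    def test_threshold_in_unit_interval(self):
        genes = [f"g{i}" for i in range(20)]
        null = null_distribution([10, 10], [5, 15], genes, 100, seed=1)
        assert 0.0 <= null.threshold <= 1.0

    def test_inconsistent_sizes_rejected(self):
        with pytest.raises(ValueError, match="partition"):
            null_distribution([5, 5], [4, 4], [f"g{i}" for i in range(10)], 10, 0)


class TestConservedNetwork:
    def test_identical_clusterings_fully_conserved(self):
        part = {k: {f"g{k}_{i}" for i in range(25)} for k in range(20)}
        genes = [g for s in part.values() for g in s]
        net = build_complete_network(part, dict(part))
        null = null_distribution([25] * 20, [25] * 20, genes, 1000, seed=2)
        assert null.threshold < 1.0
        net = conserved_network(net, null)
        assert len(net.conserved_edges()) == 20

    def test_threshold_strictness(self):
        part_a = {"a1": {"g1", "g2"}, "a2": {"g3"}}
        part_b = {"b1": {"g1"}, "b2": {"g2", "g3"}}
        net = build_complete_network(part_a, part_b)
        null = null_distribution([2, 1], [1, 2], ["g1", "g2", "g3"], 50, seed=0)
        null.threshold = 1.0
        net = conserved_network(net, null)
        assert net.conserved_edges() == []  # no J exceeds 1 strictly

    def test_random_assignments_conserve_about_five_percent(self):
        rng = np.random.default_rng(8)
        genes = [f"g{i}" for i in range(500)]
        labels = np.repeat(np.arange(10), 50)
        la = rng.permutation(labels)
        lb = rng.permutation(labels)
        pa = {k: set(np.array(genes)[la == k]) for k in range(10)}
        pb = {k: set(np.array(genes)[lb == k]) for k in range(10)}
        net = build_complete_network(pa, pb)
        null = null_distribution([50] * 10, [50] * 10, genes, 1000, seed=9)
        net = conserved_network(net, null)
        frac = len(net.conserved_edges()) / 100.0  # of all cluster pairs
        assert frac <= 0.08  # 5% nominal, discrete ties make it conservative


class TestDirectionClasses:
    def _net_with_mcvs(self):
        pa = {"a+": {"g1", "g2"}, "a-": {"g3"}}
        pb = {"b+": {"g1"}, "b-": {"g2", "g3"}}
        net = build_complete_network(pa, pb)
        up = MCV((0.0, 12.0), 1.0, "+")
        dn = MCV((48.0, 96.0), 1.0, "-")
        return net, {"a+": up, "a-": dn}, {"b+": up, "b-": dn}

    def test_same_and_opposite(self):
        net, ma, mb = self._net_with_mcvs()
        net = edge_direction_classes(net, ma, mb)
        classes = {(e.a, e.b): e.direction_class for e in net.edges}
        assert classes[("a+", "b+")] == "same"
        assert classes[("a+", "b-")] == "opposite"
        assert classes[("a-", "b-")] == "same"

    def test_classes_partition_edges(self):
        rng = np.random.default_rng(4)
        genes = [f"g{i}" for i in range(100)]
        pa = _random_partition(genes, 5, rng)
        pb = _random_partition(genes, 6, rng)
        net = build_complete_network(pa, pb)
        dirs = ["+", "-"]
        ma = {k: MCV((0.0, 12.0), 1.0, dirs[rng.integers(0, 2)]) for k in pa}
        mb = {k: MCV((0.0, 12.0), 1.0, dirs[rng.integers(0, 2)]) for k in pb}
        net = edge_direction_classes(net, ma, mb)
        n_same = sum(e.direction_class == "same" for e in net.edges)
        n_opp = sum(e.direction_class == "opposite" for e in net.edges)
        assert n_same + n_opp == len(net.edges)

    def test_missing_mcv_rejected(self):
        net, ma, mb = self._net_with_mcvs()
        with pytest.raises(ValueError, match="MCV"):
            edge_direction_classes(net, {}, mb)


class TestDirectionProportions:
    def _fabricated_network(self, conserved_counts, rest_counts):
        """Network with prescribed (opposite, same) counts per stratum."""
        net = build_complete_network({"a": {"g"}}, {"b": {"g"}})
        net.edges = []
        up = MCV((0.0, 12.0), 1.0, "+")
        i = 0
        for conserved, (n_opp, n_same) in (
            (True, conserved_counts), (False, rest_counts)):
            for cls, n in (("opposite", n_opp), ("same", n_same)):
                for _ in range(n):
                    from phasecycle.network import Edge
                    e = Edge(f"a{i}", f"b{i}", {f"g{i}"}, 0.5, conserved, cls)
                    net.edges.append(e)
                    i += 1
        return net

    def test_identical_proportions_give_zero(self):
        net = self._fabricated_network((10, 10), (20, 20))
        out = compare_direction_proportions(net)
        assert out["chi2"] == pytest.approx(0.0)

    def test_hand_evaluated_table(self):
        net = self._fabricated_network((10, 30), (30, 10))
        out = compare_direction_proportions(net)
        assert out["chi2"] == pytest.approx(20.0)
        assert out["df"] == 1

    def test_matches_scipy_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            c = tuple(rng.integers(1, 50, 2))
            r = tuple(rng.integers(1, 50, 2))
            out = compare_direction_proportions(self._fabricated_network(c, r))
            ref = chi2_contingency(out["table"], correction=False)
            assert out["chi2"] == pytest.approx(ref.statistic, abs=1e-9)
            assert out["pvalue"] == pytest.approx(ref.pvalue, abs=1e-9)

    def test_empty_network_rejected(self):
        net = self._fabricated_network((0, 0), (0, 0))
        net.edges = []
        with pytest.raises(ValueError):
            compare_direction_proportions(net)
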