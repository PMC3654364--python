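import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hopemap import (
    AlignmentNode,
    AnnotationMap,
    Namespace,
    SimilarityTable,
    combined_score,
    empirical_pvalue,
    functional_coherence,
    interaction_conservation,
    node_confidence_blast,
    node_confidence_ortholog,
    normalize_over_clusters,
    sequence_similarity_score,
    significance_scores,
)
from hopemap.components import Cluster, connected_components
from hopemap.scoring import ScoringInputs, score_clusters

from conftest import make_graph


def node(nid, a, b):
    return AlignmentNode(node_id=nid, members={"sA": a, "sB": b}, group_id=f"G{nid}")


def cluster_of(node_ids, edge_count):
    return Cluster(
        cluster_id=0,
        node_ids=frozenset(node_ids),
        edge_count=edge_count,
        size=len(node_ids),
    )


class TestBlastConfidence:
    def make_sim(self, e_values):
        sim = SimilarityTable()
        for i, e in enumerate(e_values):
            sim.add(f"a{i}", f"b{i}", e, 100.0)
        return sim, [node(i, f"a{i}", f"b{i}") for i in range(len(e_values))]

    def test_better_than_average_is_one(self):
        sim, nodes = self.make_sim([1e-12, 1e-10, 2e-10])
        assert node_confidence_blast(nodes[0], nodes, sim) == 1.0

    def test_worse_than_average_is_ratio(self):
        # cluster mean e-value 1e-10; the node at 2e-10 gets mean/E = 0.5
        sim, nodes = self.make_sim([0.5e-10, 0.5e-10, 2e-10])
        conf = node_confidence_blast(nodes[2], nodes, sim)
        assert conf == pytest.approx(0.5)

    def test_all_equal_e_values_all_one(self):
        sim, nodes = self.make_sim([1e-8, 1e-8, 1e-8])
        assert all(node_confidence_blast(n, nodes, sim) == 1.0 for n in nodes)

    def test_missing_record_zero(self):
        sim, nodes = self.make_sim([1e-8])
        orphan = node(9, "zz", "yy")
        assert node_confidence_blast(orphan, nodes + [orphan], sim) == 0.0

    def test_confidence_in_unit_interval(self, rng):
        for _ in range(50):
            e_values = 10.0 ** rng.uniform(-50, 0, size=5)
            sim, nodes = self.make_sim(list(e_values))
            for n in nodes:
                assert 0.0 <= node_confidence_blast(n, nodes, sim) <= 1.0


class TestOrthologConfidence:
    def ko(self, mapping):
        ann = AnnotationMap(namespace=Namespace.KO)
        for protein, terms in mapping.items():
            for t in terms:
                ann.add(protein, t)
        return ann

    def test_shared_term_is_one(self):
        ann = self.ko({"a0": {"K1"}, "b0": {"K1", "K2"}})
        assert node_confidence_ortholog(node(0, "a0", "b0"), ann) == 1.0

    def test_disjoint_terms_zero(self):
        ann = self.ko({"a0": {"K1"}, "b0": {"K2"}})
        assert node_confidence_ortholog(node(0, "a0", "b0"), ann) == 0.0

    def test_unannotated_member_zero(self):
        ann = self.ko({"a0": {"K1"}})
        assert node_confidence_ortholog(node(0, "a0", "b0"), ann) == 0.0

    def test_wrong_namespace_rejected(self):
        ann = AnnotationMap(namespace=Namespace.GO_BP)
        with pytest.raises(ValueError, match="KO"):
            node_confidence_ortholog(node(0, "a0", "b0"), ann)


class TestSequenceSimilarity:
    def test_example_two_thirds(self):
        cluster = cluster_of({0, 1, 2}, 0)
        assert sequence_similarity_score(
            cluster, {0: 1.0, 1: 1.0, 2: 0.0}
        ) == pytest.approx(2 / 3)

    def test_all_ones(self):
        cluster = cluster_of({0, 1}, 0)
        assert sequence_similarity_score(cluster, {0: 1.0, 1: 1.0}) == 1.0

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    def test_equals_independent_mean(self, values):
        cluster = cluster_of(set(range(len(values))), 0)
        confidences = dict(enumerate(values))
        expected = float(np.mean(values))
        assert sequence_similarity_score(cluster, confidences) == pytest.approx(
            expected, abs=1e-12
        )

    def test_missing_confidence_rejected(self):
        with pytest.raises(ValueError, match="confidence"):
            sequence_similarity_score(cluster_of({0, 1}, 0), {0: 1.0})


class TestInteractionConservation:
    @pytest.mark.parametrize(
        "size,edges,expected",
        [(3, 3, 1.0), (3, 2, 2 / 3), (4, 3, 0.5), (2, 1, 1.0)],
    )
    def test_cliqueness_ratio(self, size, edges, expected):
        cluster = cluster_of(set(range(size)), edges)
        assert interaction_conservation(cluster) == pytest.approx(expected)

    def test_singleton_not_scorable(self):
        assert interaction_conservation(cluster_of({0}, 0)) is None


class TestNormalization:
    def test_rule_arithmetic(self):
        assert normalize_over_clusters([0.5, 1.0]) == pytest.approx([2 / 3, 1.0])

    def test_value_equal_to_mean_maps_to_one(self):
        assert normalize_over_clusters([0.4, 0.4]) == [1.0, 1.0]

    def test_single_value_is_its_own_mean(self):
        assert normalize_over_clusters([0.3]) == [1.0]

    def test_degenerate_zero_mean(self):
        assert normalize_over_clusters([0.0, 0.0]) == [0.0, 0.0]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            normalize_over_clusters([])

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=2, max_size=15))
    def test_monotone_below_mean_and_bounded(self, values):
        result = normalize_over_clusters(values)
        assert all(0.0 <= v <= 1.0 for v in result)
        mean = sum(values) / len(values)
        below = [(v, r) for v, r in zip(values, result) if v < mean]
        for (v1, r1) in below:
            for (v2, r2) in below:
                if v1 < v2:
                    assert r1 <= r2


class TestFunctionalCoherence:
    def go(self, mapping):
        ann = AnnotationMap(namespace=Namespace.GO_BP)
        for protein, terms in mapping.items():
            for t in terms:
                ann.add(protein, t)
        return ann

    def graph2(self):
        return make_graph(3, [])

    def networks(self):
        from hopemap import PPINetwork
        return [PPINetwork(species_id="spA"), PPINetwork(species_id="spB")]

    def test_identical_sets_give_one(self):
        ann = self.go({
            f"{sp}_x{i}": {"t1", "t2"} for sp in ("spA", "spB") for i in range(3)
        })
        f = functional_coherence([0, 1, 2], self.graph2(), ann, self.networks())
        assert f == 1.0

    def test_partial_overlap_iu(self):
        # one species annotated {t1,t2} and {t2,t3}: IU = 1/3
        ann = self.go({"spA_x0": {"t1", "t2"}, "spA_x1": {"t2", "t3"}})
        f = functional_coherence([0, 1], self.graph2(), ann, self.networks())
        assert f == pytest.approx(1 / 3)

    def test_all_unannotated_zero(self):
        ann = self.go({})
        assert functional_coherence([0, 1, 2], self.graph2(), ann, self.networks()) == 0.0

    def test_species_with_single_annotated_protein_skipped(self):
        ann = self.go({"spA_x0": {"t1"}, "spB_x0": {"u1"}, "spB_x1": {"u1"}})
        f = functional_coherence([0, 1], self.graph2(), ann, self.networks())
        assert f == 1.0  # only spB counts, and its sets agree

    def test_wrong_namespace_rejected(self):
        ann = AnnotationMap(namespace=Namespace.KO)
        with pytest.raises(ValueError, match="GO_BP"):
            functional_coherence([0], self.graph2(), ann, self.networks())


class TestCombinedScore:
    def test_perfect_components_give_one(self):
        assert combined_score(1.0, 1.0, 1.0) == pytest.approx(1.0)

    def test_default_weights_average(self):
        assert combined_score(0.6, 0.9, 0.3) == pytest.approx(0.6)

    def test_degenerate_weights(self):
        assert combined_score(0.42, 0.0, 0.0, weights=(1.0, 0.0, 0.0)) == 0.42

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            combined_score(0.5, 0.5, 0.5, weights=(0.5, 0.5, 0.5))

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            combined_score(0.5, 0.5, 0.5, weights=(-0.5, 1.0, 0.5))

    def test_component_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            combined_score(1.2, 0.0, 0.0)


class TestEmpiricalPvalue:
    def test_extreme_observation(self):
        null = list(np.linspace(0, 0.9, 999))
        assert empirical_pvalue(1.0, null) == pytest.approx(1 / 1000)

    def test_observation_below_all_nulls(self):
        null = [0.5] * 200
        assert empirical_pvalue(0.1, null) == 1.0

    def test_empty_null_rejected(self):
        with pytest.raises(ValueError):
            empirical_pvalue(0.5, [])

    def test_ties_count_toward_r(self):
        assert empirical_pvalue(0.5, [0.5, 0.4]) == pytest.approx(2 / 3)


class TestSignificance:
    def setup_graph(self, rng, n=30, p=0.1):
        edges = [
            (i, j) for i in range(n) for j in range(i + 1, n) if rng.random() < p
        ]
        graph = make_graph(n, edges)
        confidences = {i: float(rng.random()) for i in range(n)}
        return graph, ScoringInputs(confidences=confidences)

    def test_same_seed_identical_result(self, rng):
        graph, inputs = self.setup_graph(rng)
        cluster = cluster_of({0, 1, 2, 3}, 2)
        a = significance_scores(cluster, graph, inputs, N=150, seed=5)
        b = significance_scores(cluster, graph, inputs, N=150, seed=5)
        assert a == b

    def test_planted_clique_minimal_p(self):
        # clique on 4 nodes in an otherwise empty 40-node graph: no random
        # subset can match I=1, so p_I hits its floor 1/(N+1)
        edges = [(i, j) for i in range(4) for j in range(i + 1, 4)]
        graph = make_graph(40, edges)
        inputs = ScoringInputs(confidences={i: 1.0 for i in range(40)})
        cluster = cluster_of({0, 1, 2, 3}, 6)
        result = significance_scores(cluster, graph, inputs, N=300, seed=1)
        assert result.p_I == pytest.approx(1 / 301)

    def test_combined_eq5_is_weighted_sum_of_p(self, rng):
        graph, inputs = self.setup_graph(rng)
        cluster = cluster_of({0, 1, 2}, 1)
        res = significance_scores(cluster, graph, inputs, N=120, seed=2)
        expected = (res.p_S + res.p_I + res.p_F) / 3
        assert res.combined_eq5 == pytest.approx(expected, abs=1e-12)

    def test_too_few_samples_rejected(self, rng):
        graph, inputs = self.setup_graph(rng)
        with pytest.raises(ValueError, match="at least"):
            significance_scores(cluster_of({0, 1}, 0), graph, inputs, N=99)

    def test_cluster_larger_than_graph_rejected(self, rng):
        graph, inputs = self.setup_graph(rng, n=5)
        with pytest.raises(ValueError, match="exceeds"):
            significance_scores(
                cluster_of(set(range(10)), 0), graph, inputs, N=100
            )


class TestScoreClusters:
    def test_bounds_and_identity_on_random_clusters(self, rng):
        for _ in range(10):
            n = int(rng.integers(4, 25))
            edges = [
                (i, j)
                for i in range(n)
                for j in range(i + 1, n)
                if rng.random() < 0.2
            ]
            graph = make_graph(n, edges)
            clusters = connected_components(graph)
            confidences = {i: float(rng.random()) for i in range(n)}
            inputs = ScoringInputs(confidences=confidences)
            scores = score_clusters(clusters, graph, inputs)
            for sc in scores:
                for value in (sc.S, sc.I_norm, sc.F, sc.score):
                    assert 0.0 <= value <= 1.0
                w1, w2, w3 = sc.weights
                assert sc.score == pytest.approx(
                    w1 * sc.S + w2 * sc.I_norm + w3 * sc.F, abs=1e-12
                )

    def test_invariant_to_node_relabeling(self, rng):
        edges = [(0, 1), (1, 2), (2, 0), (3, 4)]
        graph = make_graph(5, edges)
        confidences = {i: [0.2, 0.4, 0.6, 0.8, 1.0][i] for i in range(5)}
        scores = score_clusters(
            connected_components(graph), graph, ScoringInputs(confidences=confidences)
        )
        # relabel nodes 0..4 -> 4..0
        relabel = {i: 4 - i for i in range(5)}
        graph2 = make_graph(5, [(relabel[u], relabel[v]) for u, v in edges])
        confidences2 = {relabel[i]: confidences[i] for i in range(5)}
        scores2 = score_clusters(
            connected_components(graph2), graph2, ScoringInputs(confidences=confidences2)
        )
        assert sorted(s.score for s in scores) == pytest.approx(
            sorted(s.score for s in scores2)
        )
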