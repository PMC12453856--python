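"""Class-separation and topology statistics, checked against hand-derived
values, closed forms, and independent brute-force oracles."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest

from graphsep import (
    GraphAnalysisError,
    assortativity,
    basic_metrics,
    build_report,
    config_from_dict,
    degree_distribution,
    detect_communities,
    homophily,
    homophily_permutation_test,
    modularity,
    neighbor_chi_square,
    neighbor_probability,
)

from conftest import labeled_graph, random_labeled_graph


def modularity_oracle(g, communities):
    """Hand-written Newman Q = sum_c (e_c/m - (d_c/2m)^2)."""
    m = g.number_of_edges()
    q = 0.0
    for members in communities:
        e_c = sum(1 for u, v in g.edges if u in members and v in members)
        d_c = sum(g.degree[v] for v in members)
        q += e_c / m - (d_c / (2 * m)) ** 2
    return q


class TestNeighborProbability:
    def test_three_node_hand_enumeration(self):
        # ordered endpoints of class 0: A->B, B->A, B->C; of class 1: C->B
        g = labeled_graph([("A", "B"), ("B", "C")], {"A": 0, "B": 0, "C": 1})
        P = neighbor_probability(g)
        assert P.labels == [0, 1]
        np.testing.assert_allclose(
            P.probabilities, [[2 / 3, 1 / 3], [1.0, 0.0]]
        )

    def test_disjoint_same_class_cliques_give_identity(self, two_triangles):
        P = neighbor_probability(two_triangles)
        np.testing.assert_allclose(P.probabilities, np.eye(2))

    def test_cross_class_bipartite_gives_antidiagonal(self, cross_bipartite):
        P = neighbor_probability(cross_bipartite)
        np.testing.assert_allclose(P.probabilities, [[0, 1], [1, 0]])

    def test_isolated_class_row_flagged_undefined(self):
        g = labeled_graph([(0, 1)], {0: "a", 1: "a", 2: "b"})
        with pytest.warns(UserWarning, match="undefined"):
            P = neighbor_probability(g)
        assert P.undefined.tolist() == [False, True]
        assert np.isnan(P.probabilities[1]).all()

    def test_rows_sum_to_one_on_random_graphs(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            g = random_labeled_graph(rng, n_classes=3)
            P = neighbor_probability(g)
            sums = P.probabilities[~P.undefined].sum(axis=1)
            np.testing.assert_allclose(sums, 1.0, atol=1e-12)

    def test_unlabeled_graph_is_an_error(self):
        with pytest.raises(GraphAnalysisError, match="label"):
            neighbor_probability(nx.path_graph(3))


class TestHomophily:
    def test_half_same_class_edges(self):
        g = labeled_graph([("A", "B"), ("B", "C")], {"A": 0, "B": 0, "C": 1})
        assert homophily(g) == 0.5

    def test_perfect_and_zero_separation(self, two_triangles, cross_bipartite):
        assert homophily(two_triangles) == 1.0
        assert homophily(cross_bipartite) == 0.0

    def test_empty_edge_set_is_an_error(self):
        g = labeled_graph([], {0: "a", 1: "b"})
        with pytest.raises(GraphAnalysisError, match="homophily undefined"):
            homophily(g)

    def test_equals_endpoint_weighted_trace_of_probability_matrix(self):
        # consistency identity between the two separation statistics
        rng = np.random.default_rng(12)
        for _ in range(30):
            g = random_labeled_graph(rng, n_classes=3)
            P = neighbor_probability(g)
            weights = P.counts.sum(axis=1) / P.counts.sum()
            trace = np.nansum(np.diag(P.probabilities) * weights)
            assert abs(homophily(g) - trace) <= 1e-12


class TestPermutationTest:
    def test_separated_triangles_match_exhaustive_enumeration(self, two_triangles):
        # Exhaustive null: of the C(6,3)=20 balanced label assignments only
        # the original split and its mirror give homophily 1.0, so the
        # exceedance probability is 2/20 = 0.1.
        exceed = 0
        assignments = list(itertools.combinations(range(6), 3))
        for chosen in assignments:
            h = labeled_graph(
                list(two_triangles.edges),
                {v: (0 if v in chosen else 1) for v in range(6)},
            )
            if homophily(h) >= 1.0:
                exceed += 1
        assert exceed / len(assignments) == pytest.approx(0.1)

        result = homophily_permutation_test(two_triangles, n_perm=1000, seed=42)
        assert result.z > 0
        assert result.p_empirical == pytest.approx(0.1, abs=0.03)

    def test_single_class_graph_has_flagged_undefined_z(self):
        g = labeled_graph([(0, 1), (1, 2)], {0: "a", 1: "a", 2: "a"})
        with pytest.warns(UserWarning, match="degenerate"):
            result = homophily_permutation_test(g, n_perm=50, seed=1)
        assert not result.z_defined
        assert 0 < result.p_empirical <= 1

    def test_deterministic_given_seed(self, two_triangles):
        a = homophily_permutation_test(two_triangles, n_perm=200, seed=7)
        b = homophily_permutation_test(two_triangles, n_perm=200, seed=7)
        assert (a.z, a.p_empirical) == (b.z, b.p_empirical)

    def test_z_approximately_standard_normal_under_random_labels(self):
        # calibration: random balanced labels on a fixed graph
        g = nx.gnp_random_graph(60, 0.15, seed=3)
        rng = np.random.default_rng(13)
        zs = []
        for t in range(500):
            labels = rng.permutation(np.repeat([0, 1], 30))
            for v in g.nodes:
                g.nodes[v]["label"] = int(labels[v])
            zs.append(
                homophily_permutation_test(g, n_perm=100, seed=t).z
            )
        zs = np.asarray(zs)
        assert abs(zs.mean()) < 0.2
        assert 0.8 <= zs.std() <= 1.25


class TestChiSquare:
    def test_perfect_association_closed_form(self):
        # ordered-endpoint table [[2,0],[0,2]]: N=4, phi^2=1, chi2 = 4
        g = labeled_graph([("a", "b"), ("c", "d")], {"a": 0, "b": 0, "c": 1, "d": 1})
        statistic, p = neighbor_chi_square(g)
        assert statistic == pytest.approx(4.0)
        assert 0 < p < 1

    def test_independence_gives_zero_statistic(self):
        # table [[2,2],[2,2]] factorizes over its margins exactly
        g = labeled_graph(
            [("a", "b"), ("c", "d"), ("a", "c"), ("b", "d")],
            {"a": 0, "b": 0, "c": 1, "d": 1},
        )
        statistic, _ = neighbor_chi_square(g)
        assert statistic == pytest.approx(0.0, abs=1e-12)

    def test_single_class_is_an_error(self):
        g = labeled_graph([(0, 1)], {0: "a", 1: "a"})
        with pytest.raises(GraphAnalysisError, match="two classes"):
            neighbor_chi_square(g)

    def test_edgeless_class_dropped_with_warning(self):
        g = labeled_graph([(0, 1), (1, 2), (0, 2), (3, 4), (3, 5), (4, 5)],
                          {0: "a", 1: "a", 2: "b", 3: "b", 4: "b", 5: "b"})
        g.add_node(6, label="c")
        with pytest.warns(UserWarning, match="dropping"):
            statistic, p = neighbor_chi_square(g)
        assert np.isfinite(statistic)


class TestCommunities:
    def test_bridge_removal_splits_into_two_triangles(self, bridged_triangles):
        partition = detect_communities(bridged_triangles, max_splits=10)
        assert sorted(map(len, partition.communities)) == [3, 3]
        assert partition.modularity == pytest.approx(
            modularity_oracle(bridged_triangles, partition.communities)
        )
        # split Q = 5/14 beats the single-community Q = 0
        assert partition.modularity == pytest.approx(5 / 14)

    def test_disconnected_cliques_stay_components(self, two_triangles):
        partition = detect_communities(two_triangles, max_splits=10)
        assert partition.n_communities == 2
        assert partition.modularity == pytest.approx(0.5)

    def test_star_graph_keeps_single_community(self):
        partition = detect_communities(nx.star_graph(5), max_splits=10)
        assert partition.n_communities == 1
        assert partition.modularity == pytest.approx(0.0)

    def test_agrees_with_exhaustive_dendrogram_search_on_small_graphs(self):
        rng = np.random.default_rng(21)
        for _ in range(10):
            g = random_labeled_graph(rng, n=int(rng.integers(5, 13)))
            partition = detect_communities(g, max_splits=50)
            # independent oracle: walk every Girvan-Newman level and take
            # the best hand-computed modularity
            levels = [list(nx.connected_components(g))]
            levels += [
                [set(c) for c in part]
                for part in nx.community.girvan_newman(g)
            ]
            best = max(modularity_oracle(g, level) for level in levels)
            assert partition.modularity == pytest.approx(best, abs=1e-9)

    def test_community_ids_ordered_by_decreasing_size(self):
        g = nx.Graph([(0, 1), (1, 2), (0, 2), (3, 4)])
        partition = detect_communities(g, max_splits=5)
        sizes = partition.sizes()
        assert sizes == sorted(sizes, reverse=True)
        assert set(partition.node_to_community) == set(g.nodes)

    def test_composition_counts_classes_per_community(self, two_triangles):
        partition = detect_communities(two_triangles, max_splits=5)
        assert sorted(
            tuple(sorted(c.items())) for c in partition.composition
        ) == [((0, 3),), ((1, 3),)]

    def test_empty_graph_is_an_error(self):
        with pytest.raises(GraphAnalysisError):
            detect_communities(nx.Graph())


class TestModularity:
    def test_two_triangle_partition_closed_form(self, two_triangles):
        q = modularity(two_triangles, [{0, 1, 2}, {3, 4, 5}])
        assert q == pytest.approx(0.5)
        assert q == pytest.approx(modularity_oracle(two_triangles, [{0, 1, 2}, {3, 4, 5}]))

    def test_single_community_is_zero(self, bridged_triangles):
        assert modularity(bridged_triangles, [set(bridged_triangles)]) == pytest.approx(0.0)

    def test_triangle_singletons_closed_form(self):
        g = nx.cycle_graph(3)
        assert modularity(g, [{0}, {1}, {2}]) == pytest.approx(-1 / 3)

    def test_empty_edge_set_is_an_error(self):
        with pytest.raises(GraphAnalysisError):
            modularity(nx.empty_graph(3), [{0, 1, 2}])


class TestBasicMetrics:
    def test_complete_graph(self):
        density, clustering, ncomp, largest = basic_metrics(nx.complete_graph(4))
        assert (density, clustering, ncomp, largest) == (1.0, 1.0, 1, 100.0)

    def test_path_graph(self):
        density, clustering, _, _ = basic_metrics(nx.path_graph(3))
        assert density == pytest.approx(2 / 3)
        assert clustering == 0.0

    def test_isolated_node_counts_in_components(self):
        g = nx.Graph([(0, 1)])
        g.add_node(10)
        _, _, ncomp, largest = basic_metrics(g)
        assert ncomp == 2 and largest == 66.7


class TestAssortativity:
    def test_perfectly_separated_cliques(self, two_triangles):
        attribute_r, _ = assortativity(two_triangles)
        assert attribute_r == pytest.approx(1.0)

    def test_cross_class_bipartite(self, cross_bipartite):
        attribute_r, _ = assortativity(cross_bipartite)
        assert attribute_r == pytest.approx(-1.0)

    def test_random_balanced_labels_near_zero(self):
        rng = np.random.default_rng(31)
        g = nx.gnp_random_graph(500, 0.02, seed=8)
        labels = rng.permutation(np.repeat([0, 1], 250))
        for v in g.nodes:
            g.nodes[v]["label"] = int(labels[v])
        attribute_r, _ = assortativity(g)
        assert abs(attribute_r) < 0.1

    def test_single_class_flagged_undefined(self):
        g = labeled_graph([(0, 1)], {0: "a", 1: "a"})
        with pytest.warns(UserWarning):
            attribute_r, _ = assortativity(g)
        assert math.isnan(attribute_r)


class TestDegreeDistribution:
    @pytest.mark.parametrize(
        "graph,expected",
        [
            (nx.path_graph(3), {1: 2, 2: 1}),
            (nx.complete_graph(4), {3: 4}),
        ],
    )
    def test_exact_histograms(self, graph, expected):
        assert degree_distribution(graph) == expected

    def test_isolated_nodes_counted_at_degree_zero(self):
        g = nx.Graph([(0, 1)])
        g.add_node(10)
        hist = degree_distribution(g)
        assert hist == {0: 1, 1: 2}
        assert sum(hist.values()) == g.number_of_nodes()


class TestBuildReport:
    def test_separated_cliques_report(self, two_triangles):
        report = build_report(two_triangles, max_splits=5)
        assert report.homophily_score == 1.0
        assert report.attribute_assortativity == pytest.approx(1.0)
        assert report.community_count == 2
        assert report.modularity_score == pytest.approx(0.5)
        assert report.largest_component_pct == 50.0
        assert 0 <= report.permutation_p <= 1

    def test_empty_edge_graph_error_lists_undefined_metrics(self):
        g = nx.empty_graph(4)
        with pytest.raises(GraphAnalysisError, match="homophily"):
            build_report(g)

    def test_unlabeled_graph_yields_topology_only(self, bridged_triangles):
        report = build_report(bridged_triangles, max_splits=5)
        assert report.homophily_score is None
        assert report.chi2_p_value is None
        assert report.density > 0 and report.community_count == 2

    def test_report_files_written_under_config(self, tmp_path, two_triangles):
        config = config_from_dict(
            {
                "input_dataframe": "x.csv",
                "output_directory": str(tmp_path),
                "network_metrics_filename": "metrics.txt",
                "n_permutations": 50,
            }
        )
        report = build_report(two_triangles, config, max_splits=5)
        metrics = (tmp_path / "metrics.txt").read_text()
        assert "Homophily score\t1" in metrics
        assert "Largest component size (%)\t50.0" in metrics
        prob_text = (tmp_path / "neigh_prob.txt").read_text()
        assert "1.0000" in prob_text
        assert report.n_permutations == 50
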