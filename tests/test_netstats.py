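import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from transkingdom.netstats import (NetworkStatsError, detect_communities,
                                   global_metrics, keystone_taxa,
                                   network_report, node_metrics,
                                   prune_network, robustness,
                                   signed_modularity)


def brute_force_betweenness(G):
    """All-pairs shortest-path enumeration (unweighted) on tiny graphs."""
    nodes = list(G.nodes)
    n = len(nodes)
    score = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        try:
            paths = list(nx.all_shortest_paths(G, s, t))
        except nx.NetworkXNoPath:
            continue
        for v in nodes:
            if v in (s, t):
                continue
            frac = sum(v in p for p in paths) / len(paths)
            score[v] += frac
    norm = (n - 1) * (n - 2) / 2
    return {v: score[v] / norm for v in nodes}


class TestPruning:
    def test_isolates_removed(self):
        G = nx.path_graph(3)
        G.add_nodes_from([10, 11, 12])
        H = prune_network(G)
        assert set(H.nodes) == {0, 1, 2}

    def test_two_node_component_kept_for_metrics_only(self):
        G = nx.path_graph(3)
        G.add_edge("x", "y")
        metrics_graph = prune_network(G)
        viz_graph = prune_network(G, for_visualization=True)
        assert {"x", "y"} <= set(metrics_graph.nodes)
        assert "x" not in viz_graph.nodes

    def test_empty_graph_report(self):
        report = network_report(nx.Graph())
        assert report["empty"]


class TestGlobalMetrics:
    def test_triangle_closed_forms(self):
        gm = global_metrics(nx.complete_graph(3), [{0, 1, 2}])
        assert gm["transitivity"] == 1.0
        assert gm["density"] == 1.0
        assert gm["diameter"] == 1.0

    def test_path_graph(self):
        gm = global_metrics(nx.path_graph(3), [{0, 1, 2}])
        assert gm["transitivity"] == 0.0
        assert gm["diameter"] == 2.0

    def test_two_cliques_modularity_half(self):
        G = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(5))
        part = [set(range(5)), set(range(5, 10))]
        assert signed_modularity(G, part, 1.0) == pytest.approx(0.5)

    def test_disconnected_flagged(self):
        G = nx.disjoint_union(nx.path_graph(3), nx.path_graph(2))
        gm = global_metrics(G, None)
        assert gm["lcc_flagged"]


class TestNodeMetrics:
    def test_star_closed_forms(self):
        S = nx.star_graph(20)
        nm = node_metrics(S)
        assert nm.loc[0, "degree"] == 20
        # normalised betweenness of the hub is 1 (all pairs via hub)
        assert nm.loc[0, "betweenness"] == pytest.approx(1.0)
        assert nm.loc[0, "closeness"] == nm["closeness"].max()

    def test_cycle_symmetry(self):
        nm = node_metrics(nx.cycle_graph(8))
        for col in nm.columns:
            assert nm[col].std() == pytest.approx(0.0, abs=1e-9)

    def test_betweenness_matches_brute_force(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            G = nx.gnp_random_graph(10, 0.35, seed=int(rng.integers(1e6)))
            if G.number_of_edges() == 0:
                continue
            nm = node_metrics(G, weighted_paths=False)
            expected = brute_force_betweenness(G)
            for v in G.nodes:
                assert nm.loc[v, "betweenness"] == pytest.approx(
                    expected[v], abs=1e-9)


class TestCommunities:
    def test_single_clique_one_community(self):
        part = detect_communities(nx.complete_graph(6), seed=0)
        assert len(part) == 1

    def test_negative_edge_never_merges_cliques(self):
        G = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(4))
        for u, v, d in G.edges(data=True):
            d["weight"] = 1.0
        G.add_edge(0, 4, weight=-1.0)
        part = detect_communities(G, resolution=0.5, seed=1)
        assert {frozenset(c) for c in part} == {
            frozenset({0, 1, 2, 3}), frozenset({4, 5, 6, 7})}

    def test_beats_trivial_partition(self):
        G = nx.connected_caveman_graph(3, 5)
        part = detect_communities(G, resolution=0.5, seed=0)
        q_found = signed_modularity(G, part, 0.5)
        q_trivial = signed_modularity(G, [set(G.nodes)], 0.5)
        assert q_found >= q_trivial - 1e-12


class TestKeystones:
    def test_star_hub_unique_keystone(self):
        nm = node_metrics(nx.star_graph(20))
        ks = keystone_taxa(nm)
        assert list(ks.index) == [0]

    def test_cycle_degenerates_to_tie_rule(self):
        nm = node_metrics(nx.cycle_graph(10))
        ks = keystone_taxa(nm)
        assert ks["tied_at_cutoff"].all()

    def test_set_size_without_ties(self):
        # distinct scores: exactly ceil(0.05 n) selected
        G = nx.barbell_graph(10, 3)
        nm = node_metrics(G)
        ks = keystone_taxa(nm, top_fraction=0.1)
        assert len(ks) >= int(np.ceil(0.1 * len(nm)))

    def test_relabelling_invariance(self):
        G = nx.barbell_graph(6, 2)
        nm = node_metrics(G)
        ks1 = set(keystone_taxa(nm, 0.2).index)
        mapping = {v: f"n{v}" for v in G.nodes}
        H = nx.relabel_nodes(G, mapping)
        ks2 = set(keystone_taxa(node_metrics(H), 0.2).index)
        assert {mapping[v] for v in ks1} == ks2


class TestRobustness:
    def test_complete_graph_linear_curve(self):
        rc = robustness(nx.complete_graph(20), "targeted_betweenness")
        expected = (20 - np.arange(21)) / 20
        assert np.allclose(rc.lcc_fraction, expected)
        assert rc.auc == pytest.approx(0.5)

    def test_star_hub_removal_collapses(self):
        rc = robustness(nx.star_graph(20), "targeted_betweenness")
        assert rc.lcc_fraction[1] == pytest.approx(1 / 21)
        assert rc.r50 == pytest.approx(1 / 21)

    def test_random_mode_seeded_and_averaged(self):
        G = nx.erdos_renyi_graph(15, 0.3, seed=4)
        r1 = robustness(G, "random", n_random_reps=10, seed=7)
        r2 = robustness(G, "random", n_random_reps=10, seed=7)
        assert np.allclose(r1.lcc_fraction, r2.lcc_fraction)

    def test_targeted_auc_not_above_random(self):
        rng = np.random.default_rng(0)
        worse = 0
        for i in range(6):
            G = nx.erdos_renyi_graph(18, 0.2, seed=int(rng.integers(1e6)))
            if G.number_of_edges() < 5:
                continue
            t = robustness(G, "targeted_betweenness")
            r = robustness(G, "random", n_random_reps=20, seed=i)
            worse += t.auc > r.auc + 1e-9
        assert worse == 0

    def test_empty_graph_errors(self):
        with pytest.raises(NetworkStatsError):
            robustness(nx.Graph(), "random")


def test_network_report_metric_vocabulary_complete():
    """Every reported network carries the full metric set."""
    G = nx.les_miserables_graph()
    report = network_report(G, robustness_reps=5)
    for key in ("modularity", "transitivity", "density",
                "average_path_length", "diameter",
                "n_positive_edges", "n_negative_edges"):
        assert key in report["global"]
    for col in ("degree", "betweenness", "closeness", "eigen_centrality",
                "hub_score", "local_transitivity"):
        assert col in report["nodes"].columns
    assert len(report["keystones"]) >= 1
    assert 0 <= report["robustness"]["targeted"].auc <= 1


def test_visualization_export_prunes_and_annotates(tmp_path):
    from transkingdom.netstats import write_visualization
    G = nx.complete_graph(4)
    G.add_edge("x", "y")  # 2-node component: dropped from the viz file
    partition = [{0, 1, 2, 3}, {"x", "y"}]
    nm = node_metrics(G)
    ks = keystone_taxa(nm, 0.25)
    path = tmp_path / "viz.graphml"
    H = write_visualization(G, partition, ks, path)
    assert path.exists()
    assert "x" not in H.nodes
    assert all("community" in H.nodes[v] for v in H.nodes)
    assert any(H.nodes[v]["keystone"] for v in H.nodes) or len(ks) == 0
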