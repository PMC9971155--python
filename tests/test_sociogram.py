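"""Graph construction, weighted layout, and Potts-model community detection
checked against exhaustive partition search on small graphs."""
import networkx as nx
import numpy as np
import pytest

from dyadnet.association import build_matrix
from dyadnet.sociogram import (
    SocialGraph,
    build_graph,
    export_edgelist,
    export_graphml,
    import_edgelist,
    layout_fr,
    potts_hamiltonian,
    spinglass_communities,
)

from conftest import random_records


def weighted_graph(edges):
    G = nx.Graph()
    for u, v, w in edges:
        G.add_edge(u, v, weight=w)
    for v in G.nodes:
        G.nodes[v]["sex"] = "F"
    return G


def exhaustive_minimum(G, gamma=1.0):
    """Independent oracle: minimum Hamiltonian over every set partition."""
    nodes = sorted(G.nodes)
    n = len(nodes)
    best = np.inf

    def rec(i, labels, n_used):
        nonlocal best
        if i == n:
            h = potts_hamiltonian(G, dict(zip(nodes, labels)), gamma)
            best = min(best, h)
            return
        for c in range(n_used + 1):
            rec(i + 1, labels + [c], n_used + (1 if c == n_used else 0))

    rec(1, [0], 1)
    return best


class TestBuildGraph:
    def test_zero_matrix_gives_isolated_nodes(self, small_roster):
        records = random_records(np.random.default_rng(0), small_roster, 3, p=0.0)
        m = build_matrix(records, small_roster, "grooming")
        sg = build_graph(m, small_roster)
        assert sg.graph.number_of_edges() == 0
        assert sg.graph.number_of_nodes() == 4

    def test_saturated_matrix_complete_graph(self, small_roster):
        from dyadnet.association import AssociationMatrix

        ids = sorted(i.id for i in small_roster)
        vals = np.ones((4, 4))
        np.fill_diagonal(vals, np.nan)
        m = AssociationMatrix("party10m", ids, vals, np.full((4, 4), 10))
        sg = build_graph(m, small_roster)
        assert sg.graph.number_of_edges() == 6
        assert all(d["weight"] == 1.0 for _, _, d in sg.graph.edges(data=True))
    def test_positive_entries_become_edges(self, small_roster):
        records = random_records(np.random.default_rng(4), small_roster, 6)
        m = build_matrix(records, small_roster, "party10m")
        sg = build_graph(m, small_roster)
        n_pos = int(np.sum(np.nan_to_num(np.triu(m.values, 1)) > 0))
        assert sg.graph.number_of_edges() == n_pos
        for u, v, data in sg.graph.edges(data=True):
            assert data["weight"] == pytest.approx(m.value(u, v))
            assert 0 < data["weight"] <= 1

    def test_id_mismatch_rejected(self, small_roster):
        records = random_records(np.random.default_rng(4), small_roster, 4)
        m = build_matrix(records, small_roster, "party10m")
        with pytest.raises(ValueError, match="missing"):
            build_graph(m, small_roster[:2])


class TestLayout:
    def test_single_node_at_origin(self):
        G = nx.Graph()
        G.add_node("solo", sex="F")
        sg = SocialGraph(graph=G, measure="party10m")
        assert layout_fr(sg, seed=0) == {"solo": (0.0, 0.0)}

    def test_deterministic_given_seed(self):
        G = weighted_graph([("a", "b", 0.4), ("b", "c", 0.2), ("a", "c", 0.9)])
        sg = SocialGraph(graph=G, measure="party10m")
        assert layout_fr(sg, seed=11) == layout_fr(sg, seed=11)
        assert layout_fr(sg, seed=11) != layout_fr(sg, seed=12)

    def test_stronger_tie_sits_closer(self):
        def dist(w):
            G = weighted_graph([("a", "b", w), ("b", "c", 0.5)])
            sg = SocialGraph(graph=G, measure="party10m")
            pos = layout_fr(sg, seed=7)
            return np.hypot(pos["a"][0] - pos["b"][0], pos["a"][1] - pos["b"][1])

        assert dist(0.9) < dist(0.1)

    def test_coordinates_finite(self, small_roster):
        records = random_records(np.random.default_rng(1), small_roster, 5)
        sg = build_graph(build_matrix(records, small_roster, "party10m"), small_roster)
        pos = layout_fr(sg, seed=1)
        assert all(np.isfinite(x) and np.isfinite(y) for x, y in pos.values())


class TestSpinglass:
    def test_two_cliques_split(self):
        edges = [(f"a{i}", f"a{j}", 1.0) for i in range(4) for j in range(i + 1, 4)]
        edges += [(f"b{i}", f"b{j}", 1.0) for i in range(4) for j in range(i + 1, 4)]
        edges += [("a0", "b0", 0.01)]
        G = weighted_graph(edges)
        sg = SocialGraph(graph=G, measure="party10m")
        labels, h = spinglass_communities(sg, seed=2)
        assert len({labels[f"a{i}"] for i in range(4)}) == 1
        assert len({labels[f"b{i}"] for i in range(4)}) == 1
        assert labels["a0"] != labels["b0"]
        assert h == pytest.approx(exhaustive_minimum(G), abs=1e-9)

    def test_uniform_complete_graph_single_community(self):
        G = weighted_graph([(i, j, 1.0) for i in range(5) for j in range(i + 1, 5)])
        sg = SocialGraph(graph=G, measure="party10m")
        labels, h = spinglass_communities(sg, seed=0)
        assert len(set(labels.values())) == 1
        assert h == pytest.approx(exhaustive_minimum(G), abs=1e-9)

    def test_single_edge_one_community(self):
        G = weighted_graph([("a", "b", 0.3)])
        sg = SocialGraph(graph=G, measure="party10m")
        labels, _ = spinglass_communities(sg, seed=0)
        assert labels["a"] == labels["b"]

    def test_matches_exhaustive_on_random_graphs(self):
        rng = np.random.default_rng(10)
        hits = runs = 0
        for trial in range(8):
            n = int(rng.integers(5, 9))
            G = nx.gnp_random_graph(n, 0.5, seed=int(rng.integers(10**6)))
            if G.number_of_edges() == 0:
                continue
            for u, v in G.edges:
                G.edges[u, v]["weight"] = float(rng.uniform(0.05, 1.0))
            for v in G.nodes:
                G.nodes[v]["sex"] = "M"
            target = exhaustive_minimum(G)
            for seed in range(3):
                sg = SocialGraph(graph=G, measure="party10m")
                _, h = spinglass_communities(sg, seed=seed)
                runs += 1
                if abs(h - target) < 1e-9:
                    hits += 1
        assert hits / runs >= 0.95

    def test_partition_beats_trivial_partitions(self):
        rng = np.random.default_rng(5)
        G = nx.gnp_random_graph(9, 0.4, seed=33)
        for u, v in G.edges:
            G.edges[u, v]["weight"] = float(rng.uniform(0.1, 1.0))
        for v in G.nodes:
            G.nodes[v]["sex"] = "F"
        sg = SocialGraph(graph=G, measure="party10m")
        labels, h = spinglass_communities(sg, seed=1)
        one = {v: 0 for v in G.nodes}
        singletons = {v: i for i, v in enumerate(G.nodes)}
        assert h <= potts_hamiltonian(G, one) + 1e-12
        assert h <= potts_hamiltonian(G, singletons) + 1e-12

    def test_disconnected_graph_per_component(self):
        G = weighted_graph([("a", "b", 1.0), ("c", "d", 1.0)])
        G.add_node("e", sex="F")
        sg = SocialGraph(graph=G, measure="party10m")
        labels, _ = spinglass_communities(sg, seed=0)
        assert labels["a"] == labels["b"]
        assert labels["c"] == labels["d"]
        assert len({labels["a"], labels["c"], labels["e"]}) == 3

    def test_determinism(self):
        G = weighted_graph([("a", "b", 0.5), ("b", "c", 0.7), ("c", "d", 0.2), ("a", "d", 0.9)])
        sg1 = SocialGraph(graph=G, measure="party10m")
        sg2 = SocialGraph(graph=G, measure="party10m")
        assert spinglass_communities(sg1, seed=4) == spinglass_communities(sg2, seed=4)

    def test_cross_check_against_igraph_spinglass(self):
        """igraph's spinglass finds the same two-clique split."""
        import igraph as ig
        import random as pyrandom

        edges = [(i, j, 1.0) for i in range(4) for j in range(i + 1, 4)]
        edges += [(4 + i, 4 + j, 1.0) for i in range(4) for j in range(i + 1, 4)]
        edges += [(0, 4, 0.01)]
        g = ig.Graph([(u, v) for u, v, _ in edges])
        g.es["weight"] = [w for _, _, w in edges]
        ig.set_random_number_generator(pyrandom.Random(1))
        comm = g.community_spinglass(weights="weight", spins=25, gamma=1.0)
        ig.set_random_number_generator(None)
        assert len(set(comm.membership[:4])) == 1
        assert len(set(comm.membership[4:])) == 1
        assert comm.membership[0] != comm.membership[4]


class TestExport:
    def test_edgelist_roundtrip_exact_weights(self, tmp_path, small_roster):
        records = random_records(np.random.default_rng(6), small_roster, 6)
        sg = build_graph(build_matrix(records, small_roster, "party10m"), small_roster)
        export_edgelist(sg, tmp_path / "edges.csv")
        back = import_edgelist(tmp_path / "edges.csv")
        for u, v, data in sg.graph.edges(data=True):
            assert back.graph.edges[u, v]["weight"] == data["weight"]

    def test_graphml_carries_attributes(self, tmp_path, small_roster):
        records = random_records(np.random.default_rng(6), small_roster, 6)
        sg = build_graph(build_matrix(records, small_roster, "party10m"), small_roster)
        layout_fr(sg, seed=0)
        if sg.graph.number_of_edges():
            spinglass_communities(sg, seed=0)
        else:
            sg.communities = {v: i for i, v in enumerate(sg.graph.nodes)}
        export_graphml(sg, tmp_path / "g.graphml")
        back = nx.read_graphml(tmp_path / "g.graphml")
        node = list(back.nodes)[0]
        assert "sex" in back.nodes[node]
        assert "community" in back.nodes[node]
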