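"""k-clique subpathway mining against brute-force oracles."""

import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dmspn.mining import (
    MiningConfig,
    enumerate_maximal_cliques,
    graph_power,
    mine_collection,
    mine_subpathways,
    read_subpathway_table,
    write_subpathway_table,
)
from dmspn.pathway_model import EnzymeGraph, GeneAnnotationMap, PathwayDefinition, Reaction


def make_graph(nodes, edges, pid="path:test") -> EnzymeGraph:
    return EnzymeGraph(
        pid, frozenset(nodes), frozenset(tuple(sorted(e)) for e in edges)
    )


def path_graph(labels) -> EnzymeGraph:
    return make_graph(labels, list(zip(labels, labels[1:])))


def random_graph(rng, n, p=0.3) -> EnzymeGraph:
    labels = [f"n{i:02d}" for i in range(n)]
    edges = [(labels[i], labels[j]) for i in range(n) for j in range(i + 1, n)
             if rng.random() < p]
    return make_graph(labels, edges)


def brute_force_k_sets(g: EnzymeGraph, k: int) -> set[frozenset]:
    """Maximal sets with pairwise BFS distance <= k, by exhaustive subsets."""
    gr = nx.Graph()
    gr.add_nodes_from(g.nodes)
    gr.add_edges_from(g.edges)
    nodes = sorted(g.nodes)
    dist = dict(nx.all_pairs_shortest_path_length(gr))
    reach = {
        u: {v for v in nodes if v != u and dist[u].get(v, k + 1) <= k} | {u}
        for u in nodes
    }

    def valid(s):
        return all(s <= reach[u] for u in s)

    valid_sets = [
        frozenset(c)
        for r in range(1, len(nodes) + 1)
        for c in itertools.combinations(nodes, r)
        if valid(set(c))
    ]
    return {
        s for s in valid_sets
        if not any(s < t for t in valid_sets)
    }


class TestGraphPower:
    def test_k1_is_identity(self):
        g = path_graph(list("abcd"))
        assert graph_power(g, 1).edges == g.edges

    def test_path_k2_is_triangle(self):
        g = path_graph(list("abc"))
        assert graph_power(g, 2).edges == {("a", "b"), ("a", "c"), ("b", "c")}

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            graph_power(path_graph(list("ab")), 0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bfs_distances(self, seed):
        rng = np.random.default_rng(seed)
        g = random_graph(rng, 10)
        gr = nx.Graph()
        gr.add_nodes_from(g.nodes)
        gr.add_edges_from(g.edges)
        dist = dict(nx.all_pairs_shortest_path_length(gr))
        expected = frozenset(
            tuple(sorted((u, v)))
            for u in g.nodes for v in g.nodes
            if u < v and dist[u].get(v, 99) <= 3
        )
        assert graph_power(g, 3).edges == expected

    def test_disconnected_pairs_never_linked(self):
        g = make_graph(list("abcd"), [("a", "b"), ("c", "d")])
        assert graph_power(g, 10).edges == {("a", "b"), ("c", "d")}

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        edges=st.sets(
            st.tuples(st.integers(0, 7), st.integers(0, 7)).filter(lambda e: e[0] < e[1]),
            max_size=16,
        ),
        k=st.integers(1, 4),
    )
    def test_power_edges_grow_with_k_and_match_bfs(self, edges, k):
        labels = [f"n{i}" for i in range(8)]
        g = make_graph(labels, [(labels[i], labels[j]) for i, j in edges])
        gr = nx.Graph()
        gr.add_nodes_from(g.nodes)
        gr.add_edges_from(g.edges)
        dist = dict(nx.all_pairs_shortest_path_length(gr))
        pk = graph_power(g, k)
        assert pk.edges == frozenset(
            tuple(sorted((u, v)))
            for u in labels for v in labels
            if u < v and dist[u].get(v, 99) <= k
        )
        assert pk.edges <= graph_power(g, k + 1).edges


class TestMaximalCliques:
    def test_triangle(self):
        g = make_graph(list("abc"), [("a", "b"), ("b", "c"), ("a", "c")])
        assert enumerate_maximal_cliques(g) == [frozenset("abc")]

    def test_path(self):
        g = path_graph(list("abc"))
        assert enumerate_maximal_cliques(g) == [frozenset("ab"), frozenset("bc")]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_subset_brute_force(self, seed):
        rng = np.random.default_rng(100 + seed)
        g = random_graph(rng, 12, p=0.4)
        edges = set(g.edges)

        def is_clique(s):
            return all(tuple(sorted(p)) in edges
                       for p in itertools.combinations(s, 2))

        nodes = sorted(g.nodes)
        cliques = [frozenset(c) for r in range(1, 13)
                   for c in itertools.combinations(nodes, r) if is_clique(c)]
        maximal = {c for c in cliques if not any(c < d for d in cliques)}
        assert set(enumerate_maximal_cliques(g)) == maximal


class TestMineSubpathways:
    ann = GeneAnnotationMap()

    def test_seven_node_path_k3(self):
        g = path_graph(list("abcdefg"))
        mined = mine_subpathways(g, MiningConfig(k=3), self.ann)
        assert [sp.enzyme_set for sp in mined] == [
            frozenset("abcd"), frozenset("bcde"), frozenset("cdef"), frozenset("defg")
        ]
        assert [sp.subpathway_id for sp in mined] == [
            "path:test_1", "path:test_2", "path:test_3", "path:test_4"
        ]

    def test_complete_graph_single_subpathway(self):
        nodes = list("abcde")
        g = make_graph(nodes, list(itertools.combinations(nodes, 2)))
        for k in (1, 2, 5):
            mined = mine_subpathways(g, MiningConfig(k=k), self.ann)
            assert len(mined) == 1 and mined[0].enzyme_set == frozenset(nodes)

    def test_disconnected_triangles_stay_separate(self):
        g = make_graph(list("abcdef"),
                       [("a", "b"), ("b", "c"), ("a", "c"),
                        ("d", "e"), ("e", "f"), ("d", "f")])
        mined = mine_subpathways(g, MiningConfig(k=3), self.ann)
        assert {sp.enzyme_set for sp in mined} == {frozenset("abc"), frozenset("def")}

    def test_gene_sets_attached(self):
        g = path_graph(["E1", "E2"])
        ann = GeneAnnotationMap([("g1", "E1"), ("g2", "E2"), ("g3", "E2")])
        mined = mine_subpathways(g, MiningConfig(k=1), ann)
        assert mined[0].gene_set == {"g1", "g2", "g3"}

    @pytest.mark.parametrize("seed", range(8))
    def test_equals_brute_force_on_random_graphs(self, seed):
        rng = np.random.default_rng(200 + seed)
        g = random_graph(rng, int(rng.integers(4, 13)), p=0.3)
        for k in (1, 2, 3):
            mined = {sp.enzyme_set for sp in mine_subpathways(g, MiningConfig(k=k), self.ann)}
            assert mined == brute_force_k_sets(g, k), f"k={k}"

    @pytest.mark.parametrize("seed", range(4))
    def test_k_growth_merges_sets(self, seed):
        """Every k-subpathway is contained in some (k+1)-subpathway."""
        rng = np.random.default_rng(300 + seed)
        g = random_graph(rng, 11, p=0.25)
        for k in (1, 2, 3):
            small = [sp.enzyme_set for sp in mine_subpathways(g, MiningConfig(k=k), self.ann)]
            big = [sp.enzyme_set for sp in mine_subpathways(g, MiningConfig(k=k + 1), self.ann)]
            assert all(any(s <= b for b in big) for s in small)

    def test_pairwise_distance_bound_holds(self, default_study):
        """Mined subpathways respect the distance bound in the source graph."""
        from dmspn.pathway_model import build_enzyme_graph

        pw = default_study.pathways[0]
        g = build_enzyme_graph(pw)
        gr = nx.Graph()
        gr.add_nodes_from(g.nodes)
        gr.add_edges_from(g.edges)
        dist = dict(nx.all_pairs_shortest_path_length(gr))
        for sp in mine_subpathways(g, MiningConfig(k=3), GeneAnnotationMap()):
            assert all(dist[u].get(v, 99) <= 3
                       for u in sp.enzyme_set for v in sp.enzyme_set)


class TestMineCollection:
    def test_empty(self):
        assert mine_collection([], MiningConfig(), GeneAnnotationMap()) == []

    def test_duplicate_pathway_id_rejected(self):
        pw = PathwayDefinition("path:x", reactions=[Reaction("R", ("A",), ("B",), ("E1",))])
        with pytest.raises(ValueError, match="duplicate"):
            mine_collection([pw, pw], MiningConfig(), GeneAnnotationMap())

    def test_counts_sum_over_pathways(self, default_study):
        from dmspn.pathway_model import build_enzyme_graph

        total = 0
        for pw in default_study.pathways[:10]:
            g = build_enzyme_graph(pw)
            total += len(brute_force_k_sets(g, 3)) if len(g.nodes) <= 12 else len(
                mine_subpathways(g, MiningConfig(k=3), default_study.annotations)
            )
        mined = mine_collection(default_study.pathways[:10], MiningConfig(k=3),
                                default_study.annotations)
        assert len(mined) == total
        assert len({sp.subpathway_id for sp in mined}) == len(mined)

    def test_table_round_trip(self, tmp_path, default_study):
        path = tmp_path / "sub.tsv"
        write_subpathway_table(default_study.subpathways, path)
        back = read_subpathway_table(path)
        assert [(s.subpathway_id, s.enzyme_set, s.gene_set, s.class_label)
                for s in back] == \
               [(s.subpathway_id, s.enzyme_set, s.gene_set, s.class_label)
                for s in default_study.subpathways]
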