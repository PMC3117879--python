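"""Dyadicity/heterophilicity, disease diversity, and incidence clustering."""

import itertools
import math

import numpy as np
import pytest
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from dmspn.class_structure import (
    bd_bh,
    class_table,
    disease_diversity_table,
    hierarchical_cluster,
    one_mode_projection,
)
from dmspn.enrichment import EnrichmentResult
from dmspn.network import BipartiteNetwork, build_network


def res(d, s):
    return EnrichmentResult(d, s, 1, 5, 5, 50, 0.001, True)


def net_from_pairs(pairs, disease_classes=None, subpathway_classes=None):
    return build_network([res(d, s) for d, s in pairs],
                         disease_classes or {}, subpathway_classes or {})


class TestProjection:
    def test_star_projects_to_clique(self):
        net = net_from_pairs([("d1", "s1"), ("d2", "s1"), ("d3", "s1")])
        proj = one_mode_projection(net, "disease")
        assert proj.edges == {("d1", "d2"), ("d1", "d3"), ("d2", "d3")}

    def test_disjoint_stars_project_to_disjoint_cliques(self):
        net = net_from_pairs([("d1", "s1"), ("d2", "s1"), ("d3", "s2"), ("d4", "s2")])
        proj = one_mode_projection(net, "disease")
        assert proj.edges == {("d1", "d2"), ("d3", "d4")}

    def test_matches_neighbor_intersection_oracle(self):
        rng = np.random.default_rng(3)
        pairs = {(f"d{int(i)}", f"s{int(j)}")
                 for i, j in zip(rng.integers(0, 8, 40), rng.integers(0, 8, 40))}
        net = net_from_pairs(sorted(pairs))
        for side in ("disease", "subpathway"):
            proj = one_mode_projection(net, side)
            nbrs = {}
            for d, s, _ in net.edges:
                a, b = (d, s) if side == "disease" else (s, d)
                nbrs.setdefault(a, set()).add(b)
            expected = {
                tuple(sorted((a, b)))
                for a, b in itertools.combinations(sorted(nbrs), 2)
                if nbrs[a] & nbrs[b]
            }
            assert proj.edges == expected

    def test_min_shared_threshold(self):
        net = net_from_pairs([("d1", "s1"), ("d2", "s1"), ("d1", "s2"), ("d2", "s2"),
                              ("d3", "s2")])
        proj2 = one_mode_projection(net, "disease", min_shared=2)
        assert proj2.edges == {("d1", "d2")}


class TestBdBh:
    def test_complete_projection_gives_unity(self):
        # complete bipartite -> complete projection -> p_bar = 1 -> BD = BH = 1
        pairs = [(f"d{i}", f"s{j}") for i in range(4) for j in range(2)]
        net = net_from_pairs(pairs, {f"d{i}": "A" if i < 2 else "B" for i in range(4)})
        proj = one_mode_projection(net, "disease")
        stats = bd_bh(proj, "A")
        assert stats.BD == pytest.approx(1.0)
        assert stats.BH == pytest.approx(1.0)

    def test_planted_fixture_hand_count(self):
        # diseases d0..d3 class A share s1; d4..d7 class B share s2; d0-d4 share s3
        pairs = [(f"d{i}", "s1") for i in range(4)] + \
                [(f"d{i}", "s2") for i in range(4, 8)] + \
                [("d0", "s3"), ("d4", "s3")]
        classes = {f"d{i}": ("A" if i < 4 else "B") for i in range(8)}
        net = net_from_pairs(pairs, classes)
        proj = one_mode_projection(net, "disease")
        # projection: clique(d0..d3) + clique(d4..d7) + edge d0-d4 -> M = 13, N = 8
        assert proj.n_edges == 13
        p_bar = 2 * 13 / (8 * 7)
        stats = bd_bh(proj, "A")
        assert stats.m11 == 6 and stats.m10 == 1
        assert stats.BD == pytest.approx(6 / (p_bar * 6))
        assert stats.BH == pytest.approx(1 / (p_bar * 4 * 4))

    def test_permutation_agrees_with_analytic(self):
        rng = np.random.default_rng(8)
        pairs = {(f"d{int(i)}", f"s{int(j)}")
                 for i, j in zip(rng.integers(0, 10, 60), rng.integers(0, 10, 60))}
        classes = {f"d{i}": ("A" if i % 2 else "B") for i in range(10)}
        net = net_from_pairs(sorted(pairs), classes)
        proj = one_mode_projection(net, "disease")
        a = bd_bh(proj, "A", mode="analytic")
        p = bd_bh(proj, "A", mode="permutation", n_perm=2000, seed=4)
        # permutation expectations hover around the analytic ones
        assert p.e11 == pytest.approx(a.e11, rel=0.2)
        assert p.e10 == pytest.approx(a.e10, rel=0.2)

    def test_class_covering_all_nodes_undefined(self):
        net = net_from_pairs([("d1", "s1"), ("d2", "s1")], {"d1": "A", "d2": "A"})
        proj = one_mode_projection(net, "disease")
        with pytest.raises(ValueError, match="undefined"):
            bd_bh(proj, "A")

    def test_edge_count_partition_identity(self, default_study):
        """Sum of m11 plus half the cross edges equals the projection size."""
        proj = one_mode_projection(default_study.network, "disease")
        records, _, _ = class_table(default_study.network, "disease")
        total = sum(r.m11 for r in records) + sum(r.m10 for r in records) / 2
        assert total == proj.n_edges


class TestClassTable:
    def test_single_class_reported_undefined(self):
        net = net_from_pairs([("d1", "s1"), ("d2", "s1")], {"d1": "A", "d2": "A"})
        records, mean_bd, mean_bh = class_table(net, "disease")
        assert len(records) == 1 and math.isnan(records[0].BD)
        assert math.isnan(mean_bd)

    def test_planted_assortative_classes_cluster(self, default_study):
        records, mean_bd, mean_bh = class_table(default_study.network, "disease")
        assert mean_bd > 1
        assert mean_bd > mean_bh

    def test_random_labels_calibrate_to_unity(self, default_study):
        """Shuffled class labels give mean BD near 1 over 200 relabelings."""
        rng = np.random.default_rng(17)
        net = default_study.network
        labels = list(net.disease_nodes.values())
        means = []
        for _ in range(200):
            rng.shuffle(labels)
            shuffled = BipartiteNetwork(
                disease_nodes=dict(zip(net.disease_nodes, labels)),
                subpathway_nodes=dict(net.subpathway_nodes),
                edges=list(net.edges),
            )
            _, mean_bd, _ = class_table(shuffled, "disease")
            means.append(mean_bd)
        means = np.array(means)
        se = means.std(ddof=1) / math.sqrt(len(means))
        assert abs(means.mean() - 1.0) <= 3 * se


class TestDiversity:
    def test_one_class_neighbors(self):
        net = net_from_pairs([("d1", "s1"), ("d2", "s1")],
                             {"d1": "A", "d2": "A"})
        rec = disease_diversity_table(net, 18)[0]
        assert rec.diversity == pytest.approx(1 / 18)

    def test_all_classes_hit(self):
        pairs = [(f"d{i}", "s1") for i in range(18)]
        net = net_from_pairs(pairs, {f"d{i}": f"c{i}" for i in range(18)})
        assert disease_diversity_table(net, 18)[0].diversity == 1.0

    def test_matches_direct_count(self, default_study):
        net = default_study.network
        n_classes = len({c for c in net.disease_nodes.values()})
        for rec in disease_diversity_table(net, n_classes):
            classes = {net.disease_nodes[d] for d, s, _ in net.edges
                       if s == rec.subpathway_id}
            assert rec.n_classes_hit == len(classes)
            assert rec.n_classes_hit <= rec.degree

    def test_adding_edge_never_decreases_diversity(self):
        pairs = [("d1", "s1"), ("d2", "s1")]
        classes = {"d1": "A", "d2": "A", "d3": "B"}
        before = disease_diversity_table(net_from_pairs(pairs, classes), 5)[0]
        after = disease_diversity_table(
            net_from_pairs(pairs + [("d3", "s1")], classes), 5)[0]
        assert after.diversity >= before.diversity

    def test_degree_diversity_positive_correlation(self, default_study):
        """Planted study mirrors the degree-diversity trend."""
        from scipy import stats as sps

        net = default_study.network
        recs = disease_diversity_table(net, 18)
        rho = sps.spearmanr([r.degree for r in recs], [r.diversity for r in recs])
        assert rho.statistic > 0 and rho.pvalue < 0.01


class TestHierarchicalCluster:
    def test_identical_rows_merge_first(self):
        pairs = [("d1", "s1"), ("d1", "s2"), ("d2", "s1"), ("d2", "s2"),
                 ("d3", "s3")]
        result = hierarchical_cluster(net_from_pairs(pairs))
        Z = result.row_linkage
        assert Z[0, 2] == 0.0  # first merge at distance zero
        merged = {int(Z[0, 0]), int(Z[0, 1])}
        assert {result.row_ids[i] for i in merged} == {"d1", "d2"}

    def test_three_row_linkage_matches_scipy_reference(self):
        pairs = [("d1", "s1"), ("d2", "s1"), ("d2", "s2"), ("d3", "s2"),
                 ("d3", "s3")]
        result = hierarchical_cluster(net_from_pairs(pairs))
        X = result.matrix
        expected = hierarchy.linkage(pdist(X, "cityblock"), "complete")
        assert np.allclose(result.row_linkage, expected)

    def test_leaf_orders_are_permutations(self, default_study):
        result = hierarchical_cluster(default_study.network)
        assert sorted(result.row_order) == sorted(default_study.network.disease_nodes)
        assert sorted(result.col_order) == sorted(default_study.network.subpathway_nodes)

    def test_newick_parses_with_all_leaves(self, default_study):
        import dendropy

        result = hierarchical_cluster(default_study.network)
        tree = dendropy.Tree.get(data=result.row_newick, schema="newick")
        leaves = {t.label for t in tree.taxon_namespace}
        assert leaves == set(default_study.network.disease_nodes)
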