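"""k-clique subpathway mining.

A *subpathway* is a maximal set of enzymes whose pairwise shortest-path
distance in the pathway's enzyme graph is at most ``k`` (the distance-k
clique of classical social-network analysis: distances are measured in
the whole graph, not inside the induced subgraph, so this is a k-clique
rather than a k-club).  Mining reduces to maximal-clique enumeration on
the k-th graph power.  Each subpathway carries the union of genes
annotated to its enzymes, which is what enrichment later tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .pathway_model import EnzymeGraph, GeneAnnotationMap, PathwayDefinition, build_enzyme_graph


@dataclass(frozen=True)
class MiningConfig:
    """Distance parameter k (>= 1) and a minimum subpathway node count."""

    k: int = 3
    min_enzymes: int = 1

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        if self.min_enzymes < 1:
            raise ValueError(f"min_enzymes must be >= 1, got {self.min_enzymes}")


@dataclass
class Subpathway:
    """A mined subpathway: its enzymes plus the genes annotated to them."""

    subpathway_id: str
    pathway_id: str
    enzyme_set: frozenset[str]
    gene_set: frozenset[str] = field(default_factory=frozenset)
    class_label: str = ""


def _to_nx(g: EnzymeGraph) -> nx.Graph:
    gr = nx.Graph()
    gr.add_nodes_from(g.nodes)
    gr.add_edges_from(g.edges)
    return gr


def graph_power(g: EnzymeGraph, k: int) -> EnzymeGraph:
    """Return the graph with an edge (u, v) iff 1 <= dist_g(u, v) <= k.

    Node set is preserved; pairs in different components never gain an
    edge (an infinite distance does not satisfy <= k).
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    gr = _to_nx(g)
    edges: set[tuple[str, str]] = set()
    for u in gr:
        for v, d in nx.single_source_shortest_path_length(gr, u, cutoff=k).items():
            if d >= 1 and u < v:
                edges.add((u, v))
    return EnzymeGraph(pathway_id=g.pathway_id, nodes=g.nodes, edges=frozenset(edges))


def enumerate_maximal_cliques(g: EnzymeGraph) -> list[frozenset[str]]:
    """All maximal cliques, sorted by size descending then lexicographically."""
    cliques = [frozenset(c) for c in nx.find_cliques(_to_nx(g))]
    return sorted(cliques, key=lambda c: (-len(c), tuple(sorted(c))))


def mine_subpathways(
    g: EnzymeGraph, cfg: MiningConfig, ann: GeneAnnotationMap
) -> list[Subpathway]:
    """Mine the distance-<=k maximal enzyme sets of one pathway graph.

    Subpathway IDs are ``<pathway_id>_<i>`` with ``i`` assigned in the
    canonical clique order (size descending, then lexicographic), so IDs
    are reproducible for identical inputs.
    """
    cliques = enumerate_maximal_cliques(graph_power(g, cfg.k))
    out: list[Subpathway] = []
    idx = 0
    for clique in cliques:
        if len(clique) < cfg.min_enzymes:
            continue
        idx += 1
        out.append(
            Subpathway(
                subpathway_id=f"{g.pathway_id}_{idx}",
                pathway_id=g.pathway_id,
                enzyme_set=clique,
                gene_set=ann.genes_of_enzymes(clique),
            )
        )
    return out


def mine_collection(
    pathways: list[PathwayDefinition],
    cfg: MiningConfig,
    ann: GeneAnnotationMap,
    currency_blacklist: frozenset[str] = frozenset(),
) -> list[Subpathway]:
    """Mine every pathway in a collection; IDs are globally unique."""
    seen: set[str] = set()
    out: list[Subpathway] = []
    for pw in pathways:
        if pw.pathway_id in seen:
            raise ValueError(f"duplicate pathway_id {pw.pathway_id!r}")
        seen.add(pw.pathway_id)
        g = build_enzyme_graph(pw, currency_blacklist)
        for sp in mine_subpathways(g, cfg, ann):
            sp.class_label = pw.class_label
            out.append(sp)
    return out


def write_subpathway_table(subpathways: list[Subpathway], path) -> None:
    """TSV: subpathway_id, pathway_id, class_label, ';'-joined enzymes and genes."""
    with open(path, "w") as fh:
        fh.write("subpathway_id\tpathway_id\tclass_label\tenzymes\tgenes\n")
        for sp in subpathways:
            fh.write(
                f"{sp.subpathway_id}\t{sp.pathway_id}\t{sp.class_label}\t"
                f"{';'.join(sorted(sp.enzyme_set))}\t{';'.join(sorted(sp.gene_set))}\n"
            )


def read_subpathway_table(path) -> list[Subpathway]:
    out: list[Subpathway] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("subpathway_id"):
            raise ValueError(f"unexpected subpathway table header: {header!r}")
        for line in fh:
            sid, pid, cls, enz, genes = line.rstrip("\n").split("\t")
            out.append(
                Subpathway(
                    subpathway_id=sid,
                    pathway_id=pid,
                    enzyme_set=frozenset(enz.split(";")) if enz else frozenset(),
                    gene_set=frozenset(genes.split(";")) if genes else frozenset(),
                    class_label=cls,
                )
            )
    return out
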