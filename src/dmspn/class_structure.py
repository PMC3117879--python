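"""Class-clustering statistics on the bipartite network.

Diseases carry a disease-class label and subpathways a metabolism-class
label.  To ask whether same-class nodes cluster, each side of the
bipartite network is projected onto a one-mode graph (two nodes adjacent
when they share at least one neighbour on the other side) and the
dyadicity / heterophilicity of every class is computed there:

    BD = m11 / E[m11]      BH = m10 / E[m10]

where m11 counts within-class edges and m10 class-to-outside edges.  The
expectation is taken under random placement of the class labels, either
analytically (every pair connected independently with the projection's
mean edge probability) or by permuting the labels.  BD > 1 means the
class wires internally more than chance; BD > BH indicates clustering.

The module also computes per-subpathway disease diversity (distinct
neighbour disease classes over all classes) and a two-way hierarchical
clustering of the binary incidence matrix with city-block distance and
complete linkage.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .network import BipartiteNetwork

log = logging.getLogger(__name__)


@dataclass
class ProjectionGraph:
    side: str  # "disease" or "subpathway"
    nodes: frozenset[str]
    edges: frozenset[tuple[str, str]]  # canonically ordered pairs
    node_class: dict[str, str] = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


@dataclass
class ClassStructureStats:
    class_label: str
    n1: int        # class size
    m11: int       # within-class edges
    m10: int       # class-to-outside edges
    e11: float     # expected m11 under random labelling
    e10: float     # expected m10
    BD: float      # m11 / e11  (NaN when undefined)
    BH: float      # m10 / e10


@dataclass
class DiversityRecord:
    subpathway_id: str
    degree: int
    n_classes_hit: int
    diversity: float


@dataclass
class ClusteringResult:
    row_order: list[str]          # disease IDs, dendrogram leaf order
    col_order: list[str]          # subpathway IDs, dendrogram leaf order
    row_linkage: np.ndarray | None
    col_linkage: np.ndarray | None
    row_newick: str
    col_newick: str
    matrix: np.ndarray            # binary incidence, original sorted-ID order
    row_ids: list[str]
    col_ids: list[str]


def one_mode_projection(
    net: BipartiteNetwork, side: str, min_shared: int = 1
) -> ProjectionGraph:
    """Project one side: nodes adjacent iff they share >= min_shared neighbours."""
    if side == "disease":
        own = net.disease_nodes
        nbrs: dict[str, set[str]] = {d: set() for d in own}
        for d, s, _ in net.edges:
            nbrs[d].add(s)
    elif side == "subpathway":
        own = net.subpathway_nodes
        nbrs = {s: set() for s in own}
        for d, s, _ in net.edges:
            nbrs[s].add(d)
    else:
        raise ValueError(f"side must be 'disease' or 'subpathway', got {side!r}")
    if not own:
        raise ValueError("network side is empty")
    edges = frozenset(
        (a, b)
        for a, b in itertools.combinations(sorted(own), 2)
        if len(nbrs[a] & nbrs[b]) >= min_shared
    )
    return ProjectionGraph(side=side, nodes=frozenset(own), edges=edges,
                           node_class=dict(own))


def _count_m11_m10(
    edges: frozenset[tuple[str, str]], members: frozenset[str]
) -> tuple[int, int]:
    m11 = m10 = 0
    for a, b in edges:
        ina, inb = a in members, b in members
        if ina and inb:
            m11 += 1
        elif ina or inb:
            m10 += 1
    return m11, m10


def bd_bh(
    proj: ProjectionGraph,
    class_label: str,
    mode: str = "analytic",
    n_perm: int = 1000,
    seed: int = 0,
) -> ClassStructureStats:
    """Dyadicity and heterophilicity of one class on a projection graph.

    Analytic mode uses the Erdos-Renyi-style expectation with the
    projection's mean edge probability p = 2M / (N(N-1)); permutation
    mode averages m11 and m10 over uniform relabelings that preserve the
    class size.  A zero expectation makes the statistic undefined and
    raises.
    """
    members = frozenset(n for n, c in proj.node_class.items() if c == class_label)
    n1, N, M = len(members), proj.n_nodes, proj.n_edges
    if n1 < 1:
        raise ValueError(f"class {class_label!r} has no members")
    m11, m10 = _count_m11_m10(proj.edges, members)

    if mode == "analytic":
        if N < 2:
            raise ValueError("projection has fewer than 2 nodes")
        p_bar = 2 * M / (N * (N - 1))
        e11 = p_bar * n1 * (n1 - 1) / 2
        e10 = p_bar * n1 * (N - n1)
    elif mode == "permutation":
        rng = np.random.default_rng(seed)
        node_list = sorted(proj.nodes)
        m11s = np.empty(n_perm)
        m10s = np.empty(n_perm)
        for i in range(n_perm):
            perm = rng.permutation(len(node_list))[:n1]
            fake = frozenset(node_list[j] for j in perm)
            m11s[i], m10s[i] = _count_m11_m10(proj.edges, fake)
        e11, e10 = float(m11s.mean()), float(m10s.mean())
    else:
        raise ValueError(f"mode must be 'analytic' or 'permutation', got {mode!r}")

    if e11 == 0 or e10 == 0:
        raise ValueError(
            f"class {class_label!r}: zero expectation (e11={e11}, e10={e10}); "
            "BD/BH undefined"
        )
    return ClassStructureStats(
        class_label=class_label, n1=n1, m11=m11, m10=m10,
        e11=e11, e10=e10, BD=m11 / e11, BH=m10 / e10,
    )


def class_table(
    net: BipartiteNetwork,
    side: str,
    mode: str = "analytic",
    min_shared: int = 1,
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[list[ClassStructureStats], float, float]:
    """(BD, BH) for every class on one side, plus unweighted class averages.

    Classes whose expectation is degenerate are reported with NaN
    statistics and excluded from the averages.
    """
    proj = one_mode_projection(net, side, min_shared=min_shared)
    classes = sorted({c for c in proj.node_class.values()})
    records: list[ClassStructureStats] = []
    for cls in classes:
        try:
            records.append(bd_bh(proj, cls, mode=mode, n_perm=n_perm, seed=seed))
        except ValueError as exc:
            log.warning("class %r excluded from BD/BH averages: %s", cls, exc)
            members = [n for n, c in proj.node_class.items() if c == cls]
            m11, m10 = _count_m11_m10(proj.edges, frozenset(members))
            records.append(
                ClassStructureStats(cls, len(members), m11, m10,
                                    math.nan, math.nan, math.nan, math.nan)
            )
    bds = [r.BD for r in records if not math.isnan(r.BD)]
    bhs = [r.BH for r in records if not math.isnan(r.BH)]
    mean_bd = float(np.mean(bds)) if bds else math.nan
    mean_bh = float(np.mean(bhs)) if bhs else math.nan
    return records, mean_bd, mean_bh


def disease_diversity_table(
    net: BipartiteNetwork, n_total_classes: int
) -> list[DiversityRecord]:
    """Per subpathway: distinct neighbour disease classes / total classes."""
    if n_total_classes < 1:
        raise ValueError("n_total_classes must be >= 1")
    nbr_classes: dict[str, set[str]] = {s: set() for s in net.subpathway_nodes}
    degree: dict[str, int] = {s: 0 for s in net.subpathway_nodes}
    for d, s, _ in net.edges:
        nbr_classes[s].add(net.disease_nodes[d])
        degree[s] += 1
    return [
        DiversityRecord(
            subpathway_id=s,
            degree=degree[s],
            n_classes_hit=len(nbr_classes[s]),
            diversity=len(nbr_classes[s]) / n_total_classes,
        )
        for s in sorted(net.subpathway_nodes)
    ]


def _linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Render a scipy linkage matrix as a Newick string with branch lengths."""
    tree = hierarchy.to_tree(Z)

    def render(node, parent_dist: float) -> str:
        length = parent_dist - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:g}"
        left = render(node.get_left(), node.dist)
        right = render(node.get_right(), node.dist)
        return f"({left},{right}):{length:g}"

    return render(tree, tree.dist) + ";"


def hierarchical_cluster(net: BipartiteNetwork) -> ClusteringResult:
    """Two-way complete-linkage clustering of the binary incidence matrix.

    Rows (diseases) and columns (subpathways) are first sorted by ID so
    linkage ties break deterministically; pairwise distances are
    city-block (L1) on the binary profiles.
    """
    row_ids = sorted(net.disease_nodes)
    col_ids = sorted(net.subpathway_nodes)
    if not row_ids or not col_ids:
        raise ValueError("network is empty")
    ridx = {d: i for i, d in enumerate(row_ids)}
    cidx = {s: j for j, s in enumerate(col_ids)}
    mat = np.zeros((len(row_ids), len(col_ids)), dtype=int)
    for d, s, _ in net.edges:
        mat[ridx[d], cidx[s]] = 1

    def cluster_axis(X: np.ndarray, labels: list[str]):
        if len(labels) < 2:
            return None, list(labels), f"{labels[0]}:0;" if labels else ";"
        Z = hierarchy.linkage(pdist(X, metric="cityblock"), method="complete")
        order = [labels[i] for i in hierarchy.leaves_list(Z)]
        return Z, order, _linkage_to_newick(Z, labels)

    row_Z, row_order, row_newick = cluster_axis(mat, row_ids)
    col_Z, col_order, col_newick = cluster_axis(mat.T, col_ids)
    return ClusteringResult(
        row_order=row_order, col_order=col_order,
        row_linkage=row_Z, col_linkage=col_Z,
        row_newick=row_newick, col_newick=col_newick,
        matrix=mat, row_ids=row_ids, col_ids=col_ids,
    )


# ---------------------------------------------------------------------------
# writers

def write_class_table(records: list[ClassStructureStats], path) -> None:
    with open(path, "w") as fh:
        fh.write("class_label\tn1\tm11\tm10\te11\te10\tBD\tBH\n")
        for r in records:
            fh.write(
                f"{r.class_label}\t{r.n1}\t{r.m11}\t{r.m10}\t"
                f"{r.e11:.6g}\t{r.e10:.6g}\t{r.BD:.6g}\t{r.BH:.6g}\n"
            )


def write_diversity_table(records: list[DiversityRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("subpathway_id\tdegree\tn_classes_hit\tdiversity\n")
        for r in records:
            fh.write(f"{r.subpathway_id}\t{r.degree}\t{r.n_classes_hit}\t{r.diversity:.6g}\n")


def write_clustered_matrix(result: ClusteringResult, path) -> None:
    """CDT-style tab table: rows and columns in dendrogram leaf order."""
    ridx = {d: i for i, d in enumerate(result.row_ids)}
    cidx = {s: j for j, s in enumerate(result.col_ids)}
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(result.col_order) + "\n")
        for d in result.row_order:
            row = result.matrix[ridx[d]]
            fh.write(d + "\t" + "\t".join(str(row[cidx[s]]) for s in result.col_order) + "\n")
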