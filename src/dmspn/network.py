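"""Assembly of the bipartite disease-subpathway network and its null ensemble.

The network links a disease to a subpathway when the disease's genes are
significantly enriched in that subpathway; edge weights carry the
enrichment P-value.  Significance of observed global features (density,
giant component, degree-distribution breadth) is assessed against an
ensemble of random networks obtained by replacing every disease's gene
set with a size-matched uniform draw from the background and rerunning
the whole enrichment pipeline.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .enrichment import DiseaseGeneSet, EnrichmentResult, enrich_all
from .mining import Subpathway


@dataclass
class BipartiteNetwork:
    """Strictly bipartite: disease nodes vs subpathway nodes, P-weighted edges.

    Only endpoints of retained edges are admitted as nodes, so every node
    has degree >= 1.
    """

    disease_nodes: dict[str, str] = field(default_factory=dict)     # id -> class
    subpathway_nodes: dict[str, str] = field(default_factory=dict)  # id -> class
    edges: list[tuple[str, str, float]] = field(default_factory=list)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for d, cls in self.disease_nodes.items():
            g.add_node(d, bipartite="disease", node_class=cls)
        for s, cls in self.subpathway_nodes.items():
            g.add_node(s, bipartite="subpathway", node_class=cls)
        for d, s, p in self.edges:
            g.add_edge(d, s, p_value=p)
        return g

    def neighbors_of_subpathway(self, sid: str) -> frozenset[str]:
        return frozenset(d for d, s, _ in self.edges if s == sid)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


@dataclass
class NetworkSummary:
    n_diseases: int
    n_subpathways: int
    n_edges: int
    mean_disease_degree: float
    mean_subpathway_degree: float
    density: float
    giant_component_size: int
    disease_degrees: dict[str, int] = field(default_factory=dict)
    subpathway_degrees: dict[str, int] = field(default_factory=dict)


@dataclass
class NullEnsemble:
    n_replicates: int
    seed: int
    summaries: list[NetworkSummary]
    densities: list[float]            # density over each replicate's retained nodes
    edge_counts: list[int]            # comparable across replicates (fixed candidate space)
    giant_components: list[int]
    disease_breadths: list[float]     # NaN where a replicate side is degenerate
    subpathway_breadths: list[float]


def build_network(
    results: list[EnrichmentResult],
    disease_classes: dict[str, str] | None = None,
    subpathway_classes: dict[str, str] | None = None,
) -> BipartiteNetwork:
    """Keep the significant enrichments as edges; nodes are their endpoints."""
    disease_classes = disease_classes or {}
    subpathway_classes = subpathway_classes or {}
    net = BipartiteNetwork()
    for r in results:
        if not r.significant:
            continue
        net.disease_nodes.setdefault(r.disease_id, disease_classes.get(r.disease_id, ""))
        net.subpathway_nodes.setdefault(
            r.subpathway_id, subpathway_classes.get(r.subpathway_id, "")
        )
        net.edges.append((r.disease_id, r.subpathway_id, r.p_value))
    return net


def summarize_network(net: BipartiteNetwork) -> NetworkSummary:
    d_deg = {d: 0 for d in net.disease_nodes}
    s_deg = {s: 0 for s in net.subpathway_nodes}
    for d, s, _ in net.edges:
        d_deg[d] += 1
        s_deg[s] += 1
    n_d, n_s, n_e = len(d_deg), len(s_deg), len(net.edges)
    giant = 0
    if n_d + n_s:
        giant = max(len(c) for c in nx.connected_components(net.to_networkx()))
    return NetworkSummary(
        n_diseases=n_d,
        n_subpathways=n_s,
        n_edges=n_e,
        mean_disease_degree=n_e / n_d if n_d else 0.0,
        mean_subpathway_degree=n_e / n_s if n_s else 0.0,
        density=n_e / (n_d * n_s) if n_d and n_s else 0.0,
        giant_component_size=giant,
        disease_degrees=d_deg,
        subpathway_degrees=s_deg,
    )


def degree_breadth_statistic(
    summary: NetworkSummary, side: str, measure: str = "cv"
) -> float:
    """Breadth of one side's degree distribution.

    ``cv`` (default) is the coefficient of variation sd/mean of the degree
    sequence; ``var`` returns the plain variance.  Both are population
    statistics (ddof=0).
    """
    degs = {"disease": summary.disease_degrees, "subpathway": summary.subpathway_degrees}[side]
    if len(degs) < 2:
        raise ValueError(f"{side} side has fewer than 2 nodes")
    arr = np.array(list(degs.values()), dtype=float)
    if measure == "cv":
        return float(arr.std() / arr.mean())
    if measure == "var":
        return float(arr.var())
    raise ValueError(f"unknown breadth measure {measure!r}")


def empirical_pvalue(observed: float, null_samples: list[float], side: str = "greater") -> float:
    """Add-one empirical P: (1 + #{as-or-more extreme}) / (1 + n)."""
    if not null_samples:
        raise ValueError("null_samples is empty")
    if side == "greater":
        extreme = sum(1 for s in null_samples if s >= observed)
    elif side == "less":
        extreme = sum(1 for s in null_samples if s <= observed)
    else:
        raise ValueError(f"side must be 'greater' or 'less', got {side!r}")
    return (1 + extreme) / (1 + len(null_samples))


def random_null_ensemble(
    diseases: list[DiseaseGeneSet],
    subpathways: list[Subpathway],
    background: frozenset[str],
    alpha: float,
    R: int,
    seed: int,
) -> NullEnsemble:
    """R random networks from size-preserving uniform resampling of disease genes.

    Each replicate redraws every disease's gene set uniformly without
    replacement from the background (same set size), reruns enrichment and
    network assembly, and records the summary statistics.  All randomness
    descends from ``seed``.
    """
    if R < 1:
        raise ValueError(f"R must be >= 1, got {R}")
    rng = np.random.default_rng(seed)
    bg_sorted = np.array(sorted(background))
    summaries: list[NetworkSummary] = []
    densities: list[float] = []
    edge_counts: list[int] = []
    giants: list[int] = []
    d_breadths: list[float] = []
    s_breadths: list[float] = []
    for _ in range(R):
        resampled = [
            DiseaseGeneSet(
                d.disease_id,
                d.disease_class,
                frozenset(rng.choice(bg_sorted, size=min(len(d.genes), len(bg_sorted)),
                                     replace=False)),
            )
            for d in diseases
        ]
        results = enrich_all(resampled, subpathways, background, alpha)
        summ = summarize_network(build_network(results))
        summaries.append(summ)
        densities.append(summ.density)
        edge_counts.append(summ.n_edges)
        giants.append(summ.giant_component_size)
        d_breadths.append(
            degree_breadth_statistic(summ, "disease") if summ.n_diseases >= 2 else math.nan
        )
        s_breadths.append(
            degree_breadth_statistic(summ, "subpathway") if summ.n_subpathways >= 2 else math.nan
        )
    return NullEnsemble(
        n_replicates=R,
        seed=seed,
        summaries=summaries,
        densities=densities,
        edge_counts=edge_counts,
        giant_components=giants,
        disease_breadths=d_breadths,
        subpathway_breadths=s_breadths,
    )


# ---------------------------------------------------------------------------
# writers / readers

def write_edge_table(net: BipartiteNetwork, path) -> None:
    with open(path, "w") as fh:
        fh.write("disease_id\tsubpathway_id\tp_value\n")
        for d, s, p in net.edges:
            fh.write(f"{d}\t{s}\t{p:.17g}\n")


def read_edge_table(
    path,
    disease_classes: dict[str, str] | None = None,
    subpathway_classes: dict[str, str] | None = None,
) -> BipartiteNetwork:
    disease_classes = disease_classes or {}
    subpathway_classes = subpathway_classes or {}
    net = BipartiteNetwork()
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("disease_id"):
            raise ValueError(f"unexpected edge table header: {header!r}")
        for line in fh:
            d, s, p = line.rstrip("\n").split("\t")
            net.disease_nodes.setdefault(d, disease_classes.get(d, ""))
            net.subpathway_nodes.setdefault(s, subpathway_classes.get(s, ""))
            net.edges.append((d, s, float(p)))
    return net


def write_graphml(net: BipartiteNetwork, path) -> None:
    nx.write_graphml(net.to_networkx(), path)


def write_sif(net: BipartiteNetwork, path) -> None:
    """Simple interaction format: disease <tab> enriched_in <tab> subpathway."""
    with open(path, "w") as fh:
        for d, s, _ in net.edges:
            fh.write(f"{d}\tenriched_in\t{s}\n")


def write_summary_json(summary: NetworkSummary, path) -> None:
    payload = {
        "n_diseases": summary.n_diseases,
        "n_subpathways": summary.n_subpathways,
        "n_edges": summary.n_edges,
        "mean_disease_degree": summary.mean_disease_degree,
        "mean_subpathway_degree": summary.mean_subpathway_degree,
        "density": summary.density,
        "giant_component_size": summary.giant_component_size,
        "disease_degrees": summary.disease_degrees,
        "subpathway_degrees": summary.subpathway_degrees,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
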