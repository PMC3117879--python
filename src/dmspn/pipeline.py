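"""End-to-end glue: run the whole analysis on a simulated or loaded study."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .class_structure import ClassStructureStats, DiversityRecord, class_table, \
    disease_diversity_table
from .enrichment import DiseaseGeneSet, EnrichmentResult, enrich_all, pathway_background
from .gene_correlates import CoexpressionSummary, GeneClassLabels, \
    SubpathwayGeneProfile, coexpression_summary, gene_ratio_profiles
from .mining import MiningConfig, Subpathway, mine_collection
from .network import BipartiteNetwork, NetworkSummary, build_network, summarize_network
from .pathway_model import GeneAnnotationMap, PathwayDefinition
from .synthetic import GroundTruth, SimulationDesign, simulate_diseases, \
    simulate_expression, simulate_gene_labels, simulate_pathways


@dataclass
class PipelineResult:
    pathways: list[PathwayDefinition]
    annotations: GeneAnnotationMap
    subpathways: list[Subpathway]
    background: frozenset[str]
    diseases: list[DiseaseGeneSet]
    enrichments: list[EnrichmentResult]
    network: BipartiteNetwork
    summary: NetworkSummary
    truth: GroundTruth | None = None
    labels: GeneClassLabels | None = None
    expression: pd.DataFrame | None = None
    coexpression_blocks: list[list[str]] = field(default_factory=list)


def run_enrichment_stage(
    pathways: list[PathwayDefinition],
    ann: GeneAnnotationMap,
    diseases: list[DiseaseGeneSet],
    k: int = 3,
    min_enzymes: int = 1,
    alpha: float = 0.01,
    currency_blacklist: frozenset[str] = frozenset(),
    background: frozenset[str] | None = None,
):
    """Mine subpathways, enrich every disease, assemble the network."""
    subpathways = mine_collection(
        pathways, MiningConfig(k=k, min_enzymes=min_enzymes), ann, currency_blacklist
    )
    bg = background if background is not None else pathway_background(subpathways)
    results = enrich_all(diseases, subpathways, bg, alpha)
    net = build_network(
        results,
        disease_classes={d.disease_id: d.disease_class for d in diseases},
        subpathway_classes={sp.subpathway_id: sp.class_label for sp in subpathways},
    )
    return subpathways, bg, results, net


def run_simulated_study(
    design: SimulationDesign, with_labels: bool = True, with_expression: bool = True
) -> PipelineResult:
    """Simulate every input from ``design`` and run the full pipeline."""
    pathways, ann = simulate_pathways(design)
    subpathways = mine_collection(pathways, MiningConfig(k=design.k), ann)
    background = pathway_background(subpathways)
    diseases, truth = simulate_diseases(design, subpathways)
    results = enrich_all(diseases, subpathways, background, design.alpha)
    net = build_network(
        results,
        disease_classes={d.disease_id: d.disease_class for d in diseases},
        subpathway_classes={sp.subpathway_id: sp.class_label for sp in subpathways},
    )
    summary = summarize_network(net)
    out = PipelineResult(
        pathways=pathways, annotations=ann, subpathways=subpathways,
        background=background, diseases=diseases, enrichments=results,
        network=net, summary=summary, truth=truth,
    )
    if with_labels:
        out.labels = simulate_gene_labels(design, subpathways, summary.subpathway_degrees)
        if with_expression:
            net_sids = sorted(net.subpathway_nodes)
            out.expression, out.coexpression_blocks = simulate_expression(
                design, out.labels, subpathways, block_subpathway_ids=net_sids
            )
    return out


def run_class_stats(
    net: BipartiteNetwork,
    n_disease_classes: int,
    mode: str = "analytic",
    min_shared: int = 1,
    seed: int = 0,
) -> dict:
    """BD/BH tables for both sides plus the disease-diversity table."""
    d_records, d_bd, d_bh = class_table(net, "disease", mode=mode,
                                        min_shared=min_shared, seed=seed)
    s_records, s_bd, s_bh = class_table(net, "subpathway", mode=mode,
                                        min_shared=min_shared, seed=seed)
    diversity = disease_diversity_table(net, n_disease_classes)
    return {
        "disease_classes": d_records,
        "disease_mean_bd": d_bd,
        "disease_mean_bh": d_bh,
        "subpathway_classes": s_records,
        "subpathway_mean_bd": s_bd,
        "subpathway_mean_bh": s_bh,
        "diversity": diversity,
    }
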