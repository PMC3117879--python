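"""Seeded generators for every pipeline input, with known ground truth.

The generators emulate the real inputs at desk scale: random connected
enzyme graphs realized as reaction lists (so KGML writing and parsing
round-trip), disease gene sets with enrichment signal planted on chosen
subpathways, gene-class labels whose prevalence trends with subpathway
degree, and a tissue expression matrix with planted coexpression blocks.
Every draw descends from ``design.seed``, so a design is a complete,
reproducible description of a simulated study.

Default condition: 50 pathways of 8-20 enzymes over a pool of 2000
genes, 120 diseases in 18 classes of which 60 carry a planted subpathway
signal (60% of their genes drawn from the target's gene set), and a
36-tissue expression panel.  The pathway graphs are dense enough that a
pathway usually yields a single distance-3 subpathway, which keeps the
subpathway-level regression points approximately independent.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from xml.etree import ElementTree
from xml.dom import minidom

import numpy as np
import pandas as pd

from .enrichment import DiseaseGeneSet
from .gene_correlates import GeneClassLabels
from .mining import Subpathway
from .pathway_model import GeneAnnotationMap, PathwayDefinition, Reaction

SUBPATHWAY_CLASSES = (
    "carbohydrate metabolism",
    "energy metabolism",
    "lipid metabolism",
    "nucleotide metabolism",
    "amino acid metabolism",
    "other amino acids metabolism",
    "glycan biosynthesis",
    "cofactor and vitamin metabolism",
    "secondary metabolite biosynthesis",
    "xenobiotics biodegradation",
    "terpenoid and polyketide metabolism",
)


@dataclass
class SimulationDesign:
    """All knobs of one simulated study; ``seed`` fixes every draw."""

    n_pathways: int = 50
    enzymes_per_pathway: tuple[int, int] = (8, 20)
    edge_density: float = 0.35          # extra-edge probability beyond the spanning chain
    genes_per_enzyme: tuple[int, int] = (1, 3)
    n_background_genes: int = 2000      # gene pool enzymes draw annotations from
    n_diseases: int = 120
    n_disease_classes: int = 18
    genes_per_disease: tuple[int, int] = (10, 30)
    n_planted_diseases: int = 60
    signal_fraction: float = 0.6        # fraction of a planted disease's genes from its targets
    n_targets_per_disease: int = 2      # targets an auto-planted disease splits its signal over
    planted_pairs: list[tuple[str, str | None, float]] | None = None
    class_assortativity: float = 0.5    # P(same-class planted disease reuses the class target)
    trend_strengths: dict[str, float] = field(
        default_factory=lambda: {"disease": 1.0, "essential": -1.0, "hk": 0.0, "ts": 1.0}
    )
    base_rates: dict[str, float] = field(
        default_factory=lambda: {"disease": 0.30, "essential": 0.25, "hk": 0.20, "ts": 0.15}
    )
    coexpression_block_r: float = 0.5
    n_tissues: int = 36
    noise_sd: float = 1.0
    k: int = 3
    alpha: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        for name in ("edge_density", "signal_fraction", "class_assortativity",
                     "coexpression_block_r"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("enzymes_per_pathway", "genes_per_enzyme", "genes_per_disease"):
            lo, hi = getattr(self, name)
            if not 1 <= lo <= hi:
                raise ValueError(f"{name} range ({lo}, {hi}) is infeasible")
        if self.n_planted_diseases > self.n_diseases:
            raise ValueError("more planted diseases than diseases")
        if self.n_tissues < 3:
            raise ValueError("need at least 3 tissues")


@dataclass
class GroundTruth:
    """What was planted, for scoring recovery after the pipeline runs."""

    planted_edges: list[tuple[str, str]] = field(default_factory=list)
    target_pathway: dict[str, list[str]] = field(default_factory=dict)  # disease -> target pathways
    disease_classes: dict[str, str] = field(default_factory=dict)
    trend_directions: dict[str, int] = field(default_factory=dict)  # class -> -1/0/+1
    coexpression_blocks: list[list[str]] = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True, default=list)
            fh.write("\n")


def _rng(design: SimulationDesign, stage: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=design.seed, spawn_key=(stage,))
    )


# ---------------------------------------------------------------------------
# pathways

def simulate_pathways(
    design: SimulationDesign,
) -> tuple[list[PathwayDefinition], GeneAnnotationMap]:
    """Random connected enzyme graphs realized as reaction lists.

    Each pathway graph is a random chain over its enzymes plus extra
    edges added with probability ``edge_density``; each graph edge is
    realized as one compound produced by one endpoint's reaction and
    consumed by the other's, so converting the reactions back to an
    enzyme graph reproduces the edge set exactly.  Every enzyme is
    annotated with at least one gene from the background pool; genes are
    assigned without replacement across enzymes, so distinct enzymes
    (and hence distinct pathways' subpathways) carry disjoint gene sets
    and downstream per-subpathway statistics are independent draws.
    """
    design.validate()
    rng = _rng(design, 0)
    pool = list(rng.permutation([f"g{i:04d}" for i in range(design.n_background_genes)]))
    next_gene = iter(pool)
    pathways: list[PathwayDefinition] = []
    ann = GeneAnnotationMap()
    lo_e, hi_e = design.enzymes_per_pathway
    lo_g, hi_g = design.genes_per_enzyme
    for p in range(design.n_pathways):
        pid = f"path:{p:05d}"
        n = int(rng.integers(lo_e, hi_e + 1))
        enzymes = [f"{p + 1}.{j + 1}.1.1" for j in range(n)]
        # connected: random chain + density extra edges
        order = rng.permutation(n)
        edges = {tuple(sorted((int(order[i]), int(order[i + 1])))) for i in range(n - 1)}
        for i in range(n):
            for j in range(i + 1, n):
                if (i, j) not in edges and rng.random() < design.edge_density:
                    edges.add((i, j))
        # realize: one reaction per enzyme, one handoff compound per edge
        subs: list[list[str]] = [[] for _ in range(n)]
        prods: list[list[str]] = [[] for _ in range(n)]
        for e_idx, (i, j) in enumerate(sorted(edges)):
            c = f"cpd:{p:05d}_{e_idx:04d}"
            prods[i].append(c)
            subs[j].append(c)
        reactions = [
            Reaction(
                reaction_id=f"rn:{pid}_{j}",
                substrates=tuple(subs[j]),
                products=tuple(prods[j]),
                enzymes=(enzymes[j],),
                reversible=False,
            )
            for j in range(n)
        ]
        pathways.append(
            PathwayDefinition(
                pathway_id=pid,
                name=f"simulated pathway {p}",
                reactions=reactions,
                class_label=SUBPATHWAY_CLASSES[p % len(SUBPATHWAY_CLASSES)],
            )
        )
        for ec in enzymes:
            n_genes = int(rng.integers(lo_g, hi_g + 1))
            try:
                for _ in range(n_genes):
                    ann.add(next(next_gene), ec)
            except StopIteration:
                raise ValueError(
                    "n_background_genes too small for the requested "
                    "pathway/annotation ranges"
                ) from None
    return pathways, ann


# ---------------------------------------------------------------------------
# diseases

def simulate_diseases(
    design: SimulationDesign, subpathways: list[Subpathway]
) -> tuple[list[DiseaseGeneSet], GroundTruth]:
    """Disease gene sets with enrichment signal planted on target subpathways.

    A planted disease draws ``signal_fraction`` of its genes from its
    target subpathway's gene set and the rest uniformly from the rest of
    the background; unplanted diseases draw all genes uniformly.  Each
    disease class prefers one subpathway class; with probability
    ``class_assortativity`` a planted disease picks its target from that
    preferred class's subpathways (a small pool, so same-class diseases
    often share exact targets and same-class subpathways share
    diseases), otherwise uniformly from all eligible subpathways.  This
    plants class clustering on both sides of the bipartite network.
    """
    design.validate()
    rng = _rng(design, 1)
    background = sorted({g for sp in subpathways for g in sp.gene_set})
    if not background:
        raise ValueError("subpathways carry no genes")
    by_id = {sp.subpathway_id: sp for sp in subpathways}

    lo_d, hi_d = design.genes_per_disease
    n_targets = max(1, design.n_targets_per_disease)
    max_share = math.ceil(design.signal_fraction * hi_d / n_targets)
    eligible = [sp.subpathway_id for sp in subpathways if len(sp.gene_set) >= max_share]
    eligible_by_class: dict[str, list[str]] = {}
    for sp in subpathways:
        if sp.subpathway_id in set(eligible):
            eligible_by_class.setdefault(sp.class_label, []).append(sp.subpathway_id)
    n_cls = len(SUBPATHWAY_CLASSES)

    disease_ids = [f"D{i:03d}" for i in range(design.n_diseases)]
    classes = [f"class_{i % design.n_disease_classes:02d}"
               for i in range(design.n_diseases)]

    if design.planted_pairs is not None:
        plan = list(design.planted_pairs)
    else:
        plan = [(disease_ids[i], None, design.signal_fraction)
                for i in range(design.n_planted_diseases)]
    planned: dict[str, tuple[str | None, float]] = {d: (t, f) for d, t, f in plan}

    truth = GroundTruth(
        disease_classes=dict(zip(disease_ids, classes)),
        trend_directions={
            cls: int(np.sign(v)) for cls, v in design.trend_strengths.items()
        },
    )
    diseases: list[DiseaseGeneSet] = []
    for did, cls in zip(disease_ids, classes):
        n_genes = int(rng.integers(lo_d, hi_d + 1))
        if did in planned:
            target_spec, frac = planned[did]
            if target_spec is None:
                if not eligible:
                    raise ValueError(
                        "no subpathway large enough for the requested signal_fraction"
                    )
                cls_idx = int(cls.rsplit("_", 1)[-1])
                preferred = eligible_by_class.get(
                    SUBPATHWAY_CLASSES[cls_idx % n_cls], []
                )
                pool = preferred if (
                    preferred and rng.random() < design.class_assortativity
                ) else eligible
                t = min(n_targets, len(pool))
                target_ids = [str(s) for s in rng.choice(pool, size=t, replace=False)]
            else:
                target_ids = [target_spec]
            n_signal = round(frac * n_genes)
            shares = [n_signal // len(target_ids)] * len(target_ids)
            for i in range(n_signal % len(target_ids)):
                shares[i] += 1
            signal: set[str] = set()
            target_genes: set[str] = set()
            for tid, share in zip(target_ids, shares):
                target = by_id[tid]
                target_genes |= target.gene_set
                if share > len(target.gene_set):
                    raise ValueError(
                        f"signal_fraction needs {share} genes but target "
                        f"{tid} has only {len(target.gene_set)}"
                    )
                signal |= set(rng.choice(sorted(target.gene_set - signal),
                                         size=min(share, len(target.gene_set - signal)),
                                         replace=False))
                truth.planted_edges.append((did, tid))
            truth.target_pathway[did] = sorted({by_id[t].pathway_id for t in target_ids})
            rest_pool = [g for g in background if g not in target_genes]
            noise = set(rng.choice(rest_pool, size=max(0, n_genes - len(signal)),
                                   replace=False))
            genes = frozenset(signal | noise)
        else:
            genes = frozenset(rng.choice(background, size=n_genes, replace=False))
        diseases.append(DiseaseGeneSet(disease_id=did, disease_class=cls, genes=genes))
    return diseases, truth


def recovery_stats(
    network_edges: set[tuple[str, str]],
    truth: GroundTruth,
    diseases: list[DiseaseGeneSet],
    subpathways: list[Subpathway],
) -> tuple[float, float]:
    """(sensitivity, false-positive rate) of planted-edge recovery.

    Sensitivity is the fraction of planted disease-target edges present
    in the network.  The FPR denominator excludes, for each planted
    disease, the other subpathways of its targets' pathways: those
    overlap the targets' gene sets by construction and genuinely contain
    part of the planted signal, so calling them is not an error of the
    method.
    """
    planted = set(truth.planted_edges)
    sens = sum(1 for e in planted if e in network_edges) / len(planted) if planted else math.nan
    pathway_of = {sp.subpathway_id: sp.pathway_id for sp in subpathways}
    fp = n_null = 0
    for d in diseases:
        target_pws = set(truth.target_pathway.get(d.disease_id, ()))
        for sp in subpathways:
            pair = (d.disease_id, sp.subpathway_id)
            if pair in planted:
                continue
            if pathway_of[sp.subpathway_id] in target_pws:
                continue
            n_null += 1
            if pair in network_edges:
                fp += 1
    return sens, (fp / n_null if n_null else math.nan)


# ---------------------------------------------------------------------------
# gene-class labels

def simulate_gene_labels(
    design: SimulationDesign,
    subpathways: list[Subpathway],
    net_degrees: dict[str, int],
) -> GeneClassLabels:
    """Gene-class memberships whose prevalence trends with subpathway degree.

    For each gene the degree score is the highest network degree among
    the subpathways containing it (0 when it sits in none), standardised
    across genes.  Membership in each class is Bernoulli with a logistic
    probability: logit(base rate) + trend strength x score.  Positive
    strengths (disease, TS by default) make the class more common in
    high-degree subpathways, negative (essential) less, zero (HK) flat.
    HK/TS disjointness is enforced by drawing them from one categorical.
    """
    rng = _rng(design, 2)
    genes = sorted({g for sp in subpathways for g in sp.gene_set})
    score = np.zeros(len(genes))
    gidx = {g: i for i, g in enumerate(genes)}
    for sp in subpathways:
        deg = net_degrees.get(sp.subpathway_id, 0)
        for g in sp.gene_set:
            score[gidx[g]] = max(score[gidx[g]], deg)
    if score.std() > 0:
        score = (score - score.mean()) / score.std()

    def probs(cls: str) -> np.ndarray:
        b0 = math.log(design.base_rates[cls] / (1 - design.base_rates[cls]))
        return 1 / (1 + np.exp(-(b0 + design.trend_strengths[cls] * score)))

    p_dis, p_ess = probs("disease"), probs("essential")
    p_hk, p_ts = probs("hk"), probs("ts")
    # one categorical draw keeps HK and TS disjoint; HK occupies [0, p_hk)
    # so its marginal is exactly p_hk (flat by default), and TS is capped
    # at the remaining mass when its logistic probability would overlap
    p_ts = np.minimum(p_ts, 1 - p_hk)

    u_dis, u_ess, u_cat = rng.random(len(genes)), rng.random(len(genes)), rng.random(len(genes))
    disease = {g for g, u, p in zip(genes, u_dis, p_dis) if u < p}
    essential = {g for g, u, p in zip(genes, u_ess, p_ess) if u < p}
    hk = {g for g, u, ph in zip(genes, u_cat, p_hk) if u < ph}
    ts = {g for g, u, ph, pt in zip(genes, u_cat, p_hk, p_ts) if ph <= u < ph + pt}
    return GeneClassLabels(
        disease_genes=frozenset(disease),
        essential_genes=frozenset(essential),
        housekeeping_genes=frozenset(hk),
        tissue_specific_genes=frozenset(ts),
    )


# ---------------------------------------------------------------------------
# expression

def simulate_expression(
    design: SimulationDesign,
    labels: GeneClassLabels,
    subpathways: list[Subpathway],
    block_subpathway_ids: list[str] | None = None,
) -> tuple[pd.DataFrame, list[list[str]]]:
    """Genes x tissues matrix with planted within-subpathway coexpression blocks.

    For each block subpathway (default: all), its disease and
    tissue-specific genes form a coexpression block sharing a latent
    tissue profile mixed at weight sqrt(r), giving expected pairwise
    Pearson correlation ~ ``coexpression_block_r`` within the block.  A
    gene belongs to at most one block (first by subpathway ID); all
    other genes are independent noise.  Returns the matrix and the list
    of blocks actually planted.
    """
    rng = _rng(design, 3)
    genes = sorted({g for sp in subpathways for g in sp.gene_set})
    T = design.n_tissues
    r = design.coexpression_block_r
    expr = rng.normal(0.0, 1.0, size=(len(genes), T))
    gidx = {g: i for i, g in enumerate(genes)}

    if block_subpathway_ids is None:
        block_subpathway_ids = sorted(sp.subpathway_id for sp in subpathways)
    by_id = {sp.subpathway_id: sp for sp in subpathways}
    assigned: set[str] = set()
    blocks: list[list[str]] = []
    for sid in sorted(block_subpathway_ids):
        sp = by_id[sid]
        members = sorted(
            (sp.gene_set & (labels.disease_genes | labels.tissue_specific_genes))
            - assigned
        )
        if len(members) < 2:
            continue
        latent = rng.normal(0.0, 1.0, size=T)
        for g in members:
            expr[gidx[g]] = math.sqrt(r) * latent + math.sqrt(1 - r) * expr[gidx[g]]
        assigned.update(members)
        blocks.append(members)
    expr *= design.noise_sd
    return (
        pd.DataFrame(expr, index=genes, columns=[f"tissue_{t:02d}" for t in range(T)]),
        blocks,
    )


# ---------------------------------------------------------------------------
# file emission (formats the readers consume)

def write_kgml(pw: PathwayDefinition, path) -> None:
    """Write a pathway as KGML that :func:`dmspn.pathway_model.parse_kgml` reads back."""
    root = ElementTree.Element("pathway", name=pw.pathway_id, title=pw.name)
    for i, ec in enumerate(sorted(pw.enzymes)):
        rxns = " ".join(r.reaction_id for r in pw.reactions if ec in r.enzymes)
        ElementTree.SubElement(
            root, "entry", id=str(i + 1), type="enzyme",
            name=f"ec:{ec}", reaction=rxns,
        )
    for r in pw.reactions:
        el = ElementTree.SubElement(
            root, "reaction", name=r.reaction_id,
            type="reversible" if r.reversible else "irreversible",
        )
        for c in r.substrates:
            ElementTree.SubElement(el, "substrate", name=c)
        for c in r.products:
            ElementTree.SubElement(el, "product", name=c)
    pretty = minidom.parseString(ElementTree.tostring(root)).toprettyxml(indent="  ")
    Path(path).write_text(pretty)


def write_gad_table(diseases: list[DiseaseGeneSet], path) -> None:
    with open(path, "w") as fh:
        fh.write("disease_id\tdisease_class\tgene_id\n")
        for d in diseases:
            for g in sorted(d.genes):
                fh.write(f"{d.disease_id}\t{d.disease_class}\t{g}\n")


def write_gene_list(genes, path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in sorted(genes)))


def write_expression_matrix(expr: pd.DataFrame, path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene_id", float_format="%.6g")


def write_all_inputs(design: SimulationDesign, outdir) -> None:
    """Emit every emulated input file plus the ground-truth JSON.

    The gene-class labels are drawn against the degrees of the network
    the planted diseases actually produce, so the emitted lists carry
    the designed ratio-degree trends.
    """
    from .enrichment import enrich_all, pathway_background
    from .mining import MiningConfig, mine_collection
    from .network import build_network, summarize_network

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pathways, ann = simulate_pathways(design)
    (outdir / "kgml").mkdir(exist_ok=True)
    for pw in pathways:
        write_kgml(pw, outdir / "kgml" / f"{pw.pathway_id.replace(':', '_')}.xml")
    with open(outdir / "gene_annotations.tsv", "w") as fh:
        fh.write("# gene_id <tab> ec\n")
        for gene, ec in ann.items():
            fh.write(f"{gene}\t{ec}\n")
    subpathways = mine_collection(pathways, MiningConfig(k=design.k), ann)
    diseases, truth = simulate_diseases(design, subpathways)
    write_gad_table(diseases, outdir / "gene_disease.tsv")
    results = enrich_all(diseases, subpathways, pathway_background(subpathways),
                         design.alpha)
    degrees = summarize_network(build_network(results)).subpathway_degrees
    labels = simulate_gene_labels(design, subpathways, degrees)
    for name, genes in (
        ("disease_genes", labels.disease_genes),
        ("essential_genes", labels.essential_genes),
        ("housekeeping_genes", labels.housekeeping_genes),
        ("tissue_specific_genes", labels.tissue_specific_genes),
    ):
        write_gene_list(genes, outdir / f"{name}.txt")
    expr, _ = simulate_expression(design, labels, subpathways)
    write_expression_matrix(expr, outdir / "expression.tsv")
    truth.to_json(outdir / "ground_truth.json")
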