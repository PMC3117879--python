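"""Gene-class composition of subpathways and coexpression contrasts.

Each subpathway in the network is profiled for the fraction of its genes
that are disease genes, essential genes (mouse-lethal orthologs),
housekeeping (HK) genes, or tissue-specific (TS) genes.  Ordinary least
squares of each ratio on the subpathway's network degree tests whether
highly disease-connected subpathways are enriched or depleted for a gene
class.  Coexpression (Pearson by default) of disease genes with each
other class is averaged per subpathway and contrasted with the all-pairs
background by a Wilcoxon rank-sum test.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .mining import Subpathway
from .network import BipartiteNetwork, summarize_network

log = logging.getLogger(__name__)

COEXPR_GROUPS = (
    "disease_disease",
    "disease_essential",
    "disease_hk",
    "disease_ts",
    "disease_other",
    "all_all",
)


@dataclass(frozen=True)
class GeneClassLabels:
    disease_genes: frozenset[str]
    essential_genes: frozenset[str]
    housekeeping_genes: frozenset[str]
    tissue_specific_genes: frozenset[str]

    def __post_init__(self) -> None:
        if self.housekeeping_genes & self.tissue_specific_genes:
            raise ValueError("housekeeping and tissue-specific sets must be disjoint")


@dataclass
class SubpathwayGeneProfile:
    subpathway_id: str
    degree: int
    n_genes: int
    ratio_disease: float
    ratio_essential: float
    ratio_hk: float
    ratio_ts: float


@dataclass
class TrendResult:
    slope: float
    intercept: float
    p_value: float
    n: int


@dataclass
class CoexpressionSummary:
    per_subpathway: pd.DataFrame          # index subpathway_id, one column per group
    medians: dict[str, float]             # per-group median across subpathways
    wilcoxon_p: dict[str, float]          # each group vs the all_all background
    n_genes_missing_from_expr: int = 0


def gene_ratio_profiles(
    net: BipartiteNetwork,
    subpathways: list[Subpathway],
    labels: GeneClassLabels,
) -> list[SubpathwayGeneProfile]:
    """One gene-class profile per subpathway node of the network."""
    by_id = {sp.subpathway_id: sp for sp in subpathways}
    degrees = summarize_network(net).subpathway_degrees
    out: list[SubpathwayGeneProfile] = []
    for sid in sorted(net.subpathway_nodes):
        sp = by_id.get(sid)
        if sp is None:
            raise KeyError(f"network subpathway {sid!r} missing from subpathway list")
        if not sp.gene_set:
            log.warning("subpathway %s has an empty gene set; excluded", sid)
            continue
        n = len(sp.gene_set)
        out.append(
            SubpathwayGeneProfile(
                subpathway_id=sid,
                degree=degrees[sid],
                n_genes=n,
                ratio_disease=len(sp.gene_set & labels.disease_genes) / n,
                ratio_essential=len(sp.gene_set & labels.essential_genes) / n,
                ratio_hk=len(sp.gene_set & labels.housekeeping_genes) / n,
                ratio_ts=len(sp.gene_set & labels.tissue_specific_genes) / n,
            )
        )
    return out


def trend_test(profiles: list[SubpathwayGeneProfile], ratio_field: str) -> TrendResult:
    """OLS of a gene-class ratio on subpathway degree; two-sided slope t-test."""
    if len(profiles) < 3:
        raise ValueError("need at least 3 profiles")
    x = np.array([p.degree for p in profiles], dtype=float)
    y = np.array([getattr(p, ratio_field) for p in profiles], dtype=float)
    if x.std() == 0:
        raise ValueError("zero variance in degree; trend undefined")
    res = stats.linregress(x, y)
    return TrendResult(slope=float(res.slope), intercept=float(res.intercept),
                       p_value=float(res.pvalue), n=len(profiles))


def binned_summary(x, y, n_bins: int = 10) -> pd.DataFrame:
    """Equal-count bins on x; per-bin mean and sd of y.

    Returns a DataFrame with columns bin_center (mean x in bin), mean_y,
    sd_y, n (sd is the population standard deviation).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if n_bins > len(x):
        raise ValueError(f"n_bins={n_bins} exceeds number of points {len(x)}")
    order = np.argsort(x, kind="stable")
    rows = []
    for chunk in np.array_split(order, n_bins):
        rows.append(
            {
                "bin_center": float(x[chunk].mean()),
                "mean_y": float(y[chunk].mean()),
                "sd_y": float(y[chunk].std()),
                "n": len(chunk),
            }
        )
    return pd.DataFrame(rows)


def pairwise_coexpression(
    expr: pd.DataFrame,
    genesA: frozenset[str] | set[str],
    genesB: frozenset[str] | set[str],
    method: str = "pearson",
) -> float:
    """Mean correlation over unordered distinct pairs (a in A, b in B).

    ``expr`` holds genes in rows, tissues in columns.  Genes absent from
    the matrix or with zero expression variance are dropped.  Returns NaN
    (an undefined-result sentinel, not zero) when no admissible pair
    remains.
    """
    usable = {
        g for g in (set(genesA) | set(genesB))
        if g in expr.index and expr.loc[g].std() > 0
    }
    a = sorted(set(genesA) & usable)
    b = sorted(set(genesB) & usable)
    if not a or not b:
        return math.nan
    if set(a) == set(b):
        pairs = list(itertools.combinations(a, 2))
    else:
        pairs = sorted({tuple(sorted((g, h))) for g in a for h in b if g != h})
    if not pairs:
        return math.nan
    genes = sorted({g for p in pairs for g in p})
    sub = expr.loc[genes]
    if method == "pearson":
        cm = np.corrcoef(sub.to_numpy())
    elif method == "spearman":
        cm = stats.spearmanr(sub.to_numpy(), axis=1).statistic
        cm = np.atleast_2d(cm)
    else:
        raise ValueError(f"unknown coexpression method {method!r}")
    gidx = {g: i for i, g in enumerate(genes)}
    return float(np.mean([cm[gidx[g], gidx[h]] for g, h in pairs]))


def coexpression_summary(
    net: BipartiteNetwork,
    subpathways: list[Subpathway],
    labels: GeneClassLabels,
    expr: pd.DataFrame,
    method: str = "pearson",
) -> CoexpressionSummary:
    """Per-subpathway group coexpression averages and Wilcoxon contrasts.

    For each subpathway in the network the mean pairwise correlation is
    computed for disease-disease, disease-essential, disease-HK,
    disease-TS, disease-other and all-all gene pairs.  Group medians are
    taken across subpathways where the group has at least one admissible
    pair, and each group is compared with the all-all background by a
    two-sided Wilcoxon rank-sum test.
    """
    by_id = {sp.subpathway_id: sp for sp in subpathways}
    missing = {
        g for sp in by_id.values() for g in sp.gene_set
        if sp.subpathway_id in net.subpathway_nodes and g not in expr.index
    }
    if missing:
        log.info("%d subpathway genes absent from the expression matrix", len(missing))

    rows: dict[str, dict[str, float]] = {}
    for sid in sorted(net.subpathway_nodes):
        gs = by_id[sid].gene_set
        dis = gs & labels.disease_genes
        other = gs - labels.disease_genes - labels.essential_genes \
            - labels.housekeeping_genes - labels.tissue_specific_genes
        rows[sid] = {
            "disease_disease": pairwise_coexpression(expr, dis, dis, method),
            "disease_essential": pairwise_coexpression(
                expr, dis, gs & labels.essential_genes, method),
            "disease_hk": pairwise_coexpression(
                expr, dis, gs & labels.housekeeping_genes, method),
            "disease_ts": pairwise_coexpression(
                expr, dis, gs & labels.tissue_specific_genes, method),
            "disease_other": pairwise_coexpression(expr, dis, other, method),
            "all_all": pairwise_coexpression(expr, gs, gs, method),
        }
    table = pd.DataFrame.from_dict(rows, orient="index")[list(COEXPR_GROUPS)]

    medians: dict[str, float] = {}
    wilcoxon_p: dict[str, float] = {}
    background = table["all_all"].dropna()
    for grp in COEXPR_GROUPS:
        vals = table[grp].dropna()
        medians[grp] = float(vals.median()) if len(vals) else math.nan
        if grp == "all_all" or not len(vals) or not len(background):
            wilcoxon_p[grp] = math.nan
            continue
        if vals.nunique() == 1 and background.nunique() == 1 \
                and vals.iloc[0] == background.iloc[0]:
            wilcoxon_p[grp] = 1.0  # identical samples convention
        else:
            wilcoxon_p[grp] = float(stats.ranksums(vals, background).pvalue)
    return CoexpressionSummary(
        per_subpathway=table,
        medians=medians,
        wilcoxon_p=wilcoxon_p,
        n_genes_missing_from_expr=len(missing),
    )


def write_profiles_table(profiles: list[SubpathwayGeneProfile], path) -> None:
    with open(path, "w") as fh:
        fh.write("subpathway_id\tdegree\tn_genes\tratio_disease\tratio_essential"
                 "\tratio_hk\tratio_ts\n")
        for p in profiles:
            fh.write(
                f"{p.subpathway_id}\t{p.degree}\t{p.n_genes}\t{p.ratio_disease:.6g}\t"
                f"{p.ratio_essential:.6g}\t{p.ratio_hk:.6g}\t{p.ratio_ts:.6g}\n"
            )
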