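"""Hypergeometric enrichment of disease gene sets in subpathways.

For a disease with n_d genes in a background of N genes, and a
subpathway with m background genes of which x are disease genes, the
enrichment P-value is the upper hypergeometric tail P(X >= x).  A
disease-subpathway pair is significant when P < alpha (default 0.01)
and at least one disease gene falls in the subpathway.  P-values are
reported raw; an optional Benjamini-Hochberg correction is available
but off by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .mining import Subpathway

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DiseaseGeneSet:
    disease_id: str
    disease_class: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"disease {self.disease_id!r}: empty gene set")
        if not self.disease_class:
            raise ValueError(f"disease {self.disease_id!r}: empty class")


@dataclass(frozen=True)
class EnrichmentResult:
    disease_id: str
    subpathway_id: str
    x: int       # disease genes in the subpathway
    m: int       # subpathway genes in the background
    n_d: int     # disease genes in the background
    N_bg: int    # background size
    p_value: float
    significant: bool


def hypergeom_pvalue(x: int, n_d: int, m: int, N_bg: int) -> float:
    """Upper-tail P(X >= x), X ~ Hypergeometric(N_bg, m, n_d)."""
    if not (0 <= x <= min(m, n_d) and m <= N_bg and n_d <= N_bg):
        raise ValueError(f"inconsistent counts x={x} n_d={n_d} m={m} N_bg={N_bg}")
    return float(stats.hypergeom.sf(x - 1, N_bg, m, n_d))


def enrich_disease(
    d: DiseaseGeneSet,
    subpathways: list[Subpathway],
    background: frozenset[str],
    alpha: float = 0.01,
) -> list[EnrichmentResult]:
    """Test one disease against every subpathway; keep pairs with x >= 1.

    Disease genes outside the background are dropped before counting.
    Every subpathway gene set must lie within the background.
    """
    if not background:
        raise ValueError("empty background")
    if not 0 < alpha <= 1:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    N_bg = len(background)
    disease_genes = d.genes & background
    n_dropped = len(d.genes) - len(disease_genes)
    if n_dropped:
        log.debug("%s: %d genes outside background dropped", d.disease_id, n_dropped)
    n_d = len(disease_genes)

    hits: list[tuple[Subpathway, int, int]] = []
    for sp in subpathways:
        if not sp.gene_set <= background:
            raise ValueError(
                f"subpathway {sp.subpathway_id!r} has genes outside the background"
            )
        x = len(disease_genes & sp.gene_set)
        if x >= 1:
            hits.append((sp, x, len(sp.gene_set)))
    if not hits:
        return []

    xs = np.array([h[1] for h in hits])
    ms = np.array([h[2] for h in hits])
    pvals = stats.hypergeom.sf(xs - 1, N_bg, ms, n_d)
    return [
        EnrichmentResult(
            disease_id=d.disease_id,
            subpathway_id=sp.subpathway_id,
            x=int(x),
            m=int(m),
            n_d=n_d,
            N_bg=N_bg,
            p_value=float(p),
            significant=bool(p < alpha),
        )
        for (sp, x, m), p in zip(hits, pvals)
    ]


def enrich_all(
    diseases: list[DiseaseGeneSet],
    subpathways: list[Subpathway],
    background: frozenset[str],
    alpha: float = 0.01,
    fdr: bool = False,
) -> list[EnrichmentResult]:
    """Test every disease; results ordered by (disease, subpathway) as given.

    With ``fdr=True`` the significance flag is re-derived from
    Benjamini-Hochberg adjusted P-values at level alpha (the raw
    p_value field is unchanged).
    """
    seen: set[str] = set()
    for d in diseases:
        if d.disease_id in seen:
            raise ValueError(f"duplicate disease_id {d.disease_id!r}")
        seen.add(d.disease_id)
    results: list[EnrichmentResult] = []
    for d in diseases:
        results.extend(enrich_disease(d, subpathways, background, alpha))
    if fdr and results:
        adj = stats.false_discovery_control([r.p_value for r in results], method="bh")
        results = [
            EnrichmentResult(
                r.disease_id, r.subpathway_id, r.x, r.m, r.n_d, r.N_bg,
                r.p_value, bool(q < alpha),
            )
            for r, q in zip(results, adj)
        ]
    return results


def pathway_background(subpathways: list[Subpathway]) -> frozenset[str]:
    """Default enrichment universe: all genes annotated to any subpathway."""
    out: set[str] = set()
    for sp in subpathways:
        out |= sp.gene_set
    return frozenset(out)


def write_enrichment_table(results: list[EnrichmentResult], path) -> None:
    with open(path, "w") as fh:
        fh.write("disease_id\tsubpathway_id\tx\tm\tn_d\tN_bg\tp_value\tsignificant\n")
        for r in results:
            fh.write(
                f"{r.disease_id}\t{r.subpathway_id}\t{r.x}\t{r.m}\t{r.n_d}\t"
                f"{r.N_bg}\t{r.p_value:.17g}\t{int(r.significant)}\n"
            )


def read_enrichment_table(path) -> list[EnrichmentResult]:
    out: list[EnrichmentResult] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("disease_id"):
            raise ValueError(f"unexpected enrichment table header: {header!r}")
        for line in fh:
            did, sid, x, m, n_d, N_bg, p, sig = line.rstrip("\n").split("\t")
            out.append(
                EnrichmentResult(did, sid, int(x), int(m), int(n_d), int(N_bg),
                                 float(p), bool(int(sig)))
            )
    return out
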