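# dmspn — disease–metabolic subpathway networks

`dmspn` builds and analyses bipartite networks linking human diseases to
*metabolic subpathways* — local regions of metabolic pathways in which
every pair of enzymes lies within a small graph distance of each other.
It is aimed at systems-biology researchers who want to ask which local
regions of metabolism are disrupted across many diseases at once, and
how the wiring of that disease–subpathway map relates to disease
classes, gene essentiality, and gene coexpression.

## The method

1. **Pathways to enzyme graphs.** Each metabolic pathway (KGML format)
   becomes an undirected graph with enzymes (EC numbers) as nodes; two
   enzymes are adjacent when they catalyse the same reaction or when a
   compound produced by one is consumed by the other. An optional
   currency-metabolite blacklist suppresses edges mediated by ubiquitous
   compounds (ATP, H2O, ...).
2. **k-clique subpathway mining.** A subpathway is a maximal enzyme set
   with pairwise shortest-path distance ≤ k in the pathway graph
   (distance-k clique semantics: distances are measured in the whole
   graph, not the induced subgraph). Mining reduces to maximal-clique
   enumeration (Bron–Kerbosch) on the k-th graph power. Default k = 3.
3. **Enrichment.** For a disease with *n* genes in a background of *N*
   pathway-annotated genes, and a subpathway with *m* genes of which *x*
   are disease genes, the association P-value is the hypergeometric
   upper tail

   P = Σ_{j≥x} C(m, j)·C(N−m, n−j) / C(N, n)

   and a disease–subpathway edge is kept when P < α (default 0.01).
4. **Network statistics.** Global features (edge count, density, giant
   component, degree-distribution breadth as the coefficient of
   variation) are compared against an ensemble of random networks in
   which every disease's gene set is replaced by a size-matched uniform
   draw from the background and the whole pipeline is rerun.
5. **Class clustering.** On the one-mode projection of each side
   (nodes adjacent when they share a neighbour), every class gets a
   dyadicity BD = m11/E[m11] and heterophilicity BH = m10/E[m10], where
   m11/m10 count within-class and class-to-outside edges and the
   expectations assume random label placement (analytic or permutation).
   BD > 1 with BD > BH indicates class clustering. Disease diversity of
   a subpathway is its number of distinct neighbour disease classes over
   all classes. The incidence matrix is also hierarchically clustered
   (city-block distance, complete linkage).
6. **Gene correlates.** Per subpathway, the fractions of disease,
   essential (mouse-lethal ortholog), housekeeping and tissue-specific
   genes are regressed on the subpathway's degree (OLS, two-sided slope
   test), and mean pairwise Pearson coexpression of disease genes with
   each class is contrasted against the all-pairs background with a
   Wilcoxon rank-sum test.

A seeded synthetic-data module generates every input with known ground
truth — random enzyme graphs realized as reaction lists, disease gene
sets with planted subpathway enrichment, gene-class labels with planted
degree trends, and an expression matrix with planted coexpression
blocks — so the full pipeline is testable end to end without downloads.

## Worked example

```python
from dmspn.pipeline import run_simulated_study
from dmspn.synthetic import SimulationDesign, recovery_stats

study = run_simulated_study(SimulationDesign(seed=1))
s = study.summary
print(f"{len(study.subpathways)} subpathways mined; network: "
      f"{s.n_diseases} diseases, {s.n_subpathways} subpathways, {s.n_edges} edges")
edges = {(d, sp) for d, sp, _ in study.network.edges}
sens, fpr = recovery_stats(edges, study.truth, study.diseases, study.subpathways)
print(f"planted-edge sensitivity {sens:.2f}, false-positive rate {fpr:.4f}")
```

prints

```
52 subpathways mined; network: 70 diseases, 46 subpathways, 146 edges
planted-edge sensitivity 1.00, false-positive rate 0.0023
```

i.e. the 60 planted diseases (120 simulated, half carrying signal on two
target subpathways each) are all recovered at α = 0.01, with 0.23% of
null disease–subpathway pairs called by chance. Class statistics on the
same study give a mean disease-class dyadicity of 2.08 against a mean
heterophilicity of 0.99 — planted same-class targeting shows up as
within-class clustering — and the disease–tissue-specific coexpression
median (0.51) clearly exceeds the all-pairs control (0.11).

The command-line interface mirrors the library: `dmspn simulate` emits a
synthetic input tree (KGML files, association tables, gene lists,
expression matrix), and `dmspn all --config cfg.yaml` runs mining,
enrichment, network assembly, class statistics and gene correlates,
writing TSV/JSON outputs plus a run manifest.

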