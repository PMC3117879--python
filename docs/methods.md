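# Methods

This note documents the models and procedures implemented in `dmspn`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical conventions.

## Enzyme graphs

A pathway is a list of reactions; each reaction carries substrate and
product compound IDs, the EC numbers catalysing it, and a reversibility
flag read from KGML. The enzyme graph places an undirected edge between
enzymes A ≠ B when (i) both appear on one reaction, or (ii) some
compound is a product of a reaction of A and a substrate of a reaction
of B (either direction; reversible reactions contribute both
orientations). Compound-mediated adjacency is the only linkage rule —
KGML relation elements are ignored — because it is fully reproducible
from the reaction list alone. A currency-metabolite blacklist removes
edges mediated only by ubiquitous compounds; it is off by default
(conservative: no edge is silently dropped), and a starter list of
ATP/NAD(P)H/H2O-class KEGG compound IDs ships with the package
(`dmspn.pathway_model.default_currency_blacklist`). Each EC is its own
node even when one gene encodes several ECs; gene IDs are opaque strings
and no identifier conversion is attempted.

## Subpathway mining

A subpathway is a maximal enzyme set with pairwise shortest-path
distance ≤ k **in the whole pathway graph** (distance-k clique, not
k-club: membership does not require short paths inside the induced
subgraph). Disconnected pairs never satisfy the bound. Mining computes
the k-th graph power by per-node BFS with cutoff k and enumerates its
maximal cliques with networkx's Bron–Kerbosch. Cliques are ordered by
size descending then lexicographically, and subpathway IDs
`<pathway>_<i>` are assigned in that order, so IDs are deterministic for
identical inputs (they are not comparable across different pathway
collections). Defaults: k = 3, no minimum size (`min_enzymes = 1`); the
size floor is exposed because some applications drop very small
subpathways before enrichment.

## Enrichment

For disease gene set D and subpathway gene set S, counted inside a
background universe B (default: all genes annotated to any subpathway in
the collection, configurable to an explicit list):

- n = |D ∩ B| (disease genes outside B are dropped and logged),
- m = |S| (subpathways must be contained in B),
- x = |D ∩ S|,
- P = P(X ≥ x) for X ~ Hypergeometric(N = |B|, m, n), one-sided
  over-representation with a strict "≥ x" tail.

Pairs with x = 0 are not reported; a pair is significant when
P < α (default 0.01) — raw P-values, no multiplicity correction, with an
optional Benjamini–Hochberg flag off by default because the analysis is
deliberately threshold-compatible with single-test usage. The test is
implemented with `scipy.stats.hypergeom.sf` and verified in the suite
against exhaustive pmf summation over the full parameter grid N ≤ 12.

## Network assembly and the null ensemble

Significant pairs become the edges of a bipartite network; only edge
endpoints are admitted as nodes, so every node has degree ≥ 1. Summaries
report per-side node counts, edge count, mean degrees, density
(edges / (diseases × subpathways) over retained nodes), and the giant
connected component.

The null ensemble replaces every disease's gene set with a uniform
without-replacement draw of the same size from the background and reruns
enrichment and assembly; R replicates (default 200; the acceptance
script uses 100) are driven by one seeded generator, so the ensemble is
replicate-for-replicate reproducible. Because a null replicate usually
retains very few nodes, its *retained-node density* is not comparable to
the observed network's; the ensemble therefore also records each
replicate's **edge count**, which lives on the fixed candidate space
(all diseases × all subpathways) and is the statistic used for the
"denser than chance" contrast. Empirical P-values use the add-one
estimator (1 + #extreme)/(1 + R), which cannot return zero. Breadth of a
degree distribution is operationalized as the coefficient of variation
(sd/mean, population convention); plain variance is available behind a
flag.

## Class structure

BD/BH are computed on the unweighted one-mode projection of each side:
two nodes adjacent when they share at least `min_shared` (default 1)
neighbours. For a class with n1 members, m11 counts projection edges
inside the class and m10 edges from the class to the rest. Expectations
under random label placement come either analytically — every pair
connected independently with the projection's mean edge probability
p̄ = 2M/(N(N−1)), giving E[m11] = p̄·n1(n1−1)/2 and
E[m10] = p̄·n1(N−n1) — or by averaging m11, m10 over uniform
relabelings that preserve class sizes. Under uniform relabeling
E[m11] and E[m10] equal the analytic values exactly, which the suite
checks by Monte-Carlo agreement. BD = m11/E[m11], BH = m10/E[m10]; a
zero expectation (e.g. a class covering all nodes, leaving no
complement) makes the statistic undefined for that class — such classes
are reported with NaN and excluded from averages, which are unweighted
across classes (classes, not nodes, are the units). This projection
construction of the bipartite BD/BH is this package's own definition;
other operationalizations (hypergeometric shared-neighbour nulls,
edge-rewiring nulls) would give different absolute values, so only
qualitative statements (BD > 1, BD > BH) should be compared across
implementations.

Disease diversity of a subpathway is the number of distinct disease
classes among its neighbours divided by the total number of classes.
Hierarchical clustering binarizes the incidence matrix (diseases ×
subpathways, rows/columns pre-sorted by ID so linkage ties break
deterministically), computes city-block (L1) pairwise distances, and
applies complete linkage per axis; leaf orders, linkage matrices, a
CDT-style ordered matrix and Newick dendrograms are exported for
external viewers. No heat-map rendering is done here.

## Gene correlates

Per network subpathway, the profile records its degree and the fractions
of its genes in each class (disease, essential, housekeeping,
tissue-specific; "other" = none of the four). Trends are ordinary least
squares of the fraction on the degree with the two-sided t-test on the
slope, fitted on per-subpathway points; binned summaries (equal-count
quantile bins, default 10) are reported separately for display and play
no role in inference. Coexpression is mean pairwise Pearson correlation
(Spearman behind a flag) over unordered distinct gene pairs; genes
absent from the expression matrix or with zero variance are dropped, and
a group with no admissible pair yields NaN, never zero. Group medians
are taken across subpathways where the group is defined, and each group
is contrasted with the all-pairs ("all–all") background — the random
control — by a two-sided Wilcoxon rank-sum test; two identical constant
samples are reported with P = 1 by convention.

## Synthetic study conditions

The generator is the package's test bench: every input is produced with
known ground truth from a single seed, at a scale where the full
pipeline runs in seconds.

- **Pathways.** 50 pathways of 8–20 enzymes: a random chain (guaranteeing
  connectivity) plus extra edges with probability 0.35. Each graph edge
  is realized as one compound produced by one endpoint and consumed by
  the other, so writing KGML and re-parsing reproduces the edge set
  exactly. At this density a pathway's diameter is usually ≤ 3, so
  mining at k = 3 yields about one subpathway per pathway; the
  per-subpathway observations used by the trend regressions are then
  approximately independent, which keeps the flat-class regression
  honest (heavily overlapping sibling subpathways would share genes and
  inflate the OLS type-I rate — a property of overlapping gene sets,
  not of the test). Overlapping-subpathway behaviour itself is exercised
  by the mining tests at lower densities.
- **Annotations.** Each enzyme gets 1–3 genes drawn without replacement
  from a pool of 2000, so distinct enzymes carry disjoint gene sets and
  the ~1000-gene annotated background gives stable hypergeometric tails.
- **Diseases.** 120 diseases in 18 classes, 10–30 genes each; 60 are
  planted. Each disease class prefers one subpathway class; with
  probability 0.5 a planted disease draws its two targets from that
  preferred pool (otherwise from all sufficiently large subpathways) and
  takes 60% of its genes from the targets' gene sets, the rest uniform.
  Two targets per disease make same-class subpathways share disease
  neighbours, planting clustering on both sides of the network; the
  preferred-pool reuse plants it on the disease side.
- **Gene-class labels.** Membership in each class is Bernoulli with a
  logistic probability in the gene's standardized subpathway-degree
  score: strengths +1 (disease), −1 (essential), 0 (housekeeping),
  +1 (tissue-specific), base rates 0.30/0.25/0.20/0.15. HK and TS come
  from one categorical draw with the HK interval first, so the TS cap
  never distorts the flat HK marginal.
- **Expression.** 36 tissues. In each network subpathway, its disease
  and tissue-specific genes form a coexpression block sharing a latent
  profile mixed at weight √r (r = 0.5 by default), giving expected
  within-block Pearson correlation ≈ r; other genes are independent
  Gaussian noise. A gene joins at most one block.

What the synthetic conditions do **not** emulate: real KEGG topology
(hub metabolites, pathway size distribution), the GAD disease
vocabulary and its curation noise, correlated disease gene sets between
related diseases beyond target sharing, and expression structure beyond
single-block latent factors. Passing the planted-recovery and
calibration suites therefore demonstrates correctness of the machinery
and its statistical calibration under controlled conditions, not
performance on real snapshots.

Evaluation convention: when scoring planted-edge recovery, the other
subpathways of a planted disease's target pathways are excluded from the
false-positive denominator — they overlap the target's gene set by
construction, so flagging them is a property of the planted signal, not
an error.

## Numerical conventions and limitations

- All randomness flows through `numpy.random.default_rng` seeded from
  the design or run seed; stage streams are spawned with fixed keys, so
  outputs are bit-reproducible across runs and platforms.
- Tables serialize floats with 17 significant digits; writer/reader
  pairs round-trip exactly and repeated runs produce byte-identical
  outputs.
- Degenerate inputs: empty pathways mine to nothing; an empty background
  or a class with zero expectation raises with a named subject;
  undefined coexpression groups propagate NaN.
- Absolute BD/BH magnitudes depend on the projection construction (see
  above) and should not be compared against values computed under a
  different bipartite adaptation.
- The trend test assumes independent per-subpathway observations; on
  collections with heavily overlapping subpathways its P-values are
  anticonservative and a cluster-aware test would be needed.
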