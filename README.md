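# focusheur

Expression-data-driven condensation of gene/protein interaction networks
and disease-gene prioritization, with a complete ROC/AUC benchmark harness
and the standard topology and expression baselines.

## The problem

Given a curated interaction network (e.g. STRING protein links) and a
replicated two-condition expression experiment (healthy vs disease),
which genes drive the disease phenotype? Purely topological rankings
(degree, PageRank, betweenness) find hubs, which are pleiotropic and
well-studied but not disease-specific; purely expression-based rankings
(|log fold change|) ignore how genes act together. `focusheur` implements
a hybrid: condense the network down to the genes and links that are
either *changed* or *highly active* in the observed conditions, and rank
genes by how long they survive increasingly strict condensation.

It is aimed at computational biologists who want either (a) a
disease-specific subnetwork for downstream pathway analysis, or (b) a
benchmarked gene ranking, including the evaluation machinery to compare
it against other methods on their own data.

## The method

Three scores are computed from mean log2 expression per condition:

* **LFC(g)** = m̄_disease(g) − m̄_healthy(g), the log2 fold change of gene g;
* **LS_d(a,b)** — the *differential link score* of edge (a,b):
  LFC(a) + LFC(b) for activation and unspecified links,
  |LFC(a) − LFC(b)| for inhibition links. Large |LS_d| marks a link whose
  activity changes between conditions;
* **LS_i(a,b)** = min( m̄_h(a)+m̄_h(b), m̄_d(a)+m̄_d(b) ) — the *interaction
  link score*: large when the link is highly active in *both* conditions.

**Condensation** keeps every element passing at least one threshold: an
edge with |LS_d| ≥ t_d or LS_i ≥ t_i, a node with |LFC| ≥ t_lfc or
incident to a kept edge. **Ranking**: sweep a strictness level q from 1
to 0 (thresholds are the per-score empirical q-quantiles, so the swept
networks are nested); genes surviving the strictest non-empty network
rank first, genes first appearing at later levels form successive tie
groups.

The **evaluation harness** scores any ranking against a gold-standard
gene set by the area under the ROC curve (tie groups advance as diagonal
segments; the trapezoidal area equals the Mann–Whitney
P(positive above negative) + ½·P(tie)), supports masking of pleiotropic
genes (≥ 10 associated diseases), restriction to each method's top 1%,
disease-specificity fractions against mismatched control datasets, a
method-similarity matrix (mean Spearman correlation), and one-sided
paired Wilcoxon comparisons between methods (exact null for n ≤ 25,
valid under ties).

## Worked example

```
$ python examples/02_rank_planted_module.py
universe: 500 genes, gold standard: 30
top of the ranking: ['G00024', 'G00079', 'G00083', 'G00354', 'G00012'] (module genes: [True, False, True, False, True])

  FocusHeuristics  AUC = 0.859
  NodeDegree       AUC = 0.693
  PageRank         AUC = 0.688
  absLFC           AUC = 0.899
```

A 500-gene scale-free network is generated with a 30-gene connected
module shifted by ±2 log2 units; the gold standard shares 80% of its
genes with the module. The condensation ranking recovers the module
(AUC 0.86 — a random gold gene beats a random non-gold gene 86% of the
time), far above the topology baselines which only see the wiring. On
mismatched (label-permuted) expression data the picture reverses — see
`examples/03_disease_specificity.py` — which is the property the hybrid
method is built for: |LFC| tracks any expression contrast, but only the
condensation ranking combines that specificity with network context
(`examples/04_method_similarity.py` shows it correlates moderately with
both the topology cluster and the expression cluster).

Real data come in as plain files: STRING protein-links (with an
ENSP-to-symbol id map, confidence filter strictly above 0.5), a TSV
expression matrix with a sample→condition file (≥ 3 replicates per
condition), and a DisGeNet-style gene–disease table. A thin CLI wires
the same pipeline: `focusheur simulate|rank|baselines|eval|benchmark`.

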