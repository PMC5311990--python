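# Methods

## Model and scores

The package assumes a two-condition, replicated log2 expression design
("healthy" vs "disease", ≥ 3 replicates each) and an undirected
interaction network whose edges may carry a sign (activation /
inhibition / unspecified) and a confidence in [0, 1]. All analysis is
restricted to the *gene universe*: genes present in both the expression
matrix and the network. Edges lose both endpoints or stay; no dangling
endpoints exist after intersection.

Per gene, the log fold change is the difference of per-condition mean
log2 expression, oriented disease − healthy. The orientation is a
convention, not a claim: every threshold acts on |LFC|, so flipping the
condition labels changes reported signs but no condensation result (this
antisymmetry is property-tested).

Per edge (a, b):

* differential link score LS_d = LFC(a) + LFC(b) for activation and
  unspecified edges; |LFC(a) − LFC(b)| for inhibition edges. The network
  is undirected, so a signed difference would depend on arbitrary
  endpoint order; the magnitude is the only symmetric choice, and the
  thresholding below uses |LS_d| anyway.
* interaction link score LS_i = min over the two conditions of the sum
  of the endpoints' mean log2 expression. It is large only when the link
  is plausibly active in *both* conditions.

Expression is assumed already log2; `scoring.log2_transform` applies
log2(x + 1) for raw intensities (pseudocount 1.0). Genes with missing
values are dropped at load time with a logged count; duplicate gene rows
(multiple probes per gene) are collapsed by their arithmetic mean — a
deliberate probe-to-gene convention, since upstream probe annotation is
out of scope.

## Condensation and the threshold sweep

Given a threshold triple (t_lfc, t_d, t_i), an edge is kept iff
|LS_d| ≥ t_d or LS_i ≥ t_i; a node is kept iff |LFC| ≥ t_lfc or it is an
endpoint of a kept edge (both endpoints of every kept edge are kept,
with no further condition on the partner — the alternative, requiring
the partner to pass a node criterion itself, would break the
edge-admission semantics). Comparisons are inclusive (≥): a score
exactly at a threshold passes. Every kept element records *why* it was
kept ("lfc" / "edge" for nodes, "ls_d" / "ls_i" for edges), which the
ranking exports.

The three scores live on incommensurate scales, so the sweep lowers them
jointly through a single strictness level q ∈ [0, 1]: t_lfc and t_d are
the empirical q-quantiles of |LFC| and |LS_d|, t_i the q-quantile of
LS_i (numpy linear-interpolation quantiles, which are monotone in q;
combined with inclusive comparisons this guarantees the swept networks
are nested). The default grid is 200 evenly spaced levels from q = 1
down to q = 0; the final level is vacuous and returns the whole
universe. 200 levels resolves tie groups finely enough that further
refinement did not change rankings in practice; it is a config knob
(`--grid`).

Ranking: genes are ordered by the first (strictest) level at which they
appear; all genes first appearing at one level form one tie group, and
universe genes never admitted before the vacuous level share the final
group. Evaluation consumes only tie groups. Within a group the order is
cosmetic but deterministic: descending best quantile-normalized score
attributable to the gene (its |LFC| quantile, or the best |LS_d| / LS_i
quantile among incident edges), then lexicographic.

## Network preprocessing

Edge lists are cleaned on load: self-loops removed, duplicate unordered
pairs collapsed keeping the maximum confidence, confidence filter
strictly above the cutoff (default 0.5, so a combined score of exactly
0.500 is dropped). STRING's integer combined_score dialect (values > 1)
is auto-detected and divided by 1000. Identifier translation (e.g. ENSP
→ HUGO symbol) is applied before filtering; edges with unmapped
endpoints are dropped with a count, never silently. Identifiers are
case-sensitive; no fuzzy matching.

## Evaluation conventions

* **ROC/AUC**: the curve is swept over tie-group cuts; each tie group is
  one diagonal segment. The trapezoidal area equals the Mann–Whitney
  statistic with the midrank convention: ties between a positive and a
  negative contribute ½. This is checked against brute-force pair
  counting to 1e-12 and cross-checked against scikit-learn.
* **Pleiotropy masking**: the "reduced" reference variant removes genes
  associated with ≥ 10 distinct diseases (counted over the *whole*
  association table, target disease included). Cutoff 10 is the default
  (`pleiotropy_cutoff`). Boundary: 10 masked, 9 retained.
* **Top-fraction restriction**: the top ceil(f·N) genes (default
  f = 0.01) keep their order; the rest collapse into one terminal tie
  group. Keeping the ROC on the full universe (rather than truncating
  it) keeps AUCs comparable across methods and on the usual 0–1 scale.
  When a tie group straddles the cut, the deterministic within-group
  order decides membership.
* **Disease specificity**: the fraction of control datasets whose AUC is
  *strictly* below the matched dataset's AUC; ties count as not-lower
  (conservative — an expression-blind method scores 0, not 0.5). All
  datasets assigned to other diseases are eligible controls.
* **Similarity matrix**: per dataset, Spearman correlation of midranks
  per method pair; mean over datasets. A fully tied ranking has no
  defined correlation and is excluded from the mean with a log entry.
  The derived distance is 1 − similarity.
* **Method comparison**: one-sided paired Wilcoxon signed-rank test.
  Zero differences are discarded (all-zero input returns p = 1 with a
  degenerate flag). For ≤ 25 non-zero pairs the null distribution of W⁺
  is enumerated exactly by sign-flip convolution over doubled midranks
  (exact even under ties, unlike the classical no-ties recursion);
  above 25, a normal approximation with tie-corrected variance and
  continuity correction. Ten straight wins give p = 2⁻¹⁰ exactly.

## Baselines

Topology measures run unweighted on the universe-intersected graph via
networkx: degree; betweenness (normalized); local (Watts–Strogatz)
clustering coefficient in high-is-better and low-is-better variants,
degree < 2 ⇒ coefficient 0; PageRank with damping 0.85 and tolerance
1e-9; HITS authority (on an undirected graph authority = hub) at the
same tolerance. |LFC| and publication-count (gene2pubmed style, missing
genes count 0) rankings are expression- and literature-only.
LocalRadiality ranks by mean shortest-path distance to the k = 100
top-|LFC| genes (ascending; k is a knob and capped at the universe
size); unreachable pairs are scored as the largest component diameter
plus one so disconnected universes remain rankable. Externally computed
rankings (e.g. moderated-t or network-perturbation methods from other
toolchains) are imported from two-column files and restricted to the
universe, with absent genes appended as a final tie group.

Because centrality scores are the product of iterative solvers, tie
grouping in `GeneRanking.from_scores` uses a relative tolerance of 1e-8
(comfortably above the 1e-9 solver tolerance, far below any real score
gap): a symmetric graph yields one tie group instead of noise-ordered
singletons.

## Synthetic benchmark generator

The generator emulates the four benchmark inputs: a Barabási–Albert
preferential-attachment network (heavy-tailed degrees, matching the
hub/pleiotropy structure of curated interactomes; attachment m = 2 gives
mean degree ≈ 4, in the range of a confidence-filtered interactome); a
connected planted module (BFS ball from a random start) whose genes get
a ±effect_size log2 shift on the disease mean; i.i.d. Gaussian
per-sample noise; baseline abundances drawn Normal(7, 1) log2 units
(typical microarray intensities, giving LS_i a realistic dynamic range);
a gold standard overlapping the module by `gold_overlap` with random
decoys for the remainder; degree-biased pleiotropic genes each annotated
to ≥ 10 pseudo-diseases; and publication counts drawn Poisson(5·degree).

Default scenario — the study condition used by the tests and the
acceptance script: 500 genes, module 30, effect size 2.0, noise sd 0.5,
3 replicates, gold overlap 0.8, pleiotropy rate 0.05, no inhibition
edges (mirroring unsigned protein-link networks). One integer seed
drives five deterministically derived substreams (topology, expression,
gold, pleiotropy, publications); repeated calls are byte-identical.

Control datasets for the specificity analysis reassign the
healthy/disease labels to a random permutation of the samples. The
identity assignment and its full complement are excluded: the complement
merely negates every LFC, which magnitude-based thresholds cannot
distinguish from the matched data, so it is not a genuine mismatch.

What the generator does *not* emulate: probe- and batch-level microarray
artifacts, correlated noise, expression–topology coupling beyond the
planted module, partial module penetrance, or multi-disease expression
compendia. Passing the synthetic benchmark therefore demonstrates the
machinery (scores, condensation, ranking, evaluation) and the intended
qualitative contrast between expression-driven and topology-driven
methods — not performance on any real disease cohort.

## Problem sizes and numerical choices

The test suite and acceptance script use 500-gene instances, 20
replicate seeds, and 10 controls per seed — large enough that AUC and
specificity estimates are stable to a few percent, small enough to run
on one CPU in minutes. AUC-oracle and condensation-oracle checks run on
hundreds of small random instances (≤ 50 genes) where brute force is
exact. Quantile thresholds use numpy's default linear interpolation;
empty edge sets fall back to vacuous edge thresholds; ROC requires at
least one positive and one negative and errors otherwise; an empty
reference set is a warning and the disease is skipped, not a crash.

## Known limitations

* The sweep couples the three thresholds through a single quantile
  level; independently optimized thresholds might condense better for a
  specific dataset but would break the nestedness that defines the
  ranking.
* Inhibition edges use |ΔLFC|; on signed, *directed* networks a signed
  convention would carry more information.
* The ranking's resolution is bounded by the grid: genes separated only
  between adjacent quantile levels tie.
* LocalRadiality's unreachable-distance convention (diameter + 1) is one
  of several reasonable choices and matters only on fragmented
  universes.
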