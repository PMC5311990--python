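"""Recover a planted disease module and compare against baselines.

Generates a 500-gene scale-free network with a 30-gene differentially
expressed module, ranks genes by the threshold sweep, and scores each
method's ranking against the synthetic gold standard by ROC AUC.
"""

from focusheur import (
    SyntheticScenario,
    auc_of_ranking,
    focus_ranking,
    generate,
    make_reference,
    rank_by_abs_lfc,
    rank_by_degree,
    rank_by_pagerank,
)
from focusheur.scoring import score_network
from focusheur.synthetic import DISEASE_ID

inst = generate(SyntheticScenario(seed=1))
ranking = focus_ranking(inst.expression, inst.network)
ref = make_reference(inst.disease_genes, DISEASE_ID, ranking.universe, "complete")
gscores, _ = score_network(inst.expression, inst.network)

print(f"universe: {len(ranking)} genes, gold standard: {len(ref.positives)}")
print(f"top of the ranking: {ranking.genes[:5]} (module genes: "
      f"{[g in inst.module for g in ranking.genes[:5]]})\n")

for name, r in [
    ("FocusHeuristics", ranking),
    ("NodeDegree", rank_by_degree(inst.network)),
    ("PageRank", rank_by_pagerank(inst.network)),
    ("absLFC", rank_by_abs_lfc(gscores)),
]:
    print(f"  {name:16s} AUC = {auc_of_ranking(r, ref):.3f}")

print("\nAUC ~ P(random gold gene ranked above a random non-gold gene); 0.5 is")
print("chance. The expression-driven methods recover the planted module; the")
print("pure topology baselines only see the scale-free wiring.")
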