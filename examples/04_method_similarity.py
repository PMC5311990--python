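"""Method-similarity matrix: which rankings agree with which?

Computes every method's ranking on one synthetic instance and prints the
pairwise Spearman correlation matrix (midrank tie handling). Topology
methods cluster together; expression methods form their own cluster; the
condensation ranking sits between them.
"""

from focusheur import SyntheticScenario, generate, similarity_matrix
from focusheur.pipeline import compute_rankings

inst = generate(SyntheticScenario(seed=3))
rankings = compute_rankings(
    inst.expression, inst.network, inst.pmid,
    methods=["focusheuristics", "degree", "betweenness", "pagerank",
             "authority", "abslfc", "pmid"],
)
sim = similarity_matrix({"instance": rankings})
print("mean pairwise Spearman rank correlation:")
print(sim.values.round(2).to_string())
print("\nValues near 1 mean two methods order the genes almost identically;")
print("near 0, independently. Degree, PageRank, HITS and PMID (publication")
print("counts track hub degree) correlate strongly; |LFC| is independent of")
print("topology; the condensation ranking shares signal with both groups.")
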