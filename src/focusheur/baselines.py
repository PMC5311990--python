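"""Comparison methods: topology centralities, expression-only scores,
publication counts, LocalRadiality, and an import path for external
rankings (e.g. Limma or DeMAND output files).

Topology measures are computed with networkx on the universe-intersected
graph, unweighted: node degree, betweenness, local (Watts–Strogatz)
clustering coefficient in a high-is-better and a low-is-better variant,
PageRank (damping 0.85) and the HITS/Authority score (on an undirected
graph authority equals hub; the principal eigenvector of the symmetric
adjacency). LocalRadiality ranks genes by their mean shortest-path
distance to the top differentially expressed genes, ascending.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import pandas as pd

from focusheur.data_io import InteractionNetwork
from focusheur.ranking import GeneRanking
from focusheur.scoring import GeneScoreTable

PAGERANK_DAMPING = 0.85
EIGEN_TOL = 1e-9


@dataclass
class PmidCounts:
    """Gene -> number of publication associations; missing genes count 0."""

    counts: dict[str, int] = field(default_factory=dict)

    def get(self, gene: str) -> int:
        return int(self.counts.get(gene, 0))


def _require_nonempty(net: InteractionNetwork) -> nx.Graph:
    if not net.nodes:
        raise ValueError("empty graph: no genes to rank")
    return net.graph


def rank_by_degree(net: InteractionNetwork) -> GeneRanking:
    g = _require_nonempty(net)
    return GeneRanking.from_scores(dict(g.degree()), method="NodeDegree")


def rank_by_betweenness(net: InteractionNetwork) -> GeneRanking:
    g = _require_nonempty(net)
    scores = nx.betweenness_centrality(g, normalized=True)
    return GeneRanking.from_scores(scores, method="Betweenness")


def rank_by_pagerank(net: InteractionNetwork) -> GeneRanking:
    g = _require_nonempty(net)
    scores = nx.pagerank(g, alpha=PAGERANK_DAMPING, tol=EIGEN_TOL)
    return GeneRanking.from_scores(scores, method="PageRank")


def rank_by_authority(net: InteractionNetwork) -> GeneRanking:
    """HITS authority; on an undirected graph every edge is bidirectional,
    so authority and hub coincide."""
    g = _require_nonempty(net)
    _, authority = nx.hits(g.to_directed(), tol=EIGEN_TOL, max_iter=10_000)
    return GeneRanking.from_scores(authority, method="HITS/Authority")


def rank_by_clustering_coefficient(
    net: InteractionNetwork, direction: str = "high"
) -> GeneRanking:
    """Local clustering coefficient, in a high- or low-is-better variant.

    Nodes of degree < 2 have coefficient 0 (no possible neighbour edges).
    """
    if direction not in ("high", "low"):
        raise ValueError("direction must be 'high' or 'low'")
    g = _require_nonempty(net)
    scores = nx.clustering(g)
    return GeneRanking.from_scores(
        scores,
        method=f"ClusterCoeff-{direction}",
        ascending=(direction == "low"),
    )


def rank_by_abs_lfc(gscores: GeneScoreTable) -> GeneRanking:
    return GeneRanking.from_scores(
        gscores.lfc.abs(), method="absLFC"
    )


def rank_by_pmid(counts: PmidCounts, universe: Sequence[str]) -> GeneRanking:
    scores = {g: counts.get(g) for g in universe}
    return GeneRanking.from_scores(scores, method="PMID")


def top_de_genes(gscores: GeneScoreTable, k: int) -> list[str]:
    """The k genes of largest |LFC| (deterministic tie-break by symbol)."""
    order = sorted(gscores.lfc.index, key=lambda g: (-abs(gscores.lfc[g]), g))
    return order[: min(k, len(order))]


def rank_by_local_radiality(
    net: InteractionNetwork, gscores: GeneScoreTable, k_de: int = 100
) -> GeneRanking:
    """Mean shortest-path distance to the top-k differentially expressed
    genes; smaller is better. An unreachable pair is scored as the largest
    component diameter plus one, so disconnected universes stay rankable.
    """
    g = _require_nonempty(net)
    genes = sorted(net.nodes)
    de = [x for x in top_de_genes(gscores, k_de) if x in net.nodes]
    if not de:
        raise ValueError("no differentially expressed genes inside the network")

    max_diameter = max(
        nx.diameter(g.subgraph(comp)) if len(comp) > 1 else 0
        for comp in nx.connected_components(g)
    )
    far = float(max_diameter + 1)

    total = {x: 0.0 for x in genes}
    for source in de:
        dist = nx.single_source_shortest_path_length(g, source)
        for x in genes:
            total[x] += dist.get(x, far)
    mean_dist = {x: total[x] / len(de) for x in genes}
    return GeneRanking.from_scores(mean_dist, method="LocalRadiality", ascending=True)


def import_ranking(
    path: str, method_name: str, universe: Sequence[str]
) -> GeneRanking:
    """Adopt an externally computed ranking (TSV ``gene\\tscore`` or
    ``gene\\trank``). The file is restricted to the universe; universe genes
    absent from the file form a final tie group.
    """
    frame = pd.read_csv(path, sep="\t", comment="#")
    if frame.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (gene, score|rank)")
    gene_col = frame.columns[0]
    value_col = "score" if "score" in frame.columns else (
        "rank" if "rank" in frame.columns else frame.columns[1]
    )
    ascending = value_col == "rank"
    frame[gene_col] = frame[gene_col].astype(str)
    in_universe = frame[frame[gene_col].isin(set(universe))]
    if in_universe.empty:
        raise ValueError(f"{path}: no overlap with the {len(universe)}-gene universe")

    partial = GeneRanking.from_scores(
        pd.Series(
            in_universe[value_col].to_numpy(dtype=float),
            index=in_universe[gene_col],
        ),
        method=method_name,
        ascending=ascending,
    )
    missing = sorted(set(universe) - set(partial.genes))
    genes = partial.genes + missing
    tie_group = list(partial.tie_group)
    if missing:
        tie_group += [partial.n_groups + 1] * len(missing)
    return GeneRanking(genes=genes, tie_group=tie_group, method=method_name)


BASELINE_BUILDERS = {
    "degree": lambda net, gscores, pmid: rank_by_degree(net),
    "betweenness": lambda net, gscores, pmid: rank_by_betweenness(net),
    "pagerank": lambda net, gscores, pmid: rank_by_pagerank(net),
    "authority": lambda net, gscores, pmid: rank_by_authority(net),
    "cc-high": lambda net, gscores, pmid: rank_by_clustering_coefficient(net, "high"),
    "cc-low": lambda net, gscores, pmid: rank_by_clustering_coefficient(net, "low"),
    "abslfc": lambda net, gscores, pmid: rank_by_abs_lfc(gscores),
    "pmid": lambda net, gscores, pmid: rank_by_pmid(pmid, sorted(net.nodes)),
    "localradiality": lambda net, gscores, pmid: rank_by_local_radiality(net, gscores),
}
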