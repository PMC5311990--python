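"""Network condensation and the threshold sweep that turns it into a ranking.

The condensation rule keeps every edge and node of the reference network
that passes at least one of three thresholds: a node passes with
|LFC| >= t_lfc, an edge passes with |LS_d| >= t_d or LS_i >= t_i, and both
endpoints of a kept edge are kept. Comparisons are inclusive, so a score
exactly at a threshold passes.

A ranking is derived by sweeping the thresholds from strict to vacuous:
genes surviving the strictest (smallest) condensed network are the most
disease-relevant, genes first appearing at the next level are the next
tier, and so on. The three thresholds are lowered jointly through a single
strictness level q in [0, 1]: t_lfc and t_d are the q-quantiles of the
empirical |LFC| and |LS_d| distributions and t_i is the q-quantile of LS_i.
The joint-quantile parameterization couples three incommensurate scales
and, with inclusive comparisons, guarantees the sweep is nested.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from focusheur.data_io import ExpressionDataset, InteractionNetwork, intersect_universe
from focusheur.ranking import GeneRanking
from focusheur.scoring import EdgeScoreTable, GeneScoreTable, score_network

METHOD_NAME = "FocusHeuristics"


@dataclass(frozen=True)
class ThresholdTriple:
    """Thresholds on |LFC| (t_lfc), |LS_d| (t_d) and LS_i (t_i)."""

    t_lfc: float
    t_d: float
    t_i: float

    def __post_init__(self) -> None:
        if self.t_lfc < 0 or self.t_d < 0:
            raise ValueError("t_lfc and t_d act on magnitudes and must be >= 0")


@dataclass
class CondensedNetwork:
    """A kept subgraph plus the admission reason for every element.

    ``node_admission`` maps a kept gene to a subset of {"lfc", "edge"};
    ``edge_admission`` maps a kept (sorted) gene pair to a subset of
    {"ls_d", "ls_i"}. Every kept element has at least one reason.
    """

    nodes: set[str]
    edges: set[tuple[str, str]]
    node_admission: dict[str, frozenset[str]] = field(default_factory=dict)
    edge_admission: dict[tuple[str, str], frozenset[str]] = field(default_factory=dict)
    level: float | None = None  # strictness q that produced this network

    def __post_init__(self) -> None:
        for a, b in self.edges:
            if a not in self.nodes or b not in self.nodes:
                raise ValueError(f"edge ({a},{b}) has an endpoint outside nodes")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def issubgraph_of(self, other: "CondensedNetwork") -> bool:
        return self.nodes <= other.nodes and self.edges <= other.edges


class _ScoreArrays:
    """Flat score arrays for fast repeated condensation."""

    def __init__(self, net: InteractionNetwork, gscores: GeneScoreTable,
                 escores: EdgeScoreTable):
        self.genes = sorted(net.nodes)
        missing = set(self.genes) - set(gscores.lfc.index)
        if missing:
            raise KeyError(f"genes without LFC: {sorted(missing)[:3]}")
        self.abs_lfc = np.abs(gscores.lfc.loc[self.genes].to_numpy())
        tab = escores.table
        pairs = {tuple(sorted(p)) for p in net.graph.edges}
        mask = [
            (a, b) in pairs for a, b in zip(tab["gene_a"], tab["gene_b"])
        ]
        tab = tab[mask] if len(tab) else tab
        if len(tab) != len(pairs):
            raise KeyError("edge score table does not cover the network")
        self.edge_a = tab["gene_a"].to_numpy() if len(tab) else np.array([])
        self.edge_b = tab["gene_b"].to_numpy() if len(tab) else np.array([])
        self.abs_lsd = np.abs(tab["ls_d"].to_numpy()) if len(tab) else np.array([])
        self.ls_i = tab["ls_i"].to_numpy() if len(tab) else np.array([])

    def condense(self, t: ThresholdTriple, level: float | None = None) -> CondensedNetwork:
        by_lsd = self.abs_lsd >= t.t_d
        by_lsi = self.ls_i >= t.t_i
        edge_kept = by_lsd | by_lsi
        by_lfc = self.abs_lfc >= t.t_lfc

        edge_admission: dict[tuple[str, str], frozenset[str]] = {}
        endpoint_nodes: set[str] = set()
        for i in np.flatnonzero(edge_kept):
            reasons = []
            if by_lsd[i]:
                reasons.append("ls_d")
            if by_lsi[i]:
                reasons.append("ls_i")
            pair = (self.edge_a[i], self.edge_b[i])
            edge_admission[pair] = frozenset(reasons)
            endpoint_nodes.update(pair)

        node_admission: dict[str, frozenset[str]] = {}
        for g, passed in zip(self.genes, by_lfc):
            reasons = []
            if passed:
                reasons.append("lfc")
            if g in endpoint_nodes:
                reasons.append("edge")
            if reasons:
                node_admission[g] = frozenset(reasons)

        return CondensedNetwork(
            nodes=set(node_admission),
            edges=set(edge_admission),
            node_admission=node_admission,
            edge_admission=edge_admission,
            level=level,
        )


def condense(
    net: InteractionNetwork,
    gscores: GeneScoreTable,
    escores: EdgeScoreTable,
    t: ThresholdTriple,
) -> CondensedNetwork:
    """Apply the keep-if-any-threshold rule once.

    An edge is kept iff |LS_d| >= t_d or LS_i >= t_i; a node is kept iff
    |LFC| >= t_lfc or it is an endpoint of a kept edge.
    """
    return _ScoreArrays(net, gscores, escores).condense(t)


def quantile_thresholds(
    q: float, arrays: _ScoreArrays
) -> ThresholdTriple:
    """Joint thresholds at strictness q: per-score empirical q-quantiles."""
    t_lfc = float(np.quantile(arrays.abs_lfc, q)) if len(arrays.abs_lfc) else 0.0
    if len(arrays.abs_lsd):
        t_d = float(np.quantile(arrays.abs_lsd, q))
        t_i = float(np.quantile(arrays.ls_i, q))
    else:
        t_d, t_i = 0.0, float("-inf")
    return ThresholdTriple(t_lfc=t_lfc, t_d=t_d, t_i=t_i)


def sweep(
    net: InteractionNetwork,
    gscores: GeneScoreTable,
    escores: EdgeScoreTable,
    grid: Sequence[float] | None = None,
    n_levels: int = 200,
) -> list[CondensedNetwork]:
    """Condense at every strictness level of a decreasing grid.

    The default grid is ``n_levels`` evenly spaced q values from 1 down
    to 0; the final (q=0) level is vacuous and keeps the full universe.
    The result is a nested sequence: each network contains its predecessor.
    """
    if grid is None:
        grid = np.linspace(1.0, 0.0, n_levels)
    grid = np.asarray(grid, dtype=float)
    if len(grid) < 1 or (np.diff(grid) >= 0).any():
        raise ValueError("grid must be strictly decreasing in strictness q")
    if grid.min() < 0 or grid.max() > 1:
        raise ValueError("grid levels must lie in [0, 1]")

    arrays = _ScoreArrays(net, gscores, escores)
    return [arrays.condense(quantile_thresholds(q, arrays), level=float(q)) for q in grid]


def rank_genes(
    sweep_result: Sequence[CondensedNetwork],
    universe: Sequence[str] | None = None,
    gscores: GeneScoreTable | None = None,
    escores: EdgeScoreTable | None = None,
    method: str = METHOD_NAME,
) -> GeneRanking:
    """Convert a nested sweep into a ranking by first appearance.

    Genes in the smallest (strictest) non-empty network rank first; genes
    first appearing at one level form one tie group; universe genes never
    appearing share a final tie group. Within a tie group, genes are
    ordered by descending quantile-normalized best score (when score
    tables are supplied) and then lexicographically — a cosmetic,
    deterministic order; evaluation uses only the tie groups.
    """
    if not sweep_result:
        raise ValueError("empty sweep")
    for prev, nxt in zip(sweep_result, sweep_result[1:]):
        if not prev.issubgraph_of(nxt):
            raise ValueError("sweep is not nested; was it produced by sweep()?")

    first_level: dict[str, int] = {}
    for k, cn in enumerate(sweep_result):
        for g in cn.nodes:
            first_level.setdefault(g, k)

    if universe is None:
        universe = sorted(sweep_result[-1].nodes | set(first_level))
    never = [g for g in universe if g not in first_level]
    sentinel = len(sweep_result)
    levels = {g: first_level.get(g, sentinel) for g in universe}

    tiebreak = _quantile_tiebreak(universe, gscores, escores)
    order = sorted(universe, key=lambda g: (levels[g], -tiebreak.get(g, 0.0), g))

    tie_group: list[int] = []
    gid = 0
    prev_level: int | None = None
    for g in order:
        if prev_level is None or levels[g] != prev_level:
            gid += 1
            prev_level = levels[g]
        tie_group.append(gid)

    first_q = {
        g: (sweep_result[lv].level if lv < sentinel else None)
        for g, lv in levels.items()
    }
    admission = {}
    for g, lv in levels.items():
        if lv < sentinel:
            admission[g] = "+".join(sorted(sweep_result[lv].node_admission[g]))
        else:
            admission[g] = "none"
    _ = never  # universe genes outside every level land in the last group
    return GeneRanking(
        genes=order,
        tie_group=tie_group,
        method=method,
        extra={"first_q": first_q, "admission": admission},
    )


def _quantile_tiebreak(
    universe: Sequence[str],
    gscores: GeneScoreTable | None,
    escores: EdgeScoreTable | None,
) -> dict[str, float]:
    """Best quantile-normalized score attributable to each gene: its |LFC|
    quantile, and the best |LS_d| / LS_i quantile among incident edges."""
    if gscores is None:
        return {}
    from scipy.stats import rankdata

    out: dict[str, float] = {}
    genes = [g for g in universe if g in gscores.lfc.index]
    abs_lfc = np.abs(gscores.lfc.loc[genes].to_numpy())
    if len(abs_lfc):
        q_lfc = rankdata(abs_lfc, method="average") / len(abs_lfc)
        out.update(zip(genes, q_lfc))
    if escores is not None and len(escores):
        tab = escores.table
        q_lsd = rankdata(np.abs(tab["ls_d"].to_numpy()), method="average") / len(tab)
        q_lsi = rankdata(tab["ls_i"].to_numpy(), method="average") / len(tab)
        best_edge = np.maximum(q_lsd, q_lsi)
        for a, b, q in zip(tab["gene_a"], tab["gene_b"], best_edge):
            for g in (a, b):
                if q > out.get(g, 0.0):
                    out[g] = float(q)
    return out


def focus_ranking(
    expr: ExpressionDataset,
    net: InteractionNetwork,
    n_levels: int = 200,
    grid: Sequence[float] | None = None,
) -> GeneRanking:
    """End-to-end convenience: intersect the universe, score, sweep, rank."""
    expr, net, universe = intersect_universe(expr, net)
    gscores, escores = score_network(expr, net)
    levels = sweep(net, gscores, escores, grid=grid, n_levels=n_levels)
    return rank_genes(levels, universe=universe, gscores=gscores, escores=escores)
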