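"""The three expression-driven scores behind the condensation heuristic.

For each gene, the log fold change (LFC) is the difference of its mean log2
expression between the disease and the healthy condition. For each network
edge two link scores are computed from the endpoint expression:

* the differential link score ``LS_d`` — the sum of the endpoint LFCs for
  activation and unspecified links, and the absolute difference of the LFCs
  for inhibition links. A large |LS_d| marks a link whose activity changes
  between conditions.
* the interaction link score ``LS_i`` — the mean log2 expression of the two
  endpoints is summed within each condition, and LS_i is the minimum of the
  two sums. A large LS_i marks a link that is highly active in both
  conditions.

The inhibition branch uses the absolute difference because the network is
undirected: the sign of "the difference" depends on an arbitrary endpoint
order, and the magnitude is the only symmetric choice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from focusheur.data_io import (
    DISEASE,
    HEALTHY,
    ExpressionDataset,
    InteractionNetwork,
)


@dataclass(frozen=True)
class ConditionMeans:
    """Per-gene arithmetic mean of log2 expression in each condition."""

    healthy: pd.Series
    disease: pd.Series


@dataclass(frozen=True)
class GeneScoreTable:
    """Per-gene LFC (disease minus healthy, log2 units)."""

    lfc: pd.Series

    @property
    def genes(self) -> list[str]:
        return list(self.lfc.index)

    def to_frame(self) -> pd.DataFrame:
        return self.lfc.rename("LFC").rename_axis("gene").reset_index()


@dataclass(frozen=True)
class EdgeScoreTable:
    """Per-edge LS_d and LS_i; one row per unordered gene pair."""

    table: pd.DataFrame  # columns: gene_a, gene_b, type, ls_d, ls_i

    def lookup(self, a: str, b: str) -> pd.Series:
        a, b = sorted((a, b))
        hit = self.table[(self.table["gene_a"] == a) & (self.table["gene_b"] == b)]
        if hit.empty:
            raise KeyError(f"no scores for edge ({a}, {b})")
        return hit.iloc[0]

    def __len__(self) -> int:
        return len(self.table)


def log2_transform(expr: ExpressionDataset, pseudocount: float = 1.0) -> ExpressionDataset:
    """log2(x + pseudocount) for raw (non-log) intensity matrices."""
    values = np.log2(expr.values + pseudocount)
    return ExpressionDataset(values, expr.condition)


def condition_means(expr: ExpressionDataset) -> ConditionMeans:
    healthy = expr.values[expr.samples_of(HEALTHY)].mean(axis=1)
    disease = expr.values[expr.samples_of(DISEASE)].mean(axis=1)
    return ConditionMeans(healthy=healthy, disease=disease)


def lfc(means: ConditionMeans) -> GeneScoreTable:
    """Log fold change, oriented disease minus healthy."""
    return GeneScoreTable(lfc=(means.disease - means.healthy).rename("LFC"))


def differential_link_score(
    a: str, b: str, edge_type: str, gscores: GeneScoreTable
) -> float:
    for g in (a, b):
        if g not in gscores.lfc.index:
            raise KeyError(f"gene {g!r} has no LFC")
    la, lb = float(gscores.lfc[a]), float(gscores.lfc[b])
    if edge_type == "inhibition":
        return abs(la - lb)
    return la + lb


def interaction_link_score(a: str, b: str, means: ConditionMeans) -> float:
    for g in (a, b):
        if g not in means.healthy.index:
            raise KeyError(f"gene {g!r} has no condition means")
    sum_h = float(means.healthy[a] + means.healthy[b])
    sum_d = float(means.disease[a] + means.disease[b])
    return min(sum_h, sum_d)


def score_network(
    expr: ExpressionDataset, net: InteractionNetwork
) -> tuple[GeneScoreTable, EdgeScoreTable]:
    """Score every gene and every edge of a universe-intersected instance.

    Vectorized over edges; equivalent to calling the per-edge functions.
    """
    missing = net.nodes - set(expr.gene_ids)
    if missing:
        raise KeyError(
            f"{len(missing)} network genes lack expression (e.g. "
            f"{sorted(missing)[:3]}); intersect the universe first"
        )
    means = condition_means(expr)
    gscores = lfc(means)

    edges = net.edge_list()
    if not edges:
        table = pd.DataFrame(columns=["gene_a", "gene_b", "type", "ls_d", "ls_i"])
        return gscores, EdgeScoreTable(table)

    a = np.array([e[0] for e in edges])
    b = np.array([e[1] for e in edges])
    etype = np.array([e[2] for e in edges])
    la = gscores.lfc.loc[a].to_numpy()
    lb = gscores.lfc.loc[b].to_numpy()
    inhib = etype == "inhibition"
    ls_d = np.where(inhib, np.abs(la - lb), la + lb)

    sum_h = means.healthy.loc[a].to_numpy() + means.healthy.loc[b].to_numpy()
    sum_d = means.disease.loc[a].to_numpy() + means.disease.loc[b].to_numpy()
    ls_i = np.minimum(sum_h, sum_d)

    table = pd.DataFrame(
        {"gene_a": a, "gene_b": b, "type": etype, "ls_d": ls_d, "ls_i": ls_i}
    )
    return gscores, EdgeScoreTable(table)


def write_score_tables(
    gscores: GeneScoreTable, escores: EdgeScoreTable, gene_path: str, edge_path: str
) -> None:
    gscores.to_frame().to_csv(gene_path, sep="\t", index=False)
    out = escores.table.rename(
        columns={"gene_a": "geneA", "gene_b": "geneB", "ls_d": "LS_d", "ls_i": "LS_i"}
    )
    out.to_csv(edge_path, sep="\t", index=False)
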